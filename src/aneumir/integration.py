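"""miRNA-target network integration with inverse-expression filtering.

Joins deregulated miRNAs to experimentally validated targets, counts
total/unique interactions, filters for miRNA-mRNA pairs whose fold changes
point in opposite directions, and scores concordance with protein-level
fold changes.

Conventions
-----------
* "Total interactions" counts one record per evidence entry; "unique
  interactions/targets" counts distinct target genes after collapsing
  multi-evidence records.
* A pair enters the inverse-expression filter only when BOTH the miRNA and
  the mRNA are deregulated; inverse means opposite call signs.
* Each (miRNA, target) pair is evaluated independently — no aggregation
  over multiple miRNAs hitting the same target.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

EVIDENCE_TIERS = ("strong", "weak")

#: miRTarBase export dialect -> internal column names
_MIRTARBASE_COLUMNS = {
    "miRNA": "mirna_id",
    "Target Gene": "target_gene_id",
    "Support Type": "evidence_tier",
}
_INTERNAL_COLUMNS = ["mirna_id", "target_gene_id", "evidence_tier"]


@dataclass
class InteractionTable:
    """Validated miRNA -> target-gene interaction records.

    Parameters
    ----------
    records
        DataFrame with columns ``mirna_id``, ``target_gene_id``,
        ``evidence_tier`` (values in :data:`EVIDENCE_TIERS`).
    provenance
        Free-text origin tag (file path, "synthetic", ...).
    causal_pairs
        Optional ground-truth subset planted by the synthetic generator
        (columns ``mirna_id``, ``target_gene_id``); used only by tests and
        recovery analyses, never by the integration logic itself.
    """

    records: pd.DataFrame
    provenance: str = ""
    causal_pairs: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        missing = [c for c in _INTERNAL_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"interaction records missing columns: {missing}")
        rec = self.records
        if len(rec):
            if rec["mirna_id"].eq("").any() or rec["target_gene_id"].eq("").any():
                raise ValueError("interaction ids must be non-empty")
            bad = set(rec["evidence_tier"]) - set(EVIDENCE_TIERS)
            if bad:
                raise ValueError(f"unknown evidence tiers: {sorted(bad)}")
        # load-time dedup on the full triple
        self.records = rec.drop_duplicates(_INTERNAL_COLUMNS, ignore_index=True)

    def __len__(self) -> int:
        return len(self.records)

    def filter_evidence(self, evidence_scope: str) -> "InteractionTable":
        """Return a table restricted to ``scope`` ('all' or 'strong')."""
        if evidence_scope == "all":
            return self
        if evidence_scope != "strong":
            raise ValueError(f"evidence_scope must be 'all' or 'strong', got {evidence_scope!r}")
        kept = self.records[self.records["evidence_tier"] == "strong"].reset_index(drop=True)
        return InteractionTable(kept, provenance=self.provenance, causal_pairs=self.causal_pairs)


def _map_support_type(value: str) -> str:
    """Map a miRTarBase 'Support Type' string to an internal evidence tier.

    'Functional MTI' is strong, any '(Weak)'-suffixed value is weak.
    """
    v = str(value).strip()
    if "(Weak)" in v:
        return "weak"
    if "Functional MTI" in v or v in EVIDENCE_TIERS:
        return v if v in EVIDENCE_TIERS else "strong"
    raise ValueError(f"unrecognized Support Type value: {value!r}")


def load_interactions(path: str | Path, evidence_scope: str = "all") -> InteractionTable:
    """Load an interaction TSV in either the miRTarBase export dialect
    (columns miRNA / Target Gene / Support Type) or the internal dialect
    (mirna_id / target_gene_id / evidence_tier), deduplicate, and filter
    to the requested evidence scope.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if set(_MIRTARBASE_COLUMNS) <= set(df.columns):
        df = df.rename(columns=_MIRTARBASE_COLUMNS)[_INTERNAL_COLUMNS]
        df["evidence_tier"] = df["evidence_tier"].map(_map_support_type)
    elif set(_INTERNAL_COLUMNS) <= set(df.columns):
        df = df[_INTERNAL_COLUMNS].copy()
    else:
        raise ValueError(
            f"unrecognized interaction table header {list(df.columns)}; expected "
            f"{list(_MIRTARBASE_COLUMNS)} (miRTarBase dialect) or {_INTERNAL_COLUMNS}"
        )
    table = InteractionTable(df, provenance=str(path))
    return table.filter_evidence(evidence_scope)


def write_interactions(table: InteractionTable, path: str | Path) -> None:
    """Write interactions in the miRTarBase export dialect."""
    out = table.records.rename(columns={v: k for k, v in _MIRTARBASE_COLUMNS.items()})
    tier_to_support = {"strong": "Functional MTI", "weak": "Functional MTI (Weak)"}
    out["Support Type"] = out["Support Type"].map(tier_to_support)
    out.to_csv(path, sep="\t", index=False)


@dataclass
class IntegrationSummary:
    """Interaction accounting for one cell line / evidence scope."""

    n_deregulated_mirnas: int
    n_deregulated_mrnas: int
    total_interactions: int
    unique_targets: int
    n_targets_deregulated: int
    percent_deregulated_mrnas_targeted: float
    inverse_total: int
    inverse_unique: int
    evidence_scope: str = "all"

    def __post_init__(self) -> None:
        if self.inverse_total > self.total_interactions:
            raise ValueError("inverse_total exceeds total_interactions")
        if self.unique_targets > self.total_interactions:
            raise ValueError("unique_targets exceeds total_interactions")
        if self.n_targets_deregulated > min(self.unique_targets, max(self.n_deregulated_mrnas, 0)):
            raise ValueError("n_targets_deregulated exceeds its bounds")

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def summarize_integration(n_targets_deregulated: int, n_deregulated_mrnas: int) -> float:
    """Percentage of deregulated mRNAs that are targets of deregulated
    miRNAs, rounded to one decimal (the printed-table convention)."""
    if n_deregulated_mrnas <= 0:
        raise ValueError("n_deregulated_mrnas must be positive")
    return round(100.0 * n_targets_deregulated / n_deregulated_mrnas, 1)


def join_targets(
    de_mirna: pd.DataFrame,
    de_mrna: pd.DataFrame,
    interactions: InteractionTable,
    evidence_scope: str = "all",
) -> tuple[pd.DataFrame, IntegrationSummary]:
    """Join deregulated miRNAs to their known targets.

    Parameters
    ----------
    de_mirna, de_mrna
        DE tables with columns ``feature_id``, ``log2fc``, ``call``.
    interactions
        The interaction table (already loaded / generated).
    evidence_scope
        'all' or 'strong'; restricts interactions before joining.

    Returns
    -------
    pairs, summary
        ``pairs`` is the pair-level record table (one row per interaction
        record of a deregulated miRNA); ``summary`` the interaction
        accounting. Targets missing from the mRNA DE table get NaN log2fc and
        call 'na'.
    """
    for tbl, name in ((de_mirna, "de_mirna"), (de_mrna, "de_mrna")):
        for col in ("feature_id", "log2fc", "call"):
            if col not in tbl.columns:
                raise ValueError(f"{name} lacks required column {col!r}")

    inter = interactions.filter_evidence(evidence_scope).records
    dereg_mi = de_mirna[de_mirna["call"].isin(["up", "down"])]
    dereg_mr = de_mrna[de_mrna["call"].isin(["up", "down"])]
    n_dereg_mirnas = len(dereg_mi)
    n_dereg_mrnas = len(dereg_mr)

    pairs = inter.merge(
        dereg_mi[["feature_id", "log2fc", "call"]].rename(
            columns={"feature_id": "mirna_id", "log2fc": "mirna_log2fc", "call": "mirna_call"}
        ),
        on="mirna_id",
        how="inner",
    )
    pairs = pairs.merge(
        de_mrna[["feature_id", "log2fc", "call"]].rename(
            columns={"feature_id": "target_gene_id", "log2fc": "mrna_log2fc", "call": "mrna_call"}
        ),
        on="target_gene_id",
        how="left",
    )
    pairs["mrna_call"] = pairs["mrna_call"].fillna("na")
    pairs["inverse"] = (
        ((pairs["mirna_call"] == "up") & (pairs["mrna_call"] == "down"))
        | ((pairs["mirna_call"] == "down") & (pairs["mrna_call"] == "up"))
    )

    total = len(pairs)
    unique_targets = pairs["target_gene_id"].nunique()
    dereg_target_ids = set(dereg_mr["feature_id"])
    n_targets_dereg = pairs.loc[
        pairs["target_gene_id"].isin(dereg_target_ids), "target_gene_id"
    ].nunique()
    inverse = pairs[pairs["inverse"]]
    percent = (
        summarize_integration(n_targets_dereg, n_dereg_mrnas) if n_dereg_mrnas > 0 else 0.0
    )
    summary = IntegrationSummary(
        n_deregulated_mirnas=n_dereg_mirnas,
        n_deregulated_mrnas=n_dereg_mrnas,
        total_interactions=total,
        unique_targets=unique_targets,
        n_targets_deregulated=n_targets_dereg,
        percent_deregulated_mrnas_targeted=percent,
        inverse_total=len(inverse),
        inverse_unique=inverse["target_gene_id"].nunique(),
        evidence_scope=evidence_scope,
    )
    return pairs.reset_index(drop=True), summary


def inverse_pairs(pairs: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Keep pairs where both members are deregulated with opposite signs.

    Returns the filtered pair table and ``{"total": ..., "unique_targets": ...}``.
    """
    if "inverse" not in pairs.columns:
        raise ValueError("pair table lacks the 'inverse' column; run join_targets first")
    kept = pairs[pairs["inverse"]].reset_index(drop=True)
    return kept, {"total": len(kept), "unique_targets": kept["target_gene_id"].nunique()}


def protein_concordance(
    pairs: pd.DataFrame,
    protein_table: pd.DataFrame,
    lfc_threshold: float = 0.6,
) -> dict:
    """Fraction of inverse-pair targets whose protein log2FC confirms the
    miRNA-driven direction.

    For targets of up-regulated miRNAs the confirming direction is protein
    log2FC <= -threshold; for down-regulated miRNAs, >= +threshold. Targets
    without protein measurements are excluded from the denominator and
    counted in ``n_missing``.

    Parameters
    ----------
    pairs
        Inverse-filtered pair table (from :func:`inverse_pairs`).
    protein_table
        DataFrame with columns ``gene_id`` and ``protein_log2fc``.

    Returns
    -------
    dict with keys ``fraction`` (NaN when no target has protein data),
    ``n_concordant``, ``n_with_protein``, ``n_missing``.
    """
    if not {"gene_id", "protein_log2fc"} <= set(protein_table.columns):
        raise ValueError("protein table needs columns 'gene_id' and 'protein_log2fc'")
    prot = protein_table.set_index("gene_id")["protein_log2fc"]
    # one verdict per distinct (target, expected direction)
    per_target = pairs[["target_gene_id", "mirna_call"]].drop_duplicates()
    with_protein = per_target[per_target["target_gene_id"].isin(prot.index)]
    n_missing = len(per_target) - len(with_protein)
    if len(with_protein) == 0:
        warnings.warn("no inverse-pair target has protein data; concordance undefined")
        return {
            "fraction": float("nan"),
            "n_concordant": 0,
            "n_with_protein": 0,
            "n_missing": n_missing,
        }
    lfc = prot.loc[with_protein["target_gene_id"]].to_numpy(dtype=float)
    up_mirna = (with_protein["mirna_call"] == "up").to_numpy()
    concordant = np.where(up_mirna, lfc <= -lfc_threshold, lfc >= lfc_threshold)
    return {
        "fraction": float(concordant.mean()),
        "n_concordant": int(concordant.sum()),
        "n_with_protein": int(len(with_protein)),
        "n_missing": int(n_missing),
    }
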