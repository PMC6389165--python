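"""Chromosome-dosage analysis of fold-change distributions.

Tests whether features encoded on gained chromosomes are expressed above
the disomic background: per-chromosome log2FC distributions are compared
with a two-sided Mann-Whitney-Wilcoxon test, and the observed median is
reported next to the expected dosage fold change log2(copy/2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import Karyotype

MODES = ("gained", "pooled", "per-chromosome")


def expected_log2fc(copy_number: int) -> float:
    """Dosage expectation log2(copy/2): 0 for disomy, ~0.585 for trisomy,
    1 for tetrasomy; -inf for a lost chromosome pair."""
    if copy_number < 0:
        raise ValueError("copy number must be >= 0")
    with np.errstate(divide="ignore"):
        return float(np.log2(copy_number / 2.0))


def assign_chromosomes(
    de_table: pd.DataFrame, annotation: pd.DataFrame, karyotype: Karyotype
) -> pd.DataFrame:
    """Annotate a DE table with each feature's chromosome and the cell
    line's copy number for it. Every feature must be annotated."""
    ann = annotation.set_index("feature_id")
    missing = [f for f in de_table["feature_id"] if f not in ann.index]
    if missing:
        raise KeyError(f"features missing from annotation: {missing[:10]}" +
                       (" ..." if len(missing) > 10 else ""))
    out = de_table.copy()
    out["chromosome"] = ann.loc[out["feature_id"], "chromosome"].to_numpy()
    out["copy_number"] = [karyotype.copy_number(c) for c in out["chromosome"]]
    return out


def mann_whitney(x, y) -> dict:
    """Two-sided Mann-Whitney-Wilcoxon test.

    Uses the exact null distribution when n + m <= 20 and there are no
    ties, and the normal approximation with tie and continuity correction
    otherwise. Returns {"U": ..., "p": ...} with U the statistic of ``x``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return {"U": float(res.statistic), "p": float(res.pvalue)}


@dataclass
class ChromosomeDosageResult:
    chromosome: str
    copy_number: int
    n_features: int
    median_log2fc: float
    expected_log2fc: float
    U: float
    p: float
    flag_significant: bool

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def dosage_test(
    annotated: pd.DataFrame,
    karyotype: Karyotype,
    alpha: float = 0.05,
    mode: str = "gained",
) -> pd.DataFrame:
    """Per-chromosome dosage tests on an annotated DE table.

    Modes
    -----
    gained
        Each non-disomic chromosome's features vs all features on disomic
        chromosomes (features on any non-disomic chromosome are excluded
        from the background).
    pooled
        All features on non-disomic chromosomes, as one group, vs all
        disomic features.
    per-chromosome
        Each chromosome (any copy number) vs all other chromosomes; no
        multiple-testing correction across chromosomes.

    Returns one row per comparison (columns of
    :class:`ChromosomeDosageResult`); chromosomes without features yield a
    row with n_features 0 and p NaN.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    if "log2fc" not in annotated.columns or "chromosome" not in annotated.columns:
        raise ValueError("table must carry log2fc and chromosome; run assign_chromosomes")
    lfc = annotated["log2fc"].to_numpy(dtype=float)
    chrom = annotated["chromosome"].to_numpy()
    disomic_chroms = {c for c, n in karyotype.copies.items() if n == 2}
    background = lfc[np.isin(chrom, list(disomic_chroms))]

    rows: list[ChromosomeDosageResult] = []

    def _row(name: str, copy: int, values: np.ndarray, other: np.ndarray) -> None:
        if len(values) == 0 or len(other) == 0:
            rows.append(
                ChromosomeDosageResult(
                    name, copy, int(len(values)), float("nan"),
                    expected_log2fc(copy) if name != "aneuploid" else float("nan"),
                    float("nan"), float("nan"), False,
                )
            )
            return
        res = mann_whitney(values, other)
        rows.append(
            ChromosomeDosageResult(
                chromosome=name,
                copy_number=copy,
                n_features=int(len(values)),
                median_log2fc=float(np.median(values)),
                expected_log2fc=expected_log2fc(copy) if copy >= 0 else float("nan"),
                U=res["U"],
                p=res["p"],
                flag_significant=bool(res["p"] < alpha),
            )
        )

    if mode == "gained":
        for c in karyotype.aneuploid_chromosomes:
            _row(c, karyotype.copy_number(c), lfc[chrom == c], background)
    elif mode == "pooled":
        gained_mask = np.isin(chrom, karyotype.aneuploid_chromosomes)
        if gained_mask.any() or len(karyotype.aneuploid_chromosomes):
            copies = {karyotype.copy_number(c) for c in karyotype.aneuploid_chromosomes}
            copy = copies.pop() if len(copies) == 1 else -1
            _row("aneuploid", copy, lfc[gained_mask], background)
    else:  # per-chromosome
        for c in sorted(set(chrom), key=str):
            mask = chrom == c
            _row(str(c), karyotype.copy_number(c), lfc[mask], lfc[~mask])

    return pd.DataFrame([r.to_dict() for r in rows])


def long_format(annotated: pd.DataFrame) -> pd.DataFrame:
    """Long-format table for boxplot rendering: one row per feature with
    chromosome, log2fc and copy number."""
    cols = ["chromosome", "feature_id", "log2fc", "copy_number"]
    return annotated[cols].sort_values(["chromosome", "feature_id"]).reset_index(drop=True)
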