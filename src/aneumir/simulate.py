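"""Synthetic aneuploid expression data with known ground truth.

Generates miRNA/mRNA count matrices, protein log2FC tables, feature
annotations, karyotypes and miRNA-target interaction tables that carry the
statistical structure the downstream analysis assumes:

* counts are negative binomial with per-sample size factors
  (variance = mu + phi * mu**2);
* features on a gained chromosome scale with the copy ratio c/2 — fully
  for mRNA, and as (c/2)**alpha for miRNA, where the compensation exponent
  alpha in [0, 1] interpolates between full dosage scaling (alpha=1) and
  full buffering back to disomic levels (alpha=0);
* a planted subset of features carries an extra differential effect, and a
  planted subset of miRNA->target interactions represses the target's mean
  by 2**(-beta * delta), delta being the miRNA's true log2FC;
* protein log2FC mirrors the mRNA truth plus Gaussian noise, with extra
  repression for planted targets.

All four operations are deterministic under a fixed ``rng_seed``: each
operation draws from its own numpy stream derived from the seed, so calling
them standalone or through the pipeline yields identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .integration import InteractionTable

# Autosomes + X with approximate lengths (Mb, GRCh37) as default sampling
# weights for feature placement.
CHROMOSOME_LENGTHS_MB: dict[str, float] = {
    "1": 249, "2": 243, "3": 198, "4": 191, "5": 181, "6": 171, "7": 159,
    "8": 146, "9": 141, "10": 136, "11": 135, "12": 134, "13": 115,
    "14": 107, "15": 103, "16": 90, "17": 81, "18": 78, "19": 59,
    "20": 63, "21": 48, "22": 51, "X": 155,
}
CHROMOSOMES: tuple[str, ...] = tuple(CHROMOSOME_LENGTHS_MB)

# per-operation RNG stream tags (first entry of the seeding sequence)
_STREAMS = {"annotation": 0, "planted": 1, "interactions": 2, "counts": 3, "protein": 4}


@dataclass(frozen=True)
class Karyotype:
    """Chromosome copy numbers of one cell line (reference ploidy 2)."""

    cell_line: str
    copies: dict[str, int]

    def __post_init__(self) -> None:
        for chrom, c in self.copies.items():
            if not (isinstance(c, (int, np.integer)) and c >= 0):
                raise ValueError(f"copy number for chr{chrom} must be an integer >= 0, got {c!r}")

    @classmethod
    def diploid(cls, cell_line: str, chromosomes: tuple[str, ...] = CHROMOSOMES) -> "Karyotype":
        return cls(cell_line, {c: 2 for c in chromosomes})

    @classmethod
    def with_gains(
        cls,
        cell_line: str,
        gains: dict[str, int],
        chromosomes: tuple[str, ...] = CHROMOSOMES,
    ) -> "Karyotype":
        """Diploid background with the given chromosome -> copy-number overrides
        (e.g. ``{"5": 4}`` for the tetrasomy-5 notation '5/4')."""
        copies = {c: 2 for c in chromosomes}
        copies.update(gains)
        return cls(cell_line, copies)

    def copy_number(self, chrom: str) -> int:
        return self.copies[chrom]

    @property
    def aneuploid_chromosomes(self) -> list[str]:
        return [c for c, n in self.copies.items() if n != 2]

    @property
    def is_diploid(self) -> bool:
        return not self.aneuploid_chromosomes


@dataclass(frozen=True)
class SimulationConfig:
    """Generator parameters.

    Parameters
    ----------
    n_mrna, n_mirna
        Number of mRNA / miRNA features.
    n_replicates
        Replicates per condition; replicate index doubles as the batch/pair
        factor for the paired DE design.
    baseline_mean
        Median of the log-normal baseline expression distribution (counts).
    baseline_log_sd
        Standard deviation of log baseline expression (natural log).
    dispersion_mrna, dispersion_mirna
        NB dispersion phi per feature type (variance = mu + phi mu^2).
    compensation_alpha
        miRNA dosage-response exponent in [0, 1]; mRNA always scales fully.
    repression_beta
        Strength of planted miRNA->target repression: the target mean is
        multiplied by 2**(-beta * delta_miRNA) in aneuploid samples.
    planted_fraction, planted_log2fc
        Fraction of features per type given an extra differential effect of
        the given magnitude (random sign; miRNAs feeding planted causal
        pairs are forced to the 'up' sign so repression is exercised).
    n_causal_pairs
        Number of planted causal miRNA->target interactions.
    interaction_density
        Bernoulli probability of a (miRNA, mRNA) pair being a reported
        interaction.
    fraction_strong_evidence
        Probability a sampled interaction is 'strong' tier (planted causal
        pairs are always strong).
    protein_noise_sd
        SD of the Gaussian noise added to mRNA truth at the protein level.
    protein_extra_repression
        Extra log2 units of repression applied to planted targets at the
        protein level (post-transcriptional effect).
    size_factor_range
        Log-uniform range for per-sample library-size factors.
    host_gene_fraction
        Fraction of miRNAs annotated with a host gene on the same chromosome
        (annotation only; no expression coupling).
    rng_seed
        Master seed; all randomness derives from it.
    """

    n_mrna: int = 5000
    n_mirna: int = 250
    n_replicates: int = 3
    baseline_mean: float = 100.0
    baseline_log_sd: float = 1.0
    dispersion_mrna: float = 0.05
    dispersion_mirna: float = 0.05
    compensation_alpha: float = 1.0
    repression_beta: float = 1.0
    planted_fraction: float = 0.1
    planted_log2fc: float = 1.0
    n_causal_pairs: int = 50
    interaction_density: float = 0.005
    fraction_strong_evidence: float = 0.1
    protein_noise_sd: float = 0.2
    protein_extra_repression: float = 0.5
    size_factor_range: tuple[float, float] = (0.7, 1.4)
    host_gene_fraction: float = 0.3
    chromosomes: tuple[str, ...] = CHROMOSOMES
    chromosome_weights: tuple[float, ...] | None = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mrna <= 0 or self.n_mirna <= 0:
            raise ValueError("n_mrna and n_mirna must be positive")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not 0.0 <= self.compensation_alpha <= 1.0:
            raise ValueError("compensation_alpha must lie in [0, 1]")
        for name in (
            "baseline_mean", "baseline_log_sd", "dispersion_mrna", "dispersion_mirna",
            "repression_beta", "planted_fraction", "planted_log2fc", "interaction_density",
            "fraction_strong_evidence", "protein_noise_sd", "protein_extra_repression",
            "host_gene_fraction",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.planted_fraction > 1 or self.fraction_strong_evidence > 1:
            raise ValueError("fractions must lie in [0, 1]")
        lo, hi = self.size_factor_range
        if not (0 < lo <= hi):
            raise ValueError("size_factor_range must satisfy 0 < lo <= hi")
        if self.chromosome_weights is not None and len(self.chromosome_weights) != len(
            self.chromosomes
        ):
            raise ValueError("chromosome_weights length must match chromosomes")

    @property
    def weights(self) -> np.ndarray:
        if self.chromosome_weights is not None:
            w = np.asarray(self.chromosome_weights, dtype=float)
        else:
            w = np.array([CHROMOSOME_LENGTHS_MB.get(c, 100.0) for c in self.chromosomes])
        return w / w.sum()


def _rng(config: SimulationConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng([_STREAMS[stream], config.rng_seed])


@dataclass
class ExpressionMatrix:
    """Integer count matrix (features x samples) for a single comparison.

    ``samples`` carries one row per column of ``counts`` with fields
    cell_line, condition ('parental'/'aneuploid') and replicate.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.samples.index):
            raise ValueError("count columns and sample metadata index must match")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            raise ValueError("counts must be integral")
        if (arr < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def feature_ids(self) -> pd.Index:
        return self.counts.index

    def subset_features(self, feature_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.counts.loc[feature_ids], self.samples)

    def subset_type(self, annotation: pd.DataFrame, feature_type: str) -> "ExpressionMatrix":
        ids = annotation.loc[annotation["feature_type"] == feature_type, "feature_id"]
        ids = [i for i in ids if i in self.counts.index]
        return self.subset_features(ids)


# ---------------------------------------------------------------------------
# annotation


def simulate_annotation(config: SimulationConfig) -> pd.DataFrame:
    """Draw a feature annotation table.

    Chromosomes are assigned proportionally to the configured weights
    (default: physical chromosome lengths); positions are uniform and used
    only for ordering. A fraction of miRNAs gets a host gene on the same
    chromosome (annotation only).
    """
    rng = _rng(config, "annotation")
    n = config.n_mrna + config.n_mirna
    ids = [f"gene-{i:05d}" for i in range(config.n_mrna)] + [
        f"mir-{i:04d}" for i in range(config.n_mirna)
    ]
    types = ["mRNA"] * config.n_mrna + ["miRNA"] * config.n_mirna
    chroms = rng.choice(np.asarray(config.chromosomes, dtype=object), size=n, p=config.weights)
    positions = rng.integers(1, 250_000_000, size=n)

    ann = pd.DataFrame(
        {
            "feature_id": ids,
            "feature_type": types,
            "chromosome": chroms,
            "position": positions,
            "host_gene": pd.array([pd.NA] * n, dtype="string"),
        }
    )
    # optional host-gene annotation: pick an mRNA on the same chromosome
    mrna_by_chrom = ann[ann["feature_type"] == "mRNA"].groupby("chromosome")["feature_id"]
    mrna_by_chrom = {c: g.to_numpy() for c, g in mrna_by_chrom}
    mirna_rows = ann.index[ann["feature_type"] == "miRNA"]
    hosted = rng.random(len(mirna_rows)) < config.host_gene_fraction
    for row, has_host in zip(mirna_rows, hosted):
        if not has_host:
            continue
        candidates = mrna_by_chrom.get(ann.at[row, "chromosome"])
        if candidates is not None and len(candidates):
            ann.at[row, "host_gene"] = candidates[rng.integers(len(candidates))]
    return ann


# ---------------------------------------------------------------------------
# planted truth


def planted_effects(annotation: pd.DataFrame, config: SimulationConfig) -> pd.Series:
    """Per-feature planted differential log2FC (0 for unaffected features).

    Deterministic given (annotation, config); recomputed identically by
    :func:`simulate_interactions` and :func:`simulate_counts` so the two
    operations agree without explicit state passing.
    """
    rng = _rng(config, "planted")
    effects = pd.Series(0.0, index=annotation["feature_id"])
    if config.planted_fraction == 0 or config.planted_log2fc == 0:
        return effects
    for ftype in ("mRNA", "miRNA"):
        ids = annotation.loc[annotation["feature_type"] == ftype, "feature_id"].to_numpy()
        k = int(round(config.planted_fraction * len(ids)))
        if k == 0:
            continue
        chosen = rng.choice(ids, size=k, replace=False)
        signs = rng.choice([-1.0, 1.0], size=k)
        if ftype == "miRNA" and config.n_causal_pairs > 0:
            # miRNAs feeding planted causal pairs must be up-regulated
            n_up = min(k, max(1, config.n_causal_pairs))
            signs[:n_up] = 1.0
        effects.loc[chosen] = signs * config.planted_log2fc
    return effects


# ---------------------------------------------------------------------------
# interactions


def simulate_interactions(annotation: pd.DataFrame, config: SimulationConfig) -> InteractionTable:
    """Sample a miRTarBase-like interaction table.

    Each (miRNA, mRNA) pair is reported with probability
    ``interaction_density``; a planted causal subset (always emitted, tier
    'strong') links up-regulated planted miRNAs to otherwise unaffected
    mRNAs and drives the repression applied by :func:`simulate_counts` and
    :func:`simulate_protein`.
    """
    mirnas = annotation.loc[annotation["feature_type"] == "miRNA", "feature_id"].to_numpy()
    mrnas = annotation.loc[annotation["feature_type"] == "mRNA", "feature_id"].to_numpy()
    if len(mirnas) == 0 or len(mrnas) == 0:
        raise ValueError("annotation must contain both miRNA and mRNA features")
    n_pairs = len(mirnas) * len(mrnas)
    if config.interaction_density > 1:
        raise ValueError("interaction_density exceeds all-pairs capacity")
    rng = _rng(config, "interactions")

    k = rng.binomial(n_pairs, config.interaction_density)
    flat = rng.choice(n_pairs, size=k, replace=False)
    mi_idx, mr_idx = np.divmod(flat, len(mrnas))
    tiers = np.where(
        rng.random(k) < config.fraction_strong_evidence, "strong", "weak"
    )
    records = pd.DataFrame(
        {
            "mirna_id": mirnas[mi_idx],
            "target_gene_id": mrnas[mr_idx],
            "evidence_tier": tiers,
        }
    )

    # planted causal pairs: up-planted miRNAs x non-planted mRNAs
    effects = planted_effects(annotation, config)
    up_mirnas = [m for m in mirnas if effects.loc[m] > 0]
    causal = pd.DataFrame(columns=["mirna_id", "target_gene_id"])
    if config.n_causal_pairs > 0 and up_mirnas:
        quiet_mrnas = np.array([g for g in mrnas if effects.loc[g] == 0])
        n_causal = min(config.n_causal_pairs, len(quiet_mrnas))
        targets = rng.choice(quiet_mrnas, size=n_causal, replace=False)
        chosen_mirnas = np.array(up_mirnas)[np.arange(n_causal) % len(up_mirnas)]
        causal = pd.DataFrame({"mirna_id": chosen_mirnas, "target_gene_id": targets})
        causal_rec = causal.assign(evidence_tier="strong")
        records = pd.concat([records, causal_rec], ignore_index=True)

    return InteractionTable(records, provenance="synthetic", causal_pairs=causal)


# ---------------------------------------------------------------------------
# ground-truth fold changes


def dosage_multiplier(copy_number: int, alpha: float) -> float:
    """Mean multiplier for a feature on a chromosome with the given copy
    number: (c/2)**alpha, with copy 0 always silencing the feature."""
    if copy_number == 0:
        return 0.0
    return float((copy_number / 2.0) ** alpha)


def true_log2fc(
    annotation: pd.DataFrame,
    karyotype: Karyotype,
    config: SimulationConfig,
    interactions: InteractionTable | None = None,
) -> pd.Series:
    """Ground-truth aneuploid-vs-parental log2FC per feature.

    Sum of the chromosome-dosage term (alpha-damped for miRNA), the planted
    differential effect, and — for targets of planted causal pairs — the
    repression -beta * delta of each causal miRNA. Copy number 0 yields
    -inf (the feature is silenced).
    """
    missing = set(annotation["chromosome"]) - set(karyotype.copies)
    if missing:
        raise ValueError(f"karyotype lacks chromosomes: {sorted(missing)}")
    effects = planted_effects(annotation, config)
    lfc = effects.copy()
    for ftype, alpha in (("mRNA", 1.0), ("miRNA", config.compensation_alpha)):
        mask = (annotation["feature_type"] == ftype).to_numpy()
        ids = annotation.loc[mask, "feature_id"]
        copies = annotation.loc[mask, "chromosome"].map(karyotype.copies).to_numpy()
        mult = np.array([dosage_multiplier(c, alpha) for c in copies])
        with np.errstate(divide="ignore"):
            lfc.loc[ids] += np.log2(mult)
    if interactions is not None and config.repression_beta > 0:
        causal = interactions.causal_pairs
        if causal is not None and len(causal):
            delta = lfc.loc[causal["mirna_id"].to_numpy()].to_numpy()
            repression = pd.Series(-config.repression_beta * delta).groupby(
                causal["target_gene_id"].to_numpy()
            ).sum()
            lfc.loc[repression.index] += repression
    return lfc


# ---------------------------------------------------------------------------
# counts


def _nb_draws(rng: np.random.Generator, mean: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """NB(mu, phi) draws with variance mu + phi mu^2; phi -> 0 is Poisson."""
    mean = np.asarray(mean, dtype=float)
    phi = np.broadcast_to(np.asarray(phi, dtype=float), mean.shape)
    out = np.zeros(mean.shape, dtype=np.int64)
    pois = phi < 1e-12
    pos = mean > 0
    m = pois & pos
    if m.any():
        out[m] = rng.poisson(mean[m])
    m = (~pois) & pos
    if m.any():
        r = 1.0 / phi[m]
        p = r / (r + mean[m])
        out[m] = rng.negative_binomial(r, p)
    return out


def simulate_counts(
    annotation: pd.DataFrame,
    karyotype: Karyotype,
    config: SimulationConfig,
    interactions: InteractionTable | None = None,
) -> ExpressionMatrix:
    """Draw a paired parental/aneuploid count matrix over all annotated
    features.

    Count_ij ~ NB(mean = s_j * mu_i * 2**lfc_i(condition_j), phi_type) where
    lfc is 0 for parental samples and the ground truth of
    :func:`true_log2fc` for aneuploid ones. Sample size factors s_j are
    log-uniform on ``size_factor_range``.
    """
    rng = _rng(config, "counts")
    n = len(annotation)
    mu = np.exp(rng.normal(np.log(config.baseline_mean), config.baseline_log_sd, size=n))

    lfc = true_log2fc(annotation, karyotype, config, interactions).to_numpy()
    mult = np.power(2.0, lfc, where=np.isfinite(lfc), out=np.zeros_like(lfc))

    lo, hi = config.size_factor_range
    n_samples = 2 * config.n_replicates
    s = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_samples))

    phi = np.where(
        annotation["feature_type"].to_numpy() == "miRNA",
        config.dispersion_mirna,
        config.dispersion_mrna,
    )
    conditions = ["parental"] * config.n_replicates + ["aneuploid"] * config.n_replicates
    cond_mult = np.array([1.0 if c == "parental" else np.nan for c in conditions])
    means = np.empty((n, n_samples))
    for j, cond in enumerate(conditions):
        base = mu if cond == "parental" else mu * mult
        means[:, j] = s[j] * base
    counts = _nb_draws(rng, means, phi[:, None])

    sample_ids = [
        f"{cond}_r{k + 1}" for cond, k in zip(conditions, list(range(config.n_replicates)) * 2)
    ]
    samples = pd.DataFrame(
        {
            "cell_line": [
                "parental" if c == "parental" else karyotype.cell_line for c in conditions
            ],
            "condition": conditions,
            "replicate": [f"r{k + 1}" for k in list(range(config.n_replicates)) * 2],
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    counts = pd.DataFrame(counts, index=pd.Index(annotation["feature_id"], name="feature_id"),
                          columns=samples.index)
    return ExpressionMatrix(counts, samples)


# ---------------------------------------------------------------------------
# protein


def simulate_protein(
    mrna_log2fc_truth: pd.Series,
    config: SimulationConfig,
    interactions: InteractionTable | None = None,
) -> pd.DataFrame:
    """Protein-level log2FC table: mRNA truth + Gaussian noise, with extra
    repression (``protein_extra_repression`` log2 units, in the direction of
    the transcript repression) for planted causal targets.
    """
    if config.protein_noise_sd < 0:
        raise ValueError("protein_noise_sd must be >= 0")
    rng = _rng(config, "protein")
    lfc = mrna_log2fc_truth.astype(float).copy()
    noise = (
        rng.normal(0.0, config.protein_noise_sd, size=len(lfc))
        if config.protein_noise_sd > 0
        else np.zeros(len(lfc))
    )
    protein = lfc + noise
    if interactions is not None and interactions.causal_pairs is not None:
        causal = interactions.causal_pairs
        targets = [t for t in causal["target_gene_id"].unique() if t in protein.index]
        if targets and config.protein_extra_repression > 0:
            direction = np.sign(lfc.loc[targets].to_numpy())
            direction[direction == 0] = -1.0  # repression direction by default
            protein.loc[targets] += direction * config.protein_extra_repression
    out = pd.DataFrame({"gene_id": protein.index, "protein_log2fc": protein.to_numpy()})
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# writers


def write_counts(matrix: ExpressionMatrix, path: str | Path, mtx: bool = False) -> None:
    """Write counts as TSV (feature_id + one column per sample); with
    ``mtx=True`` also write MatrixMarket triplets plus row/column index
    files next to it."""
    path = Path(path)
    matrix.counts.to_csv(path, sep="\t")
    matrix.samples.to_csv(path.with_suffix(".samples.tsv"), sep="\t")
    if mtx:
        from scipy import io as spio
        from scipy.sparse import csr_matrix

        spio.mmwrite(str(path.with_suffix(".mtx")), csr_matrix(matrix.counts.to_numpy()))
        path.with_suffix(".rows.txt").write_text("\n".join(matrix.counts.index) + "\n")
        path.with_suffix(".cols.txt").write_text("\n".join(matrix.counts.columns) + "\n")


def read_counts(path: str | Path) -> ExpressionMatrix:
    path = Path(path)
    counts = pd.read_csv(path, sep="\t", index_col=0)
    samples = pd.read_csv(path.with_suffix(".samples.tsv"), sep="\t", index_col=0)
    return ExpressionMatrix(counts.astype(np.int64), samples)


def write_annotation(annotation: pd.DataFrame, path: str | Path) -> None:
    annotation.to_csv(path, sep="\t", index=False)


def read_annotation(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chromosome": str, "host_gene": "string"})


def write_karyotype(karyotype: Karyotype, path: str | Path) -> None:
    pd.DataFrame(
        {
            "cell_line": karyotype.cell_line,
            "chromosome": list(karyotype.copies),
            "copy_number": list(karyotype.copies.values()),
        }
    ).to_csv(path, sep="\t", index=False)


def read_karyotype(path: str | Path) -> Karyotype:
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    cell_lines = df["cell_line"].unique()
    if len(cell_lines) != 1:
        raise ValueError("karyotype file must describe exactly one cell line")
    return Karyotype(cell_lines[0], dict(zip(df["chromosome"], df["copy_number"].astype(int))))
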