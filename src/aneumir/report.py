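"""End-to-end pipeline orchestration and summary reporting.

Runs filter -> normalize -> DE -> classify -> dosage -> integration ->
clustering over one or more aneuploid cell lines (synthetic or file-based
inputs), writes per-line deregulation/dosage/interaction summary TSVs, a
run log, and a machine-readable JSON with every summary number.
"""

from __future__ import annotations

import json
import logging
import sys
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from . import diffexpr, dosage, integration, simulate

log = logging.getLogger("aneumir")


def setup_logging(logfile: Path | None = None, level: int = logging.INFO) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler(sys.stderr)]
    if logfile is not None:
        handlers.append(logging.FileHandler(logfile, mode="w"))
    logging.basicConfig(
        level=level,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )


# ---------------------------------------------------------------------------
# clustering


@dataclass
class ClusterResult:
    row_order: np.ndarray
    col_order: np.ndarray
    row_linkage: np.ndarray | None
    col_linkage: np.ndarray | None


def cluster_profiles(log2fc_matrix: pd.DataFrame, method: str = "average") -> ClusterResult:
    """Order a miRNA x cell-line log2FC matrix for heatmap display.

    Agglomerative hierarchical clustering with Euclidean distance on rows
    and columns; missing values are imputed as 0 with a logged warning.
    With fewer than two rows (or columns) the identity ordering is
    returned for that axis. Leaf order is deterministic: scipy breaks
    distance ties by input index.
    """
    mat = log2fc_matrix.to_numpy(dtype=float)
    if np.isnan(mat).any():
        log.warning("log2FC matrix has missing values; imputing 0 for clustering")
        mat = np.nan_to_num(mat, nan=0.0)

    def _axis(data: np.ndarray) -> tuple[np.ndarray, np.ndarray | None]:
        if data.shape[0] < 2:
            return np.arange(data.shape[0]), None
        Z = linkage(pdist(data, metric="euclidean"), method=method)
        return leaves_list(Z), Z

    row_order, row_Z = _axis(mat)
    col_order, col_Z = _axis(mat.T)
    return ClusterResult(row_order, col_order, row_Z, col_Z)


# ---------------------------------------------------------------------------
# configuration


@dataclass
class PipelineConfig:
    """Pipeline settings: thresholds, cell-line registry, scope, output.

    In synthetic mode (the default) the bundled generator produces one
    paired comparison per registered karyotype; in file mode, per-line
    count/annotation/karyotype paths are read instead.
    """

    outdir: Path = Path("aneumir_out")
    min_mean: float = 10.0
    lfc_threshold: float = 0.6
    alpha: float = 0.05
    evidence_scope: str = "all"
    paired: bool = True
    dosage_mode: str = "gained"
    seed: int = 0
    simulation: simulate.SimulationConfig = field(default_factory=simulate.SimulationConfig)
    #: cell line name -> {chromosome: copy number} overrides of a diploid base
    karyotypes: dict[str, dict[str, int]] = field(
        default_factory=lambda: {"5/4": {"5": 4}, "21/3": {"21": 3}}
    )

    def __post_init__(self) -> None:
        if self.min_mean < 0 or self.lfc_threshold < 0 or not 0 < self.alpha <= 1:
            raise ValueError("thresholds must be positive (alpha in (0, 1])")
        self.outdir = Path(self.outdir)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = simulate.SimulationConfig(**raw.pop("simulation", {}))
        return cls(simulation=sim, **raw)


# ---------------------------------------------------------------------------
# pipeline


def _round_percent(k: int, n: int) -> float:
    return round(100.0 * k / n, 1) if n else 0.0


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis and write the report bundle.

    Per registered cell line: simulate paired counts, run miRNA and mRNA
    differential expression, the chromosome-dosage tests on the miRNA
    table, and the miRNA-target integration (with protein concordance).
    Across lines, cluster the miRNA log2FC profiles. Returns the summary
    dict that is also written as ``summary.json``.
    """
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    setup_logging(outdir / "run.log")
    log.info("pipeline start: seed=%d, lines=%s", config.seed, list(config.karyotypes))

    sim_cfg = replace(config.simulation, rng_seed=config.seed)
    stage = "simulate_annotation"
    try:
        annotation = simulate.simulate_annotation(sim_cfg)
        simulate.write_annotation(annotation, outdir / "annotation.tsv")
        stage = "simulate_interactions"
        interactions = simulate.simulate_interactions(annotation, sim_cfg)
        integration.write_interactions(interactions, outdir / "interactions.tsv")

        summary: dict = {
            "seed": config.seed,
            "thresholds": {
                "min_mean": config.min_mean,
                "lfc": config.lfc_threshold,
                "alpha": config.alpha,
            },
            "cell_lines": {},
        }
        mirna_profiles: dict[str, pd.Series] = {}

        for line, gains in config.karyotypes.items():
            karyotype = simulate.Karyotype.with_gains(line, gains, sim_cfg.chromosomes)
            line_dir = outdir / line.replace("/", "_")
            line_dir.mkdir(exist_ok=True)
            simulate.write_karyotype(karyotype, line_dir / "karyotype.tsv")

            stage = f"simulate_counts[{line}]"
            matrix = simulate.simulate_counts(annotation, karyotype, sim_cfg, interactions)
            simulate.write_counts(matrix, line_dir / "counts.tsv")

            line_summary: dict = {}
            de_tables: dict[str, pd.DataFrame] = {}
            for assay in ("miRNA", "mRNA"):
                stage = f"diffexpr[{line}:{assay}]"
                sub = matrix.subset_type(annotation, assay)
                de = diffexpr.de_analysis(
                    sub,
                    min_mean=config.min_mean,
                    lfc_threshold=config.lfc_threshold,
                    alpha=config.alpha,
                    paired=config.paired,
                )
                de.to_csv(line_dir / f"de_{assay.lower()}.tsv", sep="\t", index=False)
                de_tables[assay] = de
                s = diffexpr.summarize_deregulation(de) if len(de) else {
                    "n_tested": 0, "n_deregulated": 0, "percent": 0.0
                }
                line_summary[f"{assay.lower()}_deregulation"] = s

            stage = f"dosage[{line}]"
            annotated = dosage.assign_chromosomes(de_tables["miRNA"], annotation, karyotype)
            dosage_tbl = dosage.dosage_test(
                annotated, karyotype, alpha=config.alpha, mode=config.dosage_mode
            )
            dosage_tbl.to_csv(line_dir / "dosage.tsv", sep="\t", index=False)
            dosage.long_format(annotated).to_csv(
                line_dir / "dosage_long.tsv", sep="\t", index=False
            )
            line_summary["dosage"] = dosage_tbl.to_dict(orient="records")

            stage = f"integration[{line}]"
            pairs, int_summary = integration.join_targets(
                de_tables["miRNA"], de_tables["mRNA"], interactions, config.evidence_scope
            )
            pairs.to_csv(line_dir / "pairs.tsv", sep="\t", index=False)
            inv, inv_counts = integration.inverse_pairs(pairs)
            inv.to_csv(line_dir / "inverse_pairs.tsv", sep="\t", index=False)

            stage = f"protein[{line}]"
            truth = simulate.true_log2fc(annotation, karyotype, sim_cfg, interactions)
            mrna_ids = annotation.loc[annotation["feature_type"] == "mRNA", "feature_id"]
            protein = simulate.simulate_protein(truth.loc[mrna_ids], sim_cfg, interactions)
            protein.to_csv(line_dir / "protein.tsv", sep="\t", index=False)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                concordance = integration.protein_concordance(
                    inv, protein, lfc_threshold=config.lfc_threshold
                )
            line_summary["integration"] = int_summary.to_dict()
            line_summary["inverse"] = inv_counts
            line_summary["protein_concordance"] = concordance

            summary["cell_lines"][line] = line_summary
            mirna_profiles[line] = de_tables["miRNA"].set_index("feature_id")["log2fc"]

        stage = "clustering"
        profile = pd.DataFrame(mirna_profiles)
        if len(profile):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                clust = cluster_profiles(profile.fillna(np.nan))
            ordered = profile.iloc[clust.row_order, clust.col_order]
            ordered.to_csv(outdir / "mirna_log2fc_clustered.tsv", sep="\t")
            summary["cluster_row_order"] = [str(i) for i in ordered.index]
            summary["cluster_col_order"] = [str(c) for c in ordered.columns]

        summary = _sanitize(summary)
        (outdir / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True, allow_nan=False) + "\n"
        )
        log.info("pipeline complete: %s", outdir)
        return summary
    except Exception as exc:  # noqa: BLE001 - annotate the failing stage
        raise RuntimeError(f"pipeline failed at stage {stage}: {exc}") from exc


def _sanitize(obj):
    """Make a summary tree strictly JSON-serializable (NaN -> null,
    numpy scalars -> Python scalars)."""
    if isinstance(obj, dict):
        return {str(k): _sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, np.ndarray)):
        return [_sanitize(v) for v in obj]
    if isinstance(obj, (bool, np.bool_)):
        return bool(obj)
    if isinstance(obj, (int, np.integer)):
        return int(obj)
    if isinstance(obj, (float, np.floating)):
        v = float(obj)
        return None if not np.isfinite(v) else v
    return obj
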