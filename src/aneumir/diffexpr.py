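"""Negative-binomial differential expression, aneuploid vs parental.

The engine follows the standard RNA-seq count workflow: median-of-ratios
size factors, a mean-count filter, method-of-moments dispersion estimates
shrunk toward a mean-dispersion trend, a per-feature NB GLM (log link,
log-size-factor offsets, condition plus optional batch covariates) with a
Wald test on the condition coefficient, Benjamini-Hochberg adjustment, and
the deregulation call |log2FC| >= 0.6 at adjusted p < 0.05.

Reported log2 fold changes are unshrunk maximum-likelihood coefficients.
Independent filtering and outlier replacement are deliberately not
implemented; the mean-count filter is the only pre-test screen.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import polygamma
from statsmodels.stats.multitest import multipletests

from .simulate import ExpressionMatrix

LN2 = np.log(2.0)
PHI_MIN = 1e-8
IRLS_TOL = 1e-8
IRLS_MAX_ITER = 100

DE_COLUMNS = ["feature_id", "base_mean", "log2fc", "se", "p", "padj", "call"]


@dataclass(frozen=True)
class DesignSpec:
    """Comparison design: a two-level condition factor and an optional
    batch/pair factor entering as a fixed-effect covariate (the paired
    design used when replicate libraries were sequenced in batches)."""

    condition: tuple[str, ...]
    batch: tuple[str, ...] | None = None
    reference: str = "parental"
    alternative: str = "aneuploid"

    def __post_init__(self) -> None:
        levels = set(self.condition)
        if levels != {self.reference, self.alternative}:
            raise ValueError(
                f"condition must use exactly the levels "
                f"{{{self.reference!r}, {self.alternative!r}}}, got {sorted(levels)}"
            )
        counts = pd.Series(self.condition).value_counts()
        if (counts < 2).any():
            raise ValueError("need >= 2 samples per condition")
        if self.batch is not None:
            if len(self.batch) != len(self.condition):
                raise ValueError("batch factor length must match condition")

    @classmethod
    def from_samples(cls, samples: pd.DataFrame, paired: bool = False) -> "DesignSpec":
        batch = tuple(samples["replicate"]) if paired else None
        return cls(condition=tuple(samples["condition"]), batch=batch)

    def matrix(self) -> tuple[np.ndarray, int]:
        """Design matrix and the column index of the condition coefficient."""
        n = len(self.condition)
        cols = [np.ones(n), np.array([c == self.alternative for c in self.condition], float)]
        if self.batch is not None:
            levels = sorted(set(self.batch))
            for lev in levels[1:]:
                cols.append(np.array([b == lev for b in self.batch], float))
        X = np.column_stack(cols)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("design matrix is rank deficient (batch confounded with condition?)")
        return X, 1


# ---------------------------------------------------------------------------
# filtering and normalization


def filter_low_expression(matrix: ExpressionMatrix, min_mean: float = 10.0) -> ExpressionMatrix:
    """Keep features whose mean raw count across all samples of the
    comparison is >= ``min_mean`` (inclusive); input order is preserved.

    Low-count features have large log-scale variability and are screened
    out before testing.
    """
    if matrix.counts.empty:
        raise ValueError("count matrix is empty")
    keep = matrix.counts.mean(axis=1) >= min_mean
    if not keep.any():
        warnings.warn("mean-count filter removed every feature")
    return ExpressionMatrix(matrix.counts.loc[keep], matrix.samples)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    factor_j = median over features i (restricted to features with a
    positive geometric mean across samples) of count_ij / geomean_i.
    """
    arr = counts.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        log_arr = np.log(arr)
    log_geomean = log_arr.mean(axis=1)
    usable = np.isfinite(log_geomean)
    if not usable.any():
        raise ValueError(
            "no feature has nonzero counts in every sample; size factors undefined"
        )
    log_ratios = log_arr[usable] - log_geomean[usable, None]
    factors = np.exp(np.median(log_ratios, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


# ---------------------------------------------------------------------------
# dispersion


def estimate_dispersions(
    counts: pd.DataFrame,
    size_factors: pd.Series,
    condition: tuple[str, ...] | np.ndarray,
    phi_min: float = PHI_MIN,
) -> pd.Series:
    """Per-feature NB dispersion phi (variance = mu + phi mu^2).

    Method-of-moments estimates phi_raw = max(phi_min, (var - mu) / mu^2)
    on normalized counts pooled within condition are shrunk toward a
    log-linear trend in 1/mean, exp(a + b/mu), fit by a Gamma GLM. The
    shrinkage weight is empirical-Bayes adaptive: the spread of log phi_raw
    around the trend is decomposed into sampling noise (trigamma(d/2) for d
    residual degrees of freedom) and a feature-to-feature prior variance
    (floored at 0.25**2), and each feature's estimate is pulled to the
    trend in proportion to its noise share. With few replicates the
    per-feature estimates are dominated by sampling noise, so the posterior
    leans on the trend — which keeps the Wald null calibrated.
    """
    condition = np.asarray(condition)
    norm = counts.to_numpy(dtype=float) / size_factors.to_numpy()[None, :]
    levels = pd.unique(condition)
    for lev in levels:
        if (condition == lev).sum() < 2:
            raise ValueError(
                f"condition {lev!r} has a single replicate; dispersion is unidentifiable"
            )
    pooled_var = np.zeros(norm.shape[0])
    dof = 0
    for lev in levels:
        cols = condition == lev
        pooled_var += norm[:, cols].var(axis=1, ddof=1) * (cols.sum() - 1)
        dof += int(cols.sum()) - 1
    pooled_var /= dof
    mu = norm.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi_mom = (pooled_var - mu) / mu**2
    phi_mom = np.where(np.isfinite(phi_mom), phi_mom, 0.0)
    phi_raw = np.maximum(phi_mom, phi_min)

    fit_mask = (phi_mom > 0) & (mu > 0)
    if fit_mask.sum() < 10:
        return pd.Series(phi_raw, index=counts.index, name="dispersion")

    # mean-dispersion trend exp(a + b/mu): Gamma GLM, log link, one
    # outlier-trimming refit (ratio to trend outside [1e-4, 15] dropped)
    import statsmodels.api as sm

    def _fit_trend(mask: np.ndarray) -> np.ndarray:
        X = sm.add_constant(1.0 / mu[mask])
        model = sm.GLM(phi_mom[mask], X, family=sm.families.Gamma(sm.families.links.Log()))
        res = model.fit()
        a, b = res.params
        return np.exp(a + b / np.where(mu > 0, mu, np.inf))

    trend = _fit_trend(fit_mask)
    ratio = phi_mom / np.maximum(trend, phi_min)
    refit = fit_mask & (ratio > 1e-4) & (ratio < 15)
    if refit.sum() >= 10:
        trend = _fit_trend(refit)
    trend = np.maximum(trend, phi_min)

    # empirical-Bayes weight: decompose the log-residual spread into
    # per-feature sampling noise and a prior variance (floored at 0.25**2).
    # Delta method on phi_hat = (var - mu)/mu^2 with var ~ chi2_dof gives
    # sd(log phi_hat) ~ sqrt(2/dof) * (1 + 1/(phi mu)), evaluated at the
    # trend: low-count features are noisier and get pulled harder.
    with np.errstate(divide="ignore"):
        rel = 1.0 + 1.0 / np.maximum(trend * mu, 1e-12)
    sampling_var = np.minimum((2.0 / dof) * rel**2, 50.0)
    resid = np.log(phi_raw[fit_mask]) - np.log(trend[fit_mask])
    spread = (1.4826 * np.median(np.abs(resid - np.median(resid)))) ** 2
    prior_var = max(spread - float(np.median(sampling_var[fit_mask])), 0.25**2)
    w = prior_var / (prior_var + sampling_var)

    # clamp extreme/floored raw values so a single outlier cannot dominate
    log_raw = np.clip(np.log(phi_raw), np.log(trend) - 3.0, np.log(trend) + 3.0)
    phi = np.exp(w * log_raw + (1 - w) * np.log(trend))
    phi = np.maximum(phi, phi_min)
    return pd.Series(phi, index=counts.index, name="dispersion")


# ---------------------------------------------------------------------------
# NB GLM Wald test


def _irls_nb(
    y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    phi: np.ndarray,
    tol: float = IRLS_TOL,
    max_iter: int = IRLS_MAX_ITER,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized IRLS for per-feature NB GLMs with log link.

    Fits all features at once: ``y`` is (F, S), ``X`` (S, P), ``offset``
    (S,), ``phi`` (F,). Returns (beta (F, P), cov (F, P, P), converged (F,)).
    The working weights are mu / (1 + phi mu), the NB2 Fisher information.
    """
    F, S = y.shape
    P = X.shape[1]
    # initialize: intercept at the offset-adjusted mean, rest at 0
    beta = np.zeros((F, P))
    mean0 = np.maximum((y / np.exp(offset)[None, :]).mean(axis=1), 1e-8)
    beta[:, 0] = np.log(mean0)

    converged = np.zeros(F, dtype=bool)
    active = np.ones(F, dtype=bool)
    eta_cap = 50.0

    for _ in range(max_iter):
        if not active.any():
            break
        b = beta[active]
        ya = y[active]
        pa = phi[active]
        eta = offset[None, :] + b @ X.T
        eta = np.clip(eta, -eta_cap, eta_cap)
        mu = np.exp(eta)
        W = mu / (1.0 + pa[:, None] * mu)
        z = (eta - offset[None, :]) + (ya - mu) / mu
        XtWX = np.einsum("fs,si,sj->fij", W, X, X)
        XtWz = np.einsum("fs,si->fi", W * z, X)
        # regularize near-singular systems minimally
        XtWX += np.eye(P)[None, :, :] * 1e-12
        new_b = np.linalg.solve(XtWX, XtWz[..., None])[..., 0]
        delta = np.abs(new_b - b).max(axis=1)
        beta[active] = new_b
        done = delta < tol
        idx = np.where(active)[0]
        converged[idx[done]] = True
        active[idx[done]] = False

    # covariance at the final estimate
    eta = np.clip(offset[None, :] + beta @ X.T, -eta_cap, eta_cap)
    mu = np.exp(eta)
    W = mu / (1.0 + phi[:, None] * mu)
    XtWX = np.einsum("fs,si,sj->fij", W, X, X) + np.eye(P)[None, :, :] * 1e-12
    cov = np.linalg.inv(XtWX)
    return beta, cov, converged


def nb_wald(
    counts: pd.DataFrame,
    size_factors: pd.Series,
    dispersions: pd.Series,
    design: DesignSpec,
) -> pd.DataFrame:
    """Per-feature Wald test of the condition coefficient in an NB GLM.

    Returns a DE table without calls: feature_id, base_mean (mean
    normalized count), log2fc, se (of log2fc), p (two-sided normal), and a
    ``converged`` flag. Non-converged features get p = NaN and are excluded
    from the BH denominator downstream.
    """
    X, cond_idx = design.matrix()
    if X.shape[0] != counts.shape[1]:
        raise ValueError("design rows must match the number of samples")
    y = counts.to_numpy(dtype=float)
    offset = np.log(size_factors.to_numpy(dtype=float))
    phi = dispersions.reindex(counts.index).to_numpy(dtype=float)

    beta, cov, converged = _irls_nb(y, X, offset, phi)
    coef = beta[:, cond_idx]
    se_nat = np.sqrt(np.maximum(cov[:, cond_idx, cond_idx], 0))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = coef / se_nat
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.where(converged, p, np.nan)

    base_mean = (y / np.exp(offset)[None, :]).mean(axis=1)
    return pd.DataFrame(
        {
            "feature_id": counts.index,
            "base_mean": base_mean,
            "log2fc": coef / LN2,
            "se": se_nat / LN2,
            "p": p,
            "converged": converged,
        }
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# multiple testing and calls


def adjust_bh(p: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    NaN entries are excluded from the number of tests and returned as NaN.
    """
    p = np.asarray(p, dtype=float)
    mask = ~np.isnan(p)
    if ((p[mask] < 0) | (p[mask] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    padj = np.full_like(p, np.nan)
    if mask.any():
        padj[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return padj


def classify_deregulated(
    de_table: pd.DataFrame, lfc_threshold: float = 0.6, alpha: float = 0.05
) -> pd.DataFrame:
    """Add BH-adjusted p-values (if absent) and the deregulation call:
    up if log2fc >= threshold, down if log2fc <= -threshold, both at
    padj < alpha (inclusive fold-change bound, strict alpha); 'ns'
    otherwise."""
    out = de_table.copy()
    if "padj" not in out.columns:
        out["padj"] = adjust_bh(out["p"].to_numpy())
    sig = out["padj"] < alpha
    call = np.where(
        sig & (out["log2fc"] >= lfc_threshold),
        "up",
        np.where(sig & (out["log2fc"] <= -lfc_threshold), "down", "ns"),
    )
    out["call"] = call
    return out


def summarize_deregulation(de_table: pd.DataFrame) -> dict:
    """Deregulation accounting: tested features, deregulated features, and
    the percentage rounded to one decimal (printed-table convention)."""
    if "call" not in de_table.columns:
        raise ValueError("calls not populated; run classify_deregulated first")
    n_tested = len(de_table)
    if n_tested == 0:
        raise ValueError("no tested features")
    n_dereg = int(de_table["call"].isin(["up", "down"]).sum())
    return {
        "n_tested": n_tested,
        "n_deregulated": n_dereg,
        "percent": round(100.0 * n_dereg / n_tested, 1),
    }


# ---------------------------------------------------------------------------
# convenience wrapper


def de_analysis(
    matrix: ExpressionMatrix,
    min_mean: float = 10.0,
    lfc_threshold: float = 0.6,
    alpha: float = 0.05,
    paired: bool = False,
) -> pd.DataFrame:
    """Full DE workflow on one comparison matrix.

    Size factors are estimated on the unfiltered matrix (more stable), the
    mean-count filter is applied before testing, and calls are made at the
    given thresholds.
    """
    sf = size_factors(matrix.counts)
    filtered = filter_low_expression(matrix, min_mean=min_mean)
    if filtered.counts.empty:
        return pd.DataFrame(columns=DE_COLUMNS)
    design = DesignSpec.from_samples(matrix.samples, paired=paired)
    phi = estimate_dispersions(filtered.counts, sf, np.asarray(design.condition))
    table = nb_wald(filtered.counts, sf, phi, design)
    table["padj"] = adjust_bh(table["p"].to_numpy())
    return classify_deregulated(table, lfc_threshold=lfc_threshold, alpha=alpha)
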