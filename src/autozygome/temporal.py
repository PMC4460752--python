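"""Change of locus autozygosity over birth year.

Per SNP, the in-ROH indicator is modelled by logistic regression on birth
year:  P(in ROH) = exp(alpha + beta * YB) / (1 + exp(alpha + beta * YB)),
with beta the per-year change in log-odds of locus autozygosity.  Years
with fewer than ``min_per_year`` genotyped animals are dropped before
fitting.  Fitting is iteratively reweighted least squares across all SNPs
at once (shared covariate, per-SNP response), with a hard iteration cap;
SNPs that fail to converge — all-constant status or complete separation —
are flagged and given p = 1 rather than erroring, so one degenerate SNP
cannot break a genome scan.

Genome-wide calibration reuses the pooled permutation machinery of the
differential module, with |beta| as the per-SNP statistic and birth years
shuffled across animals.  Trend regions use the shared region rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .differential import PermutationNull
from .regions import RegionCall, call_regions
from .roh import ROHStatusMatrix

MAX_IRLS_ITER = 25
_BETA_CAP = 50.0  # divergence guard on |slope| and |intercept| (centered scale)


@dataclass
class TrendFit:
    """Per-SNP logistic fit of in-ROH status on birth year.

    ``intercept`` is on the original year origin (back-transformed from the
    centered fit); ``slope`` is per-year log-odds change.
    """

    intercept: np.ndarray
    slope: np.ndarray
    slope_se: np.ndarray
    p_values: np.ndarray
    converged: np.ndarray
    year_mean: float
    n_used: int


def _logistic_irls(y: np.ndarray, x: np.ndarray, max_iter: int = MAX_IRLS_ITER):
    """Vectorized per-column logistic regression of y (n x M binary) on a
    single covariate x (n,), with intercept.  Returns (b0, b1, se1, converged)
    on the given x scale.  All-constant columns are degenerate: estimates 0,
    SE NaN, non-converged."""
    n, m_all = y.shape
    ymean_all = y.mean(axis=0)
    fit_cols = np.flatnonzero((ymean_all > 0) & (ymean_all < 1))
    out_b0 = np.zeros(m_all)
    out_b1 = np.zeros(m_all)
    out_se1 = np.full(m_all, np.nan)
    out_conv = np.zeros(m_all, dtype=bool)
    if fit_cols.size == 0:
        return out_b0, out_b1, out_se1, out_conv
    y = y[:, fit_cols]
    m = fit_cols.size
    # start from the empirical logit of the marginal mean
    ybar = np.clip(y.mean(axis=0), 1e-10, 1 - 1e-10)
    b0 = np.log(ybar / (1 - ybar))
    b1 = np.zeros(m)
    active = np.ones(m, dtype=bool)
    converged = np.zeros(m, dtype=bool)
    x = np.asarray(x, dtype=float)
    for _ in range(max_iter):
        if not active.any():
            break
        eta = b0[None, :] + np.outer(x, b1)
        eta = np.clip(eta, -35, 35)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        # weighted-normal-equation elements, per SNP
        s0 = w.sum(axis=0)
        s1 = (w * x[:, None]).sum(axis=0)
        s2 = (w * (x**2)[:, None]).sum(axis=0)
        r = y - mu
        g0 = r.sum(axis=0)
        g1 = (r * x[:, None]).sum(axis=0)
        det = s0 * s2 - s1**2
        ok = det > 1e-12
        with np.errstate(invalid="ignore", divide="ignore"):
            d0 = np.where(ok, (s2 * g0 - s1 * g1) / det, 0.0)
            d1 = np.where(ok, (s0 * g1 - s1 * g0) / det, 0.0)
        step0 = np.where(active, d0, 0.0)
        step1 = np.where(active, d1, 0.0)
        b0 = b0 + step0
        b1 = b1 + step1
        newly = active & (np.abs(step0) < 1e-8) & (np.abs(step1) < 1e-8) & ok
        converged |= newly
        diverged = (np.abs(b1) > _BETA_CAP) | (np.abs(b0) > _BETA_CAP) | ~ok
        active &= ~newly & ~diverged
    # SE of slope from the final information matrix
    eta = np.clip(b0[None, :] + np.outer(x, b1), -35, 35)
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    s0 = w.sum(axis=0)
    s1 = (w * x[:, None]).sum(axis=0)
    s2 = (w * (x**2)[:, None]).sum(axis=0)
    det = s0 * s2 - s1**2
    with np.errstate(invalid="ignore", divide="ignore"):
        se1 = np.sqrt(np.where(det > 0, s0 / det, np.nan))
    out_b0[fit_cols] = b0
    out_b1[fit_cols] = b1
    out_se1[fit_cols] = se1
    out_conv[fit_cols] = converged
    return out_b0, out_b1, out_se1, out_conv


def fit_trend(
    status: ROHStatusMatrix,
    birth_years,
    min_per_year: int = 40,
    max_iter: int = MAX_IRLS_ITER,
) -> TrendFit:
    """Maximum-likelihood logistic fit of per-SNP status on birth year.

    Birth year is centered at its mean for numerical stability; the reported
    intercept is back-transformed to the original year origin.  Degenerate
    SNPs (all 0, all 1, separation/divergence) are flagged non-converged
    with p = 1.
    """
    years = np.asarray(birth_years, dtype=float)
    s = status.status
    if len(years) != s.shape[0]:
        raise ValueError("birth_years must cover all samples")
    counts = pd.Series(years).value_counts()
    keep_years = counts[counts >= min_per_year].index
    keep = np.isin(years, keep_years)
    if len(np.unique(years[keep])) < 2:
        raise ValueError("need >= 2 distinct birth years after the per-year minimum")
    y = s[keep].astype(float)
    x_raw = years[keep]
    x_mean = float(x_raw.mean())
    x = x_raw - x_mean

    b0c, b1, se1, converged = _logistic_irls(y, x, max_iter=max_iter)
    ymean = y.mean(axis=0)
    degenerate = (ymean <= 0) | (ymean >= 1)
    converged = converged & ~degenerate & np.isfinite(se1) & (se1 > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = b1 / se1
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.where(converged, p, 1.0)
    intercept = b0c - b1 * x_mean  # back to original year origin
    return TrendFit(
        intercept=intercept,
        slope=b1,
        slope_se=se1,
        p_values=p,
        converged=converged,
        year_mean=x_mean,
        n_used=int(keep.sum()),
    )


def trend_permutation_threshold(
    status: ROHStatusMatrix,
    birth_years,
    min_per_year: int = 40,
    n_permutations: int = 1000,
    alpha: float = 0.001,
    seed: int | np.random.SeedSequence | None = 0,
    null_kind: str = "pooled",
    max_iter: int = MAX_IRLS_ITER,
) -> PermutationNull:
    """Pooled empirical null of |beta| from shuffling birth years across
    animals; per-SNP p as in the differential permutation test."""
    years = np.asarray(birth_years, dtype=float)
    s = status.status
    counts = pd.Series(years).value_counts()
    keep_years = counts[counts >= min_per_year].index
    keep = np.isin(years, keep_years)
    y = s[keep].astype(float)
    x = years[keep] - years[keep].mean()
    n, m = y.shape
    _, b1_obs, _, conv_obs = _logistic_irls(y, x, max_iter=max_iter)
    observed = np.abs(np.where(conv_obs, b1_obs, 0.0))

    rng = np.random.default_rng(seed)
    B = int(n_permutations)
    null = np.empty((B, m))
    for b in range(B):
        xp = rng.permutation(x)
        _, b1, _, conv = _logistic_irls(y, xp, max_iter=max_iter)
        null[b] = np.abs(np.where(conv, b1, 0.0))

    BM = B * m
    if null_kind == "pooled":
        pooled = np.sort(null.ravel())
        ge = BM - np.searchsorted(pooled, observed, side="left")
        p = (1.0 + ge) / (1.0 + BM)
        threshold = float(np.quantile(pooled, 1.0 - alpha))
        null_out = pooled
    elif null_kind == "per-snp":
        ge = (null >= observed[None, :]).sum(axis=0)
        p = (1.0 + ge) / (1.0 + B)
        threshold = float(np.quantile(null, 1.0 - alpha))
        null_out = null
    elif null_kind == "max":
        mx = np.sort(null.max(axis=1))
        ge = B - np.searchsorted(mx, observed, side="left")
        p = (1.0 + ge) / (1.0 + B)
        threshold = float(np.quantile(mx, 1.0 - alpha))
        null_out = mx
    else:
        raise ValueError("null_kind must be pooled, per-snp or max")
    return PermutationNull(
        n_permutations=B,
        null_values=null_out,
        p_values=p,
        observed=observed,
        alpha=alpha,
        threshold=threshold,
        null_kind=null_kind,
    )


def call_trend_regions(
    p_values: np.ndarray,
    markers: pd.DataFrame,
    slopes: np.ndarray | None = None,
    min_snps: int = 45,
    min_span_mb: float = 4.0,
    alpha: float = 0.001,
) -> list[RegionCall]:
    """Same contiguity rule as differential regions, kind='temporal'; the
    region peak is the SNP of maximum |beta|."""
    flags = np.asarray(p_values) < alpha
    return call_regions(flags, markers, "temporal", min_snps, min_span_mb, peak_values=slopes)


def trend_table(markers: pd.DataFrame, fit: TrendFit, perm: PermutationNull | None = None) -> pd.DataFrame:
    out = pd.DataFrame(
        {
            "chromosome": markers["chromosome"],
            "position_bp": markers["position_bp"],
            "snp_id": markers["snp_id"],
            "alpha": fit.intercept,
            "beta": fit.slope,
            "beta_se": fit.slope_se,
            "p_wald": fit.p_values,
            "converged": fit.converged,
        }
    )
    if perm is not None:
        out["p_perm"] = perm.p_values
    return out
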