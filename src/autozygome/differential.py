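"""Between-population contrasts of per-SNP ROH45 frequency.

The per-SNP statistic is the frequency of animals whose SNP lies inside a
ROH of >= 45 SNPs (the locus-autozygosity indicator).  Two populations are
contrasted with a 1-df Pearson chi-square on the 2x2 (population x in-ROH)
table and, for genome-wide calibration, with a permutation test: group
labels are shuffled preserving group sizes, the per-SNP absolute frequency
difference is recomputed, and the empirical p-value of each observed
difference is taken against the null differences pooled across all SNPs and
permutations (add-one corrected).  Alternatives: a per-SNP null and the
genome-wide-max null.

Differential regions are contiguous runs of significant SNPs (p < 0.001) of
at least 45 SNPs spanning more than 4 Mb; common high-autozygosity regions
are runs jointly in every population's top 2.5% of ROH45 frequency under
the same length/span rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .regions import RegionCall, call_regions
from .roh import ROHStatusMatrix


@dataclass
class ROHFrequencyTrack:
    """Per-population per-SNP in-ROH counts and frequencies."""

    counts: pd.DataFrame  # populations x SNPs (rows indexed by population)
    sizes: pd.Series  # animals per population

    @property
    def frequencies(self) -> pd.DataFrame:
        return self.counts.div(self.sizes, axis=0)


@dataclass
class PermutationNull:
    """Empirical null of |frequency difference| and derived per-SNP p-values."""

    n_permutations: int
    null_values: np.ndarray  # pooled (or per-snp: B x M; max: B)
    p_values: np.ndarray  # per observed SNP
    observed: np.ndarray  # observed |difference| per SNP
    alpha: float
    threshold: float  # smallest difference significant at alpha
    null_kind: str = "pooled"


def roh45_frequency(status: ROHStatusMatrix, groups) -> ROHFrequencyTrack:
    """Per-population per-SNP frequency of the binary in-ROH status."""
    groups = np.asarray(groups)
    if len(groups) != status.status.shape[0]:
        raise ValueError("group labels must cover all samples")
    pops = pd.unique(groups)
    counts = {}
    sizes = {}
    for pop in pops:
        mask = groups == pop
        if mask.sum() == 0:
            raise ValueError(f"empty population {pop!r}")
        counts[pop] = status.status[mask].sum(axis=0)
        sizes[pop] = int(mask.sum())
    counts = pd.DataFrame(counts).T
    return ROHFrequencyTrack(counts=counts, sizes=pd.Series(sizes))


def chisq_per_snp(track: ROHFrequencyTrack, pop_a, pop_b):
    """1-df Pearson chi-square per SNP on the 2x2 population x in-ROH table.

    Returns (statistic, p).  SNPs with an all-zero (or all-one) in-ROH
    margin get statistic 0, p 1.
    """
    for pop in (pop_a, pop_b):
        if pop not in track.counts.index:
            raise ValueError(f"population {pop!r} not in track")
    a = track.counts.loc[pop_a].to_numpy(dtype=float)
    c = track.counts.loc[pop_b].to_numpy(dtype=float)
    na, nb = float(track.sizes[pop_a]), float(track.sizes[pop_b])
    b, d = na - a, nb - c
    n = na + nb
    with np.errstate(invalid="ignore", divide="ignore"):
        chi2 = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
    degenerate = ((a + c) == 0) | ((b + d) == 0)
    chi2 = np.where(degenerate, 0.0, chi2)
    p = stats.chi2.sf(chi2, df=1)
    p = np.where(degenerate, 1.0, p)
    return chi2, p


def _group_freq_diff(status: np.ndarray, mask_a: np.ndarray, mask_b: np.ndarray) -> np.ndarray:
    return np.abs(
        status[mask_a].mean(axis=0) - status[mask_b].mean(axis=0)
    )


def permutation_threshold(
    status: ROHStatusMatrix,
    groups,
    pop_a,
    pop_b,
    n_permutations: int = 1000,
    alpha: float = 0.001,
    seed: int | np.random.SeedSequence | None = 0,
    null_kind: str = "pooled",
) -> PermutationNull:
    """Permutation-calibrated per-SNP significance of the observed absolute
    ROH45-frequency difference between two populations.

    Labels are shuffled preserving group sizes; per permutation the per-SNP
    absolute frequency difference is recomputed.  ``null_kind``:

    - ``pooled`` (default): all B x M null differences pooled; per-SNP
      empirical p = (1 + #{null >= observed}) / (1 + B*M);
    - ``per-snp``: each SNP compared with its own B null values;
    - ``max``: genome-wide-max null, p = (1 + #{max_b >= obs}) / (1 + B).
    """
    groups = np.asarray(groups)
    keep = (groups == pop_a) | (groups == pop_b)
    s = status.status[keep].astype(np.float64)
    g = groups[keep]
    n_a = int((g == pop_a).sum())
    n_b = int((g == pop_b).sum())
    if n_a == 0 or n_b == 0:
        raise ValueError("both populations must be non-empty")
    n, m = s.shape
    observed = _group_freq_diff(s, g == pop_a, g == pop_b)

    rng = np.random.default_rng(seed)
    # one matmul per batch: column j of P is 1/n_a for permuted group A, -1/n_b otherwise
    B = int(n_permutations)
    if B < 1:
        raise ValueError("n_permutations must be >= 1")
    null = np.empty((B, m), dtype=np.float64)
    batch = max(1, min(B, 64))
    weights_a = np.full(n, -1.0 / n_b)
    done = 0
    while done < B:
        k = min(batch, B - done)
        P = np.tile(weights_a[:, None], (1, k))
        for c in range(k):
            idx = rng.choice(n, size=n_a, replace=False)
            P[idx, c] = 1.0 / n_a
        null[done : done + k] = np.abs(s.T @ P).T
        done += k

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


def call_differential_regions(
    p_values: np.ndarray,
    markers: pd.DataFrame,
    freq_diff: np.ndarray | None = None,
    min_snps: int = 45,
    min_span_mb: float = 4.0,
    alpha: float = 0.001,
) -> list[RegionCall]:
    """Contiguous runs of SNPs with p < alpha, kept at >= min_snps SNPs and
    > min_span_mb Mb; region peak = SNP of maximum |frequency difference|."""
    flags = np.asarray(p_values) < alpha
    return call_regions(
        flags, markers, "differential", min_snps, min_span_mb, peak_values=freq_diff
    )


def call_common_high_regions(
    track: ROHFrequencyTrack,
    markers: pd.DataFrame,
    quantile: float = 0.975,
    min_snps: int = 45,
    min_span_mb: float = 4.0,
) -> list[RegionCall]:
    """Regions of jointly high ROH45 frequency: per population, SNPs at or
    above that population's ``quantile`` frequency threshold (ties included);
    flags intersected across populations; same length/span rule."""
    freqs = track.frequencies
    flags = np.ones(freqs.shape[1], dtype=bool)
    for pop in freqs.index:
        f = freqs.loc[pop].to_numpy()
        thr = np.quantile(f, quantile)
        flags &= f >= thr
    peak = freqs.mean(axis=0).to_numpy()
    return call_regions(flags, markers, "common_high", min_snps, min_span_mb, peak_values=peak)


def differential_table(
    markers: pd.DataFrame,
    track: ROHFrequencyTrack,
    pop_a,
    pop_b,
    chi2,
    p_chisq,
    perm: PermutationNull,
) -> pd.DataFrame:
    """Per-SNP results table for export."""
    freqs = track.frequencies
    return pd.DataFrame(
        {
            "chromosome": markers["chromosome"],
            "position_bp": markers["position_bp"],
            "snp_id": markers["snp_id"],
            f"freq_{pop_a}": freqs.loc[pop_a].to_numpy(),
            f"freq_{pop_b}": freqs.loc[pop_b].to_numpy(),
            "abs_diff": perm.observed,
            "chisq": chi2,
            "p_chisq": p_chisq,
            "p_perm": perm.p_values,
        }
    )
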