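"""Population structure: genomic relationship matrix, PCA, windowed F_ST.

The GRM follows the Yang et al. single-SNP form: the diagonal element for
individual j is

    1 + (1/N) * sum_m [x_jm^2 - (1+2 p_m) x_jm + 2 p_m^2] / [2 p_m (1-p_m)]

and the off-diagonal (j,k) element is the usual standardized cross-product
(1/N) * sum_m (x_jm - 2 p_m)(x_km - 2 p_m) / [2 p_m (1-p_m)], with p_m the
allele frequency computed on the combined sample.  Under Hardy–Weinberg the
diagonal has expectation 1.  The GRM is not guaranteed positive
semi-definite; PCA keeps negative eigenvalues in the variance total.

F_ST between two populations is the Weir & Cockerham (1984) theta
= a/(a+b+c) with the full diploid variance components (including the
observed-heterozygosity term), reported per SNP and as the mean of a
moving window of consecutive SNPs within chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeDataset


@dataclass
class GRM:
    matrix: np.ndarray  # samples x samples
    sample_ids: list[str]
    n_snps_used: int


@dataclass
class PCAResult:
    eigenvalues: np.ndarray  # descending
    eigenvectors: np.ndarray  # samples x components, column i pairs with eigenvalue i
    variance_fraction: np.ndarray


@dataclass
class FstTrack:
    """Per-window mean Weir–Cockerham theta; ``per_snp`` holds the raw values."""

    table: pd.DataFrame  # chromosome, window_start_bp, window_end_bp, theta_mean
    per_snp: np.ndarray
    window_snps: int

    @property
    def genome_mean(self) -> float:
        return float(np.nanmean(self.table["theta_mean"]))

    @property
    def genome_max(self) -> float:
        return float(np.nanmax(self.table["theta_mean"]))


def build_grm(data: GenotypeDataset) -> GRM:
    """Yang-style GRM on the combined sample; SNPs fixed (p in {0,1}) or
    all-missing are excluded; missing calls drop a SNP from the affected
    pairs with per-pair N adjustment."""
    if data.n_samples < 2:
        raise ValueError("GRM needs at least two samples")
    p = data.allele_frequencies()
    usable = np.isfinite(p) & (p > 0) & (p < 1)
    n_dropped = int((~usable).sum())
    if usable.sum() == 0:
        raise ValueError("no polymorphic SNPs for GRM")
    if n_dropped:
        import logging

        logging.getLogger(__name__).info("GRM: excluded %d fixed/empty SNPs", n_dropped)
    calls = data.calls[:, usable].astype(float)
    p = p[usable]
    obs = calls != MISSING
    x = np.where(obs, calls, 0.0)
    denom = 2.0 * p * (1.0 - p)

    # off-diagonals: standardized cross-products with pairwise SNP counts
    z = np.where(obs, (x - 2.0 * p) / np.sqrt(denom), 0.0)
    cross = z @ z.T
    pair_n = obs.astype(float) @ obs.astype(float).T
    with np.errstate(invalid="ignore", divide="ignore"):
        g = cross / pair_n

    # Yang diagonal: 1 + mean of the single-SNP inbreeding term, which has
    # expectation 0 under Hardy-Weinberg (so E[diagonal] = 1)
    diag_terms = np.where(obs, (x**2 - (1 + 2 * p) * x + 2 * p**2) / denom, 0.0)
    n_i = obs.sum(axis=1)
    np.fill_diagonal(g, 1.0 + diag_terms.sum(axis=1) / n_i)
    return GRM(matrix=g, sample_ids=list(data.samples["animal_id"]), n_snps_used=int(usable.sum()))


def pca(grm: GRM, symmetry_tol: float = 1e-8) -> PCAResult:
    """Eigendecomposition of the GRM; variance fraction_i = lambda_i / sum(lambda)
    with negative eigenvalues retained in the total."""
    g = np.asarray(grm.matrix, dtype=float)
    if not np.isfinite(g).all():
        raise ValueError("GRM contains non-finite entries")
    if np.abs(g - g.T).max() > symmetry_tol * max(1.0, np.abs(g).max()):
        raise ValueError("GRM is not symmetric within tolerance")
    w, v = np.linalg.eigh((g + g.T) / 2.0)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    total = w.sum()
    frac = w / total if total != 0 else np.full_like(w, np.nan)
    return PCAResult(eigenvalues=w, eigenvectors=v, variance_fraction=frac)


def _wc_components(calls_a: np.ndarray, calls_b: np.ndarray):
    """Weir–Cockerham a, b, c variance components per SNP for two diploid
    samples (r = 2), from 0/1/2 dosages with missing as MISSING."""
    comps = []
    n_list, p_list, h_list = [], [], []
    for calls in (calls_a, calls_b):
        obs = calls != MISSING
        n = obs.sum(axis=0).astype(float)  # individuals
        x = np.where(obs, calls, 0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = x.sum(axis=0) / (2.0 * n)
            h = np.where(obs, calls == 1, False).sum(axis=0) / n
        n_list.append(n)
        p_list.append(p)
        h_list.append(h)
    n1, n2 = n_list
    p1, p2 = p_list
    h1, h2 = h_list
    r = 2.0
    nbar = (n1 + n2) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2
            - (1.0 / (nbar - 1.0))
            * (pbar * (1.0 - pbar) - ((r - 1.0) / r) * s2 - hbar / 4.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1.0 - pbar)
            - ((r - 1.0) / r) * s2
            - ((2.0 * nbar - 1.0) / (4.0 * nbar)) * hbar
        )
        c = hbar / 2.0
    return a, b, c, pbar


def fst_windowed(
    data_a: GenotypeDataset, data_b: GenotypeDataset, window_snps: int = 8
) -> FstTrack:
    """Per-SNP Weir–Cockerham theta between two populations, averaged over a
    sliding window of ``window_snps`` consecutive SNPs within chromosome
    (step 1).  SNPs monomorphic in both populations yield undefined theta and
    are excluded from window means."""
    if not data_a.markers["snp_id"].equals(data_b.markers["snp_id"]):
        raise ValueError("datasets must share an identical SNP set and order")
    if window_snps < 1:
        raise ValueError("window_snps must be >= 1")
    a, b, c, pbar = _wc_components(data_a.calls, data_b.calls)
    denom = a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = a / denom
    undefined = ~np.isfinite(theta) | (pbar <= 0) | (pbar >= 1)
    theta = np.where(undefined, np.nan, theta)

    chrom = data_a.markers["chromosome"].to_numpy()
    pos = data_a.markers["position_bp"].to_numpy()
    rows = []
    for ch in np.unique(chrom):
        idx = np.flatnonzero(chrom == ch)
        t = theta[idx]
        m = len(idx)
        w = min(window_snps, m)
        for start in range(m - w + 1):
            vals = t[start : start + w]
            mean = float(np.nanmean(vals)) if np.isfinite(vals).any() else np.nan
            rows.append(
                (int(ch), int(pos[idx[start]]), int(pos[idx[start + w - 1]]), mean)
            )
    table = pd.DataFrame(
        rows, columns=["chromosome", "window_start_bp", "window_end_bp", "theta_mean"]
    )
    return FstTrack(table=table, per_snp=theta, window_snps=window_snps)
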