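"""Region calling from per-SNP flags: contiguous runs on one chromosome of
at least ``min_snps`` SNPs spanning more than ``min_span_mb`` megabases.

The same rule declares differential-autozygosity regions (flag = permutation
p < alpha), common high-autozygosity regions (flag = jointly in every
population's top quantile) and temporal trend regions."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class RegionCall:
    kind: str  # differential | common_high | temporal
    chromosome: int
    start_bp: int
    end_bp: int
    n_snps: int
    peak_bp: int | None = None
    peak_value: float | None = None

    @property
    def span_mb(self) -> float:
        return (self.end_bp - self.start_bp) / 1e6


def call_regions(
    flags: np.ndarray,
    markers: pd.DataFrame,
    kind: str,
    min_snps: int = 45,
    min_span_mb: float = 4.0,
    peak_values: np.ndarray | None = None,
) -> list[RegionCall]:
    """Maximal runs of flagged SNPs within chromosome, kept iff the run has
    >= ``min_snps`` SNPs and spans > ``min_span_mb`` Mb.  ``peak_values``
    (e.g. |frequency difference|) locates each region's peak SNP."""
    flags = np.asarray(flags, dtype=bool)
    chrom = markers["chromosome"].to_numpy()
    pos = markers["position_bp"].to_numpy()
    if len(flags) != len(markers):
        raise ValueError("flags and marker map length mismatch")
    chrom_start = np.r_[True, chrom[1:] != chrom[:-1]]
    edges = np.zeros(len(flags) + 1, dtype=bool)
    edges[0] = edges[-1] = True
    edges[1:-1] = (flags[1:] != flags[:-1]) | chrom_start[1:]
    idx = np.flatnonzero(edges)
    regions: list[RegionCall] = []
    for a, b in zip(idx[:-1], idx[1:]):
        if not flags[a]:
            continue
        n = b - a
        span_mb = (pos[b - 1] - pos[a]) / 1e6
        if n >= min_snps and span_mb > min_span_mb:
            peak_bp = peak_value = None
            if peak_values is not None:
                vals = np.abs(peak_values[a:b])
                vmax = np.nanmax(vals)
                # ties (a flat plateau of the statistic) resolve to the
                # central tied SNP, not an arbitrary end of the plateau
                tied = np.flatnonzero(vals == vmax)
                j = a + int(tied[len(tied) // 2])
                peak_bp = int(pos[j])
                peak_value = float(peak_values[j])
            regions.append(
                RegionCall(
                    kind=kind,
                    chromosome=int(chrom[a]),
                    start_bp=int(pos[a]),
                    end_bp=int(pos[b - 1]),
                    n_snps=int(n),
                    peak_bp=peak_bp,
                    peak_value=peak_value,
                )
            )
    return regions


def regions_to_frame(regions: list[RegionCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "kind": r.kind,
                "chromosome": r.chromosome,
                "start_bp": r.start_bp,
                "end_bp": r.end_bp,
                "start_mb": r.start_bp / 1e6,
                "end_mb": r.end_bp / 1e6,
                "n_snps": r.n_snps,
                "span_mb": r.span_mb,
                "peak_bp": r.peak_bp,
                "peak_value": r.peak_value,
            }
            for r in regions
        ],
        columns=[
            "kind", "chromosome", "start_bp", "end_bp", "start_mb", "end_mb",
            "n_snps", "span_mb", "peak_bp", "peak_value",
        ],
    )
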