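"""Runs-of-homozygosity calling and the per-SNP ROH45 statistic.

A ROH is a maximal run of contiguous homozygous, non-missing SNP calls on
one chromosome of one animal, retained when its SNP count reaches the
calling length ``L`` (45, 70 or 95 by default).  This equals the union of
all length-``L`` sliding windows that contain no heterozygote and no
missing call.  The ROH-status indicator marks every SNP inside such a run
— including the SNPs beyond the first ``L`` — so animals whose runs start
and stop at slightly different markers still coincide at shared interior
SNPs.

Missing calls terminate a run (like a heterozygote) but are excluded from
the overall-homozygosity denominator; ``missing_in_roh="skip"`` instead
lets a run continue across missing calls without counting them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeDataset

DEFAULT_LENGTHS = (45, 70, 95)


@dataclass
class ROHSegment:
    animal_id: str
    chromosome: int
    start_index: int  # inclusive, genome-wide map order
    end_index: int  # inclusive
    start_bp: int
    end_bp: int
    n_snps: int

    @property
    def length_mb(self) -> float:
        return (self.end_bp - self.start_bp) / 1e6


@dataclass
class ROHStatusMatrix:
    """Binary animals x SNPs indicator of membership in a ROH of >= L SNPs."""

    status: np.ndarray  # uint8, animals x SNPs
    L: int


def _check_sorted(data: GenotypeDataset) -> None:
    m = data.markers
    chrom = m["chromosome"].to_numpy()
    pos = m["position_bp"].to_numpy()
    new_chrom = np.r_[True, chrom[1:] != chrom[:-1]]
    if not (np.diff(chrom) >= 0).all() or not (np.diff(pos)[~new_chrom[1:]] > 0).all():
        raise ValueError("marker map must be sorted by (chromosome, position)")


def _homozygous(calls: np.ndarray, missing_in_roh: str) -> np.ndarray:
    hom = (calls == 0) | (calls == 2)
    if missing_in_roh == "skip":
        hom |= calls == MISSING
    elif missing_in_roh != "break":
        raise ValueError("missing_in_roh must be 'break' or 'skip'")
    return hom


def call_roh(
    data: GenotypeDataset, L: int, missing_in_roh: str = "break"
) -> list[ROHSegment]:
    """Every maximal homozygous run of >= L SNPs, per animal per chromosome.

    With ``missing_in_roh="skip"``, missing calls neither break a run nor
    count toward its SNP length.
    """
    if L < 2:
        raise ValueError("L must be >= 2")
    _check_sorted(data)
    chrom = data.markers["chromosome"].to_numpy()
    pos = data.markers["position_bp"].to_numpy()
    hom = _homozygous(data.calls, missing_in_roh)
    # run breaks at chromosome boundaries
    chrom_start = np.r_[True, chrom[1:] != chrom[:-1]]
    segments: list[ROHSegment] = []
    ids = data.samples["animal_id"].to_numpy()
    n_markers = data.n_markers
    informative = data.calls != MISSING
    for i in range(data.n_samples):
        h = hom[i]
        # run boundaries: where h flips or a new chromosome starts
        run_edges = np.zeros(n_markers + 1, dtype=bool)
        run_edges[0] = True
        run_edges[-1] = True
        run_edges[1:-1] = (h[1:] != h[:-1]) | chrom_start[1:]
        idx = np.flatnonzero(run_edges)
        for a, b in zip(idx[:-1], idx[1:]):  # [a, b) constant-h, one chromosome
            if not h[a]:
                continue
            n_informative = int(informative[i, a:b].sum()) if missing_in_roh == "skip" else b - a
            if n_informative >= L:
                segments.append(
                    ROHSegment(
                        animal_id=str(ids[i]),
                        chromosome=int(chrom[a]),
                        start_index=int(a),
                        end_index=int(b - 1),
                        start_bp=int(pos[a]),
                        end_bp=int(pos[b - 1]),
                        n_snps=int(b - a),
                    )
                )
    return segments


def roh_status(
    data: GenotypeDataset, L: int, missing_in_roh: str = "break"
) -> ROHStatusMatrix:
    """Binary per-SNP indicator of lying in a ROH of >= L SNPs.

    Vectorized across animals: a run of length ``r >= L`` marks all ``r``
    SNPs, not only the first ``L``.
    """
    if L < 2:
        raise ValueError("L must be >= 2")
    _check_sorted(data)
    chrom = data.markers["chromosome"].to_numpy()
    hom = _homozygous(data.calls, missing_in_roh)
    n, m = hom.shape
    chrom_start = np.r_[True, chrom[1:] != chrom[:-1]]

    # cumulative run length ending at each SNP, reset at breaks
    status = np.zeros((n, m), dtype=np.uint8)
    run = np.zeros(n, dtype=np.int32)
    informative = data.calls != MISSING
    # forward pass: run length; backward fill once a run reaches L
    run_len = np.zeros((n, m), dtype=np.int32)
    for j in range(m):
        if chrom_start[j]:
            run[:] = 0
        col_hom = hom[:, j]
        if missing_in_roh == "skip":
            inc = col_hom & informative[:, j]
            run = np.where(col_hom, run + inc, 0)
        else:
            run = np.where(col_hom, run + 1, 0)
        run_len[:, j] = run
    # a SNP is in-status iff some maximal run containing it has length >= L:
    # scan backwards propagating the terminal run length
    carry = np.zeros(n, dtype=np.int32)
    for j in range(m - 1, -1, -1):
        # carry holds the final length of the run this SNP belongs to
        cur = run_len[:, j]
        ended = (j == m - 1) or chrom_start[j + 1]
        if ended:
            carry = cur.copy()
        else:
            nxt = run_len[:, j + 1]
            carry = np.where(nxt == 0, cur, carry)
        status[:, j] = (cur > 0) & (carry >= L)
    return ROHStatusMatrix(status=status, L=L)


@dataclass
class HomozygositySummary:
    """Per-animal overall homozygosity and proportion-of-genome-in-ROH."""

    table: pd.DataFrame  # animal_id, population, homozygosity, prop_roh{L}...
    genome_mb: float


def genome_covered_mb(data: GenotypeDataset) -> float:
    """SNP-covered span: sum over chromosomes of (last - first SNP bp), in Mb."""
    m = data.markers
    span = m.groupby("chromosome")["position_bp"].agg(lambda s: s.max() - s.min())
    return float(span.sum()) / 1e6


def homozygosity_summary(
    data: GenotypeDataset,
    segments_per_L: dict[int, list[ROHSegment]],
    genome_mb: float | None = None,
) -> HomozygositySummary:
    """Overall genomic homozygosity and, per calling length L, the fraction
    of the genome inside ROH (sum of segment Mb over genome Mb).

    ``genome_mb`` defaults to the SNP-covered span, under which an
    all-homozygous genome scores exactly 1; pass assembly lengths to use
    fixed chromosome sizes instead.
    """
    if genome_mb is None:
        genome_mb = genome_covered_mb(data)
    if genome_mb <= 0:
        raise ValueError("genome length must be positive")
    obs = data.calls != MISSING
    hom = (data.calls == 0) | (data.calls == 2)
    with np.errstate(invalid="ignore"):
        overall = np.where(obs.sum(axis=1) > 0, hom.sum(axis=1) / obs.sum(axis=1), np.nan)
    table = data.samples[["animal_id", "population"]].copy()
    table["homozygosity"] = overall
    for L, segs in sorted(segments_per_L.items()):
        mb = pd.Series(0.0, index=table["animal_id"])
        for s in segs:
            mb[s.animal_id] += s.length_mb
        table[f"prop_roh{L}"] = (mb / genome_mb).to_numpy()
    return HomozygositySummary(table=table, genome_mb=genome_mb)


def segments_to_frame(segments: list[ROHSegment]) -> pd.DataFrame:
    """BED-like table of segments (closed bp intervals)."""
    return pd.DataFrame(
        [
            {
                "chromosome": s.chromosome,
                "start_bp": s.start_bp,
                "end_bp": s.end_bp,
                "animal_id": s.animal_id,
                "n_snps": s.n_snps,
                "length_mb": s.length_mb,
            }
            for s in segments
        ],
        columns=["chromosome", "start_bp", "end_bp", "animal_id", "n_snps", "length_mb"],
    )
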