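"""Genotype, map, pedigree and phenotype I/O plus quality control.

Genotypes are held as an animals x SNPs matrix of alternate-allele (A2)
dosages coded 0/1/2 with ``MISSING`` (-1) as the missing sentinel.  The
marker map is a DataFrame sorted by (chromosome, position); only autosomes
(chromosomes 1..29 for cattle) are retained — sex-chromosome markers are
dropped on read.

Supported on-disk formats: PLINK ped/map (text) and bed/bim/fam
(SNP-major binary), a three-column whitespace pedigree and a headered
phenotype TSV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

MISSING: int = -1
N_AUTOSOMES: int = 29

MAP_COLUMNS = ["snp_id", "chromosome", "position_bp", "a1", "a2"]
SAMPLE_COLUMNS = ["animal_id", "population", "sex", "birth_year", "herd_id"]

# PLINK .bed 2-bit codes (SNP-major): 00=hom A1, 01=missing, 10=het, 11=hom A2
_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])
_BED_DECODE = np.array([0, MISSING, 1, 2], dtype=np.int8)


class FormatError(ValueError):
    """Raised when companion PLINK files disagree or are malformed."""


@dataclass
class GenotypeDataset:
    """Genotype matrix plus marker map and sample metadata.

    Attributes
    ----------
    samples : DataFrame with columns animal_id, population, sex,
        birth_year, herd_id (one row per animal).
    markers : DataFrame with columns snp_id, chromosome, position_bp,
        a1, a2, sorted by (chromosome, position_bp).
    calls : int8 array, shape (n_samples, n_markers); A2 dosage 0/1/2,
        MISSING for no-calls.
    """

    samples: pd.DataFrame
    markers: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.markers)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.markers)} markers"
            )
        ok = np.isin(self.calls, (0, 1, 2, MISSING))
        if not ok.all():
            bad = np.unique(self.calls[~ok])
            raise ValueError(f"invalid genotype codes {bad!r}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def allele_frequencies(self) -> np.ndarray:
        """Per-SNP A2 allele frequency over non-missing calls (nan if none)."""
        calls = self.calls
        obs = calls != MISSING
        n = obs.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(obs, calls, 0).sum(axis=0) / (2.0 * n)
        return np.where(n > 0, p, np.nan)

    def subset_samples(self, index: np.ndarray | Sequence[int]) -> "GenotypeDataset":
        index = np.asarray(index)
        return GenotypeDataset(
            self.samples.iloc[index].reset_index(drop=True),
            self.markers.copy(),
            self.calls[index],
        )

    def subset_markers(self, index: np.ndarray | Sequence[int]) -> "GenotypeDataset":
        index = np.asarray(index)
        return GenotypeDataset(
            self.samples.copy(),
            self.markers.iloc[index].reset_index(drop=True),
            self.calls[:, index],
        )


@dataclass
class QCReport:
    """Itemized record of what apply_qc removed and why."""

    removed_samples: pd.DataFrame  # animal_id, reason, value
    removed_snps: pd.DataFrame  # snp_id, reason, value
    thresholds: dict = field(default_factory=dict)

    def to_tsv(self, path: str | Path) -> None:
        samp = self.removed_samples.assign(kind="sample").rename(
            columns={"animal_id": "id"}
        )
        snp = self.removed_snps.assign(kind="snp").rename(columns={"snp_id": "id"})
        pd.concat([samp, snp], ignore_index=True).to_csv(path, sep="\t", index=False)


@dataclass
class Pedigree:
    """Three-column pedigree; unknown parents are the empty string.

    Records are kept in an order with parents before offspring; building
    enforces acyclicity.
    """

    records: pd.DataFrame  # animal_id, sire_id, dam_id

    def __post_init__(self) -> None:
        self.records = self.records.reset_index(drop=True)
        self._toposort()

    def _toposort(self) -> None:
        rec = self.records
        known = set(rec["animal_id"])
        parents = {
            a: tuple(p for p in (s, d) if p in known)
            for a, s, d in rec.itertuples(index=False)
        }
        order: list[str] = []
        state: dict[str, int] = {}

        def visit(a: str) -> None:
            stack = [(a, iter(parents[a]))]
            state[a] = 1
            while stack:
                node, it = stack[-1]
                for p in it:
                    st = state.get(p)
                    if st == 1:
                        raise ValueError(f"pedigree cycle involving {node!r}")
                    if st is None:
                        state[p] = 1
                        stack.append((p, iter(parents[p])))
                        break
                else:
                    state[node] = 2
                    order.append(node)
                    stack.pop()

        for a in rec["animal_id"]:
            if state.get(a) is None:
                visit(a)
        pos = {a: i for i, a in enumerate(order)}
        self.records = rec.iloc[np.argsort([pos[a] for a in rec["animal_id"]])]
        self.records = self.records.reset_index(drop=True)

    @property
    def animals(self) -> list[str]:
        return list(self.records["animal_id"])


def _sort_markers(markers: pd.DataFrame, calls: np.ndarray) -> tuple[pd.DataFrame, np.ndarray]:
    order = np.lexsort((markers["position_bp"].to_numpy(), markers["chromosome"].to_numpy()))
    return markers.iloc[order].reset_index(drop=True), calls[:, order]


def _drop_non_autosomal(markers: pd.DataFrame, calls: np.ndarray):
    chrom = pd.to_numeric(markers["chromosome"], errors="coerce")
    keep = chrom.between(1, N_AUTOSOMES).to_numpy()
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("dropping %d non-autosomal markers", n_drop)
    markers = markers.loc[keep].reset_index(drop=True)
    markers["chromosome"] = chrom[keep].astype(int).to_numpy()
    return markers, calls[:, keep]


def _default_samples(fam: pd.DataFrame) -> pd.DataFrame:
    sex = fam["sex"].map({1: "bull", 2: "cow"}).fillna("cow")
    return pd.DataFrame(
        {
            "animal_id": fam["iid"].astype(str),
            "population": fam["fid"].astype(str),
            "sex": sex,
            "birth_year": 0,
            "herd_id": "",
        }
    )


def read_plink(path_prefix: str | Path, dialect: str = "auto") -> GenotypeDataset:
    """Read a PLINK fileset into a :class:`GenotypeDataset`.

    ``dialect`` is ``"ped"`` (ped/map), ``"bed"`` (bed/bim/fam) or
    ``"auto"`` (prefer bed if present).  Calls are coded as the count of
    the A2 allele; non-autosomal markers are dropped with a logged count.
    The PLINK family id is used as the population label.
    """
    prefix = Path(path_prefix)
    if dialect == "auto":
        dialect = "bed" if prefix.with_suffix(".bed").exists() else "ped"
    if dialect == "bed":
        return _read_bed(prefix)
    if dialect == "ped":
        return _read_ped(prefix)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_map_like(path: Path) -> pd.DataFrame:
    raw = pd.read_csv(path, sep=r"\s+", header=None)
    if raw.shape[1] == 4:  # .map: chrom id cm bp
        markers = raw.rename(columns={0: "chromosome", 1: "snp_id", 3: "position_bp"})
        markers["a1"], markers["a2"] = "A", "B"
    elif raw.shape[1] == 6:  # .bim: chrom id cm bp a1 a2
        markers = raw.rename(
            columns={0: "chromosome", 1: "snp_id", 3: "position_bp", 4: "a1", 5: "a2"}
        )
    else:
        raise FormatError(f"{path}: expected 4 or 6 columns, got {raw.shape[1]}")
    markers["snp_id"] = markers["snp_id"].astype(str)
    if markers["snp_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate snp ids")
    return markers[MAP_COLUMNS]


def _read_fam(path: Path) -> pd.DataFrame:
    fam = pd.read_csv(path, sep=r"\s+", header=None, dtype=str)
    fam.columns = ["fid", "iid", "pat", "mat", "sex", "pheno"][: fam.shape[1]]
    fam["sex"] = pd.to_numeric(fam["sex"], errors="coerce")
    return fam


def _read_ped(prefix: Path) -> GenotypeDataset:
    markers = _read_map_like(prefix.with_suffix(".map"))
    ped = pd.read_csv(prefix.with_suffix(".ped"), sep=r"\s+", header=None, dtype=str)
    n_allele_cols = ped.shape[1] - 6
    if n_allele_cols != 2 * len(markers):
        raise FormatError(
            f"{prefix}.ped has {n_allele_cols} allele columns for "
            f"{len(markers)} map markers"
        )
    fam = ped.iloc[:, :6].copy()
    fam.columns = ["fid", "iid", "pat", "mat", "sex", "pheno"]
    fam["sex"] = pd.to_numeric(fam["sex"], errors="coerce")

    alleles = ped.iloc[:, 6:].to_numpy(dtype="U4")
    a_first, a_second = alleles[:, 0::2], alleles[:, 1::2]
    miss = (a_first == "0") | (a_second == "0")
    # .map carries no allele labels: the counted (A2) allele is the
    # lexicographically greater of the observed alleles; a SNP with a
    # single observed allele is coded as all-0 dosage of a hypothetical A2.
    a1_inf = np.empty(len(markers), dtype="U4")
    a2_inf = np.empty(len(markers), dtype="U4")
    for j in range(len(markers)):
        seen = sorted(
            set(a_first[:, j][~miss[:, j]]) | set(a_second[:, j][~miss[:, j]])
        )
        if len(seen) > 2:
            raise FormatError(f"marker {markers['snp_id'][j]}: >2 alleles {seen}")
        a1_inf[j] = seen[0] if seen else "A"
        a2_inf[j] = seen[-1] if len(seen) == 2 else "B"
    markers = markers.assign(a1=a1_inf, a2=a2_inf)
    a2 = a2_inf[None, :]
    calls = (a_first == a2).astype(np.int8) + (a_second == a2).astype(np.int8)
    calls[miss] = MISSING

    markers, calls = _drop_non_autosomal(markers, calls)
    markers, calls = _sort_markers(markers, calls)
    return GenotypeDataset(_default_samples(fam), markers, calls)


def _read_bed(prefix: Path) -> GenotypeDataset:
    markers = _read_map_like(prefix.with_suffix(".bim"))
    fam = _read_fam(prefix.with_suffix(".fam"))
    n, m = len(fam), len(markers)
    raw = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
    if raw[:3].tobytes() != _BED_MAGIC:
        raise FormatError(f"{prefix}.bed: bad magic (not SNP-major PLINK bed)")
    bytes_per_snp = (n + 3) // 4
    body = raw[3:]
    if body.size != bytes_per_snp * m:
        raise FormatError(
            f"{prefix}.bed: {body.size} data bytes, expected {bytes_per_snp * m}"
        )
    blocks = body.reshape(m, bytes_per_snp)
    two_bit = np.stack(
        [(blocks >> shift) & 0b11 for shift in (0, 2, 4, 6)], axis=-1
    ).reshape(m, -1)[:, :n]
    calls = _BED_DECODE[two_bit].T  # -> samples x markers
    markers, calls = _drop_non_autosomal(markers, calls)
    markers, calls = _sort_markers(markers, calls)
    return GenotypeDataset(_default_samples(fam), markers, calls)


def write_plink(data: GenotypeDataset, path_prefix: str | Path, dialect: str = "ped") -> None:
    """Write ped/map or bed/bim/fam; inverse of :func:`read_plink` on calls,
    map and (population, sex) metadata."""
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    markers = data.markers
    sex_code = data.samples["sex"].map({"bull": 1, "cow": 2}).fillna(0).astype(int)
    fam = pd.DataFrame(
        {
            "fid": data.samples["population"],
            "iid": data.samples["animal_id"],
            "pat": 0,
            "mat": 0,
            "sex": sex_code,
            "pheno": -9,
        }
    )
    if dialect == "ped":
        markers.assign(cm=0)[["chromosome", "snp_id", "cm", "position_bp"]].to_csv(
            prefix.with_suffix(".map"), sep="\t", header=False, index=False
        )
        a1 = markers["a1"].to_numpy(dtype="U4")
        a2 = markers["a2"].to_numpy(dtype="U4")
        first = np.where(data.calls >= 1, a2[None, :], a1[None, :]).astype("U4")
        second = np.where(data.calls == 2, a2[None, :], a1[None, :]).astype("U4")
        miss = data.calls == MISSING
        first[miss] = "0"
        second[miss] = "0"
        geno = np.empty((data.n_samples, 2 * data.n_markers), dtype="U4")
        geno[:, 0::2], geno[:, 1::2] = first, second
        out = pd.concat(
            [fam.reset_index(drop=True), pd.DataFrame(geno)], axis=1
        )
        out.to_csv(prefix.with_suffix(".ped"), sep="\t", header=False, index=False)
    elif dialect == "bed":
        markers.assign(cm=0)[
            ["chromosome", "snp_id", "cm", "position_bp", "a1", "a2"]
        ].to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
        fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)
        encode = np.array([0b00, 0b10, 0b11], dtype=np.uint8)
        codes = np.where(
            data.calls == MISSING, 0b01, encode[np.clip(data.calls, 0, 2)]
        ).astype(np.uint8)
        n = data.n_samples
        pad = (-n) % 4
        if pad:
            codes = np.vstack([codes, np.zeros((pad, data.n_markers), np.uint8)])
        quads = codes.T.reshape(data.n_markers, -1, 4)
        packed = (
            quads[:, :, 0]
            | (quads[:, :, 1] << 2)
            | (quads[:, :, 2] << 4)
            | (quads[:, :, 3] << 6)
        ).astype(np.uint8)
        with open(prefix.with_suffix(".bed"), "wb") as fh:
            fh.write(_BED_MAGIC)
            packed.tofile(fh)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_pedigree(path: str | Path) -> Pedigree:
    """Three whitespace-delimited columns: animal, sire, dam ('0' or '.' = unknown)."""
    rec = pd.read_csv(
        path, sep=r"\s+", header=None, names=["animal_id", "sire_id", "dam_id"],
        dtype=str, comment="#",
    )
    rec = rec.replace({"0": "", ".": "", "NA": ""}).fillna("")
    return Pedigree(rec)


def write_pedigree(ped: Pedigree, path: str | Path) -> None:
    out = ped.records.replace({"": "0"})
    out.to_csv(path, sep="\t", header=False, index=False)


PHENOTYPE_COLUMNS = [
    "animal_id", "herd_id", "year", "season", "parity", "month", "age",
    "milk", "fat", "protein",
]


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    pheno = pd.read_csv(path, sep="\t")
    missing_cols = set(PHENOTYPE_COLUMNS) - set(pheno.columns)
    if missing_cols:
        raise FormatError(f"phenotype file missing columns {sorted(missing_cols)}")
    return pheno


def write_phenotypes(pheno: pd.DataFrame, path: str | Path) -> None:
    pheno.to_csv(path, sep="\t", index=False)


def hwe_chisq_p(calls: np.ndarray) -> np.ndarray:
    """1-df Pearson chi-square p-value for Hardy–Weinberg per SNP column.

    Observed {0,1,2} counts against expectations from the sample allele
    frequency; no continuity correction.  Monomorphic SNPs get p = 1
    (no departure is testable).
    """
    calls = np.atleast_2d(calls)
    n_aa = (calls == 0).sum(axis=0).astype(float)
    n_ab = (calls == 1).sum(axis=0).astype(float)
    n_bb = (calls == 2).sum(axis=0).astype(float)
    n = n_aa + n_ab + n_bb
    with np.errstate(invalid="ignore", divide="ignore"):
        p = (n_ab + 2 * n_bb) / (2 * n)
        exp = np.stack([n * (1 - p) ** 2, 2 * n * p * (1 - p), n * p**2])
        obs = np.stack([n_aa, n_ab, n_bb])
        chi2 = np.where(exp > 0, (obs - exp) ** 2 / np.where(exp > 0, exp, 1), 0.0).sum(
            axis=0
        )
    pval = stats.chi2.sf(chi2, df=1)
    mono = (p <= 0) | (p >= 1) | (n == 0)
    return np.where(np.isnan(pval) | mono, 1.0, pval)


def apply_qc(
    data: GenotypeDataset,
    min_call_rate: float = 0.90,
    min_maf: float = 0.01,
    hwe_alpha: float = 0.001,
) -> tuple[GenotypeDataset, QCReport]:
    """Quality control: drop low-call-rate samples first, then SNPs failing
    MAF or Hardy–Weinberg.

    Samples with per-sample call rate < ``min_call_rate`` are removed, then
    MAF and HWE are computed on the retained samples and SNPs with
    MAF < ``min_maf`` or HWE chi-square p < ``hwe_alpha`` are removed.
    """
    for name, v in (("min_call_rate", min_call_rate), ("min_maf", min_maf),
                    ("hwe_alpha", hwe_alpha)):
        if not 0 < v < 1:
            raise ValueError(f"{name} must be in (0,1), got {v}")

    call_rate = (data.calls != MISSING).mean(axis=1)
    keep_s = call_rate >= min_call_rate
    removed_samples = pd.DataFrame(
        {
            "animal_id": data.samples.loc[~keep_s, "animal_id"],
            "reason": "call_rate",
            "value": call_rate[~keep_s],
        }
    )
    if not keep_s.any():
        raise ValueError("empty dataset after QC: all samples below call rate")
    data = data.subset_samples(np.flatnonzero(keep_s))

    p = data.allele_frequencies()
    maf = np.minimum(p, 1 - p)
    maf = np.where(np.isnan(maf), 0.0, maf)
    hwe_p = hwe_chisq_p(np.where(data.calls == MISSING, np.nan, data.calls))
    fail_maf = maf < min_maf
    fail_hwe = hwe_p < hwe_alpha
    drop = fail_maf | fail_hwe
    reason = np.where(fail_maf, "maf", "hwe")
    value = np.where(fail_maf, maf, hwe_p)
    removed_snps = pd.DataFrame(
        {
            "snp_id": data.markers.loc[drop, "snp_id"],
            "reason": reason[drop],
            "value": value[drop],
        }
    )
    data = data.subset_markers(np.flatnonzero(~drop))
    report = QCReport(
        removed_samples.reset_index(drop=True),
        removed_snps.reset_index(drop=True),
        {"min_call_rate": min_call_rate, "min_maf": min_maf, "hwe_alpha": hwe_alpha},
    )
    return data, report


def intersect_snps(datasets: Iterable[GenotypeDataset]) -> list[GenotypeDataset]:
    """Restrict every dataset to the SNP ids present in all of them, in a
    common (chromosome, position) order."""
    datasets = list(datasets)
    if len(datasets) < 2:
        raise ValueError("need at least two datasets to intersect")
    common: set[str] = set(datasets[0].markers["snp_id"])
    for d in datasets[1:]:
        common &= set(d.markers["snp_id"])
    if not common:
        raise ValueError("empty SNP intersection")
    out = []
    for d in datasets:
        keep = d.markers["snp_id"].isin(common).to_numpy()
        out.append(d.subset_markers(np.flatnonzero(keep)))
    ref = out[0].markers["snp_id"]
    for d in out[1:]:
        if not d.markers["snp_id"].equals(ref):
            raise FormatError("intersected datasets disagree on marker order")
    return out
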