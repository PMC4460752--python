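"""Multi-population synthetic genotypes, pedigree and phenotypes with truth.

Genotype model: per-SNP ancestral frequencies ~ Uniform(0.05, 0.95);
population frequencies drift from them under the Balding–Nichols model,
Beta(p(1-F)/F, (1-p)(1-F)/F) with F the target F_ST; each animal draws two
haplotypes at linkage equilibrium.  Realistic runs of homozygosity are
created explicitly: inside a planted region an animal becomes a carrier
with the region's per-population probability, and both of its haplotypes
are replaced by a single haplotype drawn once for that region, producing a
true IBD segment spanning the region.  Trend regions move the carrier
probability with birth year through a logistic link, so a logistic
regression of locus autozygosity on birth year is correctly specified and
its slope is the planted log-odds-per-year.

Background linkage disequilibrium is deliberately absent: at intermediate
allele frequencies a spontaneous run of 45 homozygous SNPs is essentially
impossible, so every long ROH in the output is a planted one and the truth
table is exact.

Phenotypes: 1–4 lactation records per cow with herd-year-season, parity,
calving-month and age effects, optional QTL dosage effects, and variance
components set so narrow-sense heritability and repeatability on the
record scale match the configured values (defaults 0.25 and 0.43).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .genotype_io import GenotypeDataset, Pedigree

DEFAULT_POPULATIONS = ("US", "AU", "NZ")


@dataclass
class PlantedRegion:
    chromosome: int
    start_bp: int
    end_bp: int
    carrier_probability: dict[str, float]  # population -> probability

    def __post_init__(self) -> None:
        if self.end_bp <= self.start_bp:
            raise ValueError("end_bp must exceed start_bp")
        for pop, p in self.carrier_probability.items():
            if not 0 <= p <= 1:
                raise ValueError(f"probability for {pop!r} outside [0,1]")


@dataclass
class SimConfig:
    n_populations: int = 2
    samples_per_population_per_year: int = 100
    birth_years: tuple[int, int] = (2001, 2006)  # inclusive
    n_chromosomes: int = 29
    snps_per_chromosome: int = 1000
    chromosome_length_bp: int = 76_000_000
    fst_target: float = 0.01
    planted_regions: list[PlantedRegion] = field(default_factory=list)
    trend_regions: list[tuple[PlantedRegion, float]] = field(default_factory=list)
    trait_h2: float = 0.25
    trait_repeatability: float = 0.43
    qtl_spec: list[tuple[int, float]] = field(default_factory=list)
    n_herds_per_population: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.fst_target < 1:
            raise ValueError("fst_target must be in [0, 1)")
        if not 0 < self.trait_h2 <= self.trait_repeatability < 1:
            raise ValueError("need 0 < h2 <= repeatability < 1")
        for region in self.all_regions():
            if region.chromosome > self.n_chromosomes:
                raise ValueError("planted region beyond chromosome count")
            if region.end_bp > self.chromosome_length_bp:
                raise ValueError("planted region beyond chromosome length")

    @property
    def populations(self) -> tuple[str, ...]:
        return DEFAULT_POPULATIONS[: self.n_populations]

    def all_regions(self) -> list[PlantedRegion]:
        return list(self.planted_regions) + [r for r, _ in self.trend_regions]


@dataclass
class TruthTable:
    """Exact bookkeeping of what was planted."""

    region_carriers: pd.DataFrame  # region, population, n_carriers, n_animals
    carrier_flags: dict[int, dict[str, np.ndarray]]  # region idx -> pop -> bool mask
    region_snp_index: dict[int, np.ndarray]  # region idx -> marker indices
    qtl_effects: list[tuple[int, float]]
    variance_components: dict[str, float]
    allele_freqs: dict[str, np.ndarray]


def _marker_map(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Uniform spacing with jitter; mean spacing length/snps_per_chromosome."""
    spacing = cfg.chromosome_length_bp / cfg.snps_per_chromosome
    rows = []
    for ch in range(1, cfg.n_chromosomes + 1):
        base = (np.arange(cfg.snps_per_chromosome) + 0.5) * spacing
        jitter = rng.uniform(-0.3 * spacing, 0.3 * spacing, cfg.snps_per_chromosome)
        pos = np.sort(np.clip(base + jitter, 1, cfg.chromosome_length_bp - 1)).astype(int)
        pos = np.maximum.accumulate(pos + np.arange(len(pos)) * 0)  # keep sorted
        # enforce strict increase
        for k in range(1, len(pos)):
            if pos[k] <= pos[k - 1]:
                pos[k] = pos[k - 1] + 1
        for j, p in enumerate(pos):
            rows.append((f"snp_{ch}_{j}", ch, int(p), "A", "B"))
    return pd.DataFrame(rows, columns=["snp_id", "chromosome", "position_bp", "a1", "a2"])


def _region_marker_index(markers: pd.DataFrame, region: PlantedRegion) -> np.ndarray:
    m = markers
    mask = (
        (m["chromosome"] == region.chromosome)
        & (m["position_bp"] >= region.start_bp)
        & (m["position_bp"] <= region.end_bp)
    )
    return np.flatnonzero(mask.to_numpy())


def simulate_genotypes(
    config: SimConfig,
) -> tuple[dict[str, GenotypeDataset], TruthTable]:
    """Generate one :class:`GenotypeDataset` per population plus the truth
    table of planted ROH carriers.  Deterministic given ``config.seed``.

    A planted region shorter than 45 map SNPs triggers a warning: such a
    region cannot satisfy the 45-SNP calling rule.
    """
    root = np.random.SeedSequence(config.seed)
    ss_map, ss_freq, ss_geno, ss_plant = root.spawn(4)
    rng_map = np.random.default_rng(ss_map)
    markers = _marker_map(config, rng_map)
    m = len(markers)

    rng_freq = np.random.default_rng(ss_freq)
    p_anc = rng_freq.uniform(0.05, 0.95, m)
    pop_freqs: dict[str, np.ndarray] = {}
    F = config.fst_target
    for pop in config.populations:
        if F == 0:
            pop_freqs[pop] = p_anc.copy()
        else:
            a = p_anc * (1 - F) / F
            b = (1 - p_anc) * (1 - F) / F
            pop_freqs[pop] = np.clip(rng_freq.beta(a, b), 1e-6, 1 - 1e-6)

    years = np.arange(config.birth_years[0], config.birth_years[1] + 1)
    n_per_pop = config.samples_per_population_per_year * len(years)
    mid_year = float(years.mean())

    all_regions = config.all_regions()
    slopes = [0.0] * len(config.planted_regions) + [s for _, s in config.trend_regions]
    region_idx = {i: _region_marker_index(markers, r) for i, r in enumerate(all_regions)}
    import warnings

    for i, r in enumerate(all_regions):
        if len(region_idx[i]) < 45:
            warnings.warn(
                f"planted region {i} covers only {len(region_idx[i])} map SNPs "
                "(< 45): it cannot satisfy the 45-SNP rule",
                stacklevel=2,
            )

    rng_geno = np.random.default_rng(ss_geno)
    rng_plant = np.random.default_rng(ss_plant)
    # one shared IBD haplotype per region, drawn from the ancestral frequencies
    region_haplotype = {
        i: (rng_plant.random(len(region_idx[i])) < p_anc[region_idx[i]]).astype(np.int8)
        for i in range(len(all_regions))
    }

    datasets: dict[str, GenotypeDataset] = {}
    carrier_flags: dict[int, dict[str, np.ndarray]] = {i: {} for i in range(len(all_regions))}
    carrier_rows = []
    for pop in config.populations:
        p = pop_freqs[pop]
        h1 = (rng_geno.random((n_per_pop, m)) < p).astype(np.int8)
        h2 = (rng_geno.random((n_per_pop, m)) < p).astype(np.int8)
        calls = h1 + h2
        birth_year = np.repeat(years, config.samples_per_population_per_year)
        herds = rng_geno.integers(0, config.n_herds_per_population, n_per_pop)
        for i, region in enumerate(all_regions):
            base = region.carrier_probability.get(pop, 0.0)
            slope = slopes[i]
            if slope == 0.0:
                prob = np.full(n_per_pop, base)
            else:
                base_clip = np.clip(base, 1e-9, 1 - 1e-9)
                prob = expit(logit(base_clip) + slope * (birth_year - mid_year))
            carrier = rng_plant.random(n_per_pop) < prob
            idx = region_idx[i]
            calls[np.ix_(carrier, idx)] = 2 * region_haplotype[i][None, :]
            carrier_flags[i][pop] = carrier
            carrier_rows.append(
                {
                    "region": i,
                    "population": pop,
                    "n_carriers": int(carrier.sum()),
                    "n_animals": n_per_pop,
                }
            )
        samples = pd.DataFrame(
            {
                "animal_id": [f"{pop}_{k:05d}" for k in range(n_per_pop)],
                "population": pop,
                "sex": "cow",
                "birth_year": birth_year,
                "herd_id": [f"{pop}_H{h}" for h in herds],
            }
        )
        datasets[pop] = GenotypeDataset(samples, markers.copy(), calls)

    truth = TruthTable(
        region_carriers=pd.DataFrame(carrier_rows),
        carrier_flags=carrier_flags,
        region_snp_index=region_idx,
        qtl_effects=list(config.qtl_spec),
        variance_components={
            "h2": config.trait_h2,
            "repeatability": config.trait_repeatability,
        },
        allele_freqs=pop_freqs,
    )
    return datasets, truth


def simulate_pedigree(
    config: SimConfig, sample_ids: list[str] | None = None, seed_offset: int = 1
) -> Pedigree:
    """Four discrete generations with heavily reused sires (AI-like).

    If ``sample_ids`` is given those animals form the final generation; the
    three ancestor generations are unknown-parent founders at the top.
    """
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, seed_offset)))
    if sample_ids is None:
        n_final = config.samples_per_population_per_year * (
            config.birth_years[1] - config.birth_years[0] + 1
        )
        sample_ids = [f"X_{k:05d}" for k in range(n_final)]
    n_final = len(sample_ids)
    gen_sizes = [max(10, n_final // 4)] * 3 + [n_final]
    records = []
    prev: list[str] = []
    for g, size in enumerate(gen_sizes):
        ids = sample_ids if g == 3 else [f"anc{g}_{k:04d}" for k in range(size)]
        if g == 0:
            for a in ids:
                records.append((a, "", ""))
        else:
            n_sires = max(2, len(prev) // 20)
            sires = rng.choice(prev, size=n_sires, replace=False)
            for a in ids:
                sire = str(rng.choice(sires))
                dam = sire
                while dam == sire:
                    dam = str(rng.choice(prev))
                records.append((a, sire, dam))
        prev = ids
    return Pedigree(pd.DataFrame(records, columns=["animal_id", "sire_id", "dam_id"]))


PARITY_EFFECTS = np.array([0.0, 0.15, 0.22, 0.25])  # lactation curve maturation
AGE_SLOPE = 0.01  # per month of age at first calving
HYS_SD = 0.20
MONTH_SD = 0.05


def simulate_phenotypes(
    data: GenotypeDataset,
    truth: TruthTable,
    config: SimConfig,
    max_parity: int = 4,
    seed_offset: int = 2,
) -> pd.DataFrame:
    """Repeated-lactation records for every animal in ``data``.

    Record model: y = mu + HYS + parity + month + age*b + sum(QTL) + u + pe
    + e, with Var(u) = h2 - V_qtl, Var(u)+Var(pe) = repeatability - V_qtl
    and Var(e) = 1 - repeatability so that narrow-sense heritability and
    repeatability on the record scale equal the configured values.  QTL
    variance (sum of 2 p (1-p) a^2) is deducted from the polygenic part.
    """
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, seed_offset)))
    h2, rep = config.trait_h2, config.trait_repeatability
    p_all = data.allele_frequencies()
    v_qtl = sum(
        2 * p_all[j] * (1 - p_all[j]) * a**2 for j, a in truth.qtl_effects
    )
    var_u = max(h2 - v_qtl, 1e-6)
    var_pe = rep - h2
    var_e = 1.0 - rep
    n = data.n_samples
    u = rng.normal(0, np.sqrt(var_u), n)
    pe = rng.normal(0, np.sqrt(var_pe), n) if var_pe > 0 else np.zeros(n)
    qtl_part = np.zeros(n)
    for j, a in truth.qtl_effects:
        dose = data.calls[:, j].astype(float)
        qtl_part += a * (dose - 2 * p_all[j])

    n_parities = rng.integers(1, max_parity + 1, n)
    age_first = rng.normal(26.0, 3.0, n)
    hys_effects: dict[tuple, float] = {}
    month_effects = rng.normal(0, MONTH_SD, 12)
    rows = []
    for i in range(n):
        animal = data.samples["animal_id"].iloc[i]
        herd = data.samples["herd_id"].iloc[i]
        birth = int(data.samples["birth_year"].iloc[i])
        base = u[i] + pe[i] + qtl_part[i]
        for parity in range(1, int(n_parities[i]) + 1):
            year = birth + 1 + parity
            month = int(rng.integers(1, 13))
            season = (month - 1) // 3 + 1
            key = (herd, year, season)
            if key not in hys_effects:
                hys_effects[key] = float(rng.normal(0, HYS_SD))
            fixed = (
                hys_effects[key]
                + PARITY_EFFECTS[min(parity, len(PARITY_EFFECTS)) - 1]
                + month_effects[month - 1]
                + AGE_SLOPE * (age_first[i] - 26.0)
            )
            record = {
                "animal_id": animal,
                "herd_id": herd,
                "year": year,
                "season": season,
                "parity": parity,
                "month": month,
                "age": age_first[i],
            }
            for trait in ("milk", "fat", "protein"):
                e = float(rng.normal(0, np.sqrt(var_e)))
                record[trait] = base + fixed + e
            rows.append(record)
    return pd.DataFrame(rows)
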