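"""Shared study configuration for the analysis drivers.

One synthetic two-population cohort (US- and AU-like, 500 animals each over
76-kb-spaced maps on five autosomes) carries a differentially autozygous
8-Mb region on chromosome 1 (carrier rates 0.35 vs 0.05), a shared
high-autozygosity region on chromosome 3, and a QTL; a separate one-
population cohort over ten birth years carries a rising-autozygosity
region.  Every driver regenerates its inputs deterministically from these
configs, so the scripts can run independently and in any order.
"""

from pathlib import Path

from autozygome.synthetic_data import PlantedRegion, SimConfig

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch" / "analysis"

SEED = 2026

# regions are 12 Mb (~158 map SNPs): the Hardy-Weinberg QC filter removes a
# sizeable share of strongly homozygosity-distorted SNPs inside a planted
# region, and >= 45 contiguous SNPs must survive it
DIFF_REGION = PlantedRegion(
    chromosome=1, start_bp=17_000_000, end_bp=29_000_000,
    carrier_probability={"US": 0.35, "AU": 0.05},
)
COMMON_REGION = PlantedRegion(
    chromosome=3, start_bp=34_000_000, end_bp=46_000_000,
    carrier_probability={"US": 0.35, "AU": 0.35},
)

COHORT = SimConfig(
    n_populations=2,
    samples_per_population_per_year=125,
    birth_years=(2001, 2004),
    n_chromosomes=5,
    snps_per_chromosome=1000,
    fst_target=0.01,
    planted_regions=[DIFF_REGION, COMMON_REGION],
    qtl_spec=[(275, 0.4)],
    n_herds_per_population=2,
    seed=SEED,
)

TREND_REGION = PlantedRegion(
    chromosome=1, start_bp=20_000_000, end_bp=26_000_000,
    carrier_probability={"US": 0.2},
)
TREND_SLOPE = 0.3  # log-odds of carrier status per birth year

TREND_COHORT = SimConfig(
    n_populations=1,
    samples_per_population_per_year=100,
    birth_years=(2001, 2010),
    n_chromosomes=2,
    snps_per_chromosome=1000,
    trend_regions=[(TREND_REGION, TREND_SLOPE)],
    seed=SEED + 1,
)


def ensure_dirs() -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    SCRATCH.mkdir(parents=True, exist_ok=True)
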