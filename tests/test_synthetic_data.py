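"""Truth-table consistency and statistical calibration of the generator."""

import numpy as np
import pandas as pd
import pytest

from autozygome.association import build_a_matrix
from autozygome.differential import roh45_frequency
from autozygome.pipeline import _concat_datasets
from autozygome.roh import roh_status
from autozygome.structure import fst_windowed
from autozygome.synthetic_data import (
    PlantedRegion,
    SimConfig,
    simulate_genotypes,
    simulate_pedigree,
    simulate_phenotypes,
)


def small_config(**kw):
    defaults = dict(
        n_populations=2, samples_per_population_per_year=50, birth_years=(2001, 2004),
        n_chromosomes=2, snps_per_chromosome=500, fst_target=0.01, seed=1,
    )
    defaults.update(kw)
    return SimConfig(**defaults)


def test_deterministic_given_seed_and_sensitive_to_it():
    d1, _ = simulate_genotypes(small_config(seed=9))
    d2, _ = simulate_genotypes(small_config(seed=9))
    d3, _ = simulate_genotypes(small_config(seed=10))
    np.testing.assert_array_equal(d1["US"].calls, d2["US"].calls)
    assert (d1["US"].calls != d3["US"].calls).any()


def test_zero_fst_target_yields_near_zero_differentiation():
    cfg = small_config(
        fst_target=0.0, samples_per_population_per_year=125, snps_per_chromosome=1000,
        n_chromosomes=2, seed=3,
    )
    datasets, _ = simulate_genotypes(cfg)
    track = fst_windowed(datasets["US"], datasets["AU"], window_snps=8)
    assert abs(track.genome_mean) < 0.005


def test_forced_plant_gives_frequency_one_at_interior_snps():
    region = PlantedRegion(1, 10_000_000, 16_000_000, {"US": 1.0, "AU": 0.0})
    cfg = small_config(planted_regions=[region], snps_per_chromosome=1000, seed=4)
    datasets, truth = simulate_genotypes(cfg)
    status = roh_status(datasets["US"], 45)
    idx = truth.region_snp_index[0]
    interior = idx[5:-5]
    assert status.status[:, interior].mean() == 1.0
    status_au = roh_status(datasets["AU"], 45)
    assert status_au.status[:, interior].mean() < 0.01


def test_planted_frequency_difference_near_target():
    region = PlantedRegion(1, 10_000_000, 16_000_000, {"US": 0.35, "AU": 0.05})
    cfg = small_config(planted_regions=[region], snps_per_chromosome=1000,
                       samples_per_population_per_year=100, seed=5)
    datasets, truth = simulate_genotypes(cfg)
    combined = _concat_datasets(datasets)
    status = roh_status(combined, 45)
    track = roh45_frequency(status, combined.samples["population"].to_numpy())
    idx = truth.region_snp_index[0]
    mid = idx[len(idx) // 2]
    diff = track.frequencies.loc["US"].iloc[mid] - track.frequencies.loc["AU"].iloc[mid]
    # binomial error at n=400/pop: 3 SE ~ 0.07
    assert diff == pytest.approx(0.30, abs=0.08)


def test_truth_table_carrier_counts_match_emitted_genotypes():
    region = PlantedRegion(1, 10_000_000, 16_000_000, {"US": 0.4, "AU": 0.1})
    cfg = small_config(planted_regions=[region], snps_per_chromosome=1000, seed=6)
    datasets, truth = simulate_genotypes(cfg)
    idx = truth.region_snp_index[0]
    for pop in ("US", "AU"):
        carriers = truth.carrier_flags[0][pop]
        recorded = truth.region_carriers.query(
            "region == 0 and population == @pop"
        )["n_carriers"].iloc[0]
        assert carriers.sum() == recorded
        # carriers are homozygous across the entire region
        calls = datasets[pop].calls[np.ix_(carriers, idx)]
        assert np.isin(calls, (0, 2)).all()


def test_background_roh45_is_negligible_without_planting():
    cfg = small_config(seed=7)
    datasets, _ = simulate_genotypes(cfg)
    status = roh_status(datasets["US"], 45)
    assert status.status.mean() < 0.01


def test_short_region_warns():
    region = PlantedRegion(1, 10_000_000, 10_500_000, {"US": 0.5})
    with pytest.warns(UserWarning, match="45"):
        simulate_genotypes(small_config(planted_regions=[region], seed=8))


def test_pedigree_structure_and_relationships():
    cfg = small_config()
    ped = simulate_pedigree(cfg, sample_ids=[f"US_{k:05d}" for k in range(40)])
    A = build_a_matrix(ped)
    # founders on the diagonal are exactly 1
    founders = ped.records[(ped.records["sire_id"] == "") & (ped.records["dam_id"] == "")]
    for a in founders["animal_id"]:
        assert A.matrix[A.index[a], A.index[a]] == 1.0
    # paternal half sibs (same sire, different unrelated dams) relate >= 0.25
    rec = ped.records.set_index("animal_id")
    final = [a for a in ped.animals if a.startswith("US_")]
    by_sire = {}
    for a in final:
        by_sire.setdefault(rec.loc[a, "sire_id"], []).append(a)
    sibs = next(v for v in by_sire.values() if len(v) >= 2)
    assert A.matrix[A.index[sibs[0]], A.index[sibs[1]]] >= 0.25 - 1e-9


def test_phenotype_repeatability_matches_configuration():
    cfg = small_config(samples_per_population_per_year=200, n_chromosomes=1,
                      snps_per_chromosome=100, seed=12)
    datasets, truth = simulate_genotypes(cfg)
    data = datasets["US"]
    pheno = simulate_phenotypes(data, truth, cfg)
    # intraclass correlation of repeated records ~ repeatability; fixed
    # effects (HYS, month) add between-record noise, so allow a generous
    # band around 0.43; moment estimator of the one-way random-effects ICC
    multi = pheno.groupby("animal_id")["milk"].count() > 1
    sub = pheno[pheno["animal_id"].isin(multi[multi].index)]
    means = sub.groupby("animal_id")["milk"].mean()
    counts = sub.groupby("animal_id")["milk"].count()
    resid_var = (
        sub.groupby("animal_id")["milk"].var(ddof=1).mul(counts - 1).sum()
        / (counts - 1).sum()
    )
    n_bar = counts.mean()
    between = means.var(ddof=1) - resid_var / n_bar
    icc = between / (between + resid_var)
    assert icc == pytest.approx(0.43, abs=0.12)


def test_phenotype_qtl_effect_recoverable_by_ols():
    cfg = small_config(
        n_populations=1, samples_per_population_per_year=500, birth_years=(2001, 2004),
        n_chromosomes=1, snps_per_chromosome=100, qtl_spec=[(10, 0.5)], seed=13,
    )
    datasets, truth = simulate_genotypes(cfg)
    data = datasets["US"]
    pheno = simulate_phenotypes(data, truth, cfg)
    means = pheno.groupby("animal_id")["milk"].mean()
    dose = pd.Series(data.calls[:, 10].astype(float), index=data.samples["animal_id"])
    x = dose.loc[means.index].to_numpy()
    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, means.to_numpy(), rcond=None)
    se = np.sqrt(
        np.sum((means.to_numpy() - X @ beta) ** 2)
        / (len(x) - 2)
        / np.sum((x - x.mean()) ** 2)
    )
    assert beta[1] == pytest.approx(0.5, abs=2.5 * se)


def test_trend_plant_probability_follows_logistic_link():
    region = PlantedRegion(1, 10_000_000, 16_000_000, {"US": 0.2})
    cfg = small_config(
        n_populations=1, samples_per_population_per_year=300,
        birth_years=(2001, 2010), trend_regions=[(region, 0.4)],
        snps_per_chromosome=1000, seed=14,
    )
    datasets, truth = simulate_genotypes(cfg)
    carriers = truth.carrier_flags[0]["US"]
    years = datasets["US"].samples["birth_year"].to_numpy()
    early = carriers[years <= 2003].mean()
    late = carriers[years >= 2008].mean()
    assert late > early  # carrier rate rises with birth year
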