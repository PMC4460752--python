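"""Garrick weights, A-matrix, yield deviations, mixed-model scan, BH FDR."""

import itertools

import numpy as np
import pandas as pd
import pytest

from autozygome.association import (
    AMatrix,
    YieldDeviations,
    _mme_fit,
    bh_fdr,
    build_a_matrix,
    garrick_weight,
    single_marker_scan,
    yield_deviations,
)
from autozygome.genotype_io import Pedigree
from autozygome.synthetic_data import SimConfig, simulate_genotypes, simulate_phenotypes
from conftest import make_dataset


# --- Garrick weights -------------------------------------------------------

def test_weight_single_parity_is_one_minus_h2():
    assert garrick_weight(1, 0.25, 0.43) == pytest.approx(0.75)


def test_weight_three_parities_hand_value():
    # 0.75 / ((1 + 0.43*2)/3) = 0.75/0.62
    assert garrick_weight(3, 0.25, 0.43) == pytest.approx(0.75 / 0.62)


def test_weight_monotone_and_limit():
    ls = np.arange(1, 200)
    w = garrick_weight(ls, 0.25, 0.43)
    assert (np.diff(w) > 0).all()
    assert garrick_weight(100000, 0.25, 0.43) == pytest.approx(0.75 / 0.43, abs=1e-4)


def test_weight_invalid_inputs():
    with pytest.raises(ValueError):
        garrick_weight(0, 0.25, 0.43)
    with pytest.raises(ValueError):
        garrick_weight(1, 0.5, 0.4)  # h2 > r2


# --- A matrix --------------------------------------------------------------

def ped_frame(rows):
    return Pedigree(pd.DataFrame(rows, columns=["animal_id", "sire_id", "dam_id"]))


def test_founders_only_identity():
    ped = ped_frame([("a", "", ""), ("b", "", ""), ("c", "", "")])
    np.testing.assert_array_equal(build_a_matrix(ped).matrix, np.eye(3))


def test_full_and_half_sib_relationships():
    ped = ped_frame(
        [("s", "", ""), ("d1", "", ""), ("d2", "", ""),
         ("f1", "s", "d1"), ("f2", "s", "d1"), ("h1", "s", "d2")]
    )
    A = build_a_matrix(ped)
    ix = A.index
    assert A.matrix[ix["f1"], ix["f2"]] == pytest.approx(0.5)
    assert A.matrix[ix["f1"], ix["h1"]] == pytest.approx(0.25)


def test_inbred_offspring_of_sire_daughter_mating():
    ped = ped_frame(
        [("s", "", ""), ("d", "", ""), ("x", "s", "d"), ("y", "s", "x")]
    )
    A = build_a_matrix(ped)
    assert A.matrix[A.index["y"], A.index["y"]] == pytest.approx(1.25)


def recursive_a(ped: Pedigree):
    """Independent oracle: memoized recursive definition of the numerator
    relationship, a(i,i) = 1 + 0.5 a(s_i, d_i); a(i,j) = 0.5(a(j,s_i)+a(j,d_i))
    for i younger than j."""
    rec = ped.records
    order = {a: k for k, a in enumerate(rec["animal_id"])}
    parents = {a: (s, d) for a, s, d in rec.itertuples(index=False)}
    from functools import lru_cache

    def a(i, j):
        if i == "" or j == "":
            return 0.0
        if order[i] < order[j]:
            i, j = j, i
        s, d = parents[i]
        if i == j:
            return 1.0 + 0.5 * a(s, d) if s and d else 1.0
        return 0.5 * (a(j, s) + a(j, d))

    n = len(rec)
    out = np.zeros((n, n))
    ids = list(rec["animal_id"])
    for i in range(n):
        for j in range(n):
            out[i, j] = a(ids[i], ids[j])
    return out, ids


def test_tabular_matches_recursive_oracle_on_random_small_pedigrees(rng):
    for trial in range(20):
        n = int(rng.integers(3, 11))
        rows = []
        ids = [f"p{k}" for k in range(n)]
        for k, a in enumerate(ids):
            if k < 2 or rng.random() < 0.3:
                rows.append((a, "", ""))
            else:
                s, d = rng.choice(k, size=2, replace=False)
                rows.append((a, ids[s], ids[d]))
        ped = ped_frame(rows)
        A = build_a_matrix(ped)
        oracle, oracle_ids = recursive_a(ped)
        idx = [A.index[a] for a in oracle_ids]
        np.testing.assert_allclose(A.matrix[np.ix_(idx, idx)], oracle, atol=1e-12)


def test_own_ancestor_is_an_error():
    with pytest.raises(ValueError):
        ped_frame([("a", "a", "")])


# --- yield deviations ------------------------------------------------------

def sim_pheno(n=300, seed=2, **cfg_kw):
    cfg = SimConfig(
        n_populations=1, samples_per_population_per_year=n // 3,
        birth_years=(2001, 2003), n_chromosomes=1, snps_per_chromosome=60,
        seed=seed, **cfg_kw,
    )
    datasets, truth = simulate_genotypes(cfg)
    data = datasets["US"]
    return data, truth, cfg, simulate_phenotypes(data, truth, cfg)


def test_yield_deviations_standardized_per_population():
    data, truth, cfg, pheno = sim_pheno()
    yd = yield_deviations(pheno)
    for trait in ("milk", "fat", "protein"):
        t = yd.for_trait(trait)
        assert t["value"].mean() == pytest.approx(0.0, abs=0.01)
        assert t["value"].var(ddof=0) == pytest.approx(1.0, abs=0.02)
        np.testing.assert_allclose(
            t["weight"], garrick_weight(t["l"].to_numpy().astype(float))
        )


def test_yield_deviations_absorb_hys_effects():
    """After adjustment the deviations are uncorrelated with the HYS label
    means, even with large planted HYS effects."""
    import autozygome.synthetic_data as sd

    old = sd.HYS_SD
    sd.HYS_SD = 1.0
    try:
        data, truth, cfg, pheno = sim_pheno(n=900, seed=4)
    finally:
        sd.HYS_SD = old
    yd = yield_deviations(pheno).for_trait("milk").set_index("animal_id")
    pheno = pheno.assign(
        hys=pheno["herd_id"].astype(str) + ":" + pheno["year"].astype(str)
        + ":" + pheno["season"].astype(str)
    )
    first = pheno.groupby("animal_id").first()
    raw_hys_mean = pheno.groupby("hys")["milk"].transform("mean")
    pheno = pheno.assign(hys_mean=raw_hys_mean)
    per_cow_hys = pheno.groupby("animal_id")["hys_mean"].mean()
    merged = yd.join(per_cow_hys)
    r = np.corrcoef(merged["value"], merged["hys_mean"])[0, 1]
    assert abs(r) < 0.08


# --- single-marker mixed model ---------------------------------------------

def gls_oracle(y, X, A, w, lam):
    V = A / lam + np.diag(1.0 / w)
    Vi = np.linalg.inv(V)
    cov = np.linalg.inv(X.T @ Vi @ X)
    return cov @ X.T @ Vi @ y, cov


def test_mme_equals_dense_gls_oracle(rng):
    n = 50
    L = rng.normal(size=(n, n)) * 0.1
    A = np.eye(n) + L @ L.T
    d = np.sqrt(np.diag(A))
    A = A / np.outer(d, d) + 0.1 * np.eye(n)
    w = rng.uniform(0.7, 1.8, n)
    X = np.column_stack([np.ones(n), rng.integers(0, 2, n), rng.binomial(2, 0.4, n)]).astype(float)
    y = rng.normal(size=n)
    b, cov, s2, dof = _mme_fit(y, X, A, w, lam=3.0)
    b_o, cov_o = gls_oracle(y, X, A, w, 3.0)
    np.testing.assert_allclose(b, b_o, atol=1e-8)
    np.testing.assert_allclose(cov, cov_o, atol=1e-8)


def test_scan_recovers_planted_qtl_within_two_se():
    cfg = SimConfig(
        n_populations=2, samples_per_population_per_year=100, birth_years=(2001, 2003),
        n_chromosomes=1, snps_per_chromosome=60, qtl_spec=[(30, 0.4)],
        n_herds_per_population=2, seed=6,
    )
    datasets, truth = simulate_genotypes(cfg)
    from autozygome.pipeline import _concat_datasets
    from autozygome.synthetic_data import simulate_pedigree

    combined = _concat_datasets(datasets)
    pheno = simulate_phenotypes(combined, truth, cfg)
    ped = simulate_pedigree(cfg, sample_ids=list(combined.samples["animal_id"]))
    A = build_a_matrix(ped)
    yd = yield_deviations(
        pheno, populations=combined.samples.set_index("animal_id")["population"]
    )
    res = single_marker_scan(yd, combined, A, ["snp_1_30"], traits=("milk",))
    row = res.table.iloc[0]
    # YD standardization rescales effects: compare on the standardized scale
    expected = 0.4 / yd.for_trait("milk")["scale"].mean()
    assert row["effect"] == pytest.approx(expected, abs=2.5 * row["se"])
    assert row["p"] < 0.05


def test_scan_invariant_to_population_level_shift():
    data, truth, cfg, pheno = sim_pheno(n=120, seed=8)
    from autozygome.synthetic_data import simulate_pedigree

    ped = simulate_pedigree(cfg, sample_ids=list(data.samples["animal_id"]))
    A = build_a_matrix(ped)
    yd = yield_deviations(pheno)
    # two artificial populations, then shift one by a constant
    yd.table["population"] = np.where(
        np.arange(len(yd.table)) % 2 == 0, "P1", "P2"
    )
    res1 = single_marker_scan(yd, data, A, ["snp_1_5"], traits=("milk",))
    shifted = YieldDeviations(table=yd.table.copy())
    shifted.table.loc[shifted.table["population"] == "P1", "value"] += 5.0
    res2 = single_marker_scan(shifted, data, A, ["snp_1_5"], traits=("milk",))
    assert res1.table["p"].iloc[0] == pytest.approx(res2.table["p"].iloc[0], rel=1e-8)


def test_scan_monomorphic_snp_reported_missing():
    data, truth, cfg, pheno = sim_pheno(n=60, seed=9)
    data.calls[:, 7] = 0
    from autozygome.synthetic_data import simulate_pedigree

    ped = simulate_pedigree(cfg, sample_ids=list(data.samples["animal_id"]))
    A = build_a_matrix(ped)
    yd = yield_deviations(pheno)
    res = single_marker_scan(yd, data, A, ["snp_1_7"], traits=("milk",))
    assert np.isnan(res.table["effect"].iloc[0])
    assert np.isnan(res.table["p"].iloc[0])


# --- BH FDR ----------------------------------------------------------------

def test_bh_single_p_is_itself():
    np.testing.assert_allclose(bh_fdr([0.2]), [0.2])


def test_bh_hand_computed_vector():
    np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)


def test_bh_all_ones():
    np.testing.assert_allclose(bh_fdr([1.0, 1.0, 1.0]), [1.0] * 3)


def test_bh_matches_statsmodels(rng):
    from statsmodels.stats.multitest import multipletests

    p = rng.uniform(0, 1, 200)
    _, q_ref, *_ = multipletests(p, method="fdr_bh")
    np.testing.assert_allclose(bh_fdr(p), q_ref, atol=1e-12)


def test_bh_monotone_in_p_order(rng):
    p = rng.uniform(0, 1, 50)
    q = bh_fdr(p)
    order = np.argsort(p)
    assert (np.diff(q[order]) >= -1e-12).all()
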