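"""ROH45 frequency contrasts, permutation calibration, and region rules."""

import itertools

import numpy as np
import pandas as pd
import pytest

from autozygome.differential import (
    call_common_high_regions,
    call_differential_regions,
    chisq_per_snp,
    permutation_threshold,
    roh45_frequency,
)
from autozygome.regions import call_regions
from autozygome.roh import ROHStatusMatrix


def make_markers(m, chromosomes=None, spacing_bp=100_000):
    if chromosomes is None:
        chromosomes = np.ones(m, dtype=int)
    positions = np.zeros(m, dtype=int)
    for ch in np.unique(chromosomes):
        idx = np.flatnonzero(chromosomes == ch)
        positions[idx] = (np.arange(len(idx)) + 1) * spacing_bp
    return pd.DataFrame(
        {
            "snp_id": [f"s{j}" for j in range(m)],
            "chromosome": chromosomes,
            "position_bp": positions,
            "a1": "A",
            "a2": "B",
        }
    )


def test_frequency_is_count_over_size(rng):
    status = ROHStatusMatrix(rng.integers(0, 2, size=(30, 20)).astype(np.uint8), 45)
    groups = np.array(["A"] * 12 + ["B"] * 18)
    track = roh45_frequency(status, groups)
    # independent tally
    for pop, mask in (("A", groups == "A"), ("B", groups == "B")):
        np.testing.assert_allclose(
            track.frequencies.loc[pop],
            status.status[mask].sum(axis=0) / mask.sum(),
        )


def test_absent_population_is_an_error():
    status = ROHStatusMatrix(np.zeros((4, 3), dtype=np.uint8), 45)
    track = roh45_frequency(status, np.array(["A"] * 4))
    with pytest.raises(ValueError):
        chisq_per_snp(track, "A", "B")
    with pytest.raises(ValueError):
        permutation_threshold(status, np.array(["A"] * 4), "A", "B", n_permutations=5)


def test_chisq_hand_computed_value():
    # a=30/100 vs c=10/100: chi2 = 200*(30*90-70*10)^2/(100*100*40*160) = 12.5
    status = ROHStatusMatrix(
        np.r_[
            np.repeat([[1], [0]], [30, 70], axis=0),
            np.repeat([[1], [0]], [10, 90], axis=0),
        ].astype(np.uint8),
        45,
    )
    groups = np.array(["A"] * 100 + ["B"] * 100)
    track = roh45_frequency(status, groups)
    chi2, p = chisq_per_snp(track, "A", "B")
    assert chi2[0] == pytest.approx(12.5)
    chi2_swapped, _ = chisq_per_snp(track, "B", "A")
    assert chi2_swapped[0] == pytest.approx(chi2[0])


def test_chisq_equal_frequencies_zero():
    status = ROHStatusMatrix(
        np.array([[1], [0], [1], [0]], dtype=np.uint8), 45
    )
    track = roh45_frequency(status, np.array(["A", "A", "B", "B"]))
    chi2, p = chisq_per_snp(track, "A", "B")
    assert chi2[0] == 0 and p[0] == 1


def test_chisq_zero_margin_degenerate():
    status = ROHStatusMatrix(np.zeros((10, 2), dtype=np.uint8), 45)
    track = roh45_frequency(status, np.array(["A"] * 5 + ["B"] * 5))
    chi2, p = chisq_per_snp(track, "A", "B")
    assert (chi2 == 0).all() and (p == 1).all()


def test_permutation_p_matches_exact_enumeration():
    """4 animals split 2/2: the empirical p over many sampled permutations
    matches exhaustive enumeration of all 6 label assignments."""
    status_mat = np.array([[1, 1], [1, 0], [0, 1], [0, 0]], dtype=np.uint8)
    groups = np.array(["A", "A", "B", "B"])
    status = ROHStatusMatrix(status_mat, 45)
    B = 6000
    perm = permutation_threshold(
        status, groups, "A", "B", n_permutations=B, seed=5, null_kind="per-snp"
    )
    # exhaustive: all C(4,2)=6 assignments of which rows form group A
    s = status_mat.astype(float)
    observed = np.abs(s[:2].mean(axis=0) - s[2:].mean(axis=0))
    for j in range(2):
        null = []
        for combo in itertools.combinations(range(4), 2):
            mask = np.zeros(4, bool)
            mask[list(combo)] = True
            null.append(abs(s[mask, j].mean() - s[~mask, j].mean()))
        exact_p = sum(v >= observed[j] for v in null) / 6
        assert perm.p_values[j] == pytest.approx(exact_p, abs=0.02)


def test_observed_zero_difference_gives_p_one():
    status = ROHStatusMatrix(
        np.array([[1], [0], [1], [0]], dtype=np.uint8), 45
    )
    perm = permutation_threshold(
        status, np.array(["A", "A", "B", "B"]), "A", "B", n_permutations=50, seed=0
    )
    assert perm.p_values[0] == pytest.approx(1.0)


def test_permutation_p_never_zero(rng):
    status = ROHStatusMatrix(rng.integers(0, 2, (20, 10)).astype(np.uint8), 45)
    groups = np.array(["A"] * 10 + ["B"] * 10)
    perm = permutation_threshold(status, groups, "A", "B", n_permutations=20, seed=1)
    assert (perm.p_values >= 1 / (20 * 10 + 1)).all()
    assert (perm.p_values <= 1).all()


def test_permutation_type_one_control(rng):
    """Two identical generating distributions: fraction of SNPs with
    p < 0.001 stays within 3x nominal."""
    status = ROHStatusMatrix(
        (rng.random((200, 2000)) < 0.15).astype(np.uint8), 45
    )
    groups = np.array(["A"] * 100 + ["B"] * 100)
    perm = permutation_threshold(status, groups, "A", "B", n_permutations=200, seed=2)
    assert (perm.p_values < 0.001).mean() <= 0.003


def test_region_rules_snp_count_and_span():
    markers = make_markers(200)
    p = np.ones(200)
    # 44 contiguous significant SNPs -> no region
    p[10:54] = 1e-6
    assert call_differential_regions(p, markers) == []
    # 45 contiguous significant SNPs spanning 4.4 Mb (> 4) -> one region
    p = np.ones(200)
    p[10:55] = 1e-6
    regions = call_differential_regions(p, markers)
    assert len(regions) == 1
    r = regions[0]
    assert (r.start_bp, r.end_bp, r.n_snps) == (1_100_000, 5_500_000, 45)
    # same 45 SNPs squeezed into 3.0 Mb -> below span rule
    markers_tight = make_markers(200, spacing_bp=68_000)
    assert call_differential_regions(p, markers_tight) == []


def test_regions_never_cross_chromosomes():
    chrom = np.repeat([1, 2], 50)
    markers = make_markers(100, chromosomes=chrom)
    p = np.full(100, 1e-6)  # everything significant
    regions = call_differential_regions(p, markers, min_snps=10, min_span_mb=0.5)
    assert [r.chromosome for r in regions] == [1, 2]


def test_region_rule_monotonicity(rng):
    markers = make_markers(300)
    p = rng.uniform(0, 1, 300) ** 4
    loose = call_differential_regions(p, markers, min_snps=5, min_span_mb=0.1, alpha=0.05)
    tighter_alpha = call_differential_regions(p, markers, min_snps=5, min_span_mb=0.1, alpha=0.01)
    tighter_snps = call_differential_regions(p, markers, min_snps=8, min_span_mb=0.1, alpha=0.05)
    # raising alpha never removes a region; raising min_snps never adds one
    def covered(regs):
        return set((r.chromosome, r.start_bp, r.end_bp) for r in regs)

    for r in tighter_alpha:
        assert any(
            r.start_bp >= q.start_bp and r.end_bp <= q.end_bp for q in loose
        )
    assert len(tighter_snps) <= len(loose)


def test_common_high_requires_all_populations():
    status = np.zeros((40, 200), dtype=np.uint8)
    status[:20, 50:120] = 1  # population A high in 50:120
    status[20:, 50:120] = 1  # population B high too
    track = roh45_frequency(
        ROHStatusMatrix(status, 45), np.array(["A"] * 20 + ["B"] * 20)
    )
    markers = make_markers(200)
    regions = call_common_high_regions(track, markers, quantile=0.9)
    assert len(regions) == 1
    assert regions[0].n_snps == 70
    # knock population B below its own threshold inside the region
    status_b_low = status.copy()
    status_b_low[20:, 50:120] = 0
    status_b_low[20:, 150:180] = 1
    track2 = roh45_frequency(
        ROHStatusMatrix(status_b_low, 45), np.array(["A"] * 20 + ["B"] * 20)
    )
    assert (
        call_common_high_regions(track2, markers, quantile=0.9, min_snps=45) == []
    )


def test_common_high_degenerate_quantile_tie_rule(rng):
    """quantile 1.0 flags only SNPs tied at the per-population maximum."""
    status = (rng.random((30, 100)) < 0.2).astype(np.uint8)
    track = roh45_frequency(ROHStatusMatrix(status, 45), np.array(["A"] * 30))
    markers = make_markers(100)
    regions = call_common_high_regions(track, markers, quantile=1.0, min_snps=1, min_span_mb=0.0)
    f = track.frequencies.loc["A"].to_numpy()
    flagged = np.zeros(100, bool)
    for r in regions:
        sel = (markers["position_bp"] >= r.start_bp) & (markers["position_bp"] <= r.end_bp)
        flagged |= sel.to_numpy()
    assert set(np.flatnonzero(flagged)) <= set(np.flatnonzero(f == f.max()))


def test_regions_pairwise_disjoint(rng):
    markers = make_markers(500)
    flags = rng.random(500) < 0.3
    regions = call_regions(flags, markers, "differential", min_snps=2, min_span_mb=0.0)
    spans = sorted((r.start_bp, r.end_bp) for r in regions)
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        assert e1 < s2
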