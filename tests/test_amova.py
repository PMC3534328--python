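"""Hierarchical AMOVA: distances, SS decomposition, components, permutations."""

from itertools import combinations

import numpy as np
import pytest

from aflpselect import (
    Hierarchy,
    MarkerMatrix,
    ValidationError,
    amova_three_level,
    simulate_dataset,
    SimulationConfig,
    squared_distance_matrix,
)

from conftest import NA, make_matrix


def brute_force_distance(m):
    """Pairwise mismatch count with missing rescale, explicit loops."""
    n = m.n_samples
    D = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        mism = joint = 0
        for k in range(m.n_loci):
            a, b = m.calls[i, k], m.calls[j, k]
            if not np.isnan(a) and not np.isnan(b):
                joint += 1
                mism += a != b
        D[i, j] = D[j, i] = mism * m.n_loci / joint
    return D


def brute_force_ss(D, sets):
    """SS of a union of samples from the pairwise identity."""
    total = 0.0
    for idx in sets:
        s = 0.0
        for i, j in combinations(idx, 2):
            s += D[i, j]
        total += s / len(idx)
    return total


class TestSquaredDistance:
    def test_identical_rows_zero(self):
        m = make_matrix([[1, 0, 1], [1, 0, 1]])
        assert squared_distance_matrix(m)[0, 1] == 0.0

    def test_complete_binary_counts_differing_loci(self):
        m = make_matrix([[1, 0, 1], [0, 0, 1]])
        assert squared_distance_matrix(m)[0, 1] == 1.0

    def test_missing_rescale(self):
        # 1 mismatch over 3 jointly scored loci, 4 loci total -> 4/3
        m = make_matrix([[1, 0, NA, 1], [0, 0, 1, 1]])
        assert squared_distance_matrix(m)[0, 1] == pytest.approx(4 / 3)

    def test_no_jointly_scored_locus_errors(self):
        m = make_matrix([[1, NA], [NA, 0]])
        with pytest.raises(ValidationError, match="jointly"):
            squared_distance_matrix(m)

    def test_matches_brute_force_on_random_matrices(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            calls = (rng.random((6, 10)) < 0.4).astype(float)
            calls[rng.random((6, 10)) < 0.2] = np.nan
            m = MarkerMatrix(calls, tuple(f"s{i}" for i in range(6)),
                             tuple(f"L{j}" for j in range(10)))
            try:
                D = squared_distance_matrix(m)
            except ValidationError:
                continue
            assert np.allclose(D, brute_force_distance(m))
            assert np.allclose(D, D.T) and (D >= 0).all()


@pytest.fixture
def balanced_case(balanced_hierarchy):
    # hand-written 8 samples x 6 loci, complete calls, clear group structure
    m = make_matrix(
        [
            [1, 1, 0, 0, 1, 0],  # a1  g1/pA
            [1, 1, 0, 0, 0, 0],  # a2
            [1, 0, 1, 0, 1, 0],  # b1  g1/pB
            [1, 0, 1, 0, 0, 1],  # b2
            [0, 1, 1, 1, 1, 0],  # c1  g2/pC
            [0, 1, 1, 1, 0, 0],  # c2
            [0, 0, 0, 1, 1, 1],  # d1  g2/pD
            [0, 0, 0, 1, 0, 1],  # d2
        ],
        sample_ids=["a1", "a2", "b1", "b2", "c1", "c2", "d1", "d2"],
    )
    return m, balanced_hierarchy


class TestThreeLevelDecomposition:
    def test_ss_match_brute_force_and_are_additive(self, balanced_case):
        m, h = balanced_case
        res = amova_three_level(m, h, n_perm=0)
        D = brute_force_distance(m)
        pops = [[0, 1], [2, 3], [4, 5], [6, 7]]
        groups = [[0, 1, 2, 3], [4, 5, 6, 7]]
        ss_total = brute_force_ss(D, [list(range(8))])
        ss_wp = brute_force_ss(D, pops)
        ss_wg = brute_force_ss(D, groups)
        assert res.ss_total == pytest.approx(ss_total)
        assert res.ss_within_pops == pytest.approx(ss_wp)
        assert res.ss_among_pops_within_groups == pytest.approx(ss_wg - ss_wp)
        assert res.ss_among_groups == pytest.approx(ss_total - ss_wg)
        assert res.ss_total == pytest.approx(
            res.ss_among_groups + res.ss_among_pops_within_groups + res.ss_within_pops
        )
        assert sum(res.df) == m.n_samples - 1
        assert res.df == (1, 2, 4)

    def test_components_match_balanced_closed_form(self, balanced_case):
        """Balanced design (k=2 samples, p=2 pops/group): EMS coefficients
        reduce to k and kp, solved independently here."""
        m, h = balanced_case
        res = amova_three_level(m, h, n_perm=0)
        ms_c = res.ss_within_pops / res.df[2]
        ms_b = res.ss_among_pops_within_groups / res.df[1]
        ms_a = res.ss_among_groups / res.df[0]
        k, p = 2, 2
        sigma_c = ms_c
        sigma_b = (ms_b - sigma_c) / k
        sigma_a = (ms_a - sigma_c - k * sigma_b) / (k * p)
        assert res.var_raw == pytest.approx((sigma_a, sigma_b, sigma_c))

    def test_percentages_sum_to_100_and_use_truncated_components(self, balanced_case):
        m, h = balanced_case
        res = amova_three_level(m, h, n_perm=0)
        assert sum(res.pct_variance) == pytest.approx(100.0)
        assert all(v >= 0 for v in res.var_components)

    def test_total_ss_invariant_under_label_permutation(self, balanced_case):
        m, h = balanced_case
        rng = np.random.default_rng(17)
        base = amova_three_level(m, h, n_perm=0).ss_total
        ids = list(m.sample_ids)
        for _ in range(5):
            perm = rng.permutation(8)
            h2 = Hierarchy({ids[i]: h.assignment[ids[j]]
                            for i, j in enumerate(perm)})
            assert amova_three_level(m, h2, n_perm=0).ss_total == pytest.approx(base)

    def test_two_level_reduction_matches_collapsed_groups(self, balanced_case):
        """Collapsing all groups into one reproduces the two-level fallback's
        among/within-population split."""
        m, h = balanced_case
        merged = Hierarchy({s: (p, "all") for s, (p, _) in h.assignment.items()})
        with pytest.warns(UserWarning, match="two-level"):
            res2 = amova_three_level(m, merged, n_perm=0)
        D = brute_force_distance(m)
        pops = [[0, 1], [2, 3], [4, 5], [6, 7]]
        ss_total = brute_force_ss(D, [list(range(8))])
        ss_wp = brute_force_ss(D, pops)
        assert res2.two_level
        assert res2.ss_within_pops == pytest.approx(ss_wp)
        assert res2.ss_among_pops_within_groups == pytest.approx(ss_total - ss_wp)
        assert res2.ss_among_groups == 0.0

    def test_all_identical_samples_degenerate(self, balanced_hierarchy):
        m = make_matrix([[1, 0, 1]] * 8,
                        sample_ids=list(balanced_hierarchy.assignment))
        res = amova_three_level(m, balanced_hierarchy, n_perm=0)
        assert res.ss_total == 0.0
        assert res.var_components == (0.0, 0.0, 0.0)
        assert res.pct_variance == (0.0, 0.0, 100.0)
        assert np.isnan(res.phi_pt)

    def test_single_population_errors(self):
        m = make_matrix([[1, 0], [0, 1]], sample_ids=["x", "y"])
        h = Hierarchy({"x": ("p", "g"), "y": ("p", "g")})
        with pytest.raises(ValidationError, match="2 populations"):
            amova_three_level(m, h, n_perm=0)


class TestPermutationPValues:
    def test_structured_data_minimal_p(self):
        """Groups fixed for disjoint loci: observed among-group variance
        exceeds every permuted value, so p hits the granularity floor."""
        cfg = SimulationConfig(n_groups=3, pops_per_group=10, samples_per_pop=3,
                               n_loci=60, replicate_fraction=0.0,
                               divergence=(0.0, 0.0), error_curve=(0, 0, 0),
                               error_noise_sd=0.0, seed=23)
        m, _, h, _ = simulate_dataset(cfg)
        calls = m.calls.copy()
        groups = np.array([h.group_of(s) for s in m.sample_ids])
        for gi, g in enumerate(("G1", "G2", "G3")):
            block = slice(20 * gi, 20 * (gi + 1))
            calls[:, block] = (groups == g)[:, None].astype(float)
        m2 = MarkerMatrix(calls, m.sample_ids, m.locus_ids)
        res = amova_three_level(m2, h, n_perm=99, seed=7)
        assert res.p_values[0] == pytest.approx(1 / 100)

    def test_p_value_granularity(self, balanced_case):
        m, h = balanced_case
        res = amova_three_level(m, h, n_perm=999, seed=1)
        for p in res.p_values:
            assert 1 / 1000 <= p <= 1
            assert (p * 1000) == pytest.approx(round(p * 1000))

    def test_structureless_data_no_among_group_inflation(self):
        """All populations drawn from one frequency vector: the among-group
        p-value should look uniform, not systematically small."""
        pvals = []
        for s in range(20):
            cfg = SimulationConfig(n_groups=3, pops_per_group=4, samples_per_pop=5,
                                   n_loci=200, replicate_fraction=0.0,
                                   divergence=(0.0, 0.0), error_curve=(0, 0, 0),
                                   error_noise_sd=0.0, seed=100 + s)
            m, _, h, _ = simulate_dataset(cfg)
            res = amova_three_level(m, h, n_perm=99, seed=s)
            pvals.append(res.p_values[0])
        assert sum(p <= 0.05 for p in pvals) <= 4
        assert np.mean(pvals) > 0.2


def test_replicate_preflight_warns(balanced_case):
    from aflpselect import ReplicateSet

    m, h = balanced_case
    reps = ReplicateSet((("a1", "a2"),))
    with pytest.warns(UserWarning, match="replicate"):
        amova_three_level(m, h, n_perm=0, replicates=reps)
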