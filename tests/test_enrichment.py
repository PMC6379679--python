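"""Fold changes, sensitive sets, GSEA running sum and permutation null."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from selandscape.enrichment import (
    RankedResponse,
    compare_fc_distributions,
    compute_log2fc,
    gsea_es,
    gsea_permutation,
    sensitive_set,
)


def counts(data, prefix):
    genes = [f"g{i}" for i in range(len(data))]
    return pd.DataFrame(
        np.asarray(data), index=genes,
        columns=[f"{prefix}_{j}" for j in range(np.asarray(data).shape[1])],
    )


class TestComputeLog2fc:
    def test_equal_matrices_zero(self):
        m = counts([[10, 20], [30, 40], [5, 5]], "x")
        fc = compute_log2fc(m, m.copy())
        assert np.allclose(fc.values, 0.0)

    def test_four_fold_limit(self):
        # CPM ratios are scale-free; with tiny pseudocount log2fc -> 2
        control = counts([[100, 100], [100, 100]], "c")
        treated = counts([[400, 400], [100, 100]], "t")
        fc = compute_log2fc(treated, control, pseudocount=1e-9)
        # CPM renormalization: treated library = 500 vs control 200
        t_cpm = np.array([400, 100]) / 500 * 1e6
        c_cpm = np.array([100, 100]) / 200 * 1e6
        assert fc.values == pytest.approx(np.log2(t_cpm / c_cpm), abs=1e-6)

    def test_three_gene_hand_computed_fixture(self):
        treated = counts([[8, 12], [2, 3], [0, 1]], "t")
        control = counts([[5, 5], [4, 6], [1, 1]], "c")
        # hand CPM: treated libs (10, 16), control libs (10, 12)
        t_cpm = np.array(
            [
                (8 / 10 + 12 / 16) / 2,
                (2 / 10 + 3 / 16) / 2,
                (0 / 10 + 1 / 16) / 2,
            ]
        ) * 1e6
        c_cpm = np.array(
            [(5 / 10 + 5 / 12) / 2, (4 / 10 + 6 / 12) / 2, (1 / 10 + 1 / 12) / 2]
        ) * 1e6
        expected = np.log2((t_cpm + 1) / (c_cpm + 1))
        fc = compute_log2fc(treated, control, pseudocount=1.0)
        assert fc.values == pytest.approx(expected, abs=1e-9)

    def test_universe_mismatch_lists_offenders(self):
        t = counts([[1], [2]], "t")
        c = counts([[1], [2]], "c")
        c.index = ["g0", "gX"]
        with pytest.raises(ValueError, match="gX"):
            compute_log2fc(t, c)

    def test_antisymmetry(self, rng):
        t = counts(rng.integers(0, 500, size=(20, 3)), "t")
        c = counts(rng.integers(0, 500, size=(20, 3)), "c")
        fwd = compute_log2fc(t, c, pseudocount=1.0)
        rev = compute_log2fc(c.rename(columns=str), t.rename(columns=str))
        assert np.allclose(fwd.values, -rev.values, atol=1e-9)


class TestSensitiveSet:
    @pytest.mark.parametrize(
        "fc,included",
        [(-1.2, True), (-1.0, False), (3.0, False), (-1.0000001, True)],
    )
    def test_strict_two_fold_threshold(self, fc, included):
        got = sensitive_set({"g": fc}, threshold_fold=2.0)
        assert ("g" in got) is included

    def test_threshold_must_exceed_one(self):
        with pytest.raises(ValueError):
            sensitive_set({}, threshold_fold=1.0)


def brute_force_es(values_ranked, hit, weight_p):
    """Independent running-sum computation (plain python loop)."""
    n = len(values_ranked)
    nh = sum(hit)
    w = [abs(v) ** weight_p for v in values_ranked]
    denom = sum(wi for wi, h in zip(w, hit) if h)
    run, best = 0.0, 0.0
    trace = []
    for v, h, wi in zip(values_ranked, hit, w):
        if h:
            run += wi / denom if denom > 0 else 1.0 / nh
        else:
            run -= 1.0 / (n - nh)
        trace.append(run)
        if abs(run) > abs(best):
            best = run
    return best, trace


class TestGseaEs:
    def _ranking(self, values):
        return RankedResponse({f"g{i}": v for i, v in enumerate(values)})

    def test_top_set_unweighted_hand_computed(self):
        # 5 genes, set = top 2, p=0: increments {+1/2,+1/2,-1/3,-1/3,-1/3}
        rr = self._ranking([5.0, 4.0, 3.0, 2.0, 1.0])
        es, rs = gsea_es(rr, {"g0", "g1"}, weight_p=0.0)
        assert es == pytest.approx(1.0)
        assert rs == pytest.approx([0.5, 1.0, 2 / 3, 1 / 3, 0.0])

    def test_bottom_set_negative(self):
        rr = self._ranking([5.0, 4.0, 3.0, 2.0, 1.0])
        es, _ = gsea_es(rr, {"g3", "g4"}, weight_p=0.0)
        assert es == pytest.approx(-1.0)

    def test_complement_has_opposite_sign_unweighted(self):
        rr = self._ranking([3.0, 1.5, 0.5, -0.5, -2.0, -4.0])
        gs = {"g0", "g2", "g4"}
        comp = {"g1", "g3", "g5"}
        es_a, rs_a = gsea_es(rr, gs, weight_p=0.0)
        es_b, rs_b = gsea_es(rr, comp, weight_p=0.0)
        assert np.allclose(rs_a, -np.array(rs_b))
        assert es_a == pytest.approx(-es_b)

    @pytest.mark.parametrize("weight_p", [0.0, 1.0])
    def test_running_sum_closes_at_zero(self, weight_p, rng):
        values = np.sort(rng.normal(0, 1, size=40))[::-1]
        rr = self._ranking(values)
        genes = list(rr.log2fc)
        gs = set(rng.choice(genes, size=10, replace=False))
        _, rs = gsea_es(rr, gs, weight_p=weight_p)
        assert rs[-1] == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("weight_p", [0.0, 1.0])
    def test_matches_bruteforce_on_random_small_fixtures(self, weight_p, rng):
        for _ in range(50):
            n = int(rng.integers(4, 21))
            values = rng.normal(0, 2, size=n)
            rr = self._ranking(values)
            order = rr.ranking
            k = int(rng.integers(1, n))
            gs = set(rng.choice(order, size=k, replace=False))
            if gs == set(order):
                continue
            hit = [g in gs for g in order]
            expected, trace = brute_force_es(rr.values_ranked, hit, weight_p)
            es, rs = gsea_es(rr, gs, weight_p=weight_p)
            assert es == pytest.approx(expected, abs=1e-12)
            assert rs == pytest.approx(trace, abs=1e-12)

    def test_monotone_relabeling_invariance(self):
        rr = self._ranking([4.0, 2.0, 1.0, -1.0, -3.0])
        renamed = RankedResponse({f"x{k}": v for k, v in rr.log2fc.items()})
        es_a, _ = gsea_es(rr, {"g0", "g3"})
        es_b, _ = gsea_es(renamed, {"xg0", "xg3"})
        assert es_a == es_b

    def test_degenerate_sets_rejected(self):
        rr = self._ranking([1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            gsea_es(rr, {"absent"})
        with pytest.raises(ValueError):
            gsea_es(rr, {"g0", "g1", "g2"})


class TestGseaPermutation:
    def _ranking(self, rng, n=200):
        return RankedResponse({f"g{i}": v for i, v in enumerate(rng.normal(0, 1, n))})

    def test_fixed_seed_bit_identical(self, rng):
        rr = self._ranking(rng)
        gs = {f"g{i}" for i in range(0, 40, 2)}
        a = gsea_permutation(rr, gs, n_perm=100, seed=7)
        b = gsea_permutation(rr, gs, n_perm=100, seed=7)
        assert a == b

    def test_p_floor_respected(self, rng):
        rr = RankedResponse({f"g{i}": float(-i) for i in range(100)})
        gs = {f"g{i}" for i in range(10)}  # exactly the top genes
        res = gsea_permutation(rr, gs, n_perm=100, seed=1)
        assert res.p_value >= 1 / 101

    def test_oversized_set_warns(self, rng):
        rr = self._ranking(rng, n=20)
        gs = {f"g{i}" for i in range(15)}
        with pytest.warns(UserWarning, match="half the universe"):
            gsea_permutation(rr, gs, n_perm=100, seed=0)

    def test_leading_edge_members_precede_extremum(self, rng):
        rr = self._ranking(rng)
        gs = {f"g{i}" for i in range(0, 60, 3)}
        res = gsea_permutation(rr, gs, n_perm=100, seed=3)
        assert set(res.leading_edge) <= gs
        assert len(res.leading_edge) >= 1


class TestCompareFcDistributions:
    def test_identical_lists(self):
        a = [0.1, -0.5, 1.2, 0.7]
        med_a, med_b, _, p = compare_fc_distributions(a, list(a))
        assert med_a == med_b
        assert p == pytest.approx(1.0)

    def test_location_shift_direction(self, rng):
        a = rng.normal(0, 1, 100)
        med_a, med_b, _, p = compare_fc_distributions(a - 1.0, a)
        assert med_a == pytest.approx(med_b - 1.0, abs=1e-9)
        assert p < 1e-6

    def test_small_samples_match_exact_enumeration(self, rng):
        a = list(rng.normal(0, 1, 6))
        b = list(rng.normal(0.5, 1, 5))
        _, _, u_obs, p = compare_fc_distributions(a, b)
        # enumerate all C(11,6) splits of the pooled sample
        pooled = a + b
        n_a = len(a)
        us = []
        for idx in itertools.combinations(range(len(pooled)), n_a):
            grp_a = [pooled[i] for i in idx]
            grp_b = [pooled[i] for i in range(len(pooled)) if i not in idx]
            u = sum(
                (x > y) + 0.5 * (x == y) for x in grp_a for y in grp_b
            )
            us.append(u)
        us = np.array(us)
        mu = len(a) * len(b) / 2
        p_exact = np.mean(np.abs(us - mu) >= abs(u_obs - mu) - 1e-12)
        assert p == pytest.approx(p_exact, abs=1e-9)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            compare_fc_distributions([], [1.0])
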