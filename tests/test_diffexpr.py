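"""Pooled-variance t-test, BH adjustment and the six-comparison runner."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from thigmo import diffexpr, simulate
from thigmo.diffexpr import InputError, bh_adjust, two_group_ttest


def bh_bruteforce(p):
    """Independent step-up oracle: q(i) = min_{j>=i} p_(j) * m / j."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        running = min(running, p[order[rank - 1]] * m / rank)
        q[order[rank - 1]] = min(running, 1.0)
    return q


class TestTwoGroupTtest:
    def test_identical_groups(self):
        a, t, df, p = two_group_ttest([1, 2, 3], [1, 2, 3])
        assert (a, t, df, p) == (0.0, 0.0, 4, 1.0)

    def test_hand_computed_example(self):
        # pooled s2 = 1, se = sqrt(2/3), delta = +1 under mean(B) - mean(A)
        a, t, df, p = two_group_ttest([1, 2, 3], [2, 3, 4])
        assert a == pytest.approx(1.0)
        assert t == pytest.approx(1.2247, abs=1e-4)
        assert df == 4
        assert p == pytest.approx(2 * stats.t.sf(np.sqrt(1.5), 4), abs=1e-10)
        assert p == pytest.approx(0.2878, abs=2e-4)

    def test_separation_limit(self):
        # as jitter shrinks, p falls toward the degenerate p = 0 case
        last = 1.0
        for eps in (0.1, 0.01, 0.001):
            _, _, _, p = two_group_ttest([0, eps, -eps], [1, 1 + eps, 1 - eps])
            assert p < last
            last = p
        _, _, _, p0 = two_group_ttest([0, 0, 0], [1, 1, 1])
        assert p0 == 0.0

    def test_matches_scipy(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            a, b = rng.normal(size=4), rng.normal(size=5)
            _, t, _, p = two_group_ttest(a, b)
            ref = stats.ttest_ind(b, a, equal_var=True)
            assert t == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue)

    def test_single_value_group_rejected(self):
        with pytest.raises(InputError):
            two_group_ttest([1.0], [1, 2, 3])


class TestBHAdjust:
    @pytest.mark.parametrize("p,expected", [
        ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
        ([0.05], [0.05]),
        ([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]),
    ])
    def test_known_values(self, p, expected):
        np.testing.assert_allclose(bh_adjust(p), expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(InputError):
            bh_adjust([0.5, 1.5])

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            p = rng.random(rng.integers(1, 40))
            np.testing.assert_allclose(bh_adjust(p), bh_bruteforce(p),
                                       atol=1e-12)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=25),
           st.randoms(use_true_random=False))
    def test_permutation_invariant(self, p, rnd):
        perm = list(range(len(p)))
        rnd.shuffle(perm)
        q = bh_adjust(p)
        q_perm = bh_adjust([p[i] for i in perm])
        np.testing.assert_allclose([q[i] for i in perm], q_perm, atol=1e-12)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.01, 1), min_size=2, max_size=15),
           st.data())
    def test_lowering_one_p_never_raises_its_q(self, p, data):
        i = data.draw(st.integers(0, len(p) - 1))
        q = bh_adjust(p)
        lowered = list(p)
        lowered[i] = data.draw(st.floats(0, p[i]))
        q2 = bh_adjust(lowered)
        assert q2[i] <= q[i] + 1e-12


class TestRunComparisons:
    def test_zero_noise_flat_genes_all_ns(self):
        cfg = simulate.SimConfig(n_genes=100, seed=2, noise_sd=0.0,
                                 archetype_fractions={"flat": 1.0},
                                 newly_regulated_fraction=0.0,
                                 low_intensity_fraction=0.0)
        matrix, design, _, _ = simulate.simulate_dataset(cfg)
        cset = diffexpr.run_comparisons(matrix, design)
        for cid, df in cset.results.items():
            assert (df.status == 0).all(), cid

    def test_planted_effect_detected(self, small_dataset, small_comparisons):
        # planted |log2FC| >= 2 at noise 0.2 and n = 3 is overwhelmingly powered
        _, _, _, truth, _ = small_dataset
        res = small_comparisons.results["C0.5"].set_index("gene_id")
        up = truth.loc[(truth["effect_0.5h"] >= 2)
                       & ~truth.low_intensity, "gene_id"]
        statuses = res.loc[res.index.intersection(up), "status"]
        assert (statuses == 1).mean() > 0.99

    def test_underreplicated_comparison_skipped(self):
        cfg = simulate.SimConfig(n_genes=50, seed=0)
        matrix, design, _, _ = simulate.simulate_dataset(cfg)
        design = design[~((design.treatment == "bent_twice")
                          & (design.replicate > 1))]
        cset = diffexpr.run_comparisons(matrix, design)
        assert "2Bvs1B24" in cset.errors and "2Bvs1B0.5" in cset.errors
        assert "C0.5" in cset.results

    def test_filters_are_per_comparison(self, small_comparisons):
        reports = small_comparisons.filter_reports
        removed = [frozenset(r["removed_unexpressed"]) for r in reports.values()]
        assert all((a["removed_unexpressed"] & a["removed_variance"]) == set()
                   for a in reports.values())
        assert len(removed) == 6

    def test_deg_union_covers_all_comparisons(self, small_comparisons):
        union = diffexpr.deg_union(small_comparisons)
        assert set(union.columns) >= {"gene_id", "status_C0.5", "log2fc_C0.5"}
        status_cols = [c for c in union.columns if c.startswith("status_")]
        assert ((union[status_cols] != 0).any(axis=1)).all()
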