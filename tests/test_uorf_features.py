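"""uORF feature comparisons: exact rank-sum behaviour, chi-squared
position tests, GC profiles and cumulative TE curves."""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from riboprof import uorf_features as uf
from riboprof.stats import chi_squared, ecdf, rank_sum_test


def enumerate_rank_sum_p(x, y):
    """Full-enumeration oracle for the two-sided rank-sum p."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    n, n1 = len(pooled), len(x)

    def u_stat(a, b):
        return (a[:, None] > b[None, :]).sum() + 0.5 * (a[:, None] == b[None, :]).sum()

    u_obs = u_stat(x, y)
    le = ge = 0
    for chosen in combinations(range(n), n1):
        mask = np.zeros(n, bool)
        mask[list(chosen)] = True
        u = u_stat(pooled[mask], pooled[~mask])
        le += u <= u_obs + 1e-12
        ge += u >= u_obs - 1e-12
    return min(1.0, 2 * min(le, ge) / comb(n, n1))


class TestLengthSummary:
    def test_fraction_below_cutoff(self):
        _, frac = uf.length_summary([9, 150, 300], cutoff=160)
        assert frac == pytest.approx(2 / 3)

    def test_all_above_cutoff(self):
        _, frac = uf.length_summary([200, 300], cutoff=160)
        assert frac == 0.0

    def test_default_sim_all_below_160(self, default_study):
        _, frac = uf.length_summary(default_study.truth.uorfs["length"], cutoff=160)
        assert frac == 1.0


class TestRankSum:
    def test_exact_hand_example(self):
        """{1,2,3} vs {4,5,6}: U=0, p = 2/C(6,3) = 0.100."""
        _, p = rank_sum_test([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.100)

    def test_identical_groups_p_one(self):
        _, p = rank_sum_test([1, 2, 3], [1, 2, 3])
        assert p == 1.0

    def test_matches_enumeration_all_small_splits(self):
        """Exact p equals full enumeration for every split with
        n1+n2 <= 12, on data with and without ties."""
        rng = np.random.default_rng(9)
        for n_tot in range(2, 13):
            for n1 in range(1, n_tot):
                n2 = n_tot - n1
                x = rng.integers(0, 6, n1)  # ties likely
                y = rng.integers(0, 6, n2)
                _, p = rank_sum_test(x, y)
                assert p == pytest.approx(enumerate_rank_sum_p(x, y)), (n1, n2)
                x = rng.normal(size=n1)
                y = rng.normal(size=n2)
                _, p = rank_sum_test(x, y)
                assert p == pytest.approx(enumerate_rank_sum_p(x, y)), (n1, n2)

    def test_large_samples_match_scipy(self):
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(10)
        x, y = rng.normal(size=30), rng.normal(0.5, 1, 25)
        _, p = rank_sum_test(x, y)
        expected = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
        assert p == pytest.approx(float(expected))


class TestCompareDistance:
    def test_direction_and_separation(self):
        comp = uf.compare_distance([0.1, 0.2, 0.3], [0.7, 0.8, 0.9])
        assert comp.direction == "translated smaller"
        assert comp.p_value == pytest.approx(0.100)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            uf.compare_distance([], [0.5])

    def test_planted_shift_detected(self):
        """A -0.2 shift in normalized distance at n=100/100 is found at
        p < 0.01 with the translated group smaller."""
        from riboprof.synthetic_data import SimConfig, simulate_annotation

        cfg = SimConfig(
            n_transcripts=900, uorf_probability=0.6, seed=42,
            uorf_dist_translated=(0.0, 0.8), uorf_dist_untranslated=(0.2, 1.0),
        )
        _, _, _, truth = simulate_annotation(cfg)
        u = truth.uorfs
        tr = u[u["translated"]]["norm_distance"].to_numpy()[:100]
        un = u[~u["translated"]]["norm_distance"].to_numpy()[:100]
        assert len(tr) == len(un) == 100
        comp = uf.compare_distance(tr, un)
        assert comp.direction == "translated smaller"
        assert comp.p_value < 0.01


class TestChiSquared:
    def test_closed_form_2x2(self):
        """[[30,10],[10,30]] collapse: chi2 = n(ad-bc)^2/products = 20."""
        stat, p = chi_squared([[30, 10], [10, 30]])
        assert stat == pytest.approx(20.0)

    def test_identical_distributions_zero(self):
        stat, p = chi_squared([[10, 10, 10, 10], [5, 5, 5, 5]])
        assert stat == 0.0 and p == 1.0

    def test_matches_scipy_on_random_tables(self):
        from scipy.stats import chi2_contingency

        rng = np.random.default_rng(11)
        for _ in range(200):
            t = rng.integers(1, 40, (2, 4))
            stat, p = chi_squared(t)
            ref = chi2_contingency(t, correction=False)
            assert stat == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue)


class TestKozakTest:
    def test_identical_groups_null(self):
        flanks = ["AAAAAAATGGG", "CCCCCCATGCC"] * 10
        for r in uf.kozak_position_test(flanks, list(flanks)):
            assert r.chi2 == pytest.approx(0.0)
            assert r.p_value == pytest.approx(1.0)

    def test_atg_positions_skipped(self):
        flanks = ["AAAAAAATGGG"] * 5
        positions = [r.position for r in uf.kozak_position_test(flanks, flanks)]
        assert set(positions).isdisjoint({1, 2, 3})
        assert 4 in positions and -3 in positions

    def test_plus4_g_enrichment_detected(self, feature_study):
        """With a Kozak-dependent generator, +4 G is enriched in the
        translated group at p < 0.05 (n >= 200 per group)."""
        truth = {r.uorf_id: r.translated for r in feature_study.truth.uorfs.itertuples()}
        tr = [o.flank_sequence for o in feature_study.orfs
              if o.category == "uORF" and truth[o.orf_id]]
        un = [o.flank_sequence for o in feature_study.orfs
              if o.category == "uORF" and not truth[o.orf_id]]
        assert len(tr) >= 200 and len(un) >= 200
        (t4,) = [r for r in uf.kozak_position_test(tr, un) if r.position == 4]
        f_tr = t4.counts_translated["G"] / sum(t4.counts_translated.values())
        f_un = t4.counts_untranslated["G"] / sum(t4.counts_untranslated.values())
        assert f_tr > f_un
        assert t4.p_value < 0.05


class TestGcProfile:
    def test_all_gc_is_one(self):
        prof = uf.gc_flank_profile({"grp": ["G" * 53]}, window=25)
        assert (prof["grp"] == 1.0).all()

    def test_at_only_is_zero(self):
        prof = uf.gc_flank_profile({"grp": ["AT" * 27]}, window=25)
        assert (prof["grp"] == 0.0).all()

    def test_mixed_group_half(self):
        prof = uf.gc_flank_profile({"grp": ["G" * 53, "A" * 53]}, window=25)
        assert (prof["grp"] == 0.5).all()


class TestEcdf:
    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 100, allow_nan=False), min_size=1, max_size=50))
    def test_monotone_and_order_invariant(self, values):
        v, frac = ecdf(values)
        assert (np.diff(frac) >= 0).all() and frac[-1] == 1.0
        v2, frac2 = ecdf(list(reversed(values)))
        assert np.array_equal(v, v2) and np.array_equal(frac, frac2)


class TestCumulativeTe:
    def test_dominance_and_significance(self):
        te = pd.Series(
            [0.6] * 8 + [2.0] * 8, index=[f"g{i}" for i in range(16)]
        )
        flag = pd.Series([True] * 8 + [False] * 8, index=te.index)
        curves, comp = uf.cumulative_te_curve(te, flag, te_min=0.5)
        assert comp.direction == "translated lower"
        assert comp.p_value < 0.05
        tr = {c.group: c for c in curves}["translated"]
        assert (tr.values <= 0.6).all()

    def test_identical_groups(self):
        te = pd.Series([1.0, 2.0, 3.0, 1.0, 2.0, 3.0],
                       index=[f"g{i}" for i in range(6)])
        flag = pd.Series([True] * 3 + [False] * 3, index=te.index)
        _, comp = uf.cumulative_te_curve(te, flag)
        assert comp.p_value == 1.0

    def test_te_filter_applied(self):
        te = pd.Series([0.1, 0.6, 0.2, 2.0], index=list("abcd"))
        flag = pd.Series([True, True, False, False], index=te.index)
        curves, comp = uf.cumulative_te_curve(te, flag, te_min=0.5)
        assert comp.n_translated == 1 and comp.n_untranslated == 1
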