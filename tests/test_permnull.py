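"""Permutation empirical-null testing: t-statistic, null build, p-values, DEG calls."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from senosyn.data_model import Arm
from senosyn.permnull import (
    Comparison,
    DEGThresholds,
    T_CAP,
    build_null,
    call_degs,
    empirical_pvalue,
    t_statistic,
)

from conftest import make_dataset

finite_floats = st.floats(-50, 50, allow_nan=False)


class TestTStatistic:
    def test_identical_groups_give_zero(self):
        assert t_statistic([1, 2, 3], [1, 2, 3]) == 0.0

    def test_hand_computed_value(self):
        # pooled s^2 = 2, t = 1 / sqrt(2 * (1/2 + 1/2)) = 1/sqrt(2)
        assert t_statistic([2, 4], [1, 3]) == pytest.approx(1 / math.sqrt(2))

    def test_matches_scipy_pooled(self, rng):
        from scipy import stats

        a, b = rng.normal(size=6), rng.normal(size=5)
        expect = stats.ttest_ind(a, b, equal_var=True).statistic
        assert t_statistic(a, b) == pytest.approx(expect)

    def test_welch_matches_scipy(self, rng):
        from scipy import stats

        a, b = rng.normal(size=6), rng.normal(1, 2, size=5)
        expect = stats.ttest_ind(a, b, equal_var=False).statistic
        assert t_statistic(a, b, variance="welch") == pytest.approx(expect)

    @given(
        a=st.lists(finite_floats, min_size=2, max_size=6),
        b=st.lists(finite_floats, min_size=2, max_size=6),
    )
    @settings(max_examples=50, deadline=None)
    def test_antisymmetric_in_group_swap(self, a, b):
        assert t_statistic(a, b) == pytest.approx(-t_statistic(b, a))

    def test_zero_variance_unequal_means_is_capped(self):
        assert t_statistic([1, 1], [2, 2]) == -T_CAP
        assert t_statistic([3, 3], [2, 2]) == T_CAP

    def test_group_of_one_errors(self):
        with pytest.raises(ValueError):
            t_statistic([1.0], [1.0, 2.0])


def _null_dataset(rng, n_genes, na, nb):
    values = rng.normal(size=(n_genes, na + nb))
    arms = ["OLD_DMSO"] * na + ["YOUNG"] * nb
    dpts = [3] * na + [0] * nb
    return make_dataset(values, arms, dpts)


CMP = Comparison("old/young@3", Arm.OLD_DMSO, Arm.YOUNG, 3, None)


class TestBuildNull:
    def test_small_design_enumerated_exhaustively(self, two_vs_two_dataset):
        null = build_null(two_vs_two_dataset, CMP, n_perm=10_000, seed=0)
        assert null.exhaustive
        assert null.n_perm == 6  # C(4,2) distinct assignments
        assert null.pooled_t.size == 3 * 6  # genes x assignments

    def test_same_seed_bit_identical(self, rng):
        ds = _null_dataset(rng, 30, 6, 6)  # C(12,6)=924 -> random draws
        a = build_null(ds, CMP, n_perm=200, seed=7)
        b = build_null(ds, CMP, n_perm=200, seed=7)
        assert not a.exhaustive
        assert (a.pooled_t == b.pooled_t).all()

    def test_null_mean_near_zero(self, rng):
        ds = _null_dataset(rng, 500, 5, 5)
        null = build_null(ds, CMP, n_perm=200, seed=1)
        assert abs(float(null.pooled_t.mean())) < 0.05

    def test_density_integrates_to_one(self, rng):
        ds = _null_dataset(rng, 100, 4, 4)
        null = build_null(ds, CMP, n_perm=500, seed=2)
        assert null.density_total == pytest.approx(1.0, abs=1e-3)

    def test_n_perm_below_one_errors(self, two_vs_two_dataset):
        with pytest.raises(ValueError):
            build_null(two_vs_two_dataset, CMP, n_perm=0)


class TestEmpiricalPvalue:
    def symmetric_null(self, rng, estimator="kde"):
        ds = _null_dataset(rng, 200, 4, 4)
        return build_null(ds, CMP, n_perm=500, seed=3, estimator=estimator)

    @pytest.mark.parametrize("estimator", ["kde", "gaussian_fit"])
    def test_center_of_symmetric_null_is_one(self, rng, estimator):
        # exhaustive 4v4 assignments come in sign-swapped pairs: exactly symmetric
        null = self.symmetric_null(rng, estimator)
        assert empirical_pvalue(null, 0.0) == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("estimator", ["kde", "gaussian_fit"])
    def test_p_decreases_with_magnitude(self, rng, estimator):
        null = self.symmetric_null(rng, estimator)
        assert empirical_pvalue(null, 2.0) < empirical_pvalue(null, 1.0)
        assert empirical_pvalue(null, -2.0) < empirical_pvalue(null, -1.0)

    def test_p_strictly_positive_far_in_tail(self, rng):
        null = self.symmetric_null(rng)
        assert empirical_pvalue(null, 50.0) > 0.0

    def test_non_finite_t_errors(self, rng):
        null = self.symmetric_null(rng)
        with pytest.raises(ValueError):
            empirical_pvalue(null, float("nan"))

    def test_small_null_tracks_midp_permutation_fraction(self, rng):
        # one gene, 3v3: C(6,3)=20 exhaustive assignments; the smoothed p
        # should track the mid-p fraction (ties at |t_obs| counted half)
        ds = _null_dataset(rng, 1, 3, 3)
        null = build_null(ds, CMP, n_perm=10_000, seed=0)
        assert null.exhaustive and null.pooled_t.size == 20
        t_obs = t_statistic(
            ds.submatrix(ds.select_samples("OLD_DMSO", 3))[0],
            ds.submatrix(ds.select_samples("YOUNG"))[0],
        )
        abs_t = np.abs(null.pooled_t)
        midp = float(
            np.mean(abs_t > abs(t_obs) + 1e-12)
            + 0.5 * np.mean(np.abs(abs_t - abs(t_obs)) <= 1e-12)
        )
        assert empirical_pvalue(null, t_obs) == pytest.approx(midp, abs=0.1)


class TestCallDegs:
    def test_threshold_logic_up_mid_flat(self, rng):
        # large dataset so the pooled null is well populated
        noise = rng.normal(0, 0.1, size=(300, 8))
        # plant exact observed mean differences: 1.0 (clear UP) and 0.50
        # (significant t but below the 0.58 fold-change cutoff -> NS)
        for row, shift in ((0, 1.0), (1, 0.50)):
            noise[row, :4] += shift - (noise[row, :4].mean() - noise[row, 4:].mean())
        gene_ids = ["g_up", "g_mid"] + [f"n{i}" for i in range(298)]
        ds = make_dataset(noise, ["OLD_DMSO"] * 4 + ["YOUNG"] * 4,
                          [3] * 4 + [0] * 4, gene_ids=gene_ids)
        null = build_null(ds, CMP, n_perm=1000, seed=0)
        table = call_degs(ds, CMP, null, DEGThresholds())
        assert table.direction_of("g_up") == "UP"
        assert table.direction_of("g_mid") == "NS"  # 0.50 < 0.58 cutoff
        row_mid = table.frame.set_index("gene_id").loc["g_mid"]
        assert row_mid["p"] < 0.05  # fails only the fold-change criterion

    def test_high_p_large_lfc_is_ns(self, rng):
        # large fold change but huge variance -> insignificant
        ds = _null_dataset(rng, 200, 4, 4)
        null = build_null(ds, CMP, n_perm=500, seed=1)
        table = call_degs(ds, CMP, null, DEGThresholds())
        frame = table.frame
        ns_big_lfc = frame[(frame["p"] >= 0.05) & (frame["log2fc"].abs() > 0.58)]
        assert (ns_big_lfc["direction"] == "NS").all()

    def test_table_sorted_and_deterministic(self, rng):
        ds = _null_dataset(rng, 50, 4, 4)
        null = build_null(ds, CMP, n_perm=300, seed=5)
        t1 = call_degs(ds, CMP, null, DEGThresholds())
        t2 = call_degs(ds, CMP, null, DEGThresholds())
        assert list(t1.frame["gene_id"]) == sorted(t1.frame["gene_id"])
        assert t1.frame.equals(t2.frame)

    def test_deg_count_monotone_in_thresholds(self, rng):
        values = rng.normal(size=(400, 8))
        values[:100, :4] += rng.uniform(0.3, 1.5, size=(100, 1))
        ds = make_dataset(values, ["OLD_DMSO"] * 4 + ["YOUNG"] * 4, [3] * 4 + [0] * 4)
        null = build_null(ds, CMP, n_perm=500, seed=2)
        counts = []
        for alpha, lam in [(0.10, 0.3), (0.05, 0.58), (0.01, 1.0)]:
            table = call_degs(ds, CMP, null, DEGThresholds(alpha, lam))
            counts.append(len(table.significant()))
        assert counts[0] >= counts[1] >= counts[2]
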