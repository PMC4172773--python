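import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from ringpta.spatial_autocorr import (
    SpatialError,
    correlogram,
    distance_classes,
    holm_adjust,
    morans_i,
)

from oracles import holm_brute, morans_i_brute


class TestDistanceClasses:
    def test_four_points_on_unit_line(self):
        coords = np.column_stack([np.arange(4.0), np.zeros(4)])
        cls = distance_classes(coords, breaks=[0.0, 1.5, 3.0])
        np.testing.assert_array_equal(cls.n_pairs, [3, 3])

    def test_three_points_pair_conservation(self):
        coords = np.array([[0.0, 0.0], [1.0, 0.0], [5.0, 2.0]])
        cls = distance_classes(coords, n_classes=2)
        assert cls.n_pairs.sum() == 3

    @pytest.mark.parametrize("seed", range(3))
    def test_every_pair_in_exactly_one_class(self, seed):
        rng = np.random.default_rng(seed)
        n = 20
        coords = rng.uniform(0, 10, size=(n, 2))
        cls = distance_classes(coords)
        assert cls.n_pairs.sum() == n * (n - 1) // 2

    def test_coincident_pairs_fall_in_first_bin(self):
        coords = np.array([[0.0, 0.0], [0.0, 0.0], [3.0, 0.0], [0.0, 4.0]])
        cls = distance_classes(coords, n_classes=3)
        # the (0, 1) pair at distance 0 lands in bin 0
        assert any((p == [0, 1]).all() for p in cls.pair_indices[0])

    def test_all_coincident_error(self):
        with pytest.raises(SpatialError, match="coincident"):
            distance_classes(np.zeros((4, 2)))

    def test_too_few_points(self):
        with pytest.raises(SpatialError, match="at least 3"):
            distance_classes(np.array([[0.0, 0.0], [1.0, 1.0]]))

    def test_breaks_must_cover_max_distance(self):
        coords = np.column_stack([np.arange(4.0), np.zeros(4)])
        with pytest.raises(SpatialError, match="exceeds last break"):
            distance_classes(coords, breaks=[0.0, 1.0, 2.0])

    def test_unreliable_flag(self):
        coords = np.column_stack([np.arange(5.0), np.zeros(5)])
        cls = distance_classes(coords, n_classes=2)
        assert cls.unreliable.all()  # 10 pairs total, both bins < 20


class TestMoransI:
    def test_alternating_pattern_on_line_is_minus_one(self):
        coords = np.column_stack([np.arange(4.0), np.zeros(4)])
        values = np.array([1.0, -1.0, 1.0, -1.0])
        cls = distance_classes(coords, breaks=[0.0, 1.0, 3.0])
        assert morans_i(values, cls, 0) == pytest.approx(-1.0, abs=1e-12)

    def test_matches_weight_matrix_brute_force(self):
        rng = np.random.default_rng(0)
        coords = rng.uniform(0, 10, size=(12, 2))
        values = rng.standard_normal(12)
        cls = distance_classes(coords, n_classes=3)
        breaks = cls.breaks
        for c in range(3):
            if cls.n_pairs[c] == 0:
                continue
            expected = morans_i_brute(
                values.tolist(),
                coords.tolist(),
                breaks[c],
                breaks[c + 1],
                include_zero=(c == 0),
            )
            assert morans_i(values, cls, c) == pytest.approx(expected, abs=1e-10)

    def test_shuffle_expectation(self):
        rng = np.random.default_rng(1)
        n = 15
        coords = rng.uniform(0, 10, size=(n, 2))
        values = rng.standard_normal(n)
        cls = distance_classes(coords, n_classes=2)
        sims = [
            morans_i(values[rng.permutation(n)], cls, 0) for _ in range(4000)
        ]
        assert np.mean(sims) == pytest.approx(-1.0 / (n - 1), abs=0.01)

    def test_smooth_gradient_positive_in_first_class(self):
        x = np.linspace(0, 10, 20)
        coords = np.column_stack([x, np.zeros(20)])
        cls = distance_classes(coords, n_classes=5)
        assert morans_i(x, cls, 0) > 0

    def test_affine_invariance(self):
        rng = np.random.default_rng(2)
        coords = rng.uniform(0, 10, size=(10, 2))
        values = rng.standard_normal(10)
        cls = distance_classes(coords, n_classes=2)
        i0 = morans_i(values, cls, 0)
        assert morans_i(3.7 * values - 12.0, cls, 0) == pytest.approx(i0, abs=1e-10)

    def test_zero_variance_error(self):
        coords = np.column_stack([np.arange(4.0), np.zeros(4)])
        cls = distance_classes(coords, n_classes=2)
        with pytest.raises(SpatialError, match="zero variance"):
            morans_i(np.ones(4), cls, 0)


class TestHolmAdjust:
    def test_hand_worked_example(self):
        np.testing.assert_allclose(
            holm_adjust([0.01, 0.04, 0.03]), [0.03, 0.06, 0.06], atol=1e-12
        )

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(holm_adjust([0.2]), [0.2])

    def test_all_ones(self):
        np.testing.assert_allclose(holm_adjust([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_never_below_input(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(0.001, 1.0, size=20)
        assert np.all(holm_adjust(p) >= p)

    def test_matches_brute_force_and_statsmodels(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(0.001, 1.0, size=9)
        ours = holm_adjust(p)
        np.testing.assert_allclose(ours, holm_brute(p.tolist()), atol=1e-12)
        _, sm_adj, _, _ = multipletests(p, method="holm")
        np.testing.assert_allclose(ours, sm_adj, atol=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(
            st.floats(min_value=1e-6, max_value=1.0), min_size=1, max_size=12
        )
    )
    def test_monotone_in_sorted_order(self, pvals):
        adj = holm_adjust(pvals)
        order = np.argsort(pvals, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_empty_error(self):
        with pytest.raises(SpatialError, match="empty"):
            holm_adjust([])

    def test_out_of_range_error(self):
        with pytest.raises(SpatialError, match=r"\(0, 1\]"):
            holm_adjust([0.0, 0.5])


class TestCorrelogram:
    @staticmethod
    def setup_field(seed=0, n=30):
        rng = np.random.default_rng(seed)
        coords = rng.uniform(0, 100, size=(n, 2))
        values = rng.standard_normal(n)
        return values, coords

    def test_deterministic_under_seed(self):
        values, coords = self.setup_field()
        a = correlogram(values, coords, n_perm=199, seed=11)
        b = correlogram(values, coords, n_perm=199, seed=11)
        np.testing.assert_array_equal(a.perm_pvalues, b.perm_pvalues)
        np.testing.assert_array_equal(a.morans_i, b.morans_i)
        assert a.globally_significant == b.globally_significant

    def test_pvalues_in_unit_interval_and_holm_dominates(self):
        values, coords = self.setup_field(seed=1)
        res = correlogram(values, coords, n_perm=199, seed=5)
        ok = ~np.isnan(res.perm_pvalues)
        assert np.all(res.perm_pvalues[ok] > 0)
        assert np.all(res.perm_pvalues[ok] <= 1)
        assert np.all(res.holm_pvalues[ok] >= res.perm_pvalues[ok] - 1e-15)

    def test_pair_conservation(self):
        values, coords = self.setup_field(seed=2, n=25)
        res = correlogram(values, coords, n_perm=99, seed=5)
        assert res.n_pairs.sum() == 25 * 24 // 2

    def test_expected_value(self):
        values, coords = self.setup_field(seed=3, n=21)
        res = correlogram(values, coords, n_perm=99, seed=5)
        assert res.expected_i == pytest.approx(-1.0 / 20)

    def test_planted_gradient_is_significant_with_positive_short_range_i(self):
        # strong smooth gradient: positive I at short distances, global
        # significance after Holm
        rng = np.random.default_rng(4)
        coords = rng.uniform(0, 100, size=(60, 2))
        values = coords[:, 0] / 100.0 + 0.05 * rng.standard_normal(60)
        # n_perm must exceed n_classes/alpha, else the Holm floor
        # n_classes/(n_perm+1) already sits above alpha
        res = correlogram(values, coords, n_perm=999, seed=7)
        assert res.globally_significant
        first = np.flatnonzero(~np.isnan(res.morans_i))[0]
        assert res.morans_i[first] > 0

    def test_low_n_perm_warns(self):
        values, coords = self.setup_field(seed=5)
        with pytest.warns(UserWarning, match="coarse p-value resolution"):
            correlogram(values, coords, n_perm=49, seed=1)

    def test_invalid_seed_error(self):
        values, coords = self.setup_field(seed=6)
        with pytest.raises(SpatialError, match="invalid seed"):
            correlogram(values, coords, n_perm=99, seed=-3)

    def test_length_mismatch_error(self):
        values, coords = self.setup_field(seed=7)
        with pytest.raises(SpatialError, match="values for"):
            correlogram(values[:-1], coords, n_perm=99, seed=1)

    def test_one_sided_alternative(self):
        values, coords = self.setup_field(seed=8)
        res = correlogram(
            values, coords, n_perm=199, seed=3, alternative="greater"
        )
        ok = ~np.isnan(res.perm_pvalues)
        assert np.all(res.perm_pvalues[ok] > 0)

    def test_unknown_alternative(self):
        values, coords = self.setup_field(seed=9)
        with pytest.raises(SpatialError, match="alternative"):
            correlogram(values, coords, n_perm=99, seed=1, alternative="less")
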