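"""Decision coefficients, subdivision table, cutoffs, selection,
direction and decision percentages."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pathdc import (
    dc_cutoff,
    decision_coefficients,
    decision_percentages,
    impact_direction,
    select_impacted,
)
from pathdc.estimator import PathwayDecisionAnalysis
from pathdc.path_model import PathModel


def _model_from(r_x, b_star, n=20, ids=None):
    est = PathwayDecisionAnalysis.from_coefficients(r_x, b_star, n, child_ids=ids)
    return PathModel(
        parent_id="y", child_ids=tuple(est.child_ids_), n=est.n_, r_x=est.r_x_,
        r_xy=est.r_xy_, b_star=est.b_star_, r2=est.r2_, c_diag=est.c_diag_,
        condition_flag=est.condition_flag_,
    )


class TestDecisionCoefficients:
    def test_reference_fixture_reproduces_printed_dc(self, ref4):
        dc, _ = decision_coefficients(ref4.model())
        np.testing.assert_allclose(dc.to_numpy(), ref4.dc_expected, atol=0.005)

    def test_orthogonal_structure_dc_is_squared_direct_effect(self):
        b = np.array([0.5, -0.3, 0.1])
        dc, s = decision_coefficients(_model_from(np.eye(3), b, n=10))
        np.testing.assert_allclose(dc.to_numpy(), b**2)
        np.testing.assert_allclose(s.to_numpy() - np.diag(b**2), 0.0, atol=1e-15)

    def test_two_child_hand_arithmetic(self):
        r = np.array([[1.0, -0.6], [-0.6, 1.0]])
        dc, _ = decision_coefficients(_model_from(r, [1.0, 1.0], n=10))
        assert dc.iloc[0] == pytest.approx(1 + 2 * 1 * (-0.6) * 1)

    def test_subdivision_columns_sum_to_dc(self, ref4):
        dc, s = decision_coefficients(ref4.model())
        np.testing.assert_allclose(s.sum(axis=0).to_numpy(), dc.to_numpy(), atol=1e-12)
        np.testing.assert_allclose(s.to_numpy(), s.to_numpy().T, atol=1e-12)

    def test_subdivision_matches_printed_doubled_products(self, ref4):
        # the printed table is itself asymmetric by up to 0.027
        # (-12.772 vs -12.799 for the x3/x4 pair), so the symmetric
        # subdivision can only match it to that asymmetry
        _, s = decision_coefficients(ref4.model())
        printed = ref4.doubled_products_printed
        off = ~np.eye(4, dtype=bool)
        np.testing.assert_allclose(
            s.to_numpy()[off], printed.to_numpy()[off], atol=0.03
        )

    def test_dc_sum_identity(self, ref4):
        # sum_j DC_j = 2 R^2 - sum_j (b*_j)^2
        model = ref4.model()
        dc, _ = decision_coefficients(model)
        assert dc.sum() == pytest.approx(
            2 * model.r2 - np.sum(model.b_star**2), abs=1e-10
        )


class TestCutoff:
    def test_zero_indirect_effect_gives_zero_cutoff(self):
        model = _model_from(np.eye(3), [0.4, 0.2, -0.1], n=12)
        for alpha in (0.01, 0.05, 0.10):
            np.testing.assert_allclose(dc_cutoff(model, alpha).to_numpy(), 0.0)

    def test_hand_computed_value(self):
        # 2 * t_{0.025}(5) * 0.5 * sqrt(2 * 0.1 / 5) = 0.51412...
        est = PathwayDecisionAnalysis.from_correlations(np.eye(4), np.zeros(4), n=10)
        est.r2_ = 0.9
        est.c_diag_ = np.full(4, 2.0)
        est.b_star_ = np.zeros(4)
        est.r_xy_ = np.full(4, 0.5)
        expected = 2 * stats.t.ppf(0.975, 5) * 0.5 * np.sqrt(2 * 0.1 / 5)
        np.testing.assert_allclose(est.cutoff(0.05), expected)
        assert expected == pytest.approx(0.5141, abs=5e-4)

    def test_saturated_model_r2_one_gives_zero_cutoffs(self, rng):
        x = rng.standard_normal((10, 2))
        y = x @ [1.0, -1.0]  # exact linear response
        est = PathwayDecisionAnalysis().fit(x, y)
        assert est.r2_ == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(est.cutoff(0.05), 0.0, atol=1e-12)

    def test_monotone_in_alpha(self, rng):
        x = rng.standard_normal((15, 3))
        y = x @ [1.0, 0.5, -0.2] + rng.normal(scale=0.8, size=15)
        est = PathwayDecisionAnalysis().fit(x, y)
        c1, c5, c10 = est.cutoff(0.01), est.cutoff(0.05), est.cutoff(0.10)
        assert np.all(c1 >= c5) and np.all(c5 >= c10)
        assert np.all(c10 >= 0)

    def test_degrees_of_freedom_guard(self):
        model = _model_from(np.eye(4), [0.1, 0.2, 0.3, 0.4], n=5)  # n-q-1 = 0
        with pytest.raises(ValueError, match="n - q - 1"):
            dc_cutoff(model, 0.05)

    @pytest.mark.parametrize("alpha", [0.0, 1.0, -0.2, 2.0])
    def test_alpha_domain(self, alpha, ref4):
        with pytest.raises(ValueError, match="alpha"):
            dc_cutoff(ref4.model(), alpha)


class TestSelection:
    def test_fixed_threshold_on_reference_dc(self, ref4):
        dc = pd.Series(ref4.dc_expected, index=ref4.child_ids)
        flags, order = select_impacted(dc, 0.4)
        assert set(dc.index[flags]) == {"x2", "x3", "x4"}
        assert order == ["x4", "x3", "x2", "x1"]

    def test_tie_break_is_lexicographic(self):
        dc = pd.Series({"b": -1.0, "a": 1.0, "c": 0.5})
        _, order = select_impacted(dc, 0.0)
        assert order == ["a", "b", "c"]

    def test_relabeling_invariance(self, rng):
        values = rng.normal(size=5)
        dc1 = pd.Series(values, index=list("abcde"))
        dc2 = pd.Series(values, index=list("vwxyz"))
        f1, _ = select_impacted(dc1, 0.4)
        f2, _ = select_impacted(dc2, 0.4)
        np.testing.assert_array_equal(f1.to_numpy(), f2.to_numpy())

    def test_per_child_cutoff_series(self):
        dc = pd.Series({"a": 0.5, "b": -0.5})
        cut = pd.Series({"a": 0.6, "b": 0.4})
        flags, _ = select_impacted(dc, cut)
        assert flags.tolist() == [False, True]

    def test_cutoff_series_must_cover_children(self):
        dc = pd.Series({"a": 0.5, "b": -0.5})
        with pytest.raises(ValueError, match="cover"):
            select_impacted(dc, pd.Series({"a": 0.6}))


class TestDirection:
    def test_reference_fixture_directions(self, ref4):
        labels = impact_direction(pd.Series(ref4.dc_expected, index=ref4.child_ids))
        assert labels.tolist() == ["activated", "activated", "inhibited", "inhibited"]

    def test_zero_is_neutral(self):
        assert impact_direction([0.0]).tolist() == ["neutral"]

    def test_sign_flip_flips_labels(self, rng):
        dc = pd.Series(rng.normal(size=6))
        flipped = impact_direction(-dc)
        original = impact_direction(dc)
        swap = {"activated": "inhibited", "inhibited": "activated", "neutral": "neutral"}
        assert flipped.tolist() == [swap[d] for d in original]


class TestDecisionPercentages:
    def test_single_child_gets_everything(self):
        assert decision_percentages([2.5]).iloc[0] == pytest.approx(100.0)

    def test_reference_fixture_percentages(self, ref4):
        dp = decision_percentages(pd.Series(ref4.dc_expected, index=ref4.child_ids))
        np.testing.assert_allclose(
            dp.to_numpy(), [1.07, 4.85, 26.76, 67.32], atol=0.01
        )
        assert dp.sum() == pytest.approx(100.0, abs=1e-8)

    def test_equal_magnitudes_split_evenly(self):
        np.testing.assert_allclose(
            decision_percentages([3.0, -3.0]).to_numpy(), [50.0, 50.0]
        )

    def test_all_zero_dc_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            decision_percentages([0.0, 0.0])
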