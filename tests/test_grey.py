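"""GM(1,1) grey forecasting and Deng grey relational analysis."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from ecofoot3d import (
    GreySeries,
    gm11_accuracy,
    gm11_fit,
    gm11_forecast,
    grey_relation,
)


def hand_normal_equations(x0):
    """Independent 2×2 normal-equation solve of the grey difference system."""
    x1 = np.cumsum(x0)
    z1 = 0.5 * (x1[1:] + x1[:-1])
    y = np.asarray(x0[1:], dtype=float)
    n = len(z1)
    szz = (z1 * z1).sum()
    sz = z1.sum()
    szy = (z1 * y).sum()
    sy = y.sum()
    det = szz * n - sz * sz
    a = -(n * szy - sz * sy) / det
    b = (szz * sy - sz * szy) / det
    return a, b


class TestGM11Fit:
    def test_constant_series_fits_exactly(self):
        fit = gm11_fit(GreySeries("c", [5.0, 5.0, 5.0, 5.0]))
        assert fit.a == pytest.approx(0.0, abs=1e-12)
        assert fit.b == pytest.approx(5.0, abs=1e-10)
        assert fit.residuals == pytest.approx(np.zeros(4), abs=1e-9)
        assert fit.C == 0.0 and fit.p == 1.0 and fit.grade == 1

    def test_geometric_series_closed_form_parameters(self):
        """q=2 doubling series solves the grey equation with (a,b)=(−2/3, 2/3)."""
        fit = gm11_fit(GreySeries("g", [1.0, 2.0, 4.0, 8.0, 16.0]))
        assert fit.a == pytest.approx(-2.0 / 3.0, abs=1e-10)
        assert fit.b == pytest.approx(2.0 / 3.0, abs=1e-10)
        # the LS system is exactly consistent: x0(k) + a z1(k) = b for all k
        assert fit.x0[1:] + fit.a * fit.z1 == pytest.approx(np.full(4, fit.b), abs=1e-9)

    def test_parameters_match_hand_solved_normal_equations(self):
        x0 = [1.0, 2.0, 3.0, 4.0, 5.0]
        fit = gm11_fit(GreySeries("lin", x0))
        a, b = hand_normal_equations(x0)
        assert fit.a == pytest.approx(a, abs=1e-10)
        assert fit.b == pytest.approx(b, abs=1e-10)

    def test_ago_round_trip_and_background_series(self):
        x0 = np.array([3.0, 1.0, 4.0, 1.5, 9.0])
        fit = gm11_fit(GreySeries("s", x0))
        assert fit.x1 == pytest.approx(np.cumsum(x0))
        assert np.diff(fit.x1) == pytest.approx(x0[1:])
        assert fit.z1 == pytest.approx(0.5 * (fit.x1[1:] + fit.x1[:-1]))
        assert fit.fitted_x0[0] == x0[0]  # boundary condition

    def test_restored_series_is_homogeneous_exponential(self):
        fit = gm11_fit(GreySeries("s", [2.0, 2.5, 3.4, 4.1, 5.3, 6.6]))
        ratios = fit.fitted_x0[2:] / fit.fitted_x0[1:-1]
        assert ratios == pytest.approx(np.full(4, np.exp(-fit.a)), rel=1e-9)

    def test_rejects_short_and_nonpositive_series(self):
        with pytest.raises(ValueError, match="n >= 4"):
            gm11_fit(GreySeries("s", [1.0, 2.0, 3.0]))
        with pytest.raises(ValueError, match="> 0"):
            GreySeries("s", [1.0, -2.0, 3.0, 4.0])


class TestGM11Accuracy:
    def test_posterior_error_oracle(self):
        """C and p recomputed by hand from the residual vector."""
        x0 = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        fit = gm11_fit(GreySeries("lin", x0))
        eps = fit.residuals
        s1 = np.sqrt(np.mean((x0 - x0.mean()) ** 2))
        s2 = np.sqrt(np.mean((eps - eps.mean()) ** 2))
        assert fit.C == pytest.approx(s2 / s1, abs=1e-12)
        p = np.mean(np.abs(eps - eps.mean()) < 0.6745 * s1)
        assert fit.p == pytest.approx(p)

    def test_threshold_table(self):
        assert gm11_accuracy(0.0, 1.0) == 1
        assert gm11_accuracy(0.45, 0.85) == 2
        assert gm11_accuracy(0.60, 0.75) == 3
        assert gm11_accuracy(0.9, 0.5) == 4
        # p fails grade 1 even with excellent C
        assert gm11_accuracy(0.1, 0.9) == 2


class TestGM11Forecast:
    def test_constant_fit_forecasts_constant(self):
        fit = gm11_fit(GreySeries("c", [5.0] * 5))
        values, _ = gm11_forecast(fit, 3)
        assert values == pytest.approx([5.0, 5.0, 5.0])

    @settings(max_examples=100, deadline=None)
    @given(arrays(float, st.integers(4, 10), elements=st.floats(0.5, 50.0)))
    def test_difference_and_closed_form_agree(self, x0):
        fit = gm11_fit(GreySeries("r", x0))
        diff, _ = gm11_forecast(fit, 4, method="difference")
        closed, _ = gm11_forecast(fit, 4, method="closed_form")
        assert diff == pytest.approx(closed, rel=1e-9, abs=1e-9)

    def test_forecast_years_continue_the_index(self):
        years = tuple(range(2011, 2021))
        fit = gm11_fit(GreySeries("eti", np.linspace(2.0, 3.3, 10), index=years))
        _, labels = gm11_forecast(fit, 3)
        assert labels == (2021, 2022, 2023)


class TestGreyRelation:
    def ref(self):
        return GreySeries("ref", [1.0, 2.0, 3.0])

    def test_identical_series_degree_one(self):
        res = grey_relation(self.ref(), [GreySeries("same", [1.0, 2.0, 3.0])])
        assert res.degrees["same"] == pytest.approx(1.0)

    def test_proportional_series_degree_one_under_mean_normalization(self):
        res = grey_relation(self.ref(), [GreySeries("double", [2.0, 4.0, 6.0])])
        assert res.degrees["double"] == pytest.approx(1.0)

    def test_hand_computed_three_point_case(self):
        """Reversed ramp vs ramp: Δ=(1,0,1) after normalization → degree 5/9."""
        res = grey_relation(self.ref(), [GreySeries("rev", [3.0, 2.0, 1.0])], rho=0.5)
        assert res.degrees["rev"] == pytest.approx(5.0 / 9.0, abs=1e-12)

    def test_degrees_in_unit_interval_and_self_reference(self):
        comps = [
            GreySeries("a", [1.1, 2.2, 2.9]),
            GreySeries("ref_copy", [1.0, 2.0, 3.0]),
            GreySeries("b", [5.0, 1.0, 5.0]),
        ]
        res = grey_relation(self.ref(), comps)
        assert res.degrees["ref_copy"] == pytest.approx(1.0)
        for d in res.degrees.values():
            assert 0.0 < d <= 1.0

    @settings(max_examples=100, deadline=None)
    @given(scale=st.floats(0.01, 100.0))
    def test_invariant_under_common_rescaling(self, scale):
        comps = [GreySeries("c", [2.0, 1.5, 4.0])]
        base = grey_relation(self.ref(), comps).degrees["c"]
        scaled = grey_relation(
            GreySeries("ref", np.array([1.0, 2.0, 3.0]) * scale),
            [GreySeries("c", np.array([2.0, 1.5, 4.0]) * scale)],
        ).degrees["c"]
        assert scaled == pytest.approx(base, rel=1e-9)

    def test_degree_decreases_with_pointwise_perturbation(self):
        ref = GreySeries("ref", [1.0, 2.0, 3.0, 4.0])
        near = GreySeries("near", [1.0, 2.1, 3.0, 4.0])
        far = GreySeries("far", [1.0, 3.5, 3.0, 4.0])
        res = grey_relation(ref, [near, far])
        assert res.degrees["near"] > res.degrees["far"]

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            grey_relation(self.ref(), [GreySeries("c", [1.0, 2.0])])
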