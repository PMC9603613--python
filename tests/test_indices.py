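"""Security indices: EFDI, comprehensive pressure, ETI grading, ECC, helpers."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_fv
from ecofoot3d import (
    GradeTable,
    avg_annual_growth,
    classify_eti,
    comprehensive_pressure,
    correlation_matrix,
    ecc,
    efdi,
    efdi_from_footprint,
    eti,
    eti_from_footprint,
    footprint_depth,
    security_indices,
)
from ecofoot3d.landclasses import LandClass


class TestEfdi:
    @pytest.mark.parametrize(
        "shares, expected",
        [
            ([1.0], 0.0),
            ([1 / 6] * 6, math.log(6)),
            ([0.5, 0.3, 0.2], 1.029653),  # hand sum of −Σ p ln p
            ([0.5, 0.5, 0.0], math.log(2)),  # zero share contributes nothing
        ],
    )
    def test_shannon_entropy(self, shares, expected):
        assert efdi(shares) == pytest.approx(expected, abs=1e-6)

    def test_shares_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            efdi([0.5, 0.4])

    @settings(max_examples=100, deadline=None)
    @given(st.permutations([0.05, 0.1, 0.15, 0.2, 0.5]))
    def test_permutation_invariance_and_uniform_maximum(self, shares):
        assert efdi(shares) == pytest.approx(efdi(sorted(shares)), abs=1e-12)
        assert efdi(shares) < math.log(len(shares))

    def test_footprint_shares_over_ef(self, mixed_fv):
        total = sum(mixed_fv.ef.values())
        expected = efdi([v / total for v in mixed_fv.ef.values()])
        assert efdi_from_footprint(mixed_fv) == pytest.approx(expected)


class TestPressureIndices:
    def test_comprehensive_pressure_is_depth(self, mixed_fv, deficit_fv):
        for fv in (mixed_fv, deficit_fv):
            assert comprehensive_pressure(fv) == footprint_depth(fv)

    def test_all_surplus_pressure_is_one(self):
        assert comprehensive_pressure(make_fv([0.5, 0.8], [1, 1])) == pytest.approx(1.0)

    @pytest.mark.parametrize("ef_r, ec, expected", [(2.46, 0.75, 3.28), (0.7, 0.7, 1.0), (0.0, 1.0, 0.0)])
    def test_eti_ratio(self, ef_r, ec, expected):
        assert eti(ef_r, ec) == pytest.approx(expected)

    def test_eti_zero_biocapacity_rejected(self):
        with pytest.raises(ValueError, match="biocapacity"):
            eti(1.0, 0.0)

    def test_eti_from_footprint_excludes_fossil_energy(self, mixed_fv):
        renewable = sum(
            v for lc, v in mixed_fv.ef.items() if lc is not LandClass.FOSSIL_ENERGY
        )
        assert eti_from_footprint(mixed_fv) == pytest.approx(
            renewable / sum(mixed_fv.bc.values())
        )


class TestGrading:
    @pytest.mark.parametrize(
        "value, label",
        [
            (0.3, "Very safe"),
            (0.0, "Very safe"),
            (0.65, "Relatively safe"),
            (0.9, "Slightly unsafe"),
            (1.2, "Moderately unsafe"),
            (1.7, "Highly unsafe"),
            (3.28, "Serious insecurity"),
        ],
    )
    def test_six_level_scale(self, value, label):
        assert classify_eti(value) == label

    def test_linear_scan_oracle(self):
        """Bin classification agrees with a literal scan for 10⁴ random draws."""
        table = GradeTable()
        rng = np.random.default_rng(7)
        values = rng.uniform(0.0, 4.0, 10_000)
        for v in values:
            expected = table.labels[-1]
            for bound, label in zip(table.boundaries, table.labels):
                if v < bound:
                    expected = label
                    break
            assert classify_eti(v, table) == expected

    def test_exactly_one_label_at_boundaries(self):
        for b in GradeTable().boundaries:
            assert isinstance(classify_eti(b), str)


class TestEcc:
    @pytest.mark.parametrize(
        "epi, expected, tol",
        [
            (1.0, math.sqrt(2), 1e-6),
            (3.28, 1.2482, 5e-5),
            (1.23, 1.4068, 5e-5),
            (0.0, 1.0, 0.0),  # degenerate closed-form value
        ],
    )
    def test_closed_form(self, epi, expected, tol):
        assert ecc(epi) == pytest.approx(expected, abs=tol)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            ecc(-0.1)

    def test_unimodal_with_maximum_sqrt2_at_one(self):
        grid = np.linspace(0.0, 1.0, 200)
        rising = np.array([ecc(x) for x in grid])
        assert (np.diff(rising) > 0).all()
        grid = np.linspace(1.0, 10.0, 400)
        falling = np.array([ecc(x) for x in grid])
        assert (np.diff(falling) < 0).all()
        assert max(rising.max(), falling.max()) <= math.sqrt(2) + 1e-12


class TestGrowthAndCorrelation:
    @pytest.mark.parametrize(
        "start, end, periods, expected",
        [
            (2.6256, 3.3163, 10, 0.0236),  # full-span divisor convention
            (5.0, 5.0, 7, 0.0),
            (1.0, 4.0, 2, 1.0),
        ],
    )
    def test_compound_growth(self, start, end, periods, expected):
        assert avg_annual_growth(start, end, periods) == pytest.approx(expected, abs=5e-5)

    def test_nonpositive_start_rejected(self):
        with pytest.raises(ValueError):
            avg_annual_growth(0.0, 1.0, 5)

    def test_self_and_negation_correlations(self):
        x = np.arange(10.0)
        df = pd.DataFrame({"x": x, "neg": -x, "noise": np.sin(x)})
        corr = correlation_matrix(df)
        assert corr.loc["x", "x"] == pytest.approx(1.0)
        assert corr.loc["x", "neg"] == pytest.approx(-1.0)
        assert np.allclose(corr.values, corr.values.T)
        assert (corr.abs().values <= 1.0 + 1e-12).all()

    def test_independent_white_noise_nearly_uncorrelated(self):
        rng = np.random.default_rng(11)
        df = pd.DataFrame({"a": rng.normal(size=1000), "b": rng.normal(size=1000)})
        assert abs(correlation_matrix(df).loc["a", "b"]) < 0.1

    def test_zero_variance_flagged_not_zeroed(self):
        df = pd.DataFrame({"x": np.arange(5.0), "const": np.ones(5)})
        with pytest.warns(UserWarning, match="const"):
            corr = correlation_matrix(df)
        assert math.isnan(corr.loc["x", "const"])


def test_security_indices_bundle(mixed_fv):
    s = security_indices(mixed_fv)
    assert s.i_comprehensive == pytest.approx(footprint_depth(mixed_fv))
    assert s.eti == pytest.approx(eti_from_footprint(mixed_fv))
    assert s.eti_grade == classify_eti(s.eti)
    assert s.ecc == pytest.approx(ecc(s.eti))
    assert 1.0 <= s.ecc <= math.sqrt(2)
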