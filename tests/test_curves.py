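"""Compatibility/surprisal/likelihood curves and interval estimates."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from surpval import (
    EffectEstimate,
    TestHypothesis,
    build_curve,
    curve_to_frame,
    interval_at_level,
    likelihood_interval,
    mlr_from_p,
    p_value,
    plot_curve,
    values_more_compatible_than,
)


class TestBuildCurve:
    def test_peak_at_point_estimate(self, brown):
        curve = build_curve(brown, n_points=201)
        i = np.argmax(curve.p)
        assert curve.grid[i] == pytest.approx(brown.point, rel=1e-6)
        assert curve.p[i] == pytest.approx(1.0)
        assert curve.s_bits[i] == pytest.approx(0.0, abs=1e-9)

    def test_unimodal_and_aligned(self, brown):
        curve = build_curve(brown, n_points=101)
        assert len(curve.results) == len(curve.grid) == 101
        i = int(np.argmax(curve.p))
        assert np.all(np.diff(curve.p[: i + 1]) > 0)
        assert np.all(np.diff(curve.p[i:]) < 0)

    def test_symmetric_in_z_on_analysis_scale(self, brown):
        curve = build_curve(brown, n_points=101)  # odd count centers the peak
        z = np.array([r.z for r in curve.results])
        assert z[::-1] == pytest.approx(-z, abs=1e-9)
        assert curve.p[::-1] == pytest.approx(curve.p, rel=1e-9)

    def test_deviance_curve_is_z_squared(self, brown):
        curve = build_curve(brown, n_points=51)
        z = np.array([r.z for r in curve.results])
        assert curve.deviance == pytest.approx(z**2, rel=1e-12)

    def test_rel_likelihood_is_inverse_mlr(self, brown):
        curve = build_curve(brown, n_points=51)
        mlr = np.array([r.mlr for r in curve.results])
        assert curve.rel_likelihood == pytest.approx(1.0 / mlr, rel=1e-12)

    def test_grid_spans_requested_level(self, brown):
        curve = build_curve(brown, span_level=0.999, n_points=51)
        ival = interval_at_level(brown, 0.999)
        assert curve.grid[0] <= ival.lower * (1 + 1e-9)
        assert curve.grid[-1] >= ival.upper * (1 - 1e-9)

    def test_too_few_points_rejected(self, brown):
        with pytest.raises(ValueError):
            build_curve(brown, n_points=2)

    def test_frame_export_columns(self, brown):
        df = curve_to_frame(build_curve(brown, n_points=11))
        assert list(df.columns) == [
            "hypothesis", "p", "s_bits", "mlr", "deviance", "rel_likelihood",
        ]
        assert len(df) == 11


class TestIntervalAtLevel:
    def test_recovers_reported_95_limits(self, brown):
        ival = interval_at_level(brown, 0.95)
        # reported inputs are 3-sig-fig rounded: +/-0.5% relative
        assert ival.lower == pytest.approx(0.997, rel=5e-3)
        assert ival.upper == pytest.approx(2.59, rel=5e-3)

    @pytest.mark.parametrize("level", [0.75, 0.95, 0.99])
    def test_endpoints_sit_at_p_equals_alpha(self, brown, level):
        ival = interval_at_level(brown, level)
        for end in ival:
            assert p_value(brown, end) == pytest.approx(1 - level, rel=1e-6)

    def test_ninety_nine_percent_endpoints(self, brown):
        ival = interval_at_level(brown, 0.99)
        q = 2.5758293
        se = brown.se
        assert ival.lower == pytest.approx(math.exp(math.log(1.61) - q * se), rel=1e-6)
        assert ival.upper == pytest.approx(math.exp(math.log(1.61) + q * se), rel=1e-6)

    @given(a=st.floats(0.05, 0.985), b=st.floats(0.05, 0.985))
    def test_nesting(self, brown, a, b):
        if math.isclose(a, b):
            return
        lo, hi = sorted((a, b))
        inner, outer = interval_at_level(brown, lo), interval_at_level(brown, hi)
        assert outer.lower < inner.lower < inner.upper < outer.upper

    def test_curve_interval_consistency(self, brown):
        curve = build_curve(brown, n_points=401)
        ival = interval_at_level(brown, 0.95)
        inside = (curve.grid > ival.lower) & (curve.grid < ival.upper)
        assert np.all(curve.p[inside] > 0.05)
        assert np.all(curve.p[~inside] <= 0.05 + 1e-12)

    def test_invalid_level(self, brown):
        with pytest.raises(ValueError):
            interval_at_level(brown, 1.5)


class TestLikelihoodInterval:
    def test_one_over_mlr_cutoff_matches_compatibility_interval(self, brown):
        li = likelihood_interval(brown, 1 / 6.83)
        ci = interval_at_level(brown, 0.95)
        assert li.lower == pytest.approx(ci.lower, rel=1e-3)
        assert li.upper == pytest.approx(ci.upper, rel=1e-3)

    def test_exact_duality_at_any_level(self, brown):
        for level in (0.75, 0.95, 0.99):
            cutoff = 1 / mlr_from_p(1 - level)
            li = likelihood_interval(brown, cutoff)
            ci = interval_at_level(brown, level)
            assert li.lower == pytest.approx(ci.lower, rel=1e-9)
            assert li.upper == pytest.approx(ci.upper, rel=1e-9)

    def test_cutoff_one_degenerates_to_point(self, brown):
        li = likelihood_interval(brown, 1.0)
        assert li.lower == li.upper == pytest.approx(brown.point)

    def test_invalid_cutoff(self, brown):
        with pytest.raises(ValueError):
            likelihood_interval(brown, 0.0)


class TestValuesMoreCompatibleThan:
    def test_null_reference_mirrors_to_squared_point(self, brown):
        ival = values_more_compatible_than(brown, 1.0)
        assert ival.lower == pytest.approx(1.0)
        assert ival.upper == pytest.approx(1.61**2, rel=1e-9)

    def test_reference_above_point_mirrors_down(self, brown):
        ival = values_more_compatible_than(brown, 2.0)
        assert ival.upper == pytest.approx(2.0)
        assert ival.lower == pytest.approx(math.exp(2 * math.log(1.61) - math.log(2)))
        # equal P-values at both endpoints
        assert p_value(brown, ival.lower) == pytest.approx(
            p_value(brown, ival.upper), rel=1e-9
        )

    def test_reference_at_point_rejected(self, brown):
        with pytest.raises(ValueError, match="degenerate"):
            values_more_compatible_than(brown, 1.61)


class TestPlots:
    def test_all_four_kinds_render(self, brown, tmp_path):
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        curve = build_curve(brown, n_points=51)
        for kind in ("p", "s", "likelihood", "deviance"):
            ax = plot_curve(curve, kind=kind, show_null=True)
            ax.figure.savefig(tmp_path / f"{kind}.png")
            plt.close(ax.figure)
        assert len(list(tmp_path.iterdir())) == 4
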