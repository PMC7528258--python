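"""Compatibility, surprisal, likelihood and deviance functions and intervals.

A compatibility curve evaluates the full evidential panel on an ordered
grid of hypothesis values, giving the P-value (compatibility) function
that peaks at the point estimate, the S-value (surprisal) function that
bottoms out there, the relative-likelihood function ``exp(-z^2/2)`` and
the deviance function ``z^2``.

Interval estimates are closed-form Wald endpoints, not grid
interpolation: a level-L compatibility interval collects every
hypothesis with ``p > 1 - L`` and has endpoints
``T^-1(T(point) +/- q SE)`` with ``q = Phi^-1((1+L)/2)``; a
likelihood interval at cutoff c collects every hypothesis whose relative
likelihood exceeds c, endpoints ``T^-1(T(point) +/- SE sqrt(-2 ln c))``.
The 1/6.83 likelihood interval coincides with the 95% compatibility
interval under the Wald model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .estimates import EffectEstimate, TestHypothesis, _transform
from .surprisal import TestResult, test_panel

__all__ = [
    "CompatibilityCurve",
    "IntervalEstimate",
    "build_curve",
    "interval_at_level",
    "likelihood_interval",
    "values_more_compatible_than",
    "curve_to_frame",
    "plot_curve",
]

DEFAULT_SPAN_LEVEL = 0.999
DEFAULT_N_POINTS = 400
DEFAULT_LEVELS = (0.75, 0.95, 0.99)


@dataclass(frozen=True)
class IntervalEstimate:
    """A compatibility (p > alpha) or likelihood (RL >= cutoff) interval."""

    kind: Literal["compatibility", "likelihood"]
    level_or_cutoff: float
    lower: float
    upper: float

    def __post_init__(self):
        if self.lower > self.upper:
            raise ValueError("interval endpoints out of order")

    def contains(self, value: float) -> bool:
        return self.lower <= value <= self.upper

    def __iter__(self):
        yield self.lower
        yield self.upper


@dataclass(frozen=True)
class CompatibilityCurve:
    """Evidential panel over an ordered hypothesis grid.

    ``results`` align 1:1 with ``grid``; ``rel_likelihood[i]`` equals
    ``1 / results[i].mlr``.
    """

    estimate: EffectEstimate
    grid: np.ndarray
    results: tuple[TestResult, ...]

    @property
    def p(self) -> np.ndarray:
        return np.array([r.p for r in self.results])

    @property
    def s_bits(self) -> np.ndarray:
        return np.array([r.s_bits for r in self.results])

    @property
    def deviance(self) -> np.ndarray:
        return np.array([r.deviance for r in self.results])

    @property
    def rel_likelihood(self) -> np.ndarray:
        return np.array([r.rel_likelihood for r in self.results])


def build_curve(
    est: EffectEstimate,
    span_level: float = DEFAULT_SPAN_LEVEL,
    n_points: int = DEFAULT_N_POINTS,
) -> CompatibilityCurve:
    """Evaluate the compatibility function over a uniform analysis-scale grid.

    The grid spans the ``span_level`` compatibility interval (99.9% by
    default), spaced uniformly on the analysis scale — log-uniform for
    ratio measures — so the deviance curve is an exact quadratic in the
    grid index.
    """
    if n_points < 3:
        raise ValueError("need at least 3 grid points")
    if not (0 < span_level < 1):
        raise ValueError("span_level must be in (0,1)")
    lo, hi = interval_at_level(est, span_level)
    T, Tinv = _transform(est.scale)
    tgrid = np.linspace(T(lo), T(hi), n_points)
    grid = np.array([Tinv(t) for t in tgrid])
    results = tuple(test_panel(est, list(grid)))
    return CompatibilityCurve(estimate=est, grid=grid, results=results)


def interval_at_level(est: EffectEstimate, level: float) -> IntervalEstimate:
    """Closed-form Wald compatibility interval at a percentile level.

    Endpoints satisfy ``p = 1 - level`` exactly; every interior value
    has ``p > 1 - level``.

    >>> from surpval import BROWN_HDPS
    >>> ival = interval_at_level(BROWN_HDPS, 0.95)
    >>> round(ival.lower, 3), round(ival.upper, 2)
    (0.997, 2.59)
    """
    if not (0 < level < 1):
        raise ValueError(f"level must be in (0,1), got {level}")
    T, Tinv = _transform(est.scale)
    q = stats.norm.ppf(0.5 + level / 2)
    center = T(est.point)
    half = q * est.se
    return IntervalEstimate(
        kind="compatibility",
        level_or_cutoff=level,
        lower=Tinv(center - half),
        upper=Tinv(center + half),
    )


def likelihood_interval(est: EffectEstimate, cutoff: float) -> IntervalEstimate:
    """Interval of hypotheses with relative likelihood ``exp(-z^2/2) >= cutoff``.

    Closed form ``T^-1(T(point) +/- SE sqrt(-2 ln cutoff))``.  A cutoff
    of 1 gives the degenerate interval at the point estimate.
    """
    if not (0 < cutoff <= 1):
        raise ValueError(f"cutoff must be in (0,1], got {cutoff}")
    T, Tinv = _transform(est.scale)
    half = est.se * math.sqrt(-2.0 * math.log(cutoff))
    center = T(est.point)
    return IntervalEstimate(
        kind="likelihood",
        level_or_cutoff=cutoff,
        lower=Tinv(center - half),
        upper=Tinv(center + half),
    )


def values_more_compatible_than(
    est: EffectEstimate, reference: TestHypothesis | float
) -> IntervalEstimate:
    """All hypothesis values with a larger P-value than a reference value.

    By Wald symmetry on the analysis scale, the reference mirrors about
    the point estimate: for a reference below the point estimate the
    interval is ``(ref, T^-1(2 T(point) - T(ref)))``, mirrored
    otherwise.  A reference at the point estimate is degenerate (no
    value is strictly more compatible) and rejected.
    """
    if not isinstance(reference, TestHypothesis):
        reference = TestHypothesis(float(reference))
    T, Tinv = _transform(est.scale)
    t_ref, t_pt = T(reference.value), T(est.point)
    if math.isclose(t_ref, t_pt, rel_tol=0.0, abs_tol=1e-12):
        raise ValueError("reference equals the point estimate: degenerate interval")
    mirror = Tinv(2.0 * t_pt - t_ref)
    lo, hi = sorted((reference.value, mirror))
    # the set {θ : p(θ) > p(ref)} is the (1 - p(ref))-level compatibility interval
    from .estimates import p_value

    level = 1.0 - p_value(est, reference)
    return IntervalEstimate(kind="compatibility", level_or_cutoff=level, lower=lo, upper=hi)


def curve_to_frame(curve: CompatibilityCurve) -> pd.DataFrame:
    """Curve export: one row per grid point with all evidential columns."""
    return pd.DataFrame(
        {
            "hypothesis": curve.grid,
            "p": curve.p,
            "s_bits": curve.s_bits,
            "mlr": 1.0 / curve.rel_likelihood,
            "deviance": curve.deviance,
            "rel_likelihood": curve.rel_likelihood,
        }
    )


_CURVE_KINDS = {
    "p": ("p", "P-value (compatibility)"),
    "s": ("s_bits", "S-value (bits of information)"),
    "likelihood": ("rel_likelihood", "Relative likelihood  exp(-z²/2)"),
    "deviance": ("deviance", "Deviance statistic  z²"),
}


def plot_curve(
    curve: CompatibilityCurve,
    kind: Literal["p", "s", "likelihood", "deviance"] = "p",
    levels: Sequence[float] = DEFAULT_LEVELS,
    show_null: bool = False,
    ax=None,
):
    """Plot one of the four evidential functions over the hypothesis grid.

    The x axis uses analysis-scale spacing (log for ratios) with
    natural-scale labels.  The P-value plot carries a right-hand axis
    reading off compatibility-interval percentiles (100(1-p)%), and
    interval levels are drawn as horizontal guides.  A vertical
    reference line at the null (1 for ratios, 0 for differences) is
    drawn only on request.
    """
    import matplotlib.pyplot as plt

    if kind not in _CURVE_KINDS:
        raise ValueError(f"unknown curve kind {kind!r}")
    attr, ylabel = _CURVE_KINDS[kind]
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4.5))
    y = getattr(curve, attr)
    ax.plot(curve.grid, y, color="#1f4e79", lw=1.8)
    est = curve.estimate
    if est.scale == "log":
        ax.set_xscale("log")
        ax.xaxis.set_major_formatter("{x:g}")
    peak = {"p": 1.0, "s": 0.0, "likelihood": 1.0, "deviance": 0.0}[kind]
    ax.plot([est.point], [peak], marker="o", color="#c0392b", zorder=5)
    ax.annotate(
        f"point estimate {est.point:g}",
        (est.point, peak),
        textcoords="offset points",
        xytext=(6, -2 if kind in ("p", "likelihood") else 6),
        fontsize=8,
    )
    if kind == "p":
        for lvl in levels:
            ax.axhline(1 - lvl, color="0.6", lw=0.7, ls="--")
        right = ax.secondary_yaxis(
            "right", functions=(lambda p: 100 * (1 - p), lambda c: 1 - c / 100)
        )
        right.set_ylabel("Compatibility interval (%)")
    elif kind == "likelihood":
        from .surprisal import mlr_from_p

        for lvl in levels:
            ax.axhline(1.0 / mlr_from_p(1 - lvl), color="0.6", lw=0.7, ls="--")
    if show_null:
        null = 1.0 if est.scale == "log" else 0.0
        ax.axvline(null, color="0.3", lw=0.8, ls=":")
    ax.set_xlabel(est.label or "hypothesis value")
    ax.set_ylabel(ylabel)
    ax.set_title({"p": "Compatibility (P-value) function",
                  "s": "Surprisal (S-value) function",
                  "likelihood": "Relative-likelihood function",
                  "deviance": "Deviance function"}[kind])
    return ax
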