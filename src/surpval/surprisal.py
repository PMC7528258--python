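"""S-values, maximum-likelihood ratios and deviance statistics.

The S-value (surprisal, Shannon information) of a P-value is
``s = -log2(p)`` bits: the information against the test model, calibrated
as the number of consecutive heads in fair coin tosses that would be
equally surprising.  For a simple one-parameter hypothesis tested with a
Wald z statistic, the maximized-over-observed likelihood ratio against
the hypothesis is ``MLR = exp(z^2 / 2)`` and the deviance
(likelihood-ratio) statistic is ``2 ln(MLR) = z^2``; both are recovered
from a two-sided P-value by the inverse-normal map ``z = Phi^-1(1 - p/2)``.

`test_panel` assembles the full evidential panel (z, P, S, MLR,
deviance) for an effect estimate over a list of test hypotheses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .estimates import EffectEstimate, TestHypothesis, log_p_value, z_score

SUnit = Literal["bits", "nats"]

__all__ = [
    "TestResult",
    "s_value",
    "p_from_s",
    "mlr_from_p",
    "deviance_from_p",
    "test_panel",
    "format_s_value",
    "panel_to_frame",
    "panel_to_text",
]

_LN2 = math.log(2.0)

# S-values above -log2(0.001) ~ 10 bits rest on normal-tail approximations
# with at most 2-digit accuracy, so display rounds them to whole bits
_S_ROUND_THRESHOLD = 10.0


def _check_p(p: float) -> float:
    p = float(p)
    if not (0.0 < p <= 1.0):
        raise ValueError(f"P-value must lie in (0, 1], got {p}")
    return p


def s_value(p: float, base: SUnit = "bits") -> float:
    """Surprisal of a P-value: ``-log2(p)`` bits or ``-ln(p)`` nats.

    >>> round(s_value(0.05), 2)
    4.32
    >>> s_value(0.5), s_value(1.0)
    (1.0, -0.0)
    """
    p = _check_p(p)
    if base == "bits":
        return -math.log2(p) + 0.0  # +0.0 turns -0.0 into 0.0 at p = 1
    if base == "nats":
        return -math.log(p) + 0.0
    raise ValueError(f"unknown S-value unit {base!r}")


def p_from_s(s: float, base: SUnit = "bits") -> float:
    """Invert the surprisal transform: ``2**-s`` (bits) or ``e**-s`` (nats)."""
    s = float(s)
    if s < 0:
        raise ValueError(f"S-value must be non-negative, got {s}")
    if base == "bits":
        return 2.0 ** (-s)
    if base == "nats":
        return math.exp(-s)
    raise ValueError(f"unknown S-value unit {base!r}")


def _z_from_two_sided_p(p: float) -> float:
    """|z| whose two-sided normal tail equals p (exact inverse CDF)."""
    return float(stats.norm.isf(p / 2.0))


def mlr_from_p(p: float) -> float:
    """Maximum-likelihood ratio against a simple hypothesis, from a two-sided P.

    ``exp(z^2/2)`` with ``z = Phi^-1(1 - p/2)``.  All quoted tail
    probabilities (including one-sided sigma cutoffs) are treated as
    two-sided P-values and re-inverted under this single convention.

    >>> round(mlr_from_p(0.05), 2)
    6.83
    """
    p = _check_p(p)
    z = _z_from_two_sided_p(p)
    return math.exp(0.5 * z * z)


def deviance_from_p(p: float) -> float:
    """Deviance (likelihood-ratio) statistic ``z^2 = 2 ln(MLR)`` from a two-sided P.

    >>> round(deviance_from_p(0.05), 2)
    3.84
    """
    p = _check_p(p)
    z = _z_from_two_sided_p(p)
    return z * z


@dataclass(frozen=True)
class TestResult:
    """The evidential panel for one test hypothesis against one estimate.

    Fields satisfy ``s_bits = -log2(p)``, ``deviance = 2 ln(mlr) = z^2``
    (when z is present), and ``p = 1  <=>  s_bits = 0  <=>  mlr = 1``.
    """

    __test__ = False  # public name starts with "Test"; not a pytest item

    hypothesis: TestHypothesis
    p: float
    s_bits: float
    mlr: float
    deviance: float
    z: float | None = None

    @property
    def s_nats(self) -> float:
        return self.s_bits * _LN2

    @property
    def rel_likelihood(self) -> float:
        """Relative likelihood of the hypothesis: ``1 / MLR = exp(-z^2/2)``."""
        return 1.0 / self.mlr


def _result_for(est: EffectEstimate, hyp: TestHypothesis) -> TestResult:
    z = z_score(est, hyp)
    log_p = log_p_value(est, hyp, "two")
    p = math.exp(log_p)
    s_bits = -log_p / _LN2 + 0.0  # log-tail form avoids underflow; +0.0 kills -0.0
    dev = z * z
    return TestResult(
        hypothesis=hyp, p=p, s_bits=s_bits, mlr=math.exp(0.5 * dev), deviance=dev, z=z
    )


def test_panel(
    est: EffectEstimate, hyps: Sequence[TestHypothesis | float]
) -> list[TestResult]:
    """Evidential panel: one :class:`TestResult` per hypothesis, order preserved.

    MLR and deviance use the two-sided convention; the panel is built
    from two-sided Wald P-values throughout (a panel of one-sided
    P-values would not support this convention and is not offered).

    >>> from surpval import BROWN_HDPS
    >>> row = test_panel(BROWN_HDPS, [1.0])[0]
    >>> round(row.p, 4), round(row.s_bits, 2), round(row.mlr, 2), round(row.deviance, 2)
    (0.0505, 4.31, 6.76, 3.82)
    """
    hyps = list(hyps)
    if not hyps:
        raise ValueError("hypothesis list is empty")
    out = []
    for h in hyps:
        if not isinstance(h, TestHypothesis):
            h = TestHypothesis(float(h))
        out.append(_result_for(est, h))
    return out


test_panel.__test__ = False  # public name starts with "test"; not a pytest item


def format_s_value(s: float) -> str:
    """Display an S-value: two decimals up to 10 bits, whole bits above.

    Stored values keep full precision; this policy is display-only.
    """
    if s < 0:
        raise ValueError("S-value must be non-negative")
    if s <= _S_ROUND_THRESHOLD:
        return f"{s:.2f}"
    return f"{s:.0f}"


def _fmt_sig(x: float, sig: int = 3) -> str:
    if x == 0:
        return "0.00"
    if abs(x) >= 1e4 or abs(x) < 1e-3:
        return f"{x:.{sig - 1}e}"
    return f"{x:.{sig}g}"


def panel_to_frame(results: Iterable[TestResult]) -> pd.DataFrame:
    """Panel as a DataFrame at full precision (CSV-ready), Table-style columns."""
    rows = []
    for r in results:
        rows.append(
            {
                "hypothesis_label": r.hypothesis.label,
                "hypothesis_value": r.hypothesis.value,
                "p": r.p,
                "s_bits": r.s_bits,
                "mlr": r.mlr,
                "deviance": r.deviance,
            }
        )
    return pd.DataFrame(rows)


def panel_to_text(results: Iterable[TestResult]) -> str:
    """Aligned plain-text panel with display rounding applied to S-values."""
    header = ("hypothesis", "value", "P", "S (bits)", "MLR", "deviance")
    body = []
    for r in results:
        body.append(
            (
                r.hypothesis.label or "-",
                f"{r.hypothesis.value:g}",
                _fmt_sig(r.p),
                format_s_value(r.s_bits),
                _fmt_sig(r.mlr),
                f"{r.deviance:.2f}",
            )
        )
    widths = [max(len(row[i]) for row in [header, *body]) for i in range(len(header))]
    lines = ["  ".join(h.ljust(w) for h, w in zip(header, widths))]
    lines.append("  ".join("-" * w for w in widths))
    for row in body:
        lines.append("  ".join(c.ljust(w) for c, w in zip(row, widths)))
    return "\n".join(lines)
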