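"""Combining evidence across studies and checking P-value validity.

Natural-log S-values (``-ln p``) from K independent studies of the same
hypothesis sum to a statistic with expectation K when the hypothesis and
all background assumptions hold; doubling the sum and referring it to a
chi-squared distribution with 2K degrees of freedom (Fisher's method)
gives the combined P-value.  All K inputs must share one sidedness
convention (all two-sided, or all one-sided in the same direction);
mixing conventions silently produces a meaningless combination, and
P-values that are not valid — not uniform under the test model, e.g.
posterior predictive P-values — are outside the method's premises and
cannot be detected from the numbers alone.

`check_uniformity` tests the validity criterion itself — that a
P-value is uniform on (0,1) under the test model — on a sample of
P-values, and `simulate_studies` generates reproducible Wald-model study
sets for such checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .estimates import EffectEstimate, Scale

__all__ = [
    "StudyEvidence",
    "SimulatedStudySet",
    "CombinationResult",
    "combine_studies",
    "check_uniformity",
    "simulate_studies",
    "read_pvalues_csv",
]


@dataclass(frozen=True)
class StudyEvidence:
    """Per-study P-values for one shared test hypothesis.

    All entries must use the same sidedness convention and direction.
    """

    p_values: tuple[float, ...]
    labels: tuple[str, ...] | None = None

    def __post_init__(self):
        object.__setattr__(self, "p_values", tuple(float(p) for p in self.p_values))
        if len(self.p_values) < 1:
            raise ValueError("need at least one study")
        if any(not (0.0 < p <= 1.0) for p in self.p_values):
            raise ValueError("all P-values must lie in (0, 1]")
        if self.labels is not None and len(self.labels) != len(self.p_values):
            raise ValueError("labels must match p_values in length")

    @property
    def K(self) -> int:
        return len(self.p_values)


class CombinationResult(NamedTuple):
    statistic: float  # 2 * sum of natural-log S-values
    df: int  # 2K
    p_combined: float


def combine_studies(ev: StudyEvidence | Sequence[float]) -> CombinationResult:
    """Fisher combination of K independent P-values via summed nat S-values.

    ``statistic = 2 * sum(-ln p_k)`` referred to chi-squared with
    ``df = 2K``.  With K = 1 the combined P-value reproduces the input
    exactly.  Small P-values combine toward evidence; the method is
    one-directional and has no two-sided variant here.

    >>> round(combine_studies([0.05, 0.05]).p_combined, 4)
    0.0175
    """
    if not isinstance(ev, StudyEvidence):
        ev = StudyEvidence(tuple(ev))
    nat_s = [-math.log(p) for p in ev.p_values]
    statistic = 2.0 * sum(nat_s)
    df = 2 * ev.K
    p_combined = float(stats.chi2.sf(statistic, df))
    return CombinationResult(statistic=statistic, df=df, p_combined=p_combined)


class UniformityResult(NamedTuple):
    ks_distance: float
    ks_p: float


def check_uniformity(p_values: Sequence[float]) -> UniformityResult:
    """Kolmogorov–Smirnov test of P-value validity (uniformity on (0,1)).

    A valid P-value is uniform when the test hypothesis and all
    background assumptions hold; a distribution piled up near 0 when
    testing a wrong hypothesis is the power side of the same coin.
    Requires at least 10 values.
    """
    p_values = np.asarray(p_values, dtype=float)
    if p_values.size < 10:
        raise ValueError(f"need at least 10 P-values, got {p_values.size}")
    if np.any((p_values <= 0) | (p_values > 1)):
        raise ValueError("all P-values must lie in (0, 1]")
    res = stats.kstest(p_values, "uniform")
    return UniformityResult(ks_distance=float(res.statistic), ks_p=float(res.pvalue))


@dataclass(frozen=True)
class SimulatedStudySet:
    """Reproducible Wald-model study draws: same seed, bit-identical estimates."""

    seed: int
    n_studies: int
    true_effect: float  # analysis scale
    se_per_study: float
    scale: Scale
    estimates: tuple[EffectEstimate, ...] = field(repr=False)

    @property
    def points_analysis_scale(self) -> np.ndarray:
        """Point estimates transformed back to the analysis scale."""
        pts = np.array([e.point for e in self.estimates])
        return np.log(pts) if self.scale == "log" else pts


def simulate_studies(
    seed: int,
    n_studies: int,
    true_effect: float,
    se_per_study: float,
    scale: Scale = "identity",
    ci_level: float = 0.95,
) -> SimulatedStudySet:
    """Draw study estimates from the Wald model itself.

    Analysis-scale estimates are drawn from
    ``Normal(true_effect, se_per_study)``, then each is wrapped as an
    :class:`EffectEstimate` carrying the stated (true) standard error —
    the regime in which all background assumptions are correct, so
    P-values at the true effect are uniform and level-L intervals cover
    at rate L.  One explicit seed per set; no global state.
    """
    if n_studies < 1:
        raise ValueError("n_studies must be >= 1")
    if se_per_study <= 0:
        raise ValueError("se_per_study must be positive")
    rng = np.random.default_rng(seed)
    draws = rng.normal(true_effect, se_per_study, size=n_studies)
    _, Tinv = (np.log, np.exp) if scale == "log" else (None, lambda x: x)
    estimates = tuple(
        EffectEstimate(
            point=float(Tinv(d)),
            ci_level=ci_level,
            scale=scale,
            std_error=se_per_study,
            label=f"simulated study {i}",
        )
        for i, d in enumerate(draws)
    )
    return SimulatedStudySet(
        seed=seed,
        n_studies=n_studies,
        true_effect=true_effect,
        se_per_study=se_per_study,
        scale=scale,
        estimates=estimates,
    )


def read_pvalues_csv(path) -> StudyEvidence:
    """Read per-study P-values from CSV with columns ``study_label, p``."""
    df = pd.read_csv(path)
    if "p" not in df.columns:
        raise ValueError("input CSV needs a 'p' column")
    labels = (
        tuple(str(x) for x in df["study_label"]) if "study_label" in df.columns else None
    )
    return StudyEvidence(p_values=tuple(float(p) for p in df["p"]), labels=labels)
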