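# Methods

## The model

All quantities derive from a single approximation: the reported
estimator, transformed to its analysis scale, is treated as normally
distributed about the true parameter with known standard error (the
Wald model). For ratio measures (hazard, odds, risk ratios) the
analysis scale is the natural log; for differences it is the identity.
The scale is a mandatory input — `surpval` never guesses it from the
numbers, because a silently wrong guess corrupts every downstream
quantity.

Given a point estimate θ̂ with interval limits (L, U) at level 1 − α,
the analysis-scale standard error is back-calculated as

    SE = (T(U) − T(L)) / (2 q),   q = Φ⁻¹(1 − α/2),

using the exact normal quantile rather than the rounded 1.96. For any
hypothesized value θ the Wald statistic is z = (T(θ) − T(θ̂))/SE and the
two-sided P-value is p = 2(1 − Φ(|z|)), capped at 1. From p follow

- the S-value s = −log₂ p (bits) or −ln p (nats),
- the maximum-likelihood ratio MLR = exp(z²/2) (the ratio of the
  normal likelihood at its maximum to the likelihood at θ), and
- the deviance statistic 2 ln MLR = z².

MLR and deviance are defined only for simple one-parameter hypotheses
under the two-sided inversion z = Φ⁻¹(1 − p/2); quoted one-sided tail
probabilities (sigma cutoffs, genome-wide thresholds) are deliberately
treated as two-sided P-values and re-inverted under that single
convention, matching how such translation tables are conventionally
printed. Panels are always built from two-sided P-values; the
machinery refuses to attach MLR/deviance to one-sided inputs rather
than emit a wrong convention.

## Numerical choices

- **Log-space tails.** P-values are computed from the log of the normal
  survival function, so a hypothesis 50 standard errors from the
  estimate still yields a finite S-value. Where the final
  exponentiation would underflow double precision entirely, the
  P-value is clamped to the smallest positive subnormal instead of
  returning an impossible exact zero; the S-value is always computed
  from the log tail directly and never passes through the underflow.
- **Closed-form intervals.** A level-Λ compatibility interval has
  endpoints T⁻¹(T(θ̂) ± q·SE), q = Φ⁻¹((1+Λ)/2); a likelihood interval
  at cutoff c has endpoints T⁻¹(T(θ̂) ± SE·√(−2 ln c)). Curves are for
  display; intervals come from the formula, so there are no
  grid-resolution artifacts and the endpoints satisfy p = 1 − Λ to
  machine precision.
- **Consistency guard.** If both interval limits and a standard error
  are supplied and disagree by more than 1% relative, construction
  fails loudly rather than silently preferring one source.
- **Display rounding.** S-values above −log₂(0.001) ≈ 10 bits are
  displayed to the nearest whole bit, because normal-approximation
  P-values below 0.001 rarely carry more than two accurate digits.
  Stored values keep full precision; the policy is display-only.
- **Rounded published inputs.** A published estimate like (1.61,
  0.997, 2.59) is itself rounded to three significant figures, and the
  printed limits need not be exactly log-symmetric about the printed
  point. Reconstructed Wald endpoints therefore agree with printed
  limits only to within the input rounding (about ±0.5% relative, from
  a half-unit in the third significant figure of the point estimate);
  the test suite compares interval endpoints at that tolerance and all
  printed-table values at half a unit in the last printed digit
  (capped at three significant figures).

## Combination and validity

S-values for the *same* hypothesis from K independent studies add.
Under the hypothesis and background assumptions each natural-log
S-value −ln p is a unit exponential, so the sum has expectation K and
twice the sum is χ² with 2K degrees of freedom — Fisher's method,
expressed in surprisal units. The implementation converts bit-valued
inputs to nats rather than mixing units, reproduces the single-study
P-value exactly at K = 1, and is one-directional by construction (small
P-values combine toward evidence; no two-sided variant is offered).
All K inputs must share one sidedness convention; the API documents
this requirement rather than adding an unenforceable flag, since
nothing in the numbers reveals which convention produced them.
P-values that are not valid in the uniformity sense (e.g. posterior
predictive P-values) violate the method's premises and are likewise
undetectable from the values alone; they are excluded by
documentation, not by code.

`check_uniformity` applies the Kolmogorov–Smirnov test against
uniform(0,1): the operational validity criterion for a P-value is that
it is uniform when the test hypothesis and all background assumptions
hold. Sub-uniformity near zero when testing a *wrong* hypothesis is
power, not invalidity, and the simulation examples show both regimes.

## What the simulator emulates

`simulate_studies` draws analysis-scale estimates directly from the
Wald model — Normal(true effect, SE) with the SE known and stated — and
wraps each draw as an estimate object. This is exactly the regime in
which the textbook guarantees hold: P-values at the true effect are
uniform, level-Λ intervals cover at rate Λ, and the χ²(2K) combination
holds its α level. Passing tests under this generator therefore verify
the *internal* correctness of the machinery, not the adequacy of the
Wald approximation for any real study: real summary statistics carry
estimated (not known) standard errors, finite-sample skewness,
model-selection effects and publication filtering, none of which the
generator reproduces. The same caveat applies to real data: Wald
approximations deteriorate in the far tails, which is one motivation
for the whole-bit display rounding above 10 bits.

## Defaults

| Parameter | Default | Why |
| --- | --- | --- |
| interval levels | 75, 95, 99% | proportionally spaced compatibility levels p > 0.25, 0.05, 0.01 |
| curve span | 99.9% interval | covers every visually distinguishable p at plot resolution |
| curve points | 400 | smooth at publication resolution; configurable |
| S-value unit | bits | coin-toss calibration; nats used internally for combination |
| demo hypotheses | HR 0.5, 1, 1.61, 2, 3, 5 | halving to quintupling around the worked example |
| simulation sizes | 10⁵ null study-sets, 10⁴ estimates | Monte-Carlo SE ≲ 0.07% on a 5% rate, so 3-SE checks are sharp |

## Known limitations

- Wald-only: no profile-likelihood, bootstrap or exact small-sample
  curves; asymmetric published intervals are forced through the
  symmetric-on-analysis-scale approximation.
- Single-parameter hypotheses only: no multi-degree-of-freedom fit
  statistics, composite hypotheses, or MLRs for them.
- Combination is evidence-pooling for one shared hypothesis, not
  meta-analytic effect pooling: no fixed/random-effects weighting.
- The uniformity check needs the per-study P-values themselves; it
  cannot audit a published table of verdicts.
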