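# surpval

Compatibility and surprisal statistics for *reported* effect estimates.

Epidemiological and clinical papers typically report a point estimate
with a confidence interval — say a hazard ratio of 1.61 with 95% limits
0.997 and 2.59 — and then collapse all of that information into a
significant/non-significant verdict about the null. `surpval` is for
readers, reviewers and meta-analysts who want the rest of the
information back, without access to the raw data. From nothing but the
printed summary it computes, for **any** test hypothesis (null or
otherwise):

- the two-sided Wald **P-value** *p*, read as a *compatibility* measure
  between the hypothesis and the data under the background model;
- the **S-value** (surprisal) *s* = −log₂ *p*, the information against
  the hypothesis in bits — calibrated as the number of consecutive heads
  in fair coin tosses that would be equally surprising;
- the **maximum-likelihood ratio** MLR = exp(z²/2) against the
  hypothesis, and the **deviance** (likelihood-ratio) statistic
  2 ln MLR = z²;
- **compatibility intervals** at any level (the set of values with
  *p* > 1 − level) and their **likelihood-interval** duals;
- whole **compatibility, surprisal, likelihood and deviance functions**
  over a grid of hypotheses, as tables and plots;
- Fisher-type **combination of evidence** across K independent studies
  (natural-log S-values summed, doubled, referred to χ² with 2K df) and
  simulation checks of **P-value validity** (uniformity under the test
  model).

Everything rests on the Wald normal approximation on the analysis scale:
natural log for ratio measures (HR, OR, RR), identity for differences.
The standard error is back-calculated from the interval limits as
SE = (ln U − ln L) / (2 Φ⁻¹(0.975)) for a 95% ratio interval, so
z(θ) = (ln θ − ln θ̂)/SE and *p*(θ) = 2(1 − Φ(|z|)).

## Worked example

```sh
python examples/reanalysis_panel.py
```

```
Estimate: Brown et al. HDPS hazard ratio
Analysis-scale SE (log HR): 0.2435

hypothesis             value  P         S (bits)  MLR       deviance
---------------------  -----  --------  --------  --------  --------
Halving of hazard      0.5    1.57e-06  19        1.01e+05  23.06
No association (null)  1      0.0505    4.31      6.77      3.82
Point estimate         1.61   1         0.00      1         0.00
Doubling of hazard     2      0.373     1.42      1.49      0.79
Tripling of hazard     3      0.0106    6.56      26.2      6.53
Quintupling of hazard  5      3.27e-06  18        5.03e+04  21.65
```

The null hypothesis has *p* = 0.0505 — a hair over the conventional
cutoff, which is how the original authors came to declare "no
association". The S-value shows what that *p* actually carries: 4.31
bits, scarcely more surprising than four heads in a row. A *doubling*
of the hazard, meanwhile, has only 1.42 bits against it — so the data
are *more* compatible with a doubled hazard than with no association,
and the dichotomous reading had it backwards. (S-values above 10 bits
are displayed rounded to whole bits, since normal-approximation
P-values below 0.001 rarely carry more than two accurate digits.)

The same estimate from Python:

```python
from surpval import BROWN_HDPS, test_panel, interval_at_level

row = test_panel(BROWN_HDPS, [1.0])[0]
print(row.p, row.s_bits)        # 0.05053 4.307
print(tuple(interval_at_level(BROWN_HDPS, 0.95)))  # (0.9989, 2.5949)
```

Other example scripts: `examples/intervals.py` (75/95/99% compatibility
intervals, likelihood-interval duality, the range of values more
compatible than the null), `examples/compatibility_curves.py` (the four
evidential functions as plots + CSV) and
`examples/combine_and_validity.py` (multi-study combination and the
uniformity check).

## Command line

Every capability is also a subcommand; `--demo` substitutes the built-in
worked example so no input file is needed:

```sh
surpval panel --demo
surpval interval --demo --levels 0.75,0.95,0.99
surpval curves --demo --out plots/
surpval combine studies.csv        # columns: study_label,p
surpval validity --seed 1 --n-studies 10000
```

Estimate CSVs have columns `label,point,lower,upper,level,scale,se`
(limits or `se` may be omitted, not both).

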