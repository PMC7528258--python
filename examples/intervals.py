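"""Multi-level compatibility intervals and their likelihood-interval duals.

Prints the 75/95/99% compatibility intervals for the worked-example
hazard ratio, the 1/6.83 likelihood interval (which coincides with the
95% compatibility interval under the Wald model), and the range of
hazard ratios more compatible with the data than the null.
"""

from surpval import (
    BROWN_HDPS,
    interval_at_level,
    likelihood_interval,
    mlr_from_p,
    p_value,
    values_more_compatible_than,
)

est = BROWN_HDPS
print(f"Estimate: {est.label}\n")

for level in (0.75, 0.95, 0.99):
    ival = interval_at_level(est, level)
    print(
        f"{100 * level:g}% compatibility interval (p > {1 - level:g}): "
        f"({ival.lower:.3f}, {ival.upper:.3f});  "
        f"p at endpoints = {p_value(est, ival.lower):.3f}"
    )

cutoff = 1 / mlr_from_p(0.05)
li = likelihood_interval(est, cutoff)
print(
    f"\n1/{1 / cutoff:.2f} likelihood interval: ({li.lower:.3f}, {li.upper:.3f})"
    " — same as the 95% compatibility interval, as the Wald model implies."
)

more = values_more_compatible_than(est, 1.0)
print(
    f"\nHazard ratios more compatible with the data than the null: "
    f"({more.lower:g}, {more.upper:.3f}) — every value from 1 up to about "
    f"{more.upper:.2f} has a larger P-value than HR = 1."
)
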