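"""The four evidential functions over a grid of hazard ratios.

Builds the compatibility (P-value), surprisal (S-value),
relative-likelihood and deviance curves for the worked-example estimate
and writes them as PNGs plus a CSV of the grid values.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from surpval import BROWN_HDPS, build_curve, curve_to_frame, plot_curve

out = Path("scratch/curves")
out.mkdir(parents=True, exist_ok=True)

curve = build_curve(BROWN_HDPS, span_level=0.999, n_points=400)
df = curve_to_frame(curve)
df.to_csv(out / "brown_curve.csv", index=False)

for kind in ("p", "s", "likelihood", "deviance"):
    ax = plot_curve(curve, kind=kind)
    ax.figure.savefig(out / f"brown_{kind}.png", dpi=150, bbox_inches="tight")
    plt.close(ax.figure)

peak = df.loc[df["p"].idxmax()]
print(f"Curve written to {out}/ ({len(df)} grid points).")
print(f"P-value peaks at HR = {peak['hypothesis']:.3f} with p = {peak['p']:.3f};")
print(f"the S-curve bottoms out there at {peak['s_bits']:.3f} bits.")
print(
    "The P-curve shows compatibility of every hazard ratio with the data;\n"
    "reading across at p = 0.05 gives the 95% compatibility interval."
)
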