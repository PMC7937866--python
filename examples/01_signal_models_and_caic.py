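"""Evaluate the three diffusion models and the cAIC's scaling behaviour.

Prints the attenuation of the Gaussian, Kurtosis and Gamma models at a few
b-values for typical gray-matter parameters, the b-value bounds inside
which the non-Gaussian models are valid, and how rescaling the data shifts
cAIC values without changing which model wins.
"""

import numpy as np

import ivimmap as im
from ivimmap import CaicInput, ModelId, caic

d, k = 1.05e-3, 1.0  # gray-matter-like diffusivity (mm^2/s) and kurtosis

print("E(b) for D = 1.05e-3 mm^2/s, K = 1.0")
print(f"{'b':>6} {'Gaussian':>10} {'Kurtosis':>10} {'Gamma':>10}")
for b in (0, 600, 1000, 2500):
    row = [im.attenuation(m, b, d, k) for m in ModelId]
    print(f"{b:>6} {row[0]:>10.4f} {row[1]:>10.4f} {row[2]:>10.4f}")
print("-> below b ~ 600 s/mm^2 the Kurtosis and Gamma curves differ by <1%,")
print("   so only the high-b tail can separate them.\n")

kb, gb = im.validity_bounds(d, k)
print(f"validity bounds for D*K = {d * k:.2e} mm^2/s:")
print(f"  Kurtosis expansion monotone up to b = {kb:,.0f} s/mm^2")
print(f"  Kurtosis ~ Gamma far below  b = {gb:,.0f} s/mm^2\n")

# cAIC: only differences matter; rescaling the data shifts every score by
# 2 n ln(alpha) and leaves the ranking (and all fitted parameters) alone
n, alpha = 10, 1e-3
shift = caic(CaicInput(n, 3, alpha**2)) - caic(CaicInput(n, 3, 1.0))
print(f"rescaling by {alpha} shifts every cAIC by 2n ln(alpha) = {shift:.1f}")
triple = {"Gaussian": 150.7, "Kurtosis": 138.8, "Gamma": 134.6}
shifted = {m: v + shift for m, v in triple.items()}
print("example scores", triple, "->",
      {m: round(v, 1) for m, v in shifted.items()})
print("-> the Gamma model has the lowest score either way.")
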