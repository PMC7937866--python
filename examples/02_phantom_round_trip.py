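"""Noiseless phantom round trip: generate, fit, verify, summarise.

Builds a small three-region digital phantom (CSF core, gray-matter shell,
white-matter shell), fits every voxel with optimal-model selection and
shows that the selected-model map reproduces the generating models exactly
and that the regional perfusion/diffusion means match the ground truth.
"""

import numpy as np

import ivimmap as im

spec = im.default_spec(shape=(8, 8, 2), sigma=0.0, n_repeats=1, seed=0)
phantom = im.generate_phantom(spec)
print("ground truth per region:")
print(im.phantom_truth_tables(spec).to_string(index=False), "\n")

maps = im.fit_volume(phantom.volumes[0], phantom.scheme,
                     mask=phantom.labels > 0, mode="optimal")

exact = np.array_equal(maps.model, phantom.truth["model"])
print(f"selected-model map identical to the generating models: {exact}")
for label, name in ((1, "CSF"), (2, "WM"), (3, "GM")):
    terr = im.model_territory(maps.model, phantom.labels == label)
    best = max(terr, key=terr.get)
    print(f"  {name}: {best.name.lower()} model in {terr[best]:.0f}% of voxels")

masks = {"GM": phantom.labels == 3, "WM": phantom.labels == 2}
masks = im.apply_exclusions(masks, maps)
summary = im.regional_summary(masks, maps)
print("\nregional means (fp in %, D* and MD in mm^2/s):")
print(summary.table[["region", "parameter", "mean", "sd", "n"]]
      .to_string(index=False))
print(f"\nGM/WM perfusion-fraction ratio: {summary.ratios['fp_gm_wm']:.2f}")
print("-> at zero noise the fitted maps reproduce the generative truth; the")
print("   fp ratio equals the ratio of the region truths (6.6% / 5.4%).")
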