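"""Effect of averaging (SNR) on optimal-model selection stability.

Generates a Rician-noisy phantom with six repeated acquisitions, fits the
data averaged over 1, 3 and 6 repeats (NA1/NA3/NA6), and reports how much
of the optimal-model map switches relative to the NA6 map — model
selection stabilises as SNR grows.
"""

import ivimmap as im

spec = im.default_spec(shape=(16, 16, 1), sigma=10.0, n_repeats=6, seed=1)
phantom = im.generate_phantom(spec)
mask = phantom.labels > 0

b0_index = phantom.scheme.b0_frame_indices()[0]
maps = {}
for n_avg in (1, 3, 6):
    volume = im.average_repeats(phantom.volumes, n_avg)
    noise = im.estimate_ncf(volume[..., b0_index], mask=phantom.labels == 0)
    maps[n_avg] = im.fit_volume(volume, phantom.scheme, mask=mask,
                                noise=noise, mode="optimal")
    print(f"NA{n_avg}: noise floor estimate sqrt(NCF) = "
          f"{noise.mode_estimate:.1f} signal units")

for n_avg in (1, 3):
    change = im.territory_change(maps[n_avg].model, maps[6].model, mask)
    print(f"model switch NA{n_avg} -> NA6: {change:.1f}% of voxels")
print("-> averaging more repeats lowers the noise floor and the model map")
print("   converges; residual switching sits on the Kurtosis/Gamma border,")
print("   where the two models are nearly indistinguishable.")
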