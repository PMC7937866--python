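"""Shared fixtures: reference tissue parameters and pre-fitted phantoms.

The expensive whole-volume fits are session-scoped so that mapping,
regional and acceptance tests share one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

import ivimmap as im
from ivimmap.phantom import PhantomSpec, RegionParams, nested_slab_labels

# In-vivo-plausible tissue truths used throughout the suite (these are the
# phantom generator defaults; restated here so tests are explicit).
GM = RegionParams("GM", im.ModelId.GAMMA, se0=1000.0, d=1.05e-3, k=1.0,
                  fp=0.066, dstar=6.4e-3)
WM = RegionParams("WM", im.ModelId.KURTOSIS, se0=900.0, d=0.79e-3, k=0.82,
                  fp=0.054, dstar=5.2e-3)
CSF = RegionParams("CSF", im.ModelId.GAUSSIAN, se0=2000.0, d=2.9e-3, k=0.0,
                   fp=0.0)


def clean_signal(region: RegionParams, b: np.ndarray) -> np.ndarray:
    """Noise-free two-compartment signal of a region on a b-grid."""
    e = im.attenuation(region.model, b, region.d, region.k)
    return region.se0 * e + region.sv0 * np.exp(-b * region.dstar)


def voxel_series(
    region: RegionParams,
    scheme: im.AcquisitionScheme,
    sigma: float = 0.0,
    n_avg: int = 1,
    rng: np.random.Generator | None = None,
) -> list[im.DirectionSeries]:
    """Six direction series of one voxel, optionally Rician-noisy/averaged."""
    b = scheme.b_values
    sig = clean_signal(region, b)
    out = []
    for i in range(scheme.n_directions):
        if sigma == 0:
            s = sig.copy()
        else:
            reps = [
                np.hypot(sig + rng.normal(0, sigma, sig.shape),
                         rng.normal(0, sigma, sig.shape))
                for _ in range(n_avg)
            ]
            s = np.mean(reps, axis=0)
        out.append(im.DirectionSeries(i, b, s))
    return out


@pytest.fixture(scope="session")
def scheme() -> im.AcquisitionScheme:
    return im.AcquisitionScheme()


@pytest.fixture(scope="session")
def noiseless_phantom():
    spec = im.default_spec(shape=(10, 10, 3), sigma=0.0, n_repeats=1, seed=0)
    return im.generate_phantom(spec)


@pytest.fixture(scope="session")
def noiseless_maps(noiseless_phantom):
    ph = noiseless_phantom
    return im.fit_volume(ph.volumes[0], ph.scheme, mask=ph.labels > 0,
                         mode="optimal")


@pytest.fixture(scope="session")
def noisy_na6_phantom():
    """Rician phantom at b0-SNR ~100 averaged over 6 repeats, fitted."""
    spec = im.default_spec(shape=(16, 16, 4), sigma=10.0, n_repeats=6, seed=42)
    ph = im.generate_phantom(spec)
    vol = im.average_repeats(ph.volumes, 6)
    b0 = vol[..., ph.scheme.b0_frame_indices()[0]]
    noise = im.estimate_ncf(b0, mask=ph.labels == 0)
    maps = im.fit_volume(vol, ph.scheme, mask=ph.labels > 0, noise=noise,
                         mode="optimal")
    return ph, maps


@pytest.fixture(scope="session")
def gamma_row_phantom():
    """Noiseless two-tissue phantom with both regions generated by the
    Gamma model at the Gamma-row regional truths (GM fp 6.6%, WM fp 3.4%)."""
    wm_gamma = RegionParams("WM", im.ModelId.GAMMA, se0=900.0, d=0.89e-3,
                            k=1.55, fp=0.034, dstar=4.1e-3)
    labels = nested_slab_labels((10, 10, 2))
    labels[labels == 1] = 3  # merge the core into GM: two-tissue phantom
    spec = PhantomSpec(shape=(10, 10, 2), regions={2: wm_gamma, 3: GM},
                       sigma=0.0, n_repeats=1, seed=0)
    ph = im.generate_phantom(spec, labels=labels)
    maps = im.fit_volume(ph.volumes[0], ph.scheme, mask=ph.labels > 0,
                         mode="optimal")
    return ph, maps
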