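"""Rician noise-floor estimation and magnitude-signal correction.

Magnitude MRI signals are Rician distributed: at low SNR the measured
magnitude is biased upward so that approximately

    S_measured^2 = S_true^2 + NCF

where the noise correction factor NCF equals the squared noise floor. NCF is
estimated from the mode of the signal histogram of the b = 0 image — in
background (zero true signal) the magnitude is Rayleigh distributed with
mode equal to the per-channel noise sigma, so the histogram mode of an image
dominated by background sits at the noise floor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["NoiseModel", "estimate_ncf", "correct_signal"]


@dataclass(frozen=True)
class NoiseModel:
    """Estimated Rician noise floor.

    Attributes
    ----------
    ncf : float
        Noise correction factor, the squared histogram mode (signal units^2).
    mode_estimate : float
        Histogram mode of the b0 image (signal units).
    bin_width : float
        Histogram bin width used (signal units); 0 for a degenerate
        (constant) image or an externally supplied NCF.
    """

    ncf: float
    mode_estimate: float
    bin_width: float = 0.0

    def __post_init__(self) -> None:
        if self.ncf < 0:
            raise ValueError(f"ncf must be >= 0, got {self.ncf}")

    @classmethod
    def none(cls) -> "NoiseModel":
        """A no-op noise model (NCF = 0); correction becomes the identity."""
        return cls(ncf=0.0, mode_estimate=0.0, bin_width=0.0)


def estimate_ncf(b0_volume: np.ndarray, mask: np.ndarray | None = None) -> NoiseModel:
    """Estimate the NCF as the squared mode of the b0 signal histogram.

    By default the histogram is taken over the whole field of view excluding
    exact zeros (background noise dominates there); pass ``mask`` to
    restrict it. Bins use the Freedman-Diaconis rule.

    Parameters
    ----------
    b0_volume : ndarray
        The non-diffusion-weighted (b = 0) image, any shape.
    mask : ndarray of bool, optional
        Voxels to include. Must select at least one voxel.

    Returns
    -------
    NoiseModel
    """
    vol = np.asarray(b0_volume, dtype=float)
    if vol.size == 0:
        raise ValueError("b0 volume is empty")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != vol.shape:
            raise ValueError("mask shape does not match the b0 volume")
        if not mask.any():
            raise ValueError("mask selects no voxels")
        values = vol[mask]
    else:
        values = vol.ravel()
    values = values[np.isfinite(values) & (values != 0)]
    if values.size < 100:
        raise ValueError(
            f"need at least 100 finite nonzero voxels to estimate the noise floor, "
            f"got {values.size}"
        )
    if values.min() == values.max():
        warnings.warn(
            "constant b0 image: noise-floor estimate is degenerate", stacklevel=2
        )
        mode = float(values[0])
        return NoiseModel(ncf=mode * mode, mode_estimate=mode, bin_width=0.0)

    q75, q25 = np.percentile(values, [75, 25])
    iqr = q75 - q25
    if iqr > 0:
        width = 2.0 * iqr / values.size ** (1.0 / 3.0)
        n_bins = max(int(np.ceil((values.max() - values.min()) / width)), 1)
    else:
        n_bins = int(np.ceil(np.sqrt(values.size)))
    counts, edges = np.histogram(values, bins=n_bins)
    # the raw argmax jitters when the density is flat near its peak, so
    # smooth the counts with a short moving average before locating it
    half = max(n_bins // 25, 1)
    kernel = np.ones(2 * half + 1)
    smooth = np.convolve(counts, kernel / kernel.size, mode="same")
    i = int(np.argmax(smooth))
    # refine the bin-centre mode to the median of the peak window, which is
    # exact for effectively discrete data and robust for Rayleigh noise
    lo = edges[max(i - half, 0)]
    hi = edges[min(i + half + 1, n_bins)]
    in_bin = values[(values >= lo) & (values <= hi)]
    mode = float(np.median(in_bin)) if in_bin.size else 0.5 * (lo + hi)
    return NoiseModel(
        ncf=mode * mode, mode_estimate=mode, bin_width=float(edges[1] - edges[0])
    )


def correct_signal(measured, ncf: float):
    """Remove the Rician noise floor: sqrt(max(S^2 - NCF, 0)).

    Monotone non-decreasing in the measured signal and the identity when
    NCF = 0. Values whose square falls below the NCF are floored at 0.
    """
    if ncf < 0:
        raise ValueError(f"ncf must be >= 0, got {ncf}")
    measured = np.asarray(measured, dtype=float)
    if np.any(measured < 0):
        raise ValueError("measured magnitudes must be >= 0")
    out = np.sqrt(np.maximum(measured * measured - ncf, 0.0))
    return out if out.ndim else float(out)
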