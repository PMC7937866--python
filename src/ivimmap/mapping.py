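"""Whole-volume fitting and parameter-map assembly.

Applies the per-voxel two-step fit across a masked 4D series and reduces
the voxel records into volumetric maps: perfusion fraction (stored in
percent), pseudo-diffusion coefficient D*, mean diffusivity MD, apparent
mean kurtosis, the integer-coded optimal-model map and a diagnostic flag
bitmask. Also provides repeat averaging (NA1-NA6 emulation) and model
territory statistics.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .fitting import DirectionSeries, FitConfig, FitFlags, fit_voxel
from .models import ModelId
from .noise import NoiseModel, correct_signal
from .scheme import AcquisitionScheme

__all__ = [
    "ParameterMaps",
    "fit_volume",
    "average_repeats",
    "model_territory",
    "territory_change",
]

logger = logging.getLogger(__name__)


@dataclass
class ParameterMaps:
    """Volumetric outputs of one fitting run.

    All maps share the input grid shape. ``fp`` is in percent (reporting
    convention); ``dstar`` and ``md`` in mm^2/s; ``model`` holds the
    integer model codes (0 background/unfit, 1 Gaussian, 2 Kurtosis,
    3 Gamma); ``flags`` is the FitFlags bitmask. Background voxels are NaN
    in the float maps and 0 in the integer maps.
    """

    fp: np.ndarray
    dstar: np.ndarray
    md: np.ndarray
    kapp: np.ndarray
    model: np.ndarray
    flags: np.ndarray
    mode: str = "optimal"
    meta: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.model.shape


def average_repeats(volumes: list[np.ndarray], n_avg: int) -> np.ndarray:
    """Voxelwise arithmetic mean of the first ``n_avg`` repeats (NA).

    Averaging N magnitude acquisitions shrinks the noise standard
    deviation by ~1/sqrt(N), emulating the NA1-NA6 SNR ladder.
    """
    if not 1 <= n_avg <= len(volumes):
        raise ValueError(f"n_avg must be in [1, {len(volumes)}], got {n_avg}")
    first = np.asarray(volumes[0])
    for v in volumes[1:n_avg]:
        if np.asarray(v).shape != first.shape:
            raise ValueError("repeat shapes differ")
    if n_avg == 1:
        return first.copy()
    return np.mean([np.asarray(v) for v in volumes[:n_avg]], axis=0)


def fit_volume(
    volume4d: np.ndarray,
    scheme: AcquisitionScheme,
    mask: np.ndarray | None = None,
    noise: NoiseModel | None = None,
    mode: str = "optimal",
    config: FitConfig | None = None,
) -> ParameterMaps:
    """Fit every masked voxel of a 4D IVIM series and assemble maps.

    Parameters
    ----------
    volume4d : ndarray, shape (*grid, n_frames)
        Magnitude series; the frame axis must follow ``scheme``'s layout.
    scheme : AcquisitionScheme
    mask : ndarray of bool, optional
        Voxels to fit; default: voxels with positive mean b0 signal.
    noise : NoiseModel, optional
        Rician noise floor; applied to all frames before fitting.
        Default: no correction.
    mode : str
        ``"optimal"`` or a forced model name (``"gaussian"`` etc.).
    config : FitConfig, optional
        Overrides ``mode`` if provided with its own mode.

    Notes
    -----
    Per-voxel failures are recorded in the flag map, never raised; the
    result is deterministic and independent of voxel traversal order.
    """
    volume4d = np.asarray(volume4d, dtype=float)
    if volume4d.ndim != 4:
        raise ValueError("expected a 4D volume (x, y, z, frames)")
    if volume4d.shape[-1] != scheme.n_frames:
        raise ValueError(
            f"volume has {volume4d.shape[-1]} frames but the scheme defines "
            f"{scheme.n_frames}"
        )
    grid = volume4d.shape[:3]
    b0_idx = scheme.b0_frame_indices()
    if mask is None:
        mask = volume4d[..., b0_idx].mean(axis=-1) > 0
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != grid:
            raise ValueError("mask shape does not match the volume grid")

    cfg = config or FitConfig(mode=mode)
    noise = noise or NoiseModel.none()

    nan = np.full(grid, np.nan)
    maps = ParameterMaps(
        fp=nan.copy(), dstar=nan.copy(), md=nan.copy(), kapp=nan.copy(),
        model=np.zeros(grid, dtype=np.int16),
        flags=np.zeros(grid, dtype=np.int32),
        mode=cfg.mode,
    )
    n_total = int(mask.sum())
    if n_total == 0:
        warnings.warn("empty mask: nothing to fit", stacklevel=2)
        return maps

    dir_slices = [scheme.direction_slice(i) for i in range(scheme.n_directions)]
    done = 0
    for idx in zip(*np.nonzero(mask)):
        signals = correct_signal(volume4d[idx], noise.ncf)
        series = [
            DirectionSeries(i, scheme.b_values, signals[sl])
            for i, sl in enumerate(dir_slices)
        ]
        try:
            rec = fit_voxel(series, cfg)
        except Exception:  # defensive: contract says never abort the run
            logger.exception("voxel %s failed", idx)
            maps.flags[idx] = int(FitFlags.UNFIT)
            continue
        maps.flags[idx] = int(rec.flags)
        if rec.selected_model is None:
            continue
        maps.model[idx] = int(rec.selected_model)
        maps.md[idx] = rec.md
        maps.kapp[idx] = rec.kapp_mean
        maps.fp[idx] = 100.0 * rec.fp
        maps.dstar[idx] = rec.dstar
        done += 1
        if done % 500 == 0:
            logger.info("fitted %d / %d voxels", done, n_total)
    logger.info("fitted %d / %d voxels", done, n_total)
    return maps


def model_territory(
    model_map: np.ndarray, region_mask: np.ndarray
) -> dict[ModelId, float]:
    """Percentage of region voxels assigned to each model.

    Percentages are over fitted voxels in the region and sum to 100 (up to
    voxels with code 0, which are excluded as unfitted).
    """
    model_map = np.asarray(model_map)
    region_mask = np.asarray(region_mask, dtype=bool)
    if model_map.shape != region_mask.shape:
        raise ValueError("model map and region mask shapes differ")
    values = model_map[region_mask]
    values = values[values > 0]
    if values.size == 0:
        raise ValueError("region contains no fitted voxels")
    return {m: 100.0 * float((values == int(m)).sum()) / values.size for m in ModelId}


def territory_change(
    model_map_a: np.ndarray, model_map_b: np.ndarray, mask: np.ndarray | None = None
) -> float:
    """Percentage of masked voxels whose selected model differs."""
    a = np.asarray(model_map_a)
    b = np.asarray(model_map_b)
    if a.shape != b.shape:
        raise ValueError("model map shapes differ")
    if mask is None:
        mask = np.ones(a.shape, dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != a.shape:
            raise ValueError("mask shape differs from the model maps")
    n = int(mask.sum())
    if n == 0:
        raise ValueError("empty mask")
    return 100.0 * float((a[mask] != b[mask]).sum()) / n
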