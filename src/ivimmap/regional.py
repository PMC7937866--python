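"""Region-of-interest construction and regional parameter summaries.

Tissue regions (GM/WM/CSF) are built from co-registered tissue probability
maps by keeping only voxels whose tissue proportion exceeds a strict
threshold (default > 0.95), which suppresses partial-volume and
registration errors. Two physiological exclusion rules then filter
implausible fits: in tissue (GM/WM) voxels where MD > D* the perfusion
estimate is meaningless and the voxel is dropped; in CSF, voxels with
apparent kurtosis above 0.1 indicate tissue contamination and are dropped.
Summaries report per-region means and SDs plus the GM/WM ratios of fp and
D*, the headline sanity checks against classical perfusion values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mapping import ParameterMaps

__all__ = [
    "RegionDefinition",
    "RegionalSummary",
    "build_region_masks",
    "apply_exclusions",
    "regional_summary",
]

#: CSF apparent-kurtosis exclusion threshold.
CSF_KAPP_MAX = 0.1

#: Names treated as parenchymal tissue (MD > D* exclusion applies).
TISSUE_REGIONS = frozenset({"GM", "WM"})


@dataclass(frozen=True)
class RegionDefinition:
    """A named tissue region with its inclusion threshold."""

    name: str
    threshold: float = 0.95

    def __post_init__(self) -> None:
        if not 0.5 < self.threshold <= 1.0:
            raise ValueError(f"threshold must be in (0.5, 1], got {self.threshold}")


@dataclass
class RegionalSummary:
    """Per-region parameter means/SDs and GM/WM ratios."""

    table: pd.DataFrame
    ratios: dict[str, float] = field(default_factory=dict)
    counts: pd.DataFrame | None = None


def build_region_masks(
    probability_maps: dict[str, np.ndarray], threshold: float = 0.95
) -> dict[str, np.ndarray]:
    """Threshold tissue probability maps into boolean region masks.

    A voxel joins region T iff P_T > threshold (strictly). One-hot label
    probabilities therefore reproduce the label map exactly.
    """
    masks = {}
    for name, prob in probability_maps.items():
        prob = np.asarray(prob, dtype=float)
        if np.any(prob < 0) or np.any(prob > 1):
            raise ValueError(f"probabilities of {name!r} outside [0, 1]")
        RegionDefinition(name, threshold)  # validates the threshold
        masks[name] = prob > threshold
    return masks


def apply_exclusions(
    masks: dict[str, np.ndarray],
    maps: ParameterMaps,
    csf_kapp_max: float = CSF_KAPP_MAX,
) -> dict[str, np.ndarray]:
    """Drop physiologically implausible voxels from the region masks.

    GM/WM: exclude voxels with MD > D* (perfusion slower than diffusion is
    not interpretable). CSF: exclude voxels with apparent kurtosis above
    ``csf_kapp_max`` (tissue contamination). Other region names pass
    through unchanged.
    """
    out = {}
    for name, mask in masks.items():
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != maps.shape:
            raise ValueError(f"mask {name!r} shape differs from the maps")
        if name.upper() in TISSUE_REGIONS:
            with np.errstate(invalid="ignore"):
                bad = maps.md > maps.dstar
            out[name] = mask & ~np.nan_to_num(bad, nan=True)
        elif name.upper() == "CSF":
            with np.errstate(invalid="ignore"):
                bad = maps.kapp > csf_kapp_max
            out[name] = mask & ~np.nan_to_num(bad, nan=True)
        else:
            out[name] = mask.copy()
    return out


def regional_summary(
    masks: dict[str, np.ndarray],
    maps: ParameterMaps,
    subject: str | None = None,
) -> RegionalSummary:
    """Mean +/- SD of each parameter per region, with GM/WM ratios.

    Regions that are empty after exclusion are flagged with a warning and
    omitted from the table. The GM/WM ratios of fp and D* are computed from
    the reported means when both regions are present.
    """
    params = {"fp": maps.fp, "dstar": maps.dstar, "md": maps.md, "kapp": maps.kapp}
    rows = []
    counts = []
    means: dict[tuple[str, str], float] = {}
    for name, mask in masks.items():
        mask = np.asarray(mask, dtype=bool) & (maps.model > 0)
        counts.append({"region": name, "n_voxels": int(mask.sum())})
        if not mask.any():
            warnings.warn(f"region {name!r} is empty after exclusions", stacklevel=2)
            continue
        for pname, pmap in params.items():
            vals = pmap[mask]
            vals = vals[np.isfinite(vals)]
            if vals.size == 0:
                continue
            mean = float(vals.mean())
            means[(name, pname)] = mean
            rows.append({
                "subject": subject,
                "region": name,
                "parameter": pname,
                "mean": mean,
                "sd": float(vals.std(ddof=0)),
                "n": int(vals.size),
            })
    table = pd.DataFrame(
        rows, columns=["subject", "region", "parameter", "mean", "sd", "n"]
    )
    ratios = {}
    for pname in ("fp", "dstar"):
        gm = means.get(("GM", pname))
        wm = means.get(("WM", pname))
        if gm is not None and wm not in (None, 0.0):
            ratios[f"{pname}_gm_wm"] = gm / wm
    return RegionalSummary(table=table, ratios=ratios, counts=pd.DataFrame(counts))
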