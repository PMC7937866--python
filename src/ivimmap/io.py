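"""NIfTI / FSL bval-bvec I/O, run configuration and result sidecars.

The interchange format for series is a 4D NIfTI plus FSL-style ``.bval``
(one row of per-frame b-values) and ``.bvec`` (3 rows of per-frame gradient
components) files; the frame order of the image must match the column order
of the text files. Parameter maps are written one NIfTI per map together
with a JSON sidecar recording units, model codes, flag-bit meanings, the
seed and a hash of the run configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .mapping import ParameterMaps
from .phantom import PhantomData
from .scheme import AcquisitionScheme

__all__ = [
    "RunConfig",
    "read_series",
    "write_series",
    "write_maps",
    "read_maps",
    "write_phantom",
]

MODEL_CODES = {"0": "background", "1": "gaussian", "2": "kurtosis", "3": "gamma"}
FLAG_BITS = {
    "1": "unfit",
    "2": "perfusion_boundary",
    "4": "low_quality",
    "8": "validity_bound",
    "16": "no_perfusion",
}
MAP_UNITS = {
    "fp": "%",
    "dstar": "mm^2/s",
    "md": "mm^2/s",
    "kapp": "dimensionless",
    "model": "code",
    "flags": "bitmask",
}


@dataclass
class RunConfig:
    """Round-trippable configuration of a fitting run."""

    mode: str = "optimal"
    high_b_threshold: float = 600.0
    ncf: float | str = "auto"   # explicit value or "auto"/"none"
    max_nfev: int = 200
    tol: float = 1e-12
    seed: int = 0
    out_dir: str = "."
    verbosity: int = 1
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def hash(self) -> str:
        """Stable short hash distinguishing any two differing configs."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _read_bvals_bvecs(bval_path: str | Path, bvec_path: str | Path):
    bvals = np.loadtxt(bval_path, ndmin=1).ravel()
    bvecs = np.loadtxt(bvec_path, ndmin=2)
    if bvecs.shape[0] != 3:
        if bvecs.shape[1] == 3:  # column-per-axis variant
            bvecs = bvecs.T
        else:
            raise ValueError(
                f"bvec file must have 3 rows (FSL dialect), got shape {bvecs.shape}"
            )
    if bvecs.shape[1] != bvals.size:
        raise ValueError(
            f"bval count ({bvals.size}) and bvec column count "
            f"({bvecs.shape[1]}) differ"
        )
    return bvals, bvecs


def scheme_from_tables(bvals: np.ndarray, bvecs: np.ndarray) -> AcquisitionScheme:
    """Reconstruct an AcquisitionScheme from per-frame bval/bvec tables.

    Expects the direction-major layout this package writes: the b-value
    ladder repeats once per direction block.
    """
    if np.any(bvals < 0):
        raise ValueError("negative b-values")
    starts = np.concatenate([[0], np.flatnonzero(np.diff(bvals) < 0) + 1])
    n_b = (starts[1] - starts[0]) if len(starts) > 1 else len(bvals)
    if len(bvals) % n_b != 0:
        raise ValueError("frames do not divide into equal b-value blocks")
    ladder = bvals[:n_b]
    blocks = bvals.reshape(-1, n_b)
    if not np.all(blocks == ladder):
        raise ValueError("b-value blocks are not identical across directions")
    directions = []
    for i in range(blocks.shape[0]):
        block_vecs = bvecs[:, i * n_b:(i + 1) * n_b]
        weighted = block_vecs[:, ladder > 0]
        norms = np.linalg.norm(weighted, axis=0)
        if np.any(norms == 0):
            raise ValueError(f"zero gradient vector at b > 0 in block {i}")
        unit = weighted / norms
        if not np.allclose(unit, unit[:, :1], atol=1e-4):
            raise ValueError(f"direction varies within block {i}")
        directions.append(unit[:, 0])
    return AcquisitionScheme(b_values=ladder, directions=np.array(directions))


def read_series(
    image_path: str | Path, bval_path: str | Path, bvec_path: str | Path
) -> tuple[np.ndarray, np.ndarray, AcquisitionScheme]:
    """Load a 4D series with its acquisition scheme.

    Returns
    -------
    (data, affine, scheme)
        ``data`` is float64 of shape (x, y, z, n_frames).
    """
    img = nib.load(str(image_path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"expected a 4D image, got shape {data.shape}")
    bvals, bvecs = _read_bvals_bvecs(bval_path, bvec_path)
    if bvals.size != data.shape[-1]:
        raise ValueError(
            f"image has {data.shape[-1]} frames but bval lists {bvals.size}"
        )
    scheme = scheme_from_tables(bvals, bvecs)
    return data, img.affine, scheme


def write_series(
    base: str | Path,
    data: np.ndarray,
    scheme: AcquisitionScheme,
    affine: np.ndarray | None = None,
) -> dict[str, Path]:
    """Write a 4D series as ``<base>.nii.gz`` + ``<base>.bval/.bvec``."""
    base = Path(base)
    base.parent.mkdir(parents=True, exist_ok=True)
    affine = np.eye(4) if affine is None else affine
    paths = {
        "image": base.with_suffix(".nii.gz"),
        "bval": base.with_suffix(".bval"),
        "bvec": base.with_suffix(".bvec"),
    }
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine),
             str(paths["image"]))
    np.savetxt(paths["bval"], scheme.frame_b_values()[None, :], fmt="%g")
    np.savetxt(paths["bvec"], scheme.frame_directions().T, fmt="%.8f")
    return paths


def write_maps(
    maps: ParameterMaps,
    out_dir: str | Path,
    affine: np.ndarray | None = None,
    config: RunConfig | None = None,
) -> dict[str, Path]:
    """Write one NIfTI per parameter map plus a JSON sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    affine = np.eye(4) if affine is None else affine
    arrays = {
        "fp": maps.fp.astype(np.float32),
        "dstar": maps.dstar.astype(np.float32),
        "md": maps.md.astype(np.float32),
        "kapp": maps.kapp.astype(np.float32),
        "model": maps.model.astype(np.uint8),
        "flags": maps.flags.astype(np.int32),
    }
    paths = {}
    for name, arr in arrays.items():
        p = out_dir / f"{name}.nii.gz"
        nib.save(nib.Nifti1Image(arr, affine), str(p))
        paths[name] = p
    sidecar = {
        "units": MAP_UNITS,
        "model_codes": MODEL_CODES,
        "flag_bits": FLAG_BITS,
        "mode": maps.mode,
        "config_hash": config.hash() if config else None,
        "seed": config.seed if config else None,
    }
    sidecar_path = out_dir / "maps.json"
    sidecar_path.write_text(json.dumps(sidecar, indent=2))
    paths["sidecar"] = sidecar_path
    return paths


def read_maps(out_dir: str | Path) -> ParameterMaps:
    """Read back a map set written by :func:`write_maps`."""
    out_dir = Path(out_dir)
    def load(name, dtype=float):
        return np.asarray(nib.load(str(out_dir / f"{name}.nii.gz")).dataobj,
                          dtype=dtype)
    sidecar = json.loads((out_dir / "maps.json").read_text())
    return ParameterMaps(
        fp=load("fp"), dstar=load("dstar"), md=load("md"), kapp=load("kapp"),
        model=load("model", np.int16), flags=load("flags", np.int32),
        mode=sidecar.get("mode", "optimal"), meta=sidecar,
    )


def write_phantom(data: PhantomData, out_dir: str | Path) -> dict[str, Path]:
    """Write a generated phantom: repeats, labels, truth maps and sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    affine = np.eye(4)
    paths: dict[str, Path] = {}
    for i, vol in enumerate(data.volumes, start=1):
        p = write_series(out_dir / f"repeat{i:02d}", vol, data.scheme, affine)
        paths[f"repeat{i:02d}"] = p["image"]
        if i == 1:
            paths["bval"], paths["bvec"] = p["bval"], p["bvec"]
    nib.save(nib.Nifti1Image(data.labels.astype(np.uint8), affine),
             str(out_dir / "labels.nii.gz"))
    paths["labels"] = out_dir / "labels.nii.gz"
    for name, arr in data.truth.items():
        p = out_dir / f"truth_{name}.nii.gz"
        nib.save(nib.Nifti1Image(np.asarray(arr, dtype=np.float32), affine), str(p))
        paths[f"truth_{name}"] = p
    sidecar = {
        "sigma": data.spec.sigma,
        "n_repeats": data.spec.n_repeats,
        "seed": data.spec.seed,
        "shape": list(data.spec.shape),
        "regions": {
            str(label): {
                "name": reg.name,
                "model": reg.model.name.lower(),
                "se0": reg.se0,
                "d": reg.d,
                "k": reg.k,
                "fp": reg.fp,
                "dstar": reg.dstar,
            }
            for label, reg in data.spec.regions.items()
        },
    }
    sidecar_path = out_dir / "phantom.json"
    sidecar_path.write_text(json.dumps(sidecar, indent=2))
    paths["sidecar"] = sidecar_path
    return paths
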