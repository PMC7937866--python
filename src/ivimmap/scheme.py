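"""Acquisition scheme: b-values and motion-probing-gradient directions.

The scheme is the single source of truth for the layout of the 4th
dimension of an IVIM series: frames are ordered direction-major, i.e. for
each MPG direction the full b-value ladder is stored contiguously, matching
the column order of the FSL-style .bval/.bvec files the package reads and
writes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["AcquisitionScheme", "DEFAULT_B_VALUES", "DEFAULT_DIRECTIONS"]

#: The 17 b-values (s/mm^2) of the emulated protocol, 0 to 2,500.
DEFAULT_B_VALUES = (
    0.0, 100.0, 200.0, 300.0, 400.0, 500.0, 600.0, 700.0, 800.0, 1000.0,
    1200.0, 1400.0, 1600.0, 1800.0, 2000.0, 2250.0, 2500.0,
)

#: The 6 MPG directions (unit-normalised on construction).
DEFAULT_DIRECTIONS = (
    (1.0, 1.0, 0.0),
    (0.0, 1.0, 1.0),
    (1.0, 0.0, 1.0),
    (1.0, -1.0, 0.0),
    (0.0, 1.0, -1.0),
    (-1.0, 0.0, 1.0),
)

#: Lower edge of the high-b (diffusion-only) fitting window, s/mm^2.
HIGH_B_THRESHOLD = 600.0


@dataclass(frozen=True)
class AcquisitionScheme:
    """Ordered b-values and unit MPG directions of one repeat.

    Attributes
    ----------
    b_values : ndarray, shape (n_b,)
        Strictly increasing b-values in s/mm^2, acquired once per
        direction block.
    directions : ndarray, shape (n_dir, 3)
        Unit direction vectors.
    repeats : int
        Number of repeated acquisitions available for averaging.
    """

    b_values: np.ndarray = field(default_factory=lambda: np.array(DEFAULT_B_VALUES))
    directions: np.ndarray = field(
        default_factory=lambda: np.array(DEFAULT_DIRECTIONS)
    )
    repeats: int = 1

    def __post_init__(self) -> None:
        b = np.asarray(self.b_values, dtype=float)
        vecs = np.asarray(self.directions, dtype=float)
        if b.ndim != 1 or np.any(b < 0) or np.any(np.diff(b) <= 0):
            raise ValueError("b_values must be a strictly increasing 1-D array >= 0")
        if vecs.ndim != 2 or vecs.shape[1] != 3:
            raise ValueError("directions must have shape (n_dir, 3)")
        norms = np.linalg.norm(vecs, axis=1)
        if np.any(norms == 0):
            raise ValueError("zero direction vectors are not allowed")
        object.__setattr__(self, "b_values", b)
        object.__setattr__(self, "directions", vecs / norms[:, None])
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")

    @property
    def n_b(self) -> int:
        return len(self.b_values)

    @property
    def n_directions(self) -> int:
        return len(self.directions)

    @property
    def n_frames(self) -> int:
        """Frames per repeat: n_b x n_directions, direction-major."""
        return self.n_b * self.n_directions

    def frame_b_values(self) -> np.ndarray:
        """b-value of every frame (length ``n_frames``)."""
        return np.tile(self.b_values, self.n_directions)

    def frame_directions(self) -> np.ndarray:
        """Direction vector of every frame, shape (n_frames, 3)."""
        return np.repeat(self.directions, self.n_b, axis=0)

    def frame_direction_index(self) -> np.ndarray:
        """Direction index (0-based) of every frame."""
        return np.repeat(np.arange(self.n_directions), self.n_b)

    def direction_slice(self, i: int) -> slice:
        """Frame slice of direction ``i``'s b-value block."""
        if not 0 <= i < self.n_directions:
            raise IndexError(f"direction index {i} out of range")
        return slice(i * self.n_b, (i + 1) * self.n_b)

    def high_b_mask(self, threshold: float = HIGH_B_THRESHOLD) -> np.ndarray:
        """Boolean mask over ``b_values`` selecting b >= threshold."""
        return self.b_values >= threshold

    def b0_frame_indices(self) -> np.ndarray:
        """Frame indices of the b = 0 acquisitions (one per direction)."""
        return np.flatnonzero(self.frame_b_values() == 0)
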