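"""Gray-value volume container shared by the whole pipeline.

Coordinate convention: the world position of the *center* of voxel
``(i, j, k)`` is ``origin + index * spacing`` (mm). Axis order of the voxel
array is ``(x, y, z)``; all meshes and volumes in the package share this
frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GrayVolume"]


@dataclass
class GrayVolume:
    """A 3-D scalar grid with physical voxel spacing.

    Parameters
    ----------
    voxels : ndarray, shape (nx, ny, nz)
        Scalar intensities (arbitrary CBCT grayscale) or occupancy
        fractions in ``[0, 1]``.
    spacing : array-like of 3 floats
        Voxel edge length along each axis, mm.
    origin : array-like of 3 floats
        World position (mm) of the center of voxel ``(0, 0, 0)``.
    """

    voxels: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.full(3, 0.1))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if self.voxels.ndim != 3:
            raise ValueError(f"voxels must be 3-D, got shape {self.voxels.shape}")
        if min(self.voxels.shape) < 2:
            raise ValueError("volume needs at least 2 samples per axis")
        if not np.all(self.spacing > 0):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("voxel intensities must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def index_to_world(self, index: np.ndarray) -> np.ndarray:
        """Map fractional voxel indices ``(n, 3)`` to world mm."""
        return self.origin + np.asarray(index, dtype=float) * self.spacing

    @property
    def bounds(self) -> np.ndarray:
        """Outer bounds (2, 3) of the gridded region, including the half
        voxel beyond the first/last sample centers."""
        lo = self.origin - self.spacing / 2
        hi = self.origin + (np.array(self.shape) - 0.5) * self.spacing
        return np.array([lo, hi])
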