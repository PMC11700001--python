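"""Core image container for 3D scalar volumes on a regular grid.

All volumes in this package are axis-aligned regular grids. Index order is
``(x, y, z)`` and world coordinates follow ``world = origin + index * spacing``
(cell-centred sampling, identity orientation). CT values are in Hounsfield
units unless a function says otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ImageVolume", "require_aligned"]


@dataclass
class ImageVolume:
    """A 3D scalar image with physical spacing and origin.

    Parameters
    ----------
    values
        3D array of voxel values, indexed ``(x, y, z)``.
    spacing_mm
        Per-axis voxel size in millimetres, all positive.
    origin_mm
        Physical position of voxel ``(0, 0, 0)`` in millimetres.
    """

    values: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(
                f"ImageVolume requires a 3D array, got ndim={self.values.ndim}"
            )
        if any(s < 2 for s in self.values.shape):
            raise ValueError(f"each axis needs >= 2 voxels, got {self.values.shape}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.origin_mm = tuple(float(o) for o in self.origin_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be positive, got {self.spacing_mm}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("ImageVolume values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def with_values(self, values: np.ndarray) -> "ImageVolume":
        """Same grid geometry, new voxel values."""
        return ImageVolume(values, self.spacing_mm, self.origin_mm)

    def copy(self) -> "ImageVolume":
        return ImageVolume(self.values.copy(), self.spacing_mm, self.origin_mm)


def require_aligned(*volumes, names: list[str] | None = None) -> None:
    """Raise ``ValueError`` unless all volumes share shape, spacing and origin.

    Accepts anything exposing ``shape``/``spacing_mm``/``origin_mm`` (both
    ``ImageVolume`` and ``DisplacementField``).
    """
    if len(volumes) < 2:
        return
    ref = volumes[0]
    labels = names or [f"volume {i}" for i in range(len(volumes))]
    for vol, label in zip(volumes[1:], labels[1:]):
        if tuple(vol.shape) != tuple(ref.shape):
            raise ValueError(
                f"{label} shape {tuple(vol.shape)} != {labels[0]} shape {tuple(ref.shape)}"
            )
        if not np.allclose(vol.spacing_mm, ref.spacing_mm):
            raise ValueError(f"{label} spacing {vol.spacing_mm} != {ref.spacing_mm}")
        if not np.allclose(vol.origin_mm, ref.origin_mm):
            raise ValueError(f"{label} origin {vol.origin_mm} != {ref.origin_mm}")
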