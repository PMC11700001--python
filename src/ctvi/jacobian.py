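"""Displacement fields and the Jacobian ventilation surrogate.

The Jacobian map is ``det(I + grad u) - 1`` of a peak-exhale -> peak-inhale
displacement field ``u``: the local fractional volume change of lung tissue
over the breathing cycle, and the classical motion-based ventilation
surrogate. Derivatives are taken with respect to physical (mm) coordinates
with displacements in mm, so the determinant is dimensionless and
independent of voxel size; central differences in the interior, one-sided at
grid borders.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import ImageVolume, require_aligned

__all__ = ["DisplacementField", "JacobianMap", "jacobian_map", "average_ct", "warp_volume"]


@dataclass
class DisplacementField:
    """Per-voxel displacement ``u(x, y, z)`` in mm, exhale -> inhale.

    Components are indexed ``(x, y, z)`` like :class:`~ctvi.volume.ImageVolume`.
    A field whose convention points the other way can be flipped with
    :meth:`inverted_convention`.
    """

    u_x: np.ndarray
    u_y: np.ndarray
    u_z: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.u_x = np.asarray(self.u_x, dtype=np.float64)
        self.u_y = np.asarray(self.u_y, dtype=np.float64)
        self.u_z = np.asarray(self.u_z, dtype=np.float64)
        if not (self.u_x.shape == self.u_y.shape == self.u_z.shape):
            raise ValueError("displacement components must share one shape")
        if self.u_x.ndim != 3:
            raise ValueError("displacement components must be 3D")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.origin_mm = tuple(float(o) for o in self.origin_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be positive, got {self.spacing_mm}")
        for name, comp in self.components.items():
            if not np.all(np.isfinite(comp)):
                raise ValueError(f"non-finite values in {name}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.u_x.shape  # type: ignore[return-value]

    @property
    def components(self) -> dict[str, np.ndarray]:
        return {"u_x": self.u_x, "u_y": self.u_y, "u_z": self.u_z}

    def magnitude(self) -> np.ndarray:
        return np.sqrt(self.u_x**2 + self.u_y**2 + self.u_z**2)

    def scaled(self, factor: float) -> "DisplacementField":
        return DisplacementField(
            self.u_x * factor, self.u_y * factor, self.u_z * factor,
            self.spacing_mm, self.origin_mm,
        )

    def inverted_convention(self) -> "DisplacementField":
        """Negate all components (inhale->exhale convention to exhale->inhale)."""
        return self.scaled(-1.0)


@dataclass
class JacobianMap:
    """``det(I + grad u) - 1`` per voxel; > -1 wherever the field is invertible."""

    values: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float]

    def as_volume(self) -> ImageVolume:
        return ImageVolume(self.values, self.spacing_mm, self.origin_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]


def _gradient(comp: np.ndarray, spacing: tuple[float, float, float]) -> list[np.ndarray]:
    # np.gradient: central differences inside, one-sided at the edges.
    return list(np.gradient(comp, *spacing, edge_order=1))


def jacobian_map(dvf: DisplacementField) -> JacobianMap:
    """Local fractional volume change of the deformation ``x + u(x)``.

    Builds the 3x3 matrix with entries ``delta_ij + du_i/dx_j`` at each voxel
    and returns its determinant minus one.
    """
    if any(s < 2 for s in dvf.shape):
        raise ValueError(f"need >= 2 voxels per axis to differentiate, got {dvf.shape}")
    gx = _gradient(dvf.u_x, dvf.spacing_mm)
    gy = _gradient(dvf.u_y, dvf.spacing_mm)
    gz = _gradient(dvf.u_z, dvf.spacing_mm)
    f = np.empty(dvf.shape + (3, 3), dtype=np.float64)
    for j in range(3):
        f[..., 0, j] = gx[j]
        f[..., 1, j] = gy[j]
        f[..., 2, j] = gz[j]
    f[..., 0, 0] += 1.0
    f[..., 1, 1] += 1.0
    f[..., 2, 2] += 1.0
    det = np.linalg.det(f)
    return JacobianMap(det - 1.0, dvf.spacing_mm, dvf.origin_mm)


def average_ct(phases: list[ImageVolume]) -> ImageVolume:
    """Voxel-wise arithmetic mean over breathing phases (the 'average CT')."""
    if len(phases) == 0:
        raise ValueError("need at least one phase")
    require_aligned(*phases, names=[f"phase {i}" for i in range(len(phases))])
    mean = np.mean([p.values for p in phases], axis=0)
    return phases[0].with_values(mean)


def warp_volume(
    vol: ImageVolume,
    dvf: DisplacementField,
    interpolation: str = "trilinear",
    background: float = -1000.0,
) -> ImageVolume:
    """Resample ``vol`` through the field: ``out(x) = vol(x + u(x))``.

    With an exhale->inhale field this pulls the inhale phase back onto the
    exhale grid (the resampling step of the density-change surrogate).
    Samples falling outside the grid take ``background`` (-1000 HU, air).
    """
    orders = {"trilinear": 1, "nearest": 0}
    if interpolation not in orders:
        raise ValueError(f"unknown interpolation {interpolation!r}")
    require_aligned(vol, dvf, names=["volume", "displacement field"])
    idx = np.meshgrid(*[np.arange(n, dtype=np.float64) for n in vol.shape], indexing="ij")
    coords = [
        idx[a] + comp / dvf.spacing_mm[a]
        for a, comp in enumerate((dvf.u_x, dvf.u_y, dvf.u_z))
    ]
    out = ndimage.map_coordinates(
        vol.values.astype(np.float64),
        np.stack(coords),
        order=orders[interpolation],
        mode="constant",
        cval=background,
    )
    if interpolation == "nearest":
        out = out.astype(vol.values.dtype)
    return vol.with_values(out)
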