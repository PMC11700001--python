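"""Preprocessing chain for CT, Jacobian and reference-ventilation volumes.

The canonical order for network inputs is crop (lung bounding box) ->
resample (fixed cubic grid) -> normalise. CT is windowed to [-1000, 0] HU and
rescaled to [0, 1]; Jacobian maps are min-max normalised; reference
ventilation is median-filtered, capped at its 90th percentile (computed over
non-zero voxels, to blunt airway hotspots) and divided by that cap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import ImageVolume, require_aligned

__all__ = [
    "PreprocessConfig",
    "crop_to_lung_bbox",
    "normalize_ct",
    "normalize_minmax",
    "preprocess_refvi",
    "resample",
]


@dataclass
class PreprocessConfig:
    """Parameters of the preprocessing chain.

    target_shape: grid every network input is resampled to.
    ct_window: HU window mapped linearly onto [0, 1]; values outside are
        clamped first (keeps bone/vessel voxels rather than discarding them).
    refvi_percentile: hotspot cap for reference ventilation.
    median_kernel: odd edge length of the median filter applied to RefVI.
    bbox_margin_voxels: margin added around the lung bounding box.
    """

    target_shape: tuple[int, int, int] = (60, 60, 60)
    ct_window: tuple[float, float] = (-1000.0, 0.0)
    refvi_percentile: float = 90.0
    median_kernel: int = 3
    bbox_margin_voxels: int = 0

    def __post_init__(self) -> None:
        if any(int(s) <= 0 for s in self.target_shape):
            raise ValueError(f"target_shape must be positive, got {self.target_shape}")
        self.target_shape = tuple(int(s) for s in self.target_shape)
        lo, hi = self.ct_window
        if not lo < hi:
            raise ValueError(f"ct_window lower bound must be < upper, got {self.ct_window}")
        if not 0.0 < self.refvi_percentile < 100.0:
            raise ValueError(f"refvi_percentile must be in (0, 100), got {self.refvi_percentile}")
        if self.median_kernel < 1 or self.median_kernel % 2 == 0:
            raise ValueError(f"median_kernel must be odd and >= 1, got {self.median_kernel}")
        if self.bbox_margin_voxels < 0:
            raise ValueError("bbox_margin_voxels must be >= 0")


def lung_bbox(mask: ImageVolume, margin: int = 0) -> tuple[tuple[int, int], ...]:
    """Half-open index box ``((x0,x1),(y0,y1),(z0,z1))`` covering the mask."""
    nz = np.nonzero(mask.values)
    if nz[0].size == 0:
        raise ValueError("lung mask is empty: no bounding box")
    box = []
    for axis, idx in enumerate(nz):
        lo = max(int(idx.min()) - margin, 0)
        hi = min(int(idx.max()) + 1 + margin, mask.shape[axis])
        box.append((lo, hi))
    return tuple(box)


def crop_to_lung_bbox(
    vol: ImageVolume, mask: ImageVolume, cfg: PreprocessConfig | None = None
) -> ImageVolume:
    """Crop ``vol`` to the smallest axis-aligned box containing the mask.

    The origin is shifted so world coordinates of retained voxels are
    unchanged.
    """
    cfg = cfg or PreprocessConfig()
    require_aligned(vol, mask, names=["volume", "mask"])
    (x0, x1), (y0, y1), (z0, z1) = lung_bbox(mask, cfg.bbox_margin_voxels)
    values = vol.values[x0:x1, y0:y1, z0:z1]
    origin = tuple(
        o + lo * s
        for o, lo, s in zip(vol.origin_mm, (x0, y0, z0), vol.spacing_mm)
    )
    return ImageVolume(values, vol.spacing_mm, origin)


def normalize_ct(vol: ImageVolume, cfg: PreprocessConfig | None = None) -> ImageVolume:
    """Clamp HU to the CT window and rescale linearly onto [0, 1]."""
    cfg = cfg or PreprocessConfig()
    lo, hi = cfg.ct_window
    clamped = np.clip(vol.values.astype(np.float64), lo, hi)
    return vol.with_values((clamped - lo) / (hi - lo))


def normalize_minmax(vol: ImageVolume, mask: ImageVolume | None = None) -> ImageVolume:
    """Min-max normalise onto [0, 1], extremes taken inside ``mask`` if given.

    Raises on constant input over the evaluation region: a silent all-zero
    output would masquerade as a valid ventilation map.
    """
    values = vol.values.astype(np.float64)
    if mask is not None:
        require_aligned(vol, mask, names=["volume", "mask"])
        region = values[mask.values > 0]
        if region.size == 0:
            raise ValueError("mask selects no voxels for min-max normalization")
    else:
        region = values.ravel()
    vmin, vmax = float(region.min()), float(region.max())
    if vmax <= vmin:
        raise ValueError(
            f"min-max normalization undefined: volume is constant ({vmin}) over the region"
        )
    return vol.with_values((values - vmin) / (vmax - vmin))


def preprocess_refvi(
    vol: ImageVolume,
    cfg: PreprocessConfig | None = None,
    mask: ImageVolume | None = None,
) -> ImageVolume:
    """Median-filter, cap at the 90th percentile of non-zero voxels, rescale.

    With a lung ``mask``, the percentile is computed over in-mask non-zero
    voxels — out-of-lung background (noise, scatter) would otherwise drag
    the cap down and saturate the lung. Output lies in [0, 1]; voxels at or
    above the cap map exactly to 1.
    """
    cfg = cfg or PreprocessConfig()
    if np.any(vol.values < 0):
        raise ValueError("reference ventilation must be non-negative")
    values = vol.values.astype(np.float64)
    if cfg.median_kernel > 1:
        values = ndimage.median_filter(values, size=cfg.median_kernel)
    if mask is not None:
        require_aligned(vol, mask, names=["refvi", "mask"])
        region = values[mask.values > 0]
    else:
        region = values
    nonzero = region[region > 0]
    if nonzero.size == 0:
        raise ValueError("reference ventilation is identically zero")
    cap = float(np.percentile(nonzero, cfg.refvi_percentile))
    if cap <= 0:
        raise ValueError("percentile cap is non-positive; cannot normalize")
    return vol.with_values(np.minimum(values, cap) / cap)


def _resample_array(values: np.ndarray, target_shape, order: int) -> np.ndarray:
    """Resample onto a same-extent grid with cell-centred sampling."""
    old = values.shape
    coords = np.meshgrid(
        *[
            (np.arange(n) + 0.5) * (o / n) - 0.5
            for n, o in zip(target_shape, old)
        ],
        indexing="ij",
    )
    return ndimage.map_coordinates(
        values.astype(np.float64), np.stack(coords), order=order, mode="nearest"
    )


def resample(
    vol: ImageVolume,
    target_shape: tuple[int, int, int],
    interpolation: str = "trilinear",
) -> ImageVolume:
    """Resample to ``target_shape`` preserving the physical extent.

    ``interpolation`` is ``"trilinear"`` for scalar images or ``"nearest"``
    for masks. Spacing is rescaled so ``shape * spacing`` is invariant; the
    origin moves to the centre of the first new cell.
    """
    orders = {"trilinear": 1, "nearest": 0}
    if interpolation not in orders:
        raise ValueError(
            f"unknown interpolation {interpolation!r}; expected one of {sorted(orders)}"
        )
    target_shape = tuple(int(s) for s in target_shape)
    if any(s <= 0 for s in target_shape):
        raise ValueError(f"target shape must be positive, got {target_shape}")
    if target_shape == tuple(vol.shape):
        out = vol.values.astype(np.float64)
        return ImageVolume(out, vol.spacing_mm, vol.origin_mm)
    new_spacing = tuple(
        sp * (o / n) for sp, o, n in zip(vol.spacing_mm, vol.shape, target_shape)
    )
    # Cell-centred grids: voxel i of the new grid sits at (i + 0.5) * new_sp
    # measured from the old voxel-0 centre minus half an old voxel.
    new_origin = tuple(
        og - 0.5 * sp_old + 0.5 * sp_new
        for og, sp_old, sp_new in zip(vol.origin_mm, vol.spacing_mm, new_spacing)
    )
    out = _resample_array(vol.values, target_shape, orders[interpolation])
    if interpolation == "nearest":
        out = out.astype(vol.values.dtype)
    return ImageVolume(out, new_spacing, new_origin)
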