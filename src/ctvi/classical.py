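"""Non-learning ventilation estimators: Jacobian, density change, supervoxel.

Three classical surrogates computed directly from a 4DCT phase pair and its
displacement field:

* ``ctvi_jac`` — local volume change ``det(I + grad u) - 1`` (motion only);
* ``ctvi_hu`` — specific air-volume change from HU differences after warping
  the inhale phase onto exhale geometry (density only);
* ``ctvi_svd`` — the density-change signal averaged over SLIC supervoxels of
  the exhale lung, giving a piecewise-constant, noise-robust map.

All return maps min-max normalised to [0, 1] inside the lung mask and zero
outside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage.segmentation import slic

from .jacobian import DisplacementField, jacobian_map, warp_volume
from .preprocess import normalize_minmax
from .volume import ImageVolume, require_aligned

__all__ = ["VentilationMap", "ctvi_jac", "ctvi_hu", "ctvi_svd"]

logger = logging.getLogger(__name__)

# Voxels whose exhale HU is above -EPS_HU (no air content) or whose warped
# inhale HU pegs at/below -1000 + EPS_HU make the air-volume formula blow up.
EPS_HU = 10.0


@dataclass
class VentilationMap:
    """Normalised ventilation estimate: [0, 1] inside the mask, 0 outside."""

    values: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float]
    method: str = "unknown"

    def as_volume(self) -> ImageVolume:
        return ImageVolume(self.values, self.spacing_mm, self.origin_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]


def _finalize(
    raw: np.ndarray, mask: ImageVolume, method: str
) -> VentilationMap:
    """Min-max normalise the raw signal inside the mask; zero outside."""
    vol = ImageVolume(raw, mask.spacing_mm, mask.origin_mm)
    try:
        normed = normalize_minmax(vol, mask)
    except ValueError as exc:
        raise ValueError(f"{method}: {exc}") from exc
    values = np.where(mask.values > 0, normed.values, 0.0)
    return VentilationMap(values, mask.spacing_mm, mask.origin_mm, method=method)


def ctvi_jac(dvf: DisplacementField, mask: ImageVolume) -> VentilationMap:
    """Jacobian ventilation surrogate, normalised within the lung."""
    require_aligned(dvf, mask, names=["displacement field", "mask"])
    if not np.any(mask.values > 0):
        raise ValueError("ctvi_jac: empty lung mask")
    jac = jacobian_map(dvf)
    return _finalize(jac.values, mask, "jac")


def hu_ventilation_raw(
    ct_ex: ImageVolume,
    ct_in: ImageVolume,
    dvf: DisplacementField,
    mask: ImageVolume,
) -> np.ndarray:
    """Specific air-volume change per voxel, before normalisation.

    The inhale phase is pulled back onto exhale geometry through the field,
    then ``1000 (HU_in - HU_ex) / (HU_ex (1000 + HU_in))`` — the fractional
    change in local air volume under the assumption that tissue mass is
    conserved. Degenerate voxels (no air, or fully air) are replaced by the
    masked median and counted in a log message.
    """
    require_aligned(ct_ex, ct_in, dvf, mask, names=["ct_ex", "ct_in", "dvf", "mask"])
    if not np.any(mask.values > 0):
        raise ValueError("ctvi_hu: empty lung mask")
    if np.min(ct_ex.values) < -1024.0 or np.min(ct_in.values) < -1024.0:
        raise ValueError("implausible HU below -1024 in input CT")
    warped_in = warp_volume(ct_in, dvf, interpolation="trilinear").values
    hu_ex = ct_ex.values.astype(np.float64)
    in_mask = mask.values > 0
    bad = (hu_ex >= -EPS_HU) | (warped_in <= -1000.0 + EPS_HU)
    denom = hu_ex * (1000.0 + warped_in)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = 1000.0 * (warped_in - hu_ex) / denom
    good = in_mask & ~bad
    if not np.any(good):
        raise ValueError("ctvi_hu: no valid lung voxels for the air-volume formula")
    n_bad = int(np.count_nonzero(in_mask & bad))
    if n_bad:
        logger.info("ctvi_hu: %d in-mask voxels outside HU validity window, set to median", n_bad)
    raw = np.where(bad, np.median(raw[good]), raw)
    return raw


def ctvi_hu(
    ct_ex: ImageVolume,
    ct_in: ImageVolume,
    dvf: DisplacementField,
    mask: ImageVolume,
) -> VentilationMap:
    """Density-change (specific air-volume change) ventilation surrogate."""
    raw = hu_ventilation_raw(ct_ex, ct_in, dvf, mask)
    return _finalize(raw, mask, "hu")


def ctvi_svd(
    ct_ex: ImageVolume,
    ct_in: ImageVolume,
    dvf: DisplacementField,
    mask: ImageVolume,
    n_supervoxels: int = 500,
    compactness: float = 0.1,
    aggregate: str = "density_change",
) -> VentilationMap:
    """Supervoxel mean-density ventilation estimate.

    SLIC clusters the exhale lung on intensity + position; each supervoxel is
    assigned the mean of the density-change signal (``aggregate=
    "density_change"``, ventilation-like output) or of the raw exhale density
    (``aggregate="density"``). With ``n_supervoxels`` at or above the lung
    voxel count the clustering degenerates to one voxel per cluster and the
    result equals ``ctvi_hu``.
    """
    if aggregate not in ("density_change", "density"):
        raise ValueError(f"unknown aggregate {aggregate!r}")
    in_mask = mask.values > 0
    n_lung = int(np.count_nonzero(in_mask))
    if not 1 <= n_supervoxels:
        raise ValueError("n_supervoxels must be >= 1")
    if n_supervoxels > n_lung:
        raise ValueError(
            f"n_supervoxels={n_supervoxels} exceeds lung voxel count {n_lung}"
        )
    if aggregate == "density_change":
        signal = hu_ventilation_raw(ct_ex, ct_in, dvf, mask)
    else:
        require_aligned(ct_ex, mask, names=["ct_ex", "mask"])
        signal = -ct_ex.values.astype(np.float64)  # denser = less ventilated
    if n_supervoxels == n_lung:
        labels = np.zeros(mask.shape, dtype=np.int64)
        labels[in_mask] = np.arange(1, n_lung + 1)
    else:
        # SLIC on CT intensity rescaled to [0, 1]; spatial regularity set by
        # compactness (0.1 keeps clusters following density structure).
        ct = ct_ex.values.astype(np.float64)
        lo, hi = ct[in_mask].min(), ct[in_mask].max()
        ct01 = (ct - lo) / (hi - lo) if hi > lo else np.zeros_like(ct)
        labels = slic(
            ct01,
            n_segments=n_supervoxels,
            compactness=compactness,
            mask=in_mask,
            start_label=1,
            channel_axis=None,
        )
    n_clusters = len(np.unique(labels[in_mask & (labels > 0)]))
    if n_clusters < 2:
        raise ValueError(f"clustering produced {n_clusters} supervoxel(s); need >= 2")
    out = np.zeros_like(signal)
    sums = np.bincount(labels.ravel(), weights=signal.ravel())
    counts = np.bincount(labels.ravel())
    means = np.divide(sums, counts, out=np.zeros_like(sums), where=counts > 0)
    out = means[labels]
    out[~in_mask] = 0.0
    return _finalize(out, mask, "svd")
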