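"""Agreement metrics between estimated and reference ventilation.

Spearman correlation over the lung (rank transform, then the product-moment
formula on ranks), a 0.66 threshold splitting normalised ventilation into
high- and low-functional regions, and Dice overlap of those regions. The
evaluation set is the in-mask voxels with non-zero reference signal.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .volume import ImageVolume, require_aligned

__all__ = [
    "MetricsReport",
    "spearman_r",
    "functional_split",
    "dsc",
    "evaluate_case",
    "evaluate_cohort",
]

DEFAULT_THRESHOLD = 0.66


@dataclass
class MetricsReport:
    """Per-case agreement scores.

    R: Spearman rank correlation over evaluated voxels, in [-1, 1].
    DSC_h / DSC_l: Dice of the high-/low-functional regions after
        thresholding both maps at ``threshold``.
    """

    R: float
    DSC_h: float
    DSC_l: float
    n_voxels: int
    threshold: float

    def as_dict(self) -> dict:
        return asdict(self)


def _as_values(vol) -> np.ndarray:
    return vol.values if hasattr(vol, "values") else np.asarray(vol)


def _check_compat(*vols) -> None:
    """Shape check for mixed ImageVolume / VentilationMap / ndarray inputs;
    grid geometry is compared when every input carries it."""
    shapes = {tuple(_as_values(v).shape) for v in vols}
    if len(shapes) > 1:
        raise ValueError(f"misaligned inputs: shapes {sorted(shapes)}")
    if all(hasattr(v, "spacing_mm") for v in vols):
        require_aligned(*vols)


def _evaluation_set(ref: np.ndarray, mask: np.ndarray) -> np.ndarray:
    return (mask > 0) & (ref != 0)


def spearman_r(
    pred,
    ref,
    mask,
    *,
    rank: bool = True,
) -> float:
    """Spearman correlation over in-mask, non-zero-reference voxels.

    ``rank=False`` computes the plain product-moment (Pearson) coefficient on
    raw values instead of ranks, for comparison.
    """
    _check_compat(pred, ref, mask)
    p = _as_values(pred).astype(np.float64)
    y = _as_values(ref).astype(np.float64)
    sel = _evaluation_set(y, _as_values(mask))
    if np.count_nonzero(sel) < 2:
        raise ValueError("need >= 2 evaluated voxels for a correlation")
    ps, ys = p[sel], y[sel]
    if np.all(ps == ps[0]) or np.all(ys == ys[0]):
        raise ValueError("correlation undefined: constant input over the evaluation set")
    if rank:
        ps = stats.rankdata(ps)  # average ranks for ties
        ys = stats.rankdata(ys)
    ps = ps - ps.mean()
    ys = ys - ys.mean()
    return float(np.sum(ys * ps) / np.sqrt(np.sum(ys**2) * np.sum(ps**2)))


def functional_split(
    vent,
    mask,
    threshold: float = DEFAULT_THRESHOLD,
) -> tuple[np.ndarray, np.ndarray]:
    """Partition the mask into high- (> threshold) and low- (<= threshold) regions.

    A voxel at exactly the threshold counts as low-functional.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    _check_compat(vent, mask)
    v = _as_values(vent)
    m = _as_values(mask) > 0
    high = m & (v > threshold)
    low = m & ~high
    return high, low


def dsc(a: np.ndarray, b: np.ndarray) -> float:
    """Dice similarity ``2|A n B| / (|A| + |B|)``.

    Two empty regions are identical (1.0); exactly one empty gives 0.0.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    for name, arr in (("a", a), ("b", b)):
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1, True, False))):
            raise ValueError(f"mask {name} is not binary (values {uniq[:5]}...)")
    na, nb = int(a.sum()), int(b.sum())
    if na == 0 and nb == 0:
        return 1.0
    inter = int(np.count_nonzero(np.logical_and(a, b)))
    return 2.0 * inter / (na + nb)


def evaluate_case(
    pred,
    ref,
    mask,
    threshold: float = DEFAULT_THRESHOLD,
    case_id: str | None = None,
) -> MetricsReport:
    """Full per-case report: Spearman R plus Dice of functional regions.

    ``ref`` should already be preprocessed (hotspot-capped, scaled to [0, 1])
    so the shared threshold is meaningful.
    """
    try:
        r = spearman_r(pred, ref, mask)
        ref_high, ref_low = functional_split(ref, mask, threshold)
        pred_high, pred_low = functional_split(pred, mask, threshold)
        sel = _evaluation_set(_as_values(ref), _as_values(mask))
        return MetricsReport(
            R=r,
            DSC_h=dsc(ref_high, pred_high),
            DSC_l=dsc(ref_low, pred_low),
            n_voxels=int(np.count_nonzero(sel)),
            threshold=threshold,
        )
    except ValueError as exc:
        prefix = f"case {case_id}: " if case_id else ""
        raise ValueError(f"{prefix}{exc}") from exc


def evaluate_cohort(
    reports: dict[str, MetricsReport],
) -> pd.DataFrame:
    """Tabulate per-case reports with a mean +- sd footer row."""
    rows = {cid: rep.as_dict() for cid, rep in reports.items()}
    df = pd.DataFrame.from_dict(rows, orient="index")
    summary = df[["R", "DSC_h", "DSC_l"]].agg(["mean", "std"])
    footer = pd.DataFrame(
        {
            "R": [summary.loc["mean", "R"], summary.loc["std", "R"]],
            "DSC_h": [summary.loc["mean", "DSC_h"], summary.loc["std", "DSC_h"]],
            "DSC_l": [summary.loc["mean", "DSC_l"], summary.loc["std", "DSC_l"]],
        },
        index=["mean", "sd"],
    )
    return pd.concat([df, footer])
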