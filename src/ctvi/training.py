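"""Training loop, augmentation, learning-rate decay and fold splitting.

The synthesis models train with Adam at batch size one on masked mean
absolute error. The learning rate is constant until a decay-start epoch and
then falls linearly to zero at the final epoch:

    factor(e) = 1                                  e <= e_decay
    factor(e) = 1 - (e - e_decay) / (E - e_decay)  e >  e_decay

Augmentation applies one jointly-drawn geometric transform to all four
volumes of a sample (trilinear for scalar volumes, nearest for the mask):
per-axis flips, an in-plane rotation about the superior-inferior axis,
border cropping with resize-back, and a smooth random elastic deformation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .jacobian import average_ct, jacobian_map
from .model import SynthesisModel
from .nn import Adam, Tensor, autograd as ag
from .phantom import PhantomCase
from .preprocess import (
    PreprocessConfig,
    crop_to_lung_bbox,
    normalize_ct,
    normalize_minmax,
    preprocess_refvi,
    resample,
)
from .volume import ImageVolume

__all__ = [
    "TrainConfig",
    "AugmentConfig",
    "TrainingSample",
    "lr_factor",
    "augment_sample",
    "prepare_sample",
    "train",
    "kfold_split",
]

logger = logging.getLogger(__name__)


@dataclass
class AugmentConfig:
    """Magnitudes of the joint geometric augmentations."""

    enabled: bool = True
    flip_prob: float = 0.5
    rotation_deg: float = 15.0
    crop_frac: float = 0.10
    elastic_frac: float = 0.25
    p_rotate: float = 0.5
    p_crop: float = 0.5
    p_elastic: float = 0.5

    def __post_init__(self) -> None:
        for name in ("flip_prob", "p_rotate", "p_crop", "p_elastic"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        for name in ("rotation_deg", "crop_frac", "elastic_frac"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class TrainConfig:
    """Optimisation hyperparameters (full-scale defaults)."""

    epochs: int = 800
    batch_size: int = 1
    lr_initial: float = 1e-4
    decay_start_epoch: int | None = None  # defaults to epochs // 2
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    seed: int = 0
    mask_loss: bool = True
    folds: int = 3

    def __post_init__(self) -> None:
        if self.decay_start_epoch is None:
            self.decay_start_epoch = self.epochs // 2
        if not 0 <= self.decay_start_epoch < self.epochs:
            raise ValueError(
                f"need 0 <= decay_start_epoch < epochs, got "
                f"{self.decay_start_epoch} / {self.epochs}"
            )
        if self.batch_size != 1:
            raise ValueError("the synthesis models train at batch size 1")
        if self.lr_initial < 0:
            raise ValueError("lr_initial must be >= 0")


def lr_factor(epoch: int, cfg: TrainConfig) -> float:
    """Learning-rate multiplier for ``epoch`` (0-based).

    1.0 up to the decay-start epoch, linear to exactly 0.0 at
    ``epoch == epochs`` (the last optimisation step, at epoch ``epochs - 1``,
    still takes a small positive step).
    """
    if not 0 <= epoch <= cfg.epochs:
        raise ValueError(f"epoch {epoch} outside [0, {cfg.epochs}]")
    e0 = cfg.decay_start_epoch
    if epoch <= e0:
        return 1.0
    return 1.0 - (epoch - e0) / (cfg.epochs - e0)


@dataclass
class TrainingSample:
    """One preprocessed case: network inputs, target and lung mask."""

    avg_ct: np.ndarray
    jacobian: np.ndarray
    target: np.ndarray
    mask: np.ndarray
    case_id: str = ""


def prepare_sample(
    case: PhantomCase,
    target_shape: tuple[int, int, int] = (60, 60, 60),
    pre: PreprocessConfig | None = None,
) -> TrainingSample:
    """Run the preprocessing chain on a phantom case.

    Crop to the lung bounding box, resample to the network grid, then
    normalise: CT window for the average CT, min-max for the Jacobian map,
    median-filter + percentile cap for the reference ventilation.
    """
    pre = pre or PreprocessConfig(target_shape=target_shape)
    mask = case.lung_mask
    avg = crop_to_lung_bbox(average_ct(case.phases), mask, pre)
    jac = crop_to_lung_bbox(jacobian_map(case.dvf_truth).as_volume(), mask, pre)
    ref = crop_to_lung_bbox(case.refvi, mask, pre)
    msk = crop_to_lung_bbox(mask, mask, pre)
    avg = resample(avg, pre.target_shape, "trilinear")
    jac = resample(jac, pre.target_shape, "trilinear")
    ref = resample(ref, pre.target_shape, "trilinear")
    msk = resample(msk, pre.target_shape, "nearest")
    avg01 = normalize_ct(avg, pre)
    jac01 = normalize_minmax(jac)
    ref01 = preprocess_refvi(ref, pre, mask=msk)
    return TrainingSample(
        avg_ct=avg01.values.astype(np.float32),
        jacobian=jac01.values.astype(np.float32),
        target=ref01.values.astype(np.float32),
        mask=(msk.values > 0).astype(np.float32),
        case_id=f"seed{case.spec.seed}",
    )


def _rotate(arr: np.ndarray, angle: float, order: int) -> np.ndarray:
    # rotation in the axial (x, y) plane = about the superior-inferior axis
    return ndimage.rotate(
        arr, angle, axes=(0, 1), reshape=False, order=order, mode="nearest"
    )


def _crop_resize(arr: np.ndarray, lo, hi, order: int) -> np.ndarray:
    view = arr[lo[0] : arr.shape[0] - hi[0], lo[1] : arr.shape[1] - hi[1], lo[2] : arr.shape[2] - hi[2]]
    zoom = [n / v for n, v in zip(arr.shape, view.shape)]
    return ndimage.zoom(view, zoom, order=order, mode="nearest", grid_mode=True)


def _elastic(arr: np.ndarray, disp: list[np.ndarray], order: int) -> np.ndarray:
    idx = np.meshgrid(*[np.arange(n, dtype=np.float64) for n in arr.shape], indexing="ij")
    coords = [idx[a] + disp[a] for a in range(3)]
    return ndimage.map_coordinates(arr, coords, order=order, mode="nearest")


def augment_sample(
    sample: TrainingSample,
    cfg: AugmentConfig,
    rng: np.random.Generator,
) -> TrainingSample:
    """Apply one random joint geometric transform to the whole sample.

    Scalar volumes interpolate trilinearly; the mask uses nearest neighbour
    and stays exactly binary. Output shapes equal input shapes (crops are
    resized back). Deterministic given the generator state.
    """
    scalars = [sample.avg_ct, sample.jacobian, sample.target]
    mask = sample.mask
    shape = np.array(mask.shape)
    if cfg.enabled:
        flips = [rng.random() < cfg.flip_prob for _ in range(3)]
        do_rot = rng.random() < cfg.p_rotate
        angle = float(rng.uniform(-cfg.rotation_deg, cfg.rotation_deg))
        do_crop = rng.random() < cfg.p_crop
        lo = [int(rng.integers(0, int(cfg.crop_frac * n) + 1)) for n in shape]
        hi = [int(rng.integers(0, int(cfg.crop_frac * n) + 1)) for n in shape]
        do_elastic = rng.random() < cfg.p_elastic
        if do_elastic and cfg.elastic_frac > 0:
            amp = float(rng.uniform(0, cfg.elastic_frac)) * float(shape.min()) * 0.1
            disp = []
            for _ in range(3):
                noise = rng.normal(size=tuple(shape))
                smooth = ndimage.gaussian_filter(noise, sigma=float(shape.min()) / 8.0)
                peak = np.abs(smooth).max() or 1.0
                disp.append(smooth / peak * amp)
        else:
            do_elastic = False
            disp = None

        def apply(arr: np.ndarray, order: int) -> np.ndarray:
            out = arr
            for axis, f in enumerate(flips):
                if f:
                    out = np.flip(out, axis=axis)
            if do_rot and cfg.rotation_deg > 0:
                out = _rotate(out, angle, order)
            if do_crop and any(l + h > 0 for l, h in zip(lo, hi)):
                out = _crop_resize(out, lo, hi, order)
            if do_elastic:
                out = _elastic(out, disp, order)
            return np.ascontiguousarray(out)

        scalars = [apply(s.astype(np.float64), 1).astype(np.float32) for s in scalars]
        mask = apply(mask.astype(np.float64), 0)
        mask = (mask > 0.5).astype(np.float32)
    return TrainingSample(
        avg_ct=scalars[0],
        jacobian=scalars[1],
        target=scalars[2],
        mask=mask,
        case_id=sample.case_id,
    )


def train(
    model: SynthesisModel,
    samples: list[TrainingSample],
    cfg: TrainConfig,
    validation: list[TrainingSample] | None = None,
) -> dict:
    """Train in place; returns a history dict of per-epoch losses.

    Loss is mean absolute error over lung voxels (prediction and target both
    zeroed outside the mask) unless ``cfg.mask_loss`` is off. One seeded
    generator drives sample order and augmentation draws, so identical seeds
    give bit-identical histories on one machine.
    """
    if not samples:
        raise ValueError("empty training set")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 53]))
    optim = Adam(model.parameters(), lr=cfg.lr_initial)
    history: dict = {"train_loss": [], "val_loss": [], "lr_factor": []}
    n_inputs = model.expected_inputs()
    for epoch in range(cfg.epochs):
        factor = lr_factor(epoch, cfg)
        order = rng.permutation(len(samples))
        model.train()
        losses = []
        for idx in order:
            s = augment_sample(samples[idx], cfg.augment, rng)
            inputs = (Tensor(s.avg_ct[None]),) if n_inputs == 1 else (
                Tensor(s.avg_ct[None]),
                Tensor(s.jacobian[None]),
            )
            model.zero_grad()
            pred = model.forward_tensors(*inputs)
            loss = ag.mae_loss(pred, s.target[None], s.mask if cfg.mask_loss else None)
            value = float(loss.data)
            if not np.isfinite(value):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, sample {s.case_id or int(idx)}"
                )
            loss.backward()
            optim.step(lr_factor=factor)
            losses.append(value)
        history["train_loss"].append(float(np.mean(losses)))
        history["lr_factor"].append(factor)
        if validation:
            history["val_loss"].append(evaluate_loss(model, validation, cfg))
        logger.debug(
            "epoch %d: train %.5f lr_factor %.4f", epoch, history["train_loss"][-1], factor
        )
    return history


def evaluate_loss(model: SynthesisModel, samples: list[TrainingSample], cfg: TrainConfig) -> float:
    """Mean masked MAE over samples in eval mode, no augmentation."""
    model.eval()
    n_inputs = model.expected_inputs()
    losses = []
    for s in samples:
        inputs = (Tensor(s.avg_ct[None]),) if n_inputs == 1 else (
            Tensor(s.avg_ct[None]),
            Tensor(s.jacobian[None]),
        )
        pred = model.forward_tensors(*inputs)
        losses.append(float(ag.mae_loss(pred, s.target[None], s.mask if cfg.mask_loss else None).data))
    model.train()
    return float(np.mean(losses))


def kfold_split(
    case_ids: list,
    k: int,
    seed: int = 0,
    external_test: list | None = None,
) -> tuple[list[list], list]:
    """Random disjoint folds of near-equal size, plus an untouched test list.

    Ids in ``external_test`` are excluded from the folds entirely (they are
    never trained or validated on). Deterministic given ``seed``.
    """
    external = list(external_test or [])
    pool = [c for c in case_ids if c not in external]
    if k < 2:
        raise ValueError("need k >= 2 folds")
    if k > len(pool):
        raise ValueError(f"k={k} exceeds {len(pool)} available cases")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 71]))
    order = [pool[i] for i in rng.permutation(len(pool))]
    folds: list[list] = [[] for _ in range(k)]
    for i, cid in enumerate(order):
        folds[i % k].append(cid)
    return folds, external
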