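"""Dual-path fusion network for ventilation synthesis, plus baselines.

The dual-aware model ingests two preprocessed volumes — the time-averaged CT
(anatomy) and the Jacobian map (motion) — through two independent
feature-extraction branches (FEBs). Each branch is three conv blocks
(3x3x3 convolution + batch normalisation + rectifier) with two poolings,
producing feature maps at three scales. At every scale the two branches are
fused voxel-wise: their sum, product and maximum are concatenated along
channels and projected back to the branch width by a 1x1x1 convolution. A
four-block encoder (with two poolings aligning the scales) digests the fused
pyramid into a bottleneck, and a decoder with two trilinear upsamplings,
three conv layers and fused-scale skip connections reconstructs a
single-channel ventilation map through a sigmoid.

Variants: ``ct_only`` keeps a single branch (anatomy alone — the ablation
arm); ``unet_baseline`` is a standard 3D U-net with four resolution steps of
two 3x3x3 convolutions + ReLU and 2x2x2 max pooling, taking the same two
volumes as a 2-channel input.

Pooling uses floor semantics and every upsampling targets the recorded
skip shape exactly, so odd intermediate sizes (60 -> 30 -> 15) round-trip.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import yaml

from .classical import VentilationMap
from .nn import Tensor, autograd as ag
from .nn.layers import Conv3d, ConvBlock, Module
from .volume import ImageVolume

__all__ = ["ModelConfig", "SynthesisModel", "build_model", "forward", "save_checkpoint", "load_checkpoint"]

_FUSION_MODES = ("concat_sum_prod_max", "sum_only", "prod_only", "max_only")
_VARIANTS = ("dual", "ct_only", "unet_baseline")


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    Defaults follow the full-size synthesis network (three FEB blocks of
    64/128/256 channels, a 128/256/256/512 encoder, a 256/128/64 decoder,
    60-cube inputs). Tests and small studies shrink the channel widths; the
    layer counts are structural and fixed.
    """

    input_shape: tuple[int, int, int] = (60, 60, 60)
    feb_channels: tuple[int, int, int] = (64, 128, 256)
    encoder_channels: tuple[int, int, int, int] = (128, 256, 256, 512)
    decoder_channels: tuple[int, int, int] = (256, 128, 64)
    kernel: int = 3
    fusion_mode: str = "concat_sum_prod_max"
    final_activation: str = "sigmoid"
    variant: str = "dual"
    seed: int = 0

    def __post_init__(self) -> None:
        self.input_shape = tuple(int(s) for s in self.input_shape)
        self.feb_channels = tuple(int(c) for c in self.feb_channels)
        self.encoder_channels = tuple(int(c) for c in self.encoder_channels)
        self.decoder_channels = tuple(int(c) for c in self.decoder_channels)
        if len(self.feb_channels) != 3:
            raise ValueError("feb_channels must have 3 entries")
        if len(self.encoder_channels) != 4:
            raise ValueError("encoder_channels must have 4 entries")
        if len(self.decoder_channels) != 3:
            raise ValueError("decoder_channels must have 3 entries")
        if self.fusion_mode not in _FUSION_MODES:
            raise ValueError(f"fusion_mode must be one of {_FUSION_MODES}")
        if self.variant not in _VARIANTS:
            raise ValueError(f"variant must be one of {_VARIANTS}")
        if self.final_activation not in ("sigmoid", "identity"):
            raise ValueError("final_activation must be 'sigmoid' or 'identity'")
        if any(s // 4 < 1 for s in self.input_shape):
            raise ValueError(
                f"input_shape {self.input_shape} too small for two pooling stages"
            )

    @classmethod
    def small(cls, width: int = 8, **kwargs) -> "ModelConfig":
        """A width-scaled config (same topology) for small grids and studies."""
        return cls(
            feb_channels=(width, 2 * width, 4 * width),
            encoder_channels=(2 * width, 4 * width, 4 * width, 8 * width),
            decoder_channels=(4 * width, 2 * width, width),
            **kwargs,
        )


class _FEB(Module):
    """Feature-extraction branch: three conv blocks, two poolings."""

    def __init__(self, cfg: ModelConfig, rng):
        super().__init__()
        f1, f2, f3 = cfg.feb_channels
        k = cfg.kernel
        self.block1 = ConvBlock(1, f1, k, rng)
        self.block2 = ConvBlock(f1, f2, k, rng)
        self.block3 = ConvBlock(f2, f3, k, rng)

    def __call__(self, x: Tensor) -> tuple[Tensor, Tensor, Tensor]:
        b1 = self.block1(x)
        b2 = self.block2(ag.maxpool2(b1))
        b3 = self.block3(ag.maxpool2(b2))
        return b1, b2, b3


class _Fusion(Module):
    """Voxel-wise sum/product/maximum combination of two branches."""

    def __init__(self, channels: int, mode: str, rng):
        super().__init__()
        self.mode = mode
        self.proj = (
            Conv3d(3 * channels, channels, 1, rng) if mode == "concat_sum_prod_max" else None
        )

    def __call__(self, a: Tensor, b: Tensor) -> Tensor:
        if self.mode == "sum_only":
            return ag.add(a, b)
        if self.mode == "prod_only":
            return ag.mul(a, b)
        if self.mode == "max_only":
            return ag.maximum(a, b)
        fused = ag.concat([ag.add(a, b), ag.mul(a, b), ag.maximum(a, b)])
        return self.proj(fused)


class SynthesisModel(Module):
    """Common surface: ``predict`` on volumes, ``forward_tensors`` for training."""

    config: ModelConfig

    def expected_inputs(self) -> int:
        raise NotImplementedError

    def forward_tensors(self, *inputs: Tensor) -> Tensor:
        raise NotImplementedError

    def predict(self, *volumes: ImageVolume) -> VentilationMap:
        """Run the network in eval mode on preprocessed [0, 1] volumes."""
        arity = self.expected_inputs()
        if len(volumes) != arity:
            raise ValueError(
                f"{self.config.variant} model takes {arity} input volume(s), got {len(volumes)}"
            )
        tensors = []
        for vol in volumes:
            arr = vol.values if hasattr(vol, "values") else np.asarray(vol)
            if tuple(arr.shape) != self.config.input_shape:
                raise ValueError(
                    f"input shape {arr.shape} != model input_shape {self.config.input_shape}"
                )
            if not np.all(np.isfinite(arr)):
                raise ValueError("non-finite values in model input")
            tensors.append(Tensor(arr[None].astype(np.float32)))
        was_training = self.training
        self.eval()
        out = self.forward_tensors(*tensors).data[0]
        if was_training:
            self.train()
        spacing = getattr(volumes[0], "spacing_mm", (1.0, 1.0, 1.0))
        origin = getattr(volumes[0], "origin_mm", (0.0, 0.0, 0.0))
        return VentilationMap(out.astype(np.float64), spacing, origin,
                              method=self.config.variant)


class DPFN(SynthesisModel):
    """Dual-path fusion network (or its single-branch ablation)."""

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        self.config = cfg
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7]))
        f1, f2, f3 = cfg.feb_channels
        e1, e2, e3, e4 = cfg.encoder_channels
        d1, d2, d3 = cfg.decoder_channels
        k = cfg.kernel
        self.feb_ct = _FEB(cfg, rng)
        self.dual = cfg.variant == "dual"
        if self.dual:
            self.feb_jac = _FEB(cfg, rng)
            self.fuse1 = _Fusion(f1, cfg.fusion_mode, rng)
            self.fuse2 = _Fusion(f2, cfg.fusion_mode, rng)
            self.fuse3 = _Fusion(f3, cfg.fusion_mode, rng)
        self.enc1 = ConvBlock(f1, e1, k, rng)
        self.enc2 = ConvBlock(e1 + f2, e2, k, rng)
        self.enc3 = ConvBlock(e2 + f3, e3, k, rng)
        self.enc4 = ConvBlock(e3, e4, k, rng)
        self.dec1 = ConvBlock(e4 + f2, d1, k, rng)
        self.dec2 = ConvBlock(d1 + f1, d2, k, rng)
        self.dec3 = ConvBlock(d2, d3, k, rng)
        self.head = Conv3d(d3, 1, 1, rng)

    def expected_inputs(self) -> int:
        return 2 if self.dual else 1

    def forward_tensors(self, *inputs: Tensor) -> Tensor:
        if len(inputs) != self.expected_inputs():
            raise ValueError(
                f"{self.config.variant} forward expects {self.expected_inputs()} "
                f"tensor(s), got {len(inputs)}"
            )
        ct = inputs[0]
        a1, a2, a3 = self.feb_ct(ct)
        if self.dual:
            b1, b2, b3 = self.feb_jac(inputs[1])
            s1 = self.fuse1(a1, b1)
            s2 = self.fuse2(a2, b2)
            s3 = self.fuse3(a3, b3)
        else:
            s1, s2, s3 = a1, a2, a3
        # encoder: two poolings align the three fused scales; bottleneck at /4
        x = self.enc1(s1)
        x = self.enc2(ag.concat([ag.maxpool2(x), s2]))
        x = self.enc3(ag.concat([ag.maxpool2(x), s3]))
        x = self.enc4(x)
        # decoder: upsample to each recorded skip shape, merge, convolve
        x = self.dec1(ag.concat([ag.upsample_trilinear(x, s2.shape[1:]), s2]))
        x = self.dec2(ag.concat([ag.upsample_trilinear(x, s1.shape[1:]), s1]))
        x = self.dec3(x)
        out = self.head(x)
        if self.config.final_activation == "sigmoid":
            out = ag.sigmoid(out)
        return out


class Unet3d(SynthesisModel):
    """Standard 3D U-net baseline: four resolution steps, two convs each."""

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        self.config = cfg
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 11]))
        base = cfg.feb_channels[0]
        chans = [base, 2 * base, 4 * base, 8 * base]
        k = cfg.kernel
        self.down = []
        c_in = 2
        for c in chans:
            self.down.append(
                (ConvBlock(c_in, c, k, rng, norm=False), ConvBlock(c, c, k, rng, norm=False))
            )
            c_in = c
        self.up = []
        for i in range(len(chans) - 2, -1, -1):
            c_skip, c_deep = chans[i], chans[i + 1]
            self.up.append(
                (
                    ConvBlock(c_deep + c_skip, c_skip, k, rng, norm=False),
                    ConvBlock(c_skip, c_skip, k, rng, norm=False),
                )
            )
        self._modules_flat = [m for pair in self.down + self.up for m in pair]
        self.head = Conv3d(chans[0], 1, 1, rng)

    def children(self):
        return self._modules_flat + [self.head]

    def state_arrays(self, prefix: str = ""):
        state = {}
        for i, m in enumerate(self.children()):
            state.update(m.state_arrays(f"{prefix}m{i}."))
        return state

    def load_state_arrays(self, state, prefix: str = "") -> None:
        for i, m in enumerate(self.children()):
            m.load_state_arrays(state, f"{prefix}m{i}.")

    def expected_inputs(self) -> int:
        return 2

    def forward_tensors(self, *inputs: Tensor) -> Tensor:
        if len(inputs) != 2:
            raise ValueError(f"unet forward expects 2 tensors, got {len(inputs)}")
        x = ag.concat(list(inputs))
        skips = []
        for i, (c1, c2) in enumerate(self.down):
            x = c2(c1(x))
            if i < len(self.down) - 1:
                skips.append(x)
                x = ag.maxpool2(x)
        for (c1, c2), skip in zip(self.up, reversed(skips)):
            x = ag.upsample_trilinear(x, skip.shape[1:])
            x = c2(c1(ag.concat([x, skip])))
        out = self.head(x)
        if self.config.final_activation == "sigmoid":
            out = ag.sigmoid(out)
        return out


def build_model(cfg: ModelConfig) -> SynthesisModel:
    """Instantiate the configured variant with seeded weights."""
    if cfg.variant == "unet_baseline":
        return Unet3d(cfg)
    return DPFN(cfg)


def forward(model: SynthesisModel, avg_ct: ImageVolume, jacobian: ImageVolume | None = None) -> VentilationMap:
    """Convenience wrapper: run the model on its expected inputs."""
    if model.expected_inputs() == 1:
        if jacobian is not None:
            raise ValueError("ct_only model takes a single input volume")
        return model.predict(avg_ct)
    if jacobian is None:
        raise ValueError(f"{model.config.variant} model needs both avg_ct and jacobian")
    return model.predict(avg_ct, jacobian)


def save_checkpoint(model: SynthesisModel, path) -> None:
    """Persist weights + config; loadable with :func:`load_checkpoint`."""
    state = model.state_arrays()
    cfg = asdict(model.config)
    np.savez(path, __config__=np.frombuffer(yaml.safe_dump(cfg).encode(), dtype=np.uint8), **state)


def load_checkpoint(path) -> SynthesisModel:
    with np.load(path) as data:
        cfg_yaml = bytes(data["__config__"]).decode()
        cfg_dict = yaml.safe_load(cfg_yaml)
        for key in ("input_shape", "feb_channels", "encoder_channels", "decoder_channels"):
            cfg_dict[key] = tuple(cfg_dict[key])
        cfg = ModelConfig(**cfg_dict)
        model = build_model(cfg)
        model.load_state_arrays({k: data[k] for k in data.files if k != "__config__"})
    return model
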