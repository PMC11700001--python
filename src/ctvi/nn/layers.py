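"""Layer modules and the Adam optimiser for the synthesis networks."""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor

__all__ = ["Module", "Conv3d", "BatchNorm3d", "ConvBlock", "Adam"]


class Module:
    """Base class: parameter collection, train/eval mode, state export."""

    def __init__(self) -> None:
        self.training = True

    def children(self) -> list["Module"]:
        out = []
        for v in self.__dict__.values():
            if isinstance(v, Module):
                out.append(v)
            elif isinstance(v, (list, tuple)):
                out.extend(m for m in v if isinstance(m, Module))
        return out

    def parameters(self) -> list[Tensor]:
        params = list(getattr(self, "_params", []))
        for child in self.children():
            params.extend(child.parameters())
        return params

    def train(self) -> "Module":
        self.training = True
        for c in self.children():
            c.train()
        return self

    def eval(self) -> "Module":
        self.training = False
        for c in self.children():
            c.eval()
        return self

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_arrays(self, prefix: str = "") -> dict[str, np.ndarray]:
        """Flat name -> array mapping of parameters and running statistics."""
        state: dict[str, np.ndarray] = {}
        for i, p in enumerate(getattr(self, "_params", [])):
            state[f"{prefix}p{i}"] = p.data
        for name, v in self.__dict__.items():
            if isinstance(v, Module):
                state.update(v.state_arrays(f"{prefix}{name}."))
            elif isinstance(v, (list, tuple)):
                for j, m in enumerate(v):
                    if isinstance(m, Module):
                        state.update(m.state_arrays(f"{prefix}{name}.{j}."))
        if hasattr(self, "running"):
            state[f"{prefix}run_mean"] = self.running["mean"]
            state[f"{prefix}run_var"] = self.running["var"]
        return state

    def load_state_arrays(self, state: dict[str, np.ndarray], prefix: str = "") -> None:
        for i, p in enumerate(getattr(self, "_params", [])):
            p.data = np.asarray(state[f"{prefix}p{i}"], dtype=np.float32)
        for name, v in self.__dict__.items():
            if isinstance(v, Module):
                v.load_state_arrays(state, f"{prefix}{name}.")
            elif isinstance(v, (list, tuple)):
                for j, m in enumerate(v):
                    if isinstance(m, Module):
                        m.load_state_arrays(state, f"{prefix}{name}.{j}.")
        if hasattr(self, "running"):
            self.running["mean"] = np.asarray(state[f"{prefix}run_mean"], dtype=np.float32)
            self.running["var"] = np.asarray(state[f"{prefix}run_var"], dtype=np.float32)


class Conv3d(Module):
    """3D convolution with same padding and He fan-in initialisation."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        fan_in = c_in * kernel**3
        std = np.sqrt(2.0 / fan_in)
        self.weight = Tensor(
            rng.normal(0.0, std, size=(c_out, c_in, kernel, kernel, kernel)),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(c_out), requires_grad=True)
        self._params = [self.weight, self.bias]

    def __call__(self, x: Tensor) -> Tensor:
        return ag.conv3d(x, self.weight, self.bias)


class BatchNorm3d(Module):
    def __init__(self, channels: int):
        super().__init__()
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self._params = [self.gamma, self.beta]
        self.running = {
            "mean": np.zeros(channels, dtype=np.float32),
            "var": np.ones(channels, dtype=np.float32),
        }

    def __call__(self, x: Tensor) -> Tensor:
        return ag.batch_norm(x, self.gamma, self.beta, self.running, self.training)


class ConvBlock(Module):
    """Convolution -> batch normalisation -> rectifier."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 norm: bool = True):
        super().__init__()
        self.conv = Conv3d(c_in, c_out, kernel, rng)
        self.norm = BatchNorm3d(c_out) if norm else None

    def __call__(self, x: Tensor) -> Tensor:
        y = self.conv(x)
        if self.norm is not None:
            y = self.norm(y)
        return ag.relu(y)


class Adam:
    """Adam with a per-step learning-rate multiplier (for decay schedules)."""

    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self, lr_factor: float = 1.0) -> None:
        self.t += 1
        lr = self.lr * lr_factor
        if lr == 0.0:
            return
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - lr * mhat / (np.sqrt(vhat) + self.eps)
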