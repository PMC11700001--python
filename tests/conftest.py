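"""Shared fixtures: small seeded phantoms and helper constructors.

Phantom generation is the expensive step, so noiseless cases are built once
per session at a modest grid and reused read-only by the unit tests; the
acceptance tests build their own cases at the sizes they state.
"""

from __future__ import annotations

import numpy as np
import pytest

from ctvi.jacobian import DisplacementField
from ctvi.phantom import PhantomSpec, make_phantom
from ctvi.volume import ImageVolume


@pytest.fixture(scope="session")
def noiseless_spec() -> PhantomSpec:
    return PhantomSpec(
        grid_shape=(48, 48, 48), noise_sd_hu=0.0, refvi_noise_sd=0.0, seed=42
    )


@pytest.fixture(scope="session")
def noiseless_case(noiseless_spec):
    return make_phantom(noiseless_spec)


@pytest.fixture(scope="session")
def blocked_case():
    # blocked-lobe invariants are stated at the phantom's default resolution:
    # the taper shell around the blocked sphere is a fixed fraction of its
    # radius, so coarser grids leak proportionally more residual ventilation
    spec = PhantomSpec(
        noise_sd_hu=0.0,
        refvi_noise_sd=0.0,
        blocked_lobe=True,
        seed=7,
    )
    return make_phantom(spec)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def linear_field(shape=(12, 12, 12), alpha=0.1, spacing=2.0, center=None) -> DisplacementField:
    """u = alpha * (x - c): constant-gradient field with det(I+grad u) = (1+alpha)^3."""
    if center is None:
        center = [(n - 1) / 2.0 for n in shape]
    idx = np.meshgrid(*[np.arange(n, dtype=np.float64) for n in shape], indexing="ij")
    comps = [alpha * (idx[a] - center[a]) * spacing for a in range(3)]
    return DisplacementField(*comps, spacing_mm=(spacing,) * 3)


def volume_from(values, spacing=1.0) -> ImageVolume:
    return ImageVolume(np.asarray(values, dtype=np.float64), (spacing,) * 3)
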