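"""Digital breathing-thorax phantom with known ventilation ground truth.

The phantom stands in for patient 4DCT + reference-ventilation pairs. It
builds an analytic exhale thorax (soft-tissue body, two ellipsoidal lungs of
aerated parenchyma with embedded vessel-like inclusions), a smooth breathing
displacement field, and derives everything else from first principles:

* ground-truth ventilation is the local fractional volume change
  ``det(I + grad u) - 1`` of the peak-exhale -> peak-inhale field, so the
  Jacobian surrogate is an unbiased estimator in the noiseless limit;
* phase-k HU follows mass conservation, ``1000 + HU_k = (1000 + HU_ex) / J_k``
  with ``J_k`` the phase-k volume ratio, so the density surrogate is
  recoverable too;
* the reference ventilation scan is the ground truth degraded by Gaussian
  blur, additive noise and (optionally) a central-airway hotspot, i.e. the
  artifact-bearing input the preprocessing chain must clean.

Breathing follows a raised-cosine trace ``a_k = (1 - cos(2 pi k / K)) / 2``
(free-breathing cine, phase 0 = peak exhale). A blocked lobe — the
tumor-obstructed-airway scenario — is emulated by smoothly tapering the
displacement to zero inside a sphere while leaving density intact: intact
anatomy, absent motion, near-zero true ventilation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import yaml
from scipy import ndimage

from .jacobian import DisplacementField, jacobian_map
from .volume import ImageVolume

__all__ = [
    "PhantomSpec",
    "PhantomCase",
    "CohortVariation",
    "make_phantom",
    "make_cohort",
    "emulate_refvi",
    "blocked_region_mask",
    "lung_mass",
]

_PATTERNS = ("uniform", "gravity_gradient", "bilobed")

# Exhale tissue model (HU): aerated parenchyma, soft tissue, air.
HU_LUNG = -850.0
HU_BODY = 0.0
HU_AIR = -1000.0
HU_VESSEL = -450.0


@dataclass
class PhantomSpec:
    """Parameters of one synthetic case.

    Geometry fields (``blocked_center``, ``hotspot_center``) are voxel-index
    coordinates as fractions of the grid so one spec scales across grid sizes.
    ``amplitude`` is the peak fractional linear expansion of the breathing
    field; 0.15 gives peak volume changes around 0.5, typical of deep
    free-breathing.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing_mm: float = 3.0
    n_phases: int = 10
    amplitude: float = 0.15
    ventilation_pattern: str = "gravity_gradient"
    blocked_lobe: bool = False
    blocked_center: tuple[float, float, float] = (0.32, 0.50, 0.35)
    blocked_radius: float = 0.11
    noise_sd_hu: float = 10.0
    refvi_noise_sd: float = 0.05
    refvi_blur_sigma_mm: float = 4.5
    hotspot: bool = False
    hotspot_center: tuple[float, float, float] = (0.50, 0.50, 0.72)
    hotspot_radius: float = 0.06
    seed: int = 0

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(s) for s in self.grid_shape)
        if any(s < 16 for s in self.grid_shape):
            raise ValueError(f"grid_shape must be >= 16 per axis, got {self.grid_shape}")
        if not 0.0 <= self.amplitude < 0.5:
            raise ValueError(f"amplitude must be in [0, 0.5), got {self.amplitude}")
        if self.n_phases < 2:
            raise ValueError(f"need >= 2 phases, got {self.n_phases}")
        if self.ventilation_pattern not in _PATTERNS:
            raise ValueError(
                f"unknown ventilation_pattern {self.ventilation_pattern!r}; "
                f"expected one of {_PATTERNS}"
            )
        if self.noise_sd_hu < 0 or self.refvi_noise_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.spacing_mm <= 0:
            raise ValueError("spacing_mm must be positive")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__ | {
                "grid_shape": list(self.grid_shape),
                "blocked_center": list(self.blocked_center),
                "hotspot_center": list(self.hotspot_center),
            }, fh)

    @classmethod
    def from_yaml(cls, path) -> "PhantomSpec":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        for key in ("grid_shape", "blocked_center", "hotspot_center"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass
class PhantomCase:
    """One synthetic patient: phases, true field, true ventilation, mask, RefVI."""

    phases: list[ImageVolume]
    dvf_truth: DisplacementField
    vent_truth: ImageVolume
    lung_mask: ImageVolume
    refvi: ImageVolume
    spec: PhantomSpec
    phase_masks: list[ImageVolume] | None = None
    phase_lung_fracs: list[ImageVolume] | None = None

    @property
    def exhale(self) -> ImageVolume:
        return self.phases[0]

    @property
    def peak_inhale_index(self) -> int:
        k = np.arange(self.spec.n_phases)
        return int(np.argmax((1 - np.cos(2 * np.pi * k / self.spec.n_phases)) / 2))

    @property
    def inhale(self) -> ImageVolume:
        return self.phases[self.peak_inhale_index]

    def interior_mask(self, erosion_voxels: int = 3) -> ImageVolume:
        """Lung mask eroded away from the pleural surface.

        The outermost shell of lung voxels mixes parenchyma and chest-wall
        signal (partial volume); interpolation-sensitive consistency checks
        evaluate on this interior region.
        """
        interior = ndimage.binary_erosion(
            self.lung_mask.values > 0, iterations=erosion_voxels
        )
        return self.lung_mask.with_values(interior.astype(np.uint8))


@dataclass
class CohortVariation:
    """Parameter ranges for cohort sampling (uniform draws per case)."""

    amplitude_range: tuple[float, float] = (0.15, 0.15)
    patterns: tuple[str, ...] = ("gravity_gradient",)
    blocked_prob: float = 0.0

    def __post_init__(self) -> None:
        lo, hi = self.amplitude_range
        if not (0.0 <= lo <= hi < 0.5):
            raise ValueError(f"amplitude_range must satisfy 0 <= lo <= hi < 0.5, got {self.amplitude_range}")
        if not 0.0 <= self.blocked_prob <= 1.0:
            raise ValueError("blocked_prob must be a probability")
        for p in self.patterns:
            if p not in _PATTERNS:
                raise ValueError(f"unknown pattern {p!r}")


# Ellipsoid geometry as fractions of the grid: (centre, semi-axes).
_BODY = ((0.50, 0.50, 0.50), (0.44, 0.40, 0.47))
_LEFT = ((0.32, 0.50, 0.50), (0.14, 0.20, 0.28))
_RIGHT = ((0.68, 0.50, 0.50), (0.14, 0.20, 0.28))


def _rho(points: np.ndarray, shape, center_frac, semi_frac) -> np.ndarray:
    """Normalised ellipsoidal radius (1 on the surface) at index coords."""
    return np.sqrt(
        sum(
            ((points[a] - center_frac[a] * shape[a]) / (semi_frac[a] * shape[a])) ** 2
            for a in range(3)
        )
    )


def _edge(rho: np.ndarray, shape, semi_frac, width_vox: float) -> np.ndarray:
    """1 inside the surface, cosine transition to 0 over ~width_vox voxels."""
    w = width_vox / (min(semi_frac) * min(shape))
    t = np.clip((rho - 1.0) / w + 0.5, 0.0, 1.0)
    return 0.5 * (1.0 + np.cos(np.pi * t))


def _vessel_params(spec: PhantomSpec) -> list[tuple[tuple, float]]:
    """Seeded vessel-like Gaussian inclusions near each hilum (frac coords)."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 17]))
    vessels = []
    # At ~3 mm voxels only the central vessels resolve; a handful of thin
    # Gaussian cords per lung keeps the visible vascular fraction near the
    # 2-3% seen in clinical lung CT (smaller vessels vanish into partial
    # volume, which is also why their peak is -450 HU rather than blood).
    for cx in (0.32, 0.68):
        for _ in range(5):
            c = (
                cx + rng.uniform(-0.07, 0.07),
                0.5 + rng.uniform(-0.10, 0.10),
                0.5 + rng.uniform(-0.16, 0.16),
            )
            sigma_frac = rng.uniform(0.008, 0.014)
            vessels.append((c, sigma_frac))
    return vessels


def _template_hu(points: np.ndarray, shape, vessels) -> np.ndarray:
    """Smooth exhale HU at (possibly fractional) index coordinates.

    Tissue interfaces ramp over ~1 voxel — the point-spread partial-volume
    softening a real scanner produces — so trilinear sampling of warped
    anatomy carries no boundary bias.
    """
    body = _edge(_rho(points, shape, *_BODY), shape, _BODY[1], 2.0)
    left = _edge(_rho(points, shape, *_LEFT), shape, _LEFT[1], 1.0)
    right = _edge(_rho(points, shape, *_RIGHT), shape, _RIGHT[1], 1.0)
    hu = HU_AIR + (HU_BODY - HU_AIR) * body + (HU_LUNG - HU_BODY) * (left + right)
    amp = HU_VESSEL - HU_LUNG
    for c_frac, sigma_frac in vessels:
        d2 = sum(
            ((points[a] - c_frac[a] * shape[a]) / (sigma_frac * shape[a])) ** 2
            for a in range(3)
        )
        hu = hu + amp * np.exp(-0.5 * d2) * (left + right)
    return hu


def _geometry(spec: PhantomSpec):
    """Exhale HU grid, crisp lung masks and per-lung centres (index coords)."""
    shape = spec.grid_shape
    grid = np.stack(
        np.meshgrid(*[np.arange(n, dtype=np.float64) for n in shape], indexing="ij")
    )
    vessels = _vessel_params(spec)
    hu = _template_hu(grid, shape, vessels)
    left = _rho(grid, shape, *_LEFT) <= 1.0
    right = _rho(grid, shape, *_RIGHT) <= 1.0
    lungs = left | right
    centers = {
        "left": np.array(_LEFT[0]) * np.array(shape),
        "right": np.array(_RIGHT[0]) * np.array(shape),
    }
    return hu, lungs, left, right, centers, vessels


def _pattern_modulation(spec: PhantomSpec, shape, left: np.ndarray) -> np.ndarray:
    if spec.ventilation_pattern == "uniform":
        return np.ones(shape)
    if spec.ventilation_pattern == "gravity_gradient":
        # Dependent (posterior, +y) lung ventilates more when supine; the
        # ramp spans the lung's own anteroposterior extent so the resulting
        # ventral-dorsal ventilation ratio lands in the physiological 2-3x.
        c, s = _LEFT[0][1], _LEFT[1][1]
        y0, y1 = (c - s) * shape[1], (c + s) * shape[1]
        y = np.clip((np.arange(shape[1], dtype=np.float64) - y0) / (y1 - y0), 0.0, 1.0)
        return (0.4 + 0.6 * y)[None, :, None] * np.ones(shape)
    # bilobed: left lung at reduced amplitude, smoothed across the midline.
    mod = np.where(left, 0.5, 1.0)
    return ndimage.gaussian_filter(mod.astype(np.float64), sigma=2.0)


def _smooth_envelope(mask: np.ndarray, margin_vox: float) -> np.ndarray:
    """1 inside the mask, cosine falloff to 0 within ``margin_vox`` outside."""
    d_out = ndimage.distance_transform_edt(~mask)
    t = np.clip(d_out / margin_vox, 0.0, 1.0)
    env = 0.5 * (1.0 + np.cos(np.pi * t))
    # Gentle smoothing carries the falloff a little inside the boundary,
    # avoiding a gradient kink at the pleural surface.
    return ndimage.gaussian_filter(env, sigma=2.0)


def _block_factor(spec: PhantomSpec, shape) -> np.ndarray:
    """0 inside the blocked sphere, cosine ramp to 1 over 40% extra radius."""
    idx = np.meshgrid(*[np.arange(n, dtype=np.float64) for n in shape], indexing="ij")
    c = [spec.blocked_center[a] * shape[a] for a in range(3)]
    r0 = spec.blocked_radius * min(shape)
    d = np.sqrt(sum((idx[a] - c[a]) ** 2 for a in range(3)))
    t = np.clip((d - r0) / (0.4 * r0), 0.0, 1.0)
    return 0.5 * (1.0 - np.cos(np.pi * t))


def _displacement(spec: PhantomSpec, lungs, left, centers) -> DisplacementField:
    """Breathing field at full amplitude: modulated per-lung radial expansion."""
    shape = spec.grid_shape
    margin = max(3.0, min(shape) / 10.0)
    mod = _pattern_modulation(spec, shape, left)
    idx = np.meshgrid(*[np.arange(n, dtype=np.float64) for n in shape], indexing="ij")
    u = [np.zeros(shape) for _ in range(3)]
    for name, lung_mask in (("left", left), ("right", ~left & lungs)):
        env = _smooth_envelope(lung_mask, margin)
        c = centers[name]
        for a in range(3):
            u[a] += spec.amplitude * mod * env * (idx[a] - c[a]) * spec.spacing_mm
    if spec.blocked_lobe:
        block = _block_factor(spec, shape)
        for a in range(3):
            u[a] *= block
    sp = (spec.spacing_mm,) * 3
    return DisplacementField(u[0], u[1], u[2], spacing_mm=sp)


def _phase_amplitudes(n_phases: int) -> np.ndarray:
    k = np.arange(n_phases)
    return (1.0 - np.cos(2.0 * np.pi * k / n_phases)) / 2.0


def _invert_map(u_index: list[np.ndarray], n_iter: int = 8) -> np.ndarray:
    """Fixed-point inverse of ``phi(x) = x + u(x)`` on the grid (index coords)."""
    shape = u_index[0].shape
    grid = np.stack(np.meshgrid(*[np.arange(n, dtype=np.float64) for n in shape], indexing="ij"))
    x = grid.copy()
    u_arr = np.stack(u_index)
    for _ in range(n_iter):
        disp = np.stack([
            ndimage.map_coordinates(u_arr[a], x, order=1, mode="nearest")
            for a in range(3)
        ])
        x = grid - disp
    return x


def emulate_refvi(
    vent_truth: ImageVolume,
    lung_mask: ImageVolume,
    spec: PhantomSpec,
    rng: np.random.Generator,
) -> ImageVolume:
    """Degrade true ventilation into an emulated reference scan.

    Gaussian blur (scanner resolution), additive Gaussian noise, an optional
    airway hotspot brighter than the 95th percentile of the clean map, then a
    clamp to non-negative values.
    """
    if spec.refvi_noise_sd < 0:
        raise ValueError("refvi_noise_sd must be >= 0")
    values = vent_truth.values.astype(np.float64)
    if spec.refvi_blur_sigma_mm > 0:
        sigma_vox = [spec.refvi_blur_sigma_mm / s for s in vent_truth.spacing_mm]
        values = ndimage.gaussian_filter(values, sigma=sigma_vox)
    if spec.refvi_noise_sd > 0:
        values = values + rng.normal(0.0, spec.refvi_noise_sd, size=values.shape)
    if spec.hotspot:
        shape = values.shape
        idx = np.meshgrid(*[np.arange(n, dtype=np.float64) for n in shape], indexing="ij")
        c = [spec.hotspot_center[a] * shape[a] for a in range(3)]
        r = spec.hotspot_radius * min(shape)
        d2 = sum((idx[a] - c[a]) ** 2 for a in range(3)) / r**2
        clean = vent_truth.values[lung_mask.values > 0]
        peak = 2.0 * float(np.percentile(clean, 95)) if clean.size else 1.0
        values = values + peak * np.exp(-0.5 * d2 * 4.0)
    return vent_truth.with_values(np.maximum(values, 0.0))


def make_phantom(spec: PhantomSpec) -> PhantomCase:
    """Generate one synthetic case; identical specs give bit-identical cases."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 29]))
    hu_ex, lungs, left, right, centers, vessels = _geometry(spec)
    sp = (spec.spacing_mm,) * 3
    if spec.blocked_lobe:
        c_idx = tuple(int(round(spec.blocked_center[a] * spec.grid_shape[a])) for a in range(3))
        if not lungs[c_idx]:
            raise ValueError(f"blocked_lobe centre {c_idx} lies outside the lung region")
    u_full = _displacement(spec, lungs, left, centers)
    a_k = _phase_amplitudes(spec.n_phases)
    a_peak = float(a_k.max())
    dvf_truth = u_full.scaled(a_peak)
    jac_truth = jacobian_map(dvf_truth).values + 1.0
    if np.any(jac_truth <= 0):
        raise ValueError(
            f"amplitude {spec.amplitude} makes the deformation non-invertible "
            f"(min det = {jac_truth.min():.4f})"
        )
    lung_mask = ImageVolume(lungs.astype(np.uint8), sp)
    vent_truth = ImageVolume(np.where(lungs, jac_truth - 1.0, 0.0), sp)

    phases: list[ImageVolume] = []
    phase_masks: list[ImageVolume] = []
    phase_fracs: list[ImageVolume] = []
    grid = np.stack(
        np.meshgrid(*[np.arange(n, dtype=np.float64) for n in spec.grid_shape], indexing="ij")
    )
    u_index = [comp / spec.spacing_mm for comp in (u_full.u_x, u_full.u_y, u_full.u_z)]
    field_is_zero = all(not np.any(c) for c in u_index)
    for k, a in enumerate(a_k):
        if a == 0.0 or field_is_zero:
            hu_k = hu_ex.copy()
            mask_k = lungs.copy()
            x_inv = grid
        else:
            jac_k = jacobian_map(u_full.scaled(a)).values + 1.0
            if np.any(jac_k <= 0):
                raise ValueError(f"phase {k} deformation is non-invertible")
            x_inv = _invert_map([a * comp for comp in u_index])
            # Mass conservation: 1000 + HU_k = (1000 + HU_ex) / J_k, the
            # exhale template evaluated analytically and the volume ratio
            # interpolated, both at the material point x = phi_k^{-1}(y).
            mass_ex = 1000.0 + _template_hu(x_inv, spec.grid_shape, vessels)
            hu_k = (
                mass_ex
                / ndimage.map_coordinates(jac_k, x_inv, order=1, mode="nearest")
                - 1000.0
            )
            mask_k = (
                _rho(x_inv, spec.grid_shape, *_LEFT) <= 1.0
            ) | (_rho(x_inv, spec.grid_shape, *_RIGHT) <= 1.0)
        if spec.noise_sd_hu > 0:
            # clamp at the air floor: nothing images less dense than air
            hu_k = np.maximum(
                hu_k + rng.normal(0.0, spec.noise_sd_hu, size=hu_k.shape), -1000.0
            )
        # Voxel lung occupancy: a 1-voxel-wide partial-volume ramp at each
        # lung surface, evaluated at the material point. Mass accounting with
        # these fractional weights is a proper quadrature of the lung-mass
        # integral; crisp masks alias the moving boundary.
        frac_k = _edge(_rho(x_inv, spec.grid_shape, *_LEFT), spec.grid_shape, _LEFT[1], 1.0)
        frac_k = frac_k + _edge(_rho(x_inv, spec.grid_shape, *_RIGHT), spec.grid_shape, _RIGHT[1], 1.0)
        phases.append(ImageVolume(hu_k, sp))
        phase_masks.append(ImageVolume(mask_k.astype(np.uint8), sp))
        phase_fracs.append(ImageVolume(np.clip(frac_k, 0.0, 1.0), sp))

    refvi = emulate_refvi(vent_truth, lung_mask, spec, rng)
    return PhantomCase(
        phases=phases,
        dvf_truth=dvf_truth,
        vent_truth=vent_truth,
        lung_mask=lung_mask,
        refvi=refvi,
        spec=spec,
        phase_masks=phase_masks,
        phase_lung_fracs=phase_fracs,
    )


def blocked_region_mask(case: PhantomCase) -> ImageVolume:
    """Binary mask of the blocked-lobe sphere (within the lung)."""
    spec = case.spec
    if not spec.blocked_lobe:
        raise ValueError("phantom was generated without a blocked lobe")
    shape = spec.grid_shape
    idx = np.meshgrid(*[np.arange(n, dtype=np.float64) for n in shape], indexing="ij")
    c = [spec.blocked_center[a] * shape[a] for a in range(3)]
    r0 = spec.blocked_radius * min(shape)
    d = np.sqrt(sum((idx[a] - c[a]) ** 2 for a in range(3)))
    blocked = (d <= r0) & (case.lung_mask.values > 0)
    return case.lung_mask.with_values(blocked.astype(np.uint8))


def lung_mass(phase_hu: ImageVolume, lung_frac: ImageVolume) -> float:
    """Total lung tissue+air mass surrogate ``sum frac * (1000 + HU)``.

    ``1000 + HU`` is proportional to physical density; with the breathing
    deformation mass-conserving, this sum is a per-phase invariant (up to
    discretisation) and the phantom's principal physical self-check.
    """
    return float(np.sum(lung_frac.values * (1000.0 + phase_hu.values)))


def make_cohort(
    n_cases: int,
    base_spec: PhantomSpec | None = None,
    variation: CohortVariation | None = None,
    seed: int = 0,
) -> list[PhantomCase]:
    """Generate a reproducible cohort of phantoms.

    Per-case amplitude, ventilation pattern and blocked-lobe status are drawn
    from ``variation`` using one seeded stream; each case then gets its own
    derived seed, so cohorts are deterministic given ``seed`` and element-wise
    identical across repeated calls.
    """
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    base_spec = base_spec or PhantomSpec()
    variation = variation or CohortVariation()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    cases = []
    for i in range(n_cases):
        lo, hi = variation.amplitude_range
        amplitude = float(rng.uniform(lo, hi)) if hi > lo else lo
        pattern = variation.patterns[int(rng.integers(len(variation.patterns)))]
        blocked = bool(rng.random() < variation.blocked_prob)
        case_seed = int(rng.integers(0, 2**31 - 1))
        spec_i = replace(
            base_spec,
            amplitude=amplitude,
            ventilation_pattern=pattern,
            blocked_lobe=blocked,
            seed=case_seed,
        )
        try:
            cases.append(make_phantom(spec_i))
        except ValueError as exc:
            raise ValueError(f"case {i}: {exc}") from exc
    return cases
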