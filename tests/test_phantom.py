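"""Physical and statistical invariants of the breathing-thorax phantom."""

import numpy as np
import pytest

from ctvi.jacobian import jacobian_map
from ctvi.phantom import (
    CohortVariation,
    PhantomSpec,
    blocked_region_mask,
    emulate_refvi,
    lung_mass,
    make_cohort,
    make_phantom,
)


class TestSpecValidation:
    def test_rejects_bad_geometry_and_parameters(self):
        with pytest.raises(ValueError, match="grid_shape"):
            PhantomSpec(grid_shape=(8, 32, 32))
        with pytest.raises(ValueError, match="amplitude"):
            PhantomSpec(amplitude=0.6)
        with pytest.raises(ValueError, match="phases"):
            PhantomSpec(n_phases=1)
        with pytest.raises(ValueError, match="pattern"):
            PhantomSpec(ventilation_pattern="spiral")

    def test_yaml_roundtrip(self, tmp_path):
        spec = PhantomSpec(grid_shape=(24, 24, 24), amplitude=0.12, seed=5)
        path = tmp_path / "spec.yaml"
        spec.to_yaml(path)
        assert PhantomSpec.from_yaml(path) == spec

    def test_blocked_lobe_outside_lung_rejected(self):
        spec = PhantomSpec(
            grid_shape=(32, 32, 32),
            noise_sd_hu=0.0,
            blocked_lobe=True,
            blocked_center=(0.02, 0.02, 0.02),
        )
        with pytest.raises(ValueError, match="outside the lung"):
            make_phantom(spec)


class TestMakePhantom:
    def test_zero_amplitude_freezes_everything(self):
        spec = PhantomSpec(
            grid_shape=(32, 32, 32), amplitude=0.0, noise_sd_hu=0.0, refvi_noise_sd=0.0
        )
        case = make_phantom(spec)
        for phase in case.phases[1:]:
            np.testing.assert_array_equal(phase.values, case.phases[0].values)
        assert np.all(case.dvf_truth.magnitude() == 0.0)
        assert np.all(case.vent_truth.values[case.lung_mask.values > 0] == 0.0)

    def test_vent_truth_zero_outside_lung_and_above_minus_one(self, noiseless_case):
        vent = noiseless_case.vent_truth.values
        outside = noiseless_case.lung_mask.values == 0
        assert np.all(vent[outside] == 0.0)
        assert np.all(vent > -1.0)

    def test_vent_truth_consistent_with_numeric_jacobian_of_truth_field(self, noiseless_case):
        jac = jacobian_map(noiseless_case.dvf_truth).values
        in_lung = noiseless_case.lung_mask.values > 0
        diff = np.abs(noiseless_case.vent_truth.values - jac)[in_lung]
        assert diff.max() < 1e-3

    def test_mass_conserved_across_phases(self, noiseless_case):
        masses = np.array(
            [
                lung_mass(p, f)
                for p, f in zip(noiseless_case.phases, noiseless_case.phase_lung_fracs)
            ]
        )
        assert (masses.max() - masses.min()) / masses.mean() < 0.01

    def test_identical_specs_are_bit_identical(self, noiseless_spec, noiseless_case):
        other = make_phantom(
            PhantomSpec(**{**noiseless_spec.__dict__})
        )
        for a, b in zip(noiseless_case.phases, other.phases):
            np.testing.assert_array_equal(a.values, b.values)
        np.testing.assert_array_equal(noiseless_case.refvi.values, other.refvi.values)
        np.testing.assert_array_equal(noiseless_case.dvf_truth.u_x, other.dvf_truth.u_x)

    def test_all_volumes_share_grid(self, noiseless_case):
        shapes = {
            tuple(v.shape)
            for v in (
                noiseless_case.vent_truth,
                noiseless_case.lung_mask,
                noiseless_case.refvi,
                *noiseless_case.phases,
            )
        }
        assert shapes == {tuple(noiseless_case.spec.grid_shape)}

    def test_amplitude_outside_invariant_range_rejected(self):
        with pytest.raises(ValueError, match="amplitude"):
            PhantomSpec(grid_shape=(32, 32, 32), amplitude=0.5)


class TestBlockedLobe:
    def test_motion_absent_but_density_intact(self, blocked_case):
        blocked = blocked_region_mask(blocked_case).values > 0
        lung = blocked_case.lung_mask.values > 0
        mag = blocked_case.dvf_truth.magnitude()
        assert mag[blocked].mean() < 0.05 * mag[lung].mean()
        # anatomy unchanged: the exhale CT equals that of the unblocked twin
        # (same seed, blockage off) voxel for voxel
        from dataclasses import replace

        twin = make_phantom(replace(blocked_case.spec, blocked_lobe=False))
        np.testing.assert_array_equal(
            blocked_case.exhale.values, twin.exhale.values
        )

    def test_ventilation_suppressed_in_blocked_region(self, blocked_case):
        blocked = blocked_region_mask(blocked_case).values > 0
        lung = blocked_case.lung_mask.values > 0
        vent = blocked_case.vent_truth.values
        assert vent[blocked].mean() < 0.05 * vent[lung & ~blocked].mean()


class TestEmulateRefvi:
    def test_identity_configuration_returns_truth(self, noiseless_case):
        spec = PhantomSpec(
            grid_shape=noiseless_case.spec.grid_shape,
            refvi_noise_sd=0.0,
            refvi_blur_sigma_mm=0.0,
            hotspot=False,
        )
        rng = np.random.default_rng(0)
        out = emulate_refvi(noiseless_case.vent_truth, noiseless_case.lung_mask, spec, rng)
        np.testing.assert_array_equal(out.values, noiseless_case.vent_truth.values)

    def test_hotspot_contains_the_maximum(self, noiseless_case):
        spec = PhantomSpec(
            grid_shape=noiseless_case.spec.grid_shape,
            refvi_noise_sd=0.0,
            refvi_blur_sigma_mm=0.0,
            hotspot=True,
        )
        rng = np.random.default_rng(0)
        out = emulate_refvi(noiseless_case.vent_truth, noiseless_case.lung_mask, spec, rng)
        peak = np.unravel_index(np.argmax(out.values), out.values.shape)
        shape = np.array(out.values.shape)
        center = np.array(spec.hotspot_center) * shape
        radius = spec.hotspot_radius * shape.min()
        assert np.linalg.norm(peak - center) <= radius + 1.0
        clean_p95 = np.percentile(
            noiseless_case.vent_truth.values[noiseless_case.lung_mask.values > 0], 95
        )
        assert out.values[peak] > clean_p95

    def test_noise_sd_recovered_from_residuals(self, noiseless_case):
        sd = 0.05
        spec = PhantomSpec(
            grid_shape=noiseless_case.spec.grid_shape,
            refvi_noise_sd=sd,
            refvi_blur_sigma_mm=0.0,
            hotspot=False,
        )
        rng = np.random.default_rng(1)
        out = emulate_refvi(noiseless_case.vent_truth, noiseless_case.lung_mask, spec, rng)
        # measure away from the non-negativity clamp: voxels where truth is
        # high enough that truth + noise never clips at zero
        strong = noiseless_case.vent_truth.values > 4 * sd
        residual = (out.values - noiseless_case.vent_truth.values)[strong]
        assert abs(residual.std() - sd) < 0.1 * sd

    def test_negative_output_never_produced(self, noiseless_case):
        spec = PhantomSpec(
            grid_shape=noiseless_case.spec.grid_shape, refvi_noise_sd=0.5
        )
        out = emulate_refvi(
            noiseless_case.vent_truth, noiseless_case.lung_mask, spec,
            np.random.default_rng(2),
        )
        assert out.values.min() >= 0.0


class TestMakeCohort:
    def test_zero_variation_differs_only_in_noise(self):
        base = PhantomSpec(grid_shape=(24, 24, 24), noise_sd_hu=5.0, refvi_noise_sd=0.02)
        cohort = make_cohort(3, base, CohortVariation(), seed=11)
        assert len(cohort) == 3
        specs = [c.spec for c in cohort]
        assert len({s.amplitude for s in specs}) == 1
        assert len({s.ventilation_pattern for s in specs}) == 1
        # different seeds -> different noise realisations
        assert not np.array_equal(cohort[0].phases[1].values, cohort[1].phases[1].values)

    def test_same_seed_gives_elementwise_identical_cohorts(self):
        base = PhantomSpec(grid_shape=(24, 24, 24), noise_sd_hu=3.0)
        a = make_cohort(3, base, CohortVariation(amplitude_range=(0.1, 0.2)), seed=5)
        b = make_cohort(3, base, CohortVariation(amplitude_range=(0.1, 0.2)), seed=5)
        for ca, cb in zip(a, b):
            assert ca.spec == cb.spec
            np.testing.assert_array_equal(ca.refvi.values, cb.refvi.values)

    def test_blockage_draws_match_rng_replay(self):
        base = PhantomSpec(grid_shape=(24, 24, 24), noise_sd_hu=0.0, refvi_noise_sd=0.0)
        variation = CohortVariation(blocked_prob=0.5)
        cohort = make_cohort(12, base, variation, seed=7)
        n_blocked = sum(c.spec.blocked_lobe for c in cohort)
        # replay the exact seeded stream the generator uses
        rng = np.random.default_rng(np.random.SeedSequence([7, 101]))
        expected = 0
        for _ in range(12):
            _ = variation.patterns[int(rng.integers(len(variation.patterns)))]
            expected += rng.random() < variation.blocked_prob
            _ = int(rng.integers(0, 2**31 - 1))
        assert n_blocked == expected

    def test_case_errors_carry_the_case_index(self):
        base = PhantomSpec(grid_shape=(24, 24, 24))
        with pytest.raises(ValueError, match="n_cases"):
            make_cohort(0, base)
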