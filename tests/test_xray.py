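"""Material constants, mixture rule, voxelisation, imaging chain, profiles."""

import numpy as np
import pytest

from granulekit.builder import Ingredient, ModelInstanceSet, PlacementSet, SphereSDF
from granulekit.structures import BeadModel
from granulekit.util import DALTON_G, PROTEIN_DENSITY
from granulekit.xray import (
    LacVolume,
    MixtureSpec,
    ProjectionOperator,
    element_mac,
    material_mac,
    mixture_lac,
    protein_mac,
    protein_solution_lac,
    radial_profile,
    read_mrc,
    simulate_tomogram,
    voxelize,
    water_mac,
    write_mrc,
)


class TestMaterialMac:
    def test_single_element_material_equals_element_value(self):
        got = material_mac({"C": 1})
        assert got.mac == pytest.approx(element_mac("C"))

    def test_unknown_element_raises(self):
        with pytest.raises(KeyError):
            material_mac({"Xx": 1})

    def test_energy_outside_window_raises(self):
        with pytest.raises(ValueError):
            element_mac("C", energy_ev=100.0)

    def test_water_less_absorbing_than_organics_in_window(self):
        # the water-window contrast mechanism
        assert water_mac().mac < 0.2 * protein_mac().mac


class TestMixture:
    MACS = {"protein": 7971.0, "lipid": 8740.0, "water": 1114.2}

    def test_pure_water(self):
        spec = MixtureSpec(0.0, 0.0, 1.0)
        got = mixture_lac(spec, self.MACS, voxel_density=1.0)
        assert got == pytest.approx(1114.2e-4)

    def test_fifty_fifty_is_arithmetic_mean(self):
        spec = MixtureSpec(0.5, 0.0, 0.5)
        got = mixture_lac(spec, self.MACS, voxel_density=1.1)
        assert got == pytest.approx(1.1 * 0.5 * (7971.0 + 1114.2) * 1e-4)

    def test_three_component_brute_force(self):
        w = (0.25, 0.35, 0.40)
        spec = MixtureSpec(*w)
        rho = 1.07
        expected = rho * sum(wi * m for wi, m in zip(w, self.MACS.values())) * 1e-4
        assert mixture_lac(spec, self.MACS, rho) == pytest.approx(expected)

    def test_mixture_bounded_by_components(self):
        spec = MixtureSpec(0.3, 0.3, 0.4)
        got = mixture_lac(spec, self.MACS, 1.0) / 1e-4
        assert min(self.MACS.values()) <= got <= max(self.MACS.values())

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            MixtureSpec(0.5, 0.2, 0.2)


def empty_model():
    return ModelInstanceSet()


class TestVoxelize:
    def test_empty_model_is_uniform_water(self):
        vol = voxelize(empty_model(), (5, 5, 5))
        water_lac = water_mac().mac * 1e-4
        assert np.allclose(vol.data, water_lac)

    def test_single_bead_mass_deposited(self):
        model = ModelInstanceSet()
        mw = 1e7  # large but still sub-voxel in excluded volume
        beads = BeadModel(np.zeros((1, 3)), 17.0, np.array([mw]))
        model.add(
            Ingredient("x", beads, mw),
            PlacementSet("x", np.zeros((1, 3)), np.array([[1.0, 0, 0, 0]])),
        )
        vol = voxelize(model, (5, 5, 5), voxel_nm=37.42)
        voxel_cm3 = (37.42e-7) ** 3
        density = mw * DALTON_G / voxel_cm3
        from granulekit.xray import mac_from_weights
        from granulekit.structures import average_protein_mac_weights

        mac = mac_from_weights(average_protein_mac_weights())
        water_part = (voxel_cm3 - mw * DALTON_G / PROTEIN_DENSITY) / voxel_cm3
        expected = (density * mac + water_part * water_mac().mac) * 1e-4
        # bead sits at a voxel centre: all mass in one voxel
        assert vol.data[2, 2, 2] == pytest.approx(expected, rel=1e-9)

    def test_total_mass_conservation_guard(self):
        model = ModelInstanceSet()
        beads = BeadModel(np.zeros((1, 3)), 17.0, np.array([1e6]))
        model.add(
            Ingredient("x", beads, 1e6),
            PlacementSet(
                "x", np.array([[500.0, 0.0, 0.0]]), np.array([[1.0, 0, 0, 0]])
            ),
        )
        with pytest.raises(ValueError, match="grid too small"):
            voxelize(model, (5, 5, 5))

    def test_crystal_voxel_matches_closed_form(self):
        from granulekit.synthetic import PhantomSpec, generate_phantom
        from granulekit.xray import voxelize as vox

        spec = PhantomSpec(
            vesicle_diameter=180.0, crystal_diameter=120.0, maturation_step=6,
            box_shape=(9, 9, 9),
        )
        model, analytic = generate_phantom(spec, seed=0)
        built = vox(model, spec.box_shape, voxel_nm=spec.voxel_nm)
        c = 4
        assert built.data[c, c, c] == pytest.approx(analytic.data[c, c, c], rel=0.05)


class TestImagingChain:
    def sphere_volume(self, n=81, ny=5, radius_vox=12, value=0.6, background=0.2):
        data = np.full((n, ny, n), background)
        idx = np.indices((n, n))
        r = np.hypot(idx[0] - n // 2, idx[1] - n // 2)
        for iy in range(ny):
            sl = data[:, iy, :]
            sl[r <= radius_vox] = value
        return LacVolume(data, voxel_nm=37.42)

    def test_clean_fbp_recovers_input(self):
        from scipy.ndimage import gaussian_filter

        # band-limited phantom: a sharp edge cannot be represented on the
        # reconstruction grid, so fidelity is measured on a smoothed sphere
        vol = self.sphere_volume()
        vol = LacVolume(gaussian_filter(vol.data, (1.0, 0.0, 1.0)), vol.voxel_nm)
        op = ProjectionOperator(psf_fwhm_nm=1e-3, n_angles=181)
        recon = simulate_tomogram(vol, op, noise=False)
        n = vol.shape[0]
        idx = np.indices((n, n))
        inside = np.hypot(idx[0] - n // 2, idx[1] - n // 2) < n // 2 - 4
        a = vol.data[:, 2, :][inside]
        b = recon.data[:, 2, :][inside]
        assert np.linalg.norm(a - b) / np.linalg.norm(a) < 0.05

    def test_noise_does_not_bias_uniform_phantom(self):
        n = 61
        vol = LacVolume(np.full((n, 3, n), 0.3), voxel_nm=37.42)
        op = ProjectionOperator(psf_fwhm_nm=1e-3, replicates=6)
        recon = simulate_tomogram(vol, op, seed=5)
        idx = np.indices((n, n))
        inside = np.hypot(idx[0] - n // 2, idx[1] - n // 2) < n // 4
        center_mean = recon.data[:, 1, :][inside].mean()
        assert center_mean == pytest.approx(0.3, abs=0.01)

    def test_replicate_averaging_reduces_noise(self):
        n = 61
        vol = LacVolume(np.full((n, 3, n), 0.3), voxel_nm=37.42)
        idx = np.indices((n, n))
        inside = np.hypot(idx[0] - n // 2, idx[1] - n // 2) < n // 4

        def sigma(reps, seed):
            op = ProjectionOperator(psf_fwhm_nm=1e-3, replicates=reps,
                                    jitter_voxels=0.0)
            recon = simulate_tomogram(vol, op, seed=seed)
            return recon.data[:, 1, :][inside].std()

        s1 = np.mean([sigma(1, s) for s in range(3)])
        s9 = np.mean([sigma(9, s) for s in range(3)])
        assert s1 / s9 == pytest.approx(3.0, rel=0.35)

    def test_projection_linearity(self):
        # physical phantoms (water-positive backgrounds keep the LAC >= 0
        # clamp inactive): reconstruction of a sum is the sum of recons
        a = self.sphere_volume(value=0.5, background=0.2)
        b = self.sphere_volume(value=0.3, background=0.15, radius_vox=20)
        op = ProjectionOperator(n_angles=91)
        ra = simulate_tomogram(a, op, noise=False)
        rb = simulate_tomogram(b, op, noise=False)
        combined = LacVolume(a.data + b.data, voxel_nm=a.voxel_nm)
        rc = simulate_tomogram(combined, op, noise=False)
        assert np.allclose(rc.data, ra.data + rb.data, atol=1e-9)

    def test_zero_photon_budget_rejected(self):
        with pytest.raises(ValueError):
            ProjectionOperator(photons_per_pixel=0.0)


class TestRadialProfile:
    def test_flat_image_gives_flat_profile(self):
        prof = radial_profile(np.full((21, 21), 0.4), center=(10, 10))
        assert np.allclose(prof.values[np.isfinite(prof.values)], 0.4)

    def test_projected_sphere_matches_abel_closed_form(self):
        # chord length through a sphere: 2*sqrt(R^2 - r^2)
        n, R_vox, mu = 301, 90.0, 0.7
        idx = np.indices((n, n, 1))
        voxel_nm = 10.0
        # supersampled projection of a solid sphere along z
        zmax = np.sqrt(np.clip(R_vox**2 - ((idx[0] - n // 2) ** 2 + (idx[1] - n // 2) ** 2), 0, None))
        projection = (mu * 2.0 * zmax[:, :, 0]) * (voxel_nm * 1e-3)  # um^-1 * um
        prof = radial_profile(projection, voxel_nm=voxel_nm, center=(n // 2, n // 2))
        r_nm = prof.radii_nm
        sel = r_nm < 0.8 * R_vox * voxel_nm
        expected = (
            mu * 2.0 * np.sqrt(R_vox**2 - (r_nm[sel] / voxel_nm) ** 2) * voxel_nm * 1e-3
        )
        assert np.allclose(prof.values[sel], expected, rtol=0.02)

    def test_rotation_invariance(self):
        rng = np.random.default_rng(0)
        img = rng.random((41, 41))
        img[20, 20] = 5.0
        p1 = radial_profile(img)
        p2 = radial_profile(np.rot90(img))
        assert np.allclose(p1.values, p2.values, equal_nan=True)

    def test_center_defaults_to_brightest_pixel(self):
        img = np.zeros((15, 15))
        img[4, 11] = 1.0
        prof = radial_profile(img)
        assert prof.center == (4, 11)


class TestMrcRoundtrip:
    def test_volume_roundtrip(self, tmp_path, rng):
        vol = LacVolume(rng.random((8, 6, 10)) * 0.4 + 0.1, voxel_nm=37.42)
        path = tmp_path / "vol.mrc"
        write_mrc(vol, path)
        back = read_mrc(path)
        assert back.shape == vol.shape
        assert np.allclose(back.data, vol.data, atol=1e-6)
        assert back.voxel_nm == pytest.approx(37.42, rel=1e-5)

    def test_truncated_file_raises(self, tmp_path):
        path = tmp_path / "trunc.mrc"
        vol = LacVolume(np.random.default_rng(0).random((8, 8, 8)), 37.42)
        write_mrc(vol, path)
        data = path.read_bytes()
        path.write_bytes(data[: len(data) // 2])
        with pytest.raises((IOError, ValueError)):
            read_mrc(path)
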