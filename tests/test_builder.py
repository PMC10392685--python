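"""Crystal lattice, packing, relaxation, membrane tiling, maturation, library."""

import numpy as np
import pytest

from granulekit.builder import (
    LIPID_VOLUME_A3,
    LatticeSpec,
    LibraryGrid,
    MaturationState,
    ModelInstanceSet,
    Ingredient,
    PlacementSet,
    SphereSDF,
    build_library,
    overlap_energy,
    pack_compartment,
    partition_maturation,
    place_crystal,
    relax,
    tile_membrane,
)
from granulekit.structures import BeadModel


def bead(mw=15000.0, radius_a=17.0):
    return BeadModel(np.zeros((1, 3)), radius=radius_a, mass_share=np.array([mw]))


class TestPlaceCrystal:
    def test_small_boundary_contains_origin_site(self):
        lattice = LatticeSpec()
        nn = min(np.linalg.norm(lattice.basis_nm, axis=1))  # nearest-neighbour bound
        boundary = SphereSDF(np.zeros(3), 0.5 * nn)
        placements = place_crystal(lattice, boundary)
        assert len(placements) >= 1
        assert (boundary.sdf(placements.positions) <= 0).all()

    def test_site_density_approaches_lattice_density(self):
        lattice = LatticeSpec()
        r = 150.0  # nm
        placements = place_crystal(lattice, SphereSDF(np.zeros(3), r))
        cell_volume_nm3 = lattice.cell_volume_a3 * 1e-3
        expected = 4 / 3 * np.pi * r**3 * lattice.sites_per_cell / cell_volume_nm3
        assert len(placements) == pytest.approx(expected, rel=0.02)

    def test_pairwise_distances_drawn_from_lattice_vector_lengths(self):
        lattice = LatticeSpec()
        placements = place_crystal(lattice, SphereSDF(np.zeros(3), 12.0))
        pos = placements.positions
        # every pairwise difference must be a combination of cell vectors
        # with thirds-based centering offsets: check squared distances repeat
        basis = lattice.basis_nm
        inv = np.linalg.inv(basis.T)
        for i in range(len(pos)):
            for j in range(i + 1, len(pos)):
                frac = inv @ (pos[i] - pos[j])
                assert np.allclose(3.0 * frac, np.round(3.0 * frac), atol=1e-6)

    def test_orientations_coherent(self):
        placements = place_crystal(LatticeSpec(), SphereSDF(np.zeros(3), 30.0))
        assert np.allclose(placements.quaternions, placements.quaternions[0])

    def test_deterministic(self):
        a = place_crystal(LatticeSpec(), SphereSDF(np.zeros(3), 40.0))
        b = place_crystal(LatticeSpec(), SphereSDF(np.zeros(3), 40.0))
        assert np.array_equal(a.positions, b.positions)

    def test_degenerate_cell_raises(self):
        with pytest.raises(ValueError):
            LatticeSpec(a=0.0)


class TestPackCompartment:
    def test_zero_copies_empty(self):
        sdf = SphereSDF(np.zeros(3), 50.0)
        out = pack_compartment([(Ingredient("x", bead()), 0)], sdf, seed=0)
        assert len(out["x"]) == 0

    def test_single_copy_inside(self):
        sdf = SphereSDF(np.zeros(3), 100.0)
        out = pack_compartment([(Ingredient("x", bead()), 1)], sdf, seed=0)
        assert (sdf.sdf(out["x"].positions) < 0).all()

    def test_requested_overdensity_raises(self):
        sdf = SphereSDF(np.zeros(3), 10.0)
        ing = Ingredient("x", bead(radius_a=40.0))  # 4 nm bead
        with pytest.raises(ValueError, match="infeasible"):
            pack_compartment([(ing, 20000)], sdf, seed=0)

    def test_uniformity_over_octants(self):
        # one copy per seed in a large sphere: chi-square over octants
        sdf = SphereSDF(np.zeros(3), 50.0)
        ing = Ingredient("x", bead())
        counts = np.zeros(8)
        n = 1000
        for seed in range(n):
            pos = pack_compartment([(ing, 1)], sdf, seed=seed)["x"].positions[0]
            octant = (pos[0] > 0) * 4 + (pos[1] > 0) * 2 + (pos[2] > 0)
            counts[int(octant)] += 1
        chi2 = ((counts - n / 8) ** 2 / (n / 8)).sum()
        from scipy.stats import chi2 as chi2_dist

        assert chi2_dist.sf(chi2, df=7) > 0.001

    def test_reproducible_under_seed(self):
        sdf = SphereSDF(np.zeros(3), 80.0)
        frag = [(Ingredient("x", bead()), 50)]
        a = pack_compartment(frag, sdf, seed=9)["x"]
        b = pack_compartment(frag, sdf, seed=9)["x"]
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.quaternions, b.quaternions)

    def test_quaternions_unit_norm(self):
        sdf = SphereSDF(np.zeros(3), 80.0)
        out = pack_compartment([(Ingredient("x", bead()), 40)], sdf, seed=1)
        norms = np.linalg.norm(out["x"].quaternions, axis=1)
        assert np.allclose(norms, 1.0, atol=1e-9)


class TestRelax:
    def model_with(self, positions, radius_a=30.0):
        model = ModelInstanceSet()
        ing = Ingredient("x", bead(radius_a=radius_a))
        quats = np.tile([1.0, 0, 0, 0], (len(positions), 1))
        model.add(ing, PlacementSet("x", np.asarray(positions, float), quats))
        return model

    def test_no_overlap_is_identity(self):
        model = self.model_with([[0, 0, 0], [100, 0, 0]])
        before = model.placements["x"].positions.copy()
        relax(model, iterations=10)
        assert np.allclose(model.placements["x"].positions, before)

    def test_two_overlapping_instances_separate(self):
        model = self.model_with([[0, 0, 0], [2.0, 0, 0]])  # overlap: contact at 6 nm
        relax(model, iterations=1)
        pos = model.placements["x"].positions
        assert np.linalg.norm(pos[0] - pos[1]) > 2.0

    def test_overlap_soup_converges(self, rng):
        # 200 beads crammed into a small ball relax to small residual overlap
        positions = rng.normal(scale=20.0, size=(200, 3))
        model = self.model_with(positions, radius_a=20.0)
        radius_nm = 2.0
        e0 = overlap_energy(positions, np.full(200, radius_nm))
        relax(model, iterations=150, step_scale=0.4)
        pos = model.placements["x"].positions
        e1 = overlap_energy(pos, np.full(200, radius_nm))
        assert e1 < e0 * 0.05
        from scipy.spatial import cKDTree

        d, _ = cKDTree(pos).query(pos, k=2)
        worst_overlap = np.clip(2 * radius_nm - d[:, 1], 0, None).max()
        assert worst_overlap <= 0.1 * radius_nm * 2


class TestTileMembrane:
    def test_area_scaling(self):
        n1 = len(tile_membrane(SphereSDF(np.zeros(3), 100.0)))
        n2 = len(tile_membrane(SphereSDF(np.zeros(3), 200.0)))
        # quadruples up to the fixed-thickness curvature correction
        assert n2 == pytest.approx(4 * n1, rel=0.03)

    def test_lipid_volume_matches_shell_volume(self):
        r, t = 160.0, 5.0
        n = len(tile_membrane(SphereSDF(np.zeros(3), r), bilayer_thickness_nm=t))
        lipid_volume_nm3 = n * LIPID_VOLUME_A3 * 1e-3
        shell = 4 / 3 * np.pi * (r**3 - (r - t) ** 3)
        assert lipid_volume_nm3 == pytest.approx(shell, rel=0.05)

    def test_zero_radius_no_lipids(self):
        assert len(tile_membrane(SphereSDF(np.zeros(3), 0.0))) == 0

    def test_lipids_sit_on_leaflet_spheres(self):
        pl = tile_membrane(SphereSDF(np.zeros(3), 100.0), bilayer_thickness_nm=5.0)
        radii = np.linalg.norm(pl.positions, axis=1)
        assert set(np.round(np.unique(radii), 2)) == {96.25, 98.75}


class TestMaturation:
    def test_endpoints(self):
        assert partition_maturation(1000, MaturationState.from_step(6)) == (1000, 0, 0)
        assert partition_maturation(1000, MaturationState.from_step(1)) == (0, 1000, 0)

    def test_largest_remainder_fixture(self):
        state = MaturationState(step=3, crystal=0.5, proinsulin=0.3, monomer=0.2)
        assert partition_maturation(10, state) == (5, 3, 2)

    def test_counts_sum_exactly(self):
        for step in range(1, 7):
            counts = partition_maturation(363_474, MaturationState.from_step(step))
            assert sum(counts) == 363_474

    def test_invalid_fractions_raise(self):
        with pytest.raises(ValueError):
            MaturationState(step=2, crystal=0.5, proinsulin=0.6, monomer=0.2)


class TestLibrary:
    def test_default_grid_enumerates_3456_models(self):
        specs = build_library(LibraryGrid())
        assert len(specs) == 3456

    def test_single_point_grid(self):
        grid = LibraryGrid(
            diameters=np.array([320.0]),
            crystal_fractions=(0.625,),
            maturation_steps=(6,),
            cyto_concentrations=np.array([0.2]),
        )
        assert len(build_library(grid)) == 1

    def test_entry_count_is_product_of_axes(self):
        grid = LibraryGrid(
            diameters=np.array([200.0, 300.0, 400.0]),
            crystal_fractions=(0.3, 0.5),
            maturation_steps=(1, 6),
            cyto_concentrations=np.array([0.1, 0.15, 0.2]),
        )
        assert len(build_library(grid)) == 3 * 2 * 2 * 3

    def test_diameter_axis_spans_stated_range(self):
        grid = LibraryGrid()
        assert grid.diameters[0] == pytest.approx(130.0)
        assert grid.diameters[-1] == pytest.approx(473.0)
        assert len(grid.diameters) == 16
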