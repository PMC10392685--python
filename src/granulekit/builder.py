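"""Construct coarse-grained 3D granule models.

A model is a set of placed instances (position + orientation per molecule
copy).  Compartments are primitive signed distance fields (SDFs); the
insulin crystal is placed procedurally on the rhombohedral H3 lattice of the
hexameric crystal form; soluble proteins are distributed by grid-partitioned
stochastic packing; overlaps can be relaxed with a soft repulsive potential;
the membrane is tiled with lipids on Fibonacci lattices over the two leaflet
spheres.

Length unit is nm throughout this module (structure-frame bead coordinates
are Angstrom and converted on expansion).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .structures import BeadModel
from .util import rng_for, sphere_volume

ANGSTROM_TO_NM = 0.1

#: Random-close-packing guard: requested bead volume may not exceed this
#: fraction of the free compartment volume.
RCP_LIMIT = 0.64

#: DOPC molecular volume (A^3) and weight (Da).
LIPID_VOLUME_A3 = 1150.0
LIPID_MW = 734.053


# ---------------------------------------------------------------------------
# Signed distance fields
# ---------------------------------------------------------------------------

class SDF:
    """Signed distance field; negative inside."""

    role: str = "exterior"

    def sdf(self, points: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def contains(self, points: np.ndarray, tol: float = 0.0) -> np.ndarray:
        return self.sdf(points) <= tol

    def union(self, other: "SDF") -> "SDF":
        return _Combined(self, other, np.minimum)

    def intersection(self, other: "SDF") -> "SDF":
        return _Combined(self, other, np.maximum)

    def difference(self, other: "SDF") -> "SDF":
        return _Combined(self, _Negated(other), np.maximum)


@dataclass
class SphereSDF(SDF):
    """sdf(x) = |x - center| - radius."""

    center: np.ndarray
    radius: float
    role: str = "lumen"

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)
        if self.radius < 0:
            raise ValueError("radius must be nonnegative")

    def sdf(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(points)
        return np.linalg.norm(points - self.center, axis=-1) - self.radius


class _Negated(SDF):
    def __init__(self, inner: SDF):
        self.inner = inner

    def sdf(self, points):
        return -self.inner.sdf(points)


class _Combined(SDF):
    def __init__(self, a: SDF, b: SDF, op):
        self.a, self.b, self.op = a, b, op
        self.role = a.role

    def sdf(self, points):
        return self.op(self.a.sdf(points), self.b.sdf(points))


# ---------------------------------------------------------------------------
# Placements
# ---------------------------------------------------------------------------

IDENTITY_QUAT = np.array([1.0, 0.0, 0.0, 0.0])


@dataclass
class PlacementSet:
    """All copies of one ingredient: positions (nm) and unit quaternions."""

    ingredient_id: str
    positions: np.ndarray  # (n, 3) nm
    quaternions: np.ndarray  # (n, 4), scalar-first, unit norm

    def __post_init__(self):
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float)).reshape(-1, 3)
        self.quaternions = np.atleast_2d(np.asarray(self.quaternions, dtype=float)).reshape(-1, 4)
        norms = np.linalg.norm(self.quaternions, axis=1)
        if len(norms) and not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("quaternions must be unit norm")

    def __len__(self):
        return len(self.positions)


@dataclass
class Ingredient:
    """What gets placed: bead model plus mass/composition metadata."""

    ingredient_id: str
    beads: BeadModel
    mw: float | None = None  # Da; defaults to the bead-model mass
    mac_weights: dict | None = None  # element -> mass fraction (for X-ray step)
    anchored: bool = False  # constrained to a spherical shell (membrane)

    def __post_init__(self):
        if self.mw is None:
            self.mw = self.beads.total_mass

    @property
    def bounding_radius_nm(self) -> float:
        return self.beads.bounding_radius * ANGSTROM_TO_NM

    @property
    def bead_volume_nm3(self) -> float:
        r = self.beads.radius * ANGSTROM_TO_NM
        return len(self.beads.centers) * sphere_volume(r)


@dataclass
class ModelInstanceSet:
    """A built model: ingredients, their placements and uniform regions.

    ``uniform_regions`` carries compartments that are represented as a
    homogeneous protein solution (the surrounding cytoplasm) rather than as
    discrete instances: tuples ``(sdf, concentration g/ml, mac_weights)``.
    """

    ingredients: dict = field(default_factory=dict)  # id -> Ingredient
    placements: dict = field(default_factory=dict)  # id -> PlacementSet
    geometry: object = None
    maturation_step: int = 6
    uniform_regions: list = field(default_factory=list)

    def add(self, ingredient: Ingredient, placement: PlacementSet) -> None:
        if ingredient.ingredient_id in self.placements:
            old = self.placements[ingredient.ingredient_id]
            placement = PlacementSet(
                ingredient.ingredient_id,
                np.vstack([old.positions, placement.positions]),
                np.vstack([old.quaternions, placement.quaternions]),
            )
        self.ingredients[ingredient.ingredient_id] = ingredient
        self.placements[ingredient.ingredient_id] = placement

    def counts(self) -> dict:
        return {k: len(v) for k, v in self.placements.items()}

    def expanded_beads(self, ingredient_id: str) -> tuple:
        """Bead centres (nm) and masses (Da) for all copies of an ingredient."""
        from scipy.spatial.transform import Rotation

        ing = self.ingredients[ingredient_id]
        pl = self.placements[ingredient_id]
        offsets = ing.beads.centers * ANGSTROM_TO_NM  # (b, 3) nm
        offsets = offsets - offsets.mean(axis=0)  # beads about the placement point
        n, b = len(pl), len(offsets)
        if b == 1:
            centers = pl.positions.copy()
            masses = np.full(n, ing.beads.mass_share[0])
            return centers.reshape(-1, 3), masses
        # scipy uses scalar-last quaternions
        quats = np.roll(pl.quaternions, -1, axis=1)
        rot = Rotation.from_quat(quats)
        mats = rot.as_matrix()  # (n, 3, 3)
        centers = (mats @ offsets.T).transpose(0, 2, 1) + pl.positions[:, None, :]
        masses = np.tile(ing.beads.mass_share, n)
        return centers.reshape(-1, 3), masses

    # -- serialisation ------------------------------------------------------

    def to_tsv(self, path) -> None:
        """Instance table: ingredient, position (nm), quaternion."""
        import pandas as pd

        rows = []
        for iid, pl in sorted(self.placements.items()):
            for pos, q in zip(pl.positions, pl.quaternions):
                rows.append((iid, *pos, *q))
        pd.DataFrame(
            rows, columns=["ingredient", "x", "y", "z", "qw", "qx", "qy", "qz"]
        ).to_csv(path, sep="\t", index=False)

    def to_json(self, path=None) -> str:
        payload = {
            "maturation_step": self.maturation_step,
            "instances": {
                iid: {
                    "positions": pl.positions.tolist(),
                    "quaternions": pl.quaternions.tolist(),
                }
                for iid, pl in sorted(self.placements.items())
            },
        }
        text = json.dumps(payload)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


# ---------------------------------------------------------------------------
# Crystal lattice
# ---------------------------------------------------------------------------

@dataclass
class LatticeSpec:
    """Rhombohedral H3 lattice in the hexagonal setting.

    One insulin hexamer sits on each lattice point; the centering
    translations (0,0,0), (2/3,1/3,1/3), (1/3,2/3,2/3) give three hexamers
    per hexagonal cell.  Cell parameters are Angstrom.
    """

    a: float = 80.7
    c: float = 37.6
    centering: tuple = ((0, 0, 0), (2 / 3, 1 / 3, 1 / 3), (1 / 3, 2 / 3, 2 / 3))

    def __post_init__(self):
        if self.a <= 0 or self.c <= 0:
            raise ValueError("degenerate cell")

    @property
    def cell_volume_a3(self) -> float:
        return np.sqrt(3.0) / 2.0 * self.a**2 * self.c

    @property
    def basis_nm(self) -> np.ndarray:
        """Rows are the hexagonal cell vectors in nm."""
        a, c = self.a * ANGSTROM_TO_NM, self.c * ANGSTROM_TO_NM
        return np.array(
            [
                [a, 0.0, 0.0],
                [-a / 2.0, a * np.sqrt(3.0) / 2.0, 0.0],
                [0.0, 0.0, c],
            ]
        )

    @property
    def sites_per_cell(self) -> int:
        return len(self.centering)


def place_crystal(lattice: LatticeSpec, boundary: SphereSDF) -> PlacementSet:
    """One placement per lattice hexamer site inside the spherical boundary.

    All placements share the identity orientation (crystal coherence); the
    enumeration is deterministic.
    """
    basis = lattice.basis_nm
    r = boundary.radius
    # conservative index ranges from the inverse basis
    inv = np.linalg.inv(basis.T)
    frac_center = inv @ boundary.center
    margin = r / np.linalg.norm(basis, axis=1).min() + 2
    ranges = [
        np.arange(int(np.floor(fc - margin)), int(np.ceil(fc + margin)) + 1)
        for fc in frac_center
    ]
    ii, jj, kk = np.meshgrid(*ranges, indexing="ij")
    frac = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1).astype(float)
    sites = []
    for t in lattice.centering:
        sites.append((frac + np.asarray(t)) @ basis)
    pts = np.vstack(sites)
    inside = boundary.sdf(pts) <= 0.0
    pts = pts[inside]
    order = np.lexsort((pts[:, 2], pts[:, 1], pts[:, 0]))
    pts = pts[order]
    quats = np.tile(IDENTITY_QUAT, (len(pts), 1))
    return PlacementSet("insulin_hexamer", pts, quats)


# ---------------------------------------------------------------------------
# Stochastic packing
# ---------------------------------------------------------------------------

def random_quaternions(n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotations (scalar-first unit quaternions)."""
    q = rng.normal(size=(n, 4))
    return q / np.linalg.norm(q, axis=1, keepdims=True)


def estimate_free_volume_nm3(
    sdf: SDF, bbox: tuple, rng: np.random.Generator, n_samples: int = 20000
) -> float:
    """Monte-Carlo estimate of the volume where ``sdf <= 0``."""
    lo, hi = np.asarray(bbox[0], float), np.asarray(bbox[1], float)
    pts = lo + rng.random((n_samples, 3)) * (hi - lo)
    frac = float(np.mean(sdf.contains(pts)))
    return frac * float(np.prod(hi - lo))


def pack_compartment(
    fragment: list,
    sdf: SDF,
    seed: int,
    bbox: tuple | None = None,
    rng: np.random.Generator | None = None,
) -> dict:
    """Grid-partitioned stochastic placement of ``(ingredient, copies)`` pairs.

    For each ingredient the compartment is partitioned into cells of its
    bounding diameter; cells whose centre admits the bounding sphere
    (``sdf <= -r_bound``) are candidate sites, sampled without replacement
    with a sub-cell jitter and uniform random orientations.

    Raises if the requested bead volume exceeds the random-close-packing
    guard (0.64 of the free volume) or if an ingredient cannot be placed at
    the requested count.
    """
    rng = rng or rng_for(seed, "packing")
    if bbox is None:
        if not isinstance(sdf, SphereSDF):
            raise ValueError("bbox required for non-spherical compartments")
        pad = sdf.radius
        bbox = (sdf.center - pad, sdf.center + pad)

    free_volume = estimate_free_volume_nm3(sdf, bbox, rng)
    requested = sum(ing.bead_volume_nm3 * n for ing, n in fragment)
    if requested > RCP_LIMIT * free_volume:
        raise ValueError(
            f"infeasible packing: requested bead volume {requested:.3g} nm^3 "
            f"exceeds {RCP_LIMIT} x free volume {free_volume:.3g} nm^3"
        )

    lo, hi = np.asarray(bbox[0], float), np.asarray(bbox[1], float)
    out = {}
    for ing, n_copies in fragment:
        if n_copies == 0:
            out[ing.ingredient_id] = PlacementSet(
                ing.ingredient_id, np.empty((0, 3)), np.empty((0, 4))
            )
            continue
        r_b = max(ing.bounding_radius_nm, 1e-3)
        step = 2.0 * r_b
        axes = [np.arange(lo[d] + step / 2, hi[d], step) for d in range(3)]
        if min(len(ax) for ax in axes) == 0:
            raise ValueError(f"compartment too small for {ing.ingredient_id}")
        gx, gy, gz = np.meshgrid(*axes, indexing="ij")
        centers = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
        fits = sdf.sdf(centers) <= -r_b
        candidates = centers[fits]
        if len(candidates) < n_copies:
            raise ValueError(
                f"cannot place {n_copies} x {ing.ingredient_id}: "
                f"only {len(candidates)} candidate sites"
            )
        idx = rng.choice(len(candidates), size=n_copies, replace=False)
        pos = candidates[idx]
        jitter_room = step / 2.0 - r_b * 0.0  # jitter within the cell
        pos = pos + (rng.random((n_copies, 3)) - 0.5) * min(jitter_room, step / 2)
        # clamp back inside
        bad = sdf.sdf(pos) > -r_b * 0.5
        pos[bad] = candidates[idx][bad]
        out[ing.ingredient_id] = PlacementSet(
            ing.ingredient_id, pos, random_quaternions(n_copies, rng)
        )
    return out


def place_on_shell(
    ingredient_id: str, n: int, radius: float, center, rng: np.random.Generator
) -> PlacementSet:
    """Random placement on a sphere of given radius (membrane anchoring)."""
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    pos = np.asarray(center, float) + radius * v
    return PlacementSet(ingredient_id, pos, random_quaternions(n, rng))


# ---------------------------------------------------------------------------
# Relaxation
# ---------------------------------------------------------------------------

def overlap_energy(centers: np.ndarray, radii: np.ndarray) -> float:
    """Soft overlap energy: sum of squared pairwise overlap depths."""
    from scipy.spatial import cKDTree

    tree = cKDTree(centers)
    pairs = tree.query_pairs(2.0 * radii.max(), output_type="ndarray")
    if len(pairs) == 0:
        return 0.0
    d = np.linalg.norm(centers[pairs[:, 0]] - centers[pairs[:, 1]], axis=1)
    contact = radii[pairs[:, 0]] + radii[pairs[:, 1]]
    depth = np.clip(contact - d, 0.0, None)
    return float(np.sum(depth**2))


def relax(
    model: ModelInstanceSet,
    iterations: int = 150,
    step_scale: float = 0.4,
    boundary: SDF | None = None,
) -> ModelInstanceSet:
    """Damped rigid-body relaxation of overlapping instances.

    Each iteration every instance moves along the sum of soft repulsive
    forces on its beads (force proportional to overlap depth, zero beyond
    contact).  Instances of anchored (membrane) ingredients have the radial
    component of their displacement projected out so they stay on their
    shell; other instances are reflected back at the compartment boundary.
    The overlap energy is nonincreasing up to the step tolerance.
    """
    from scipy.spatial import cKDTree

    ids, spans, all_centers, all_radii, owner = [], {}, [], [], []
    k = 0
    for iid, pl in model.placements.items():
        ing = model.ingredients[iid]
        centers, _ = model.expanded_beads(iid)
        b = len(ing.beads.centers)
        n = len(pl)
        ids.append(iid)
        spans[iid] = (k, k + n, b)
        all_centers.append(centers)
        all_radii.append(np.full(n * b, ing.beads.radius * ANGSTROM_TO_NM))
        owner.append(np.repeat(np.arange(k, k + n), b))
        k += n
    if not all_centers:
        return model
    centers = np.vstack(all_centers)
    radii = np.concatenate(all_radii)
    owner = np.concatenate(owner)
    positions = np.vstack([model.placements[iid].positions for iid in ids])
    contact_max = 2.0 * radii.max()

    for _ in range(iterations):
        tree = cKDTree(centers)
        pairs = tree.query_pairs(contact_max, output_type="ndarray")
        if len(pairs) == 0:
            break
        i, j = pairs[:, 0], pairs[:, 1]
        keep = owner[i] != owner[j]
        i, j = i[keep], j[keep]
        if len(i) == 0:
            break
        delta = centers[i] - centers[j]
        dist = np.linalg.norm(delta, axis=1)
        contact = radii[i] + radii[j]
        depth = contact - dist
        active = depth > 0
        i, j, delta, dist, depth = i[active], j[active], delta[active], dist[active], depth[active]
        if len(i) == 0:
            break
        direction = delta / np.maximum(dist, 1e-9)[:, None]
        force = direction * depth[:, None]
        inst_force = np.zeros_like(positions)
        np.add.at(inst_force, owner[i], force)
        np.add.at(inst_force, owner[j], -force)
        displacement = step_scale * inst_force

        # per-ingredient constraints
        for iid in ids:
            a, b_, _ = spans[iid]
            ing = model.ingredients[iid]
            if ing.anchored and model.geometry is not None:
                center = np.zeros(3)
                rel = positions[a:b_] - center
                rhat = rel / np.maximum(np.linalg.norm(rel, axis=1, keepdims=True), 1e-9)
                radial = np.sum(displacement[a:b_] * rhat, axis=1, keepdims=True) * rhat
                displacement[a:b_] -= radial
        positions += displacement
        if boundary is not None:
            # reflect escapees back to the boundary surface
            s = boundary.sdf(positions)
            out = s > 0
            if np.any(out):
                eps = 0.5
                grad = np.zeros((out.sum(), 3))
                for d in range(3):
                    offset = np.zeros(3)
                    offset[d] = eps
                    grad[:, d] = boundary.sdf(positions[out] + offset) - boundary.sdf(
                        positions[out] - offset
                    )
                grad /= np.maximum(np.linalg.norm(grad, axis=1, keepdims=True), 1e-9) * 2 * eps
                positions[out] -= grad * (2.0 * eps) * s[out][:, None] / eps
        # update bead centres from instance displacement
        shift = positions - np.vstack([model.placements[iid].positions for iid in ids])
        centers += shift[owner]
        for n_i, iid in enumerate(ids):
            a, b_, _ = spans[iid]
            model.placements[iid] = PlacementSet(
                iid, positions[a:b_].copy(), model.placements[iid].quaternions
            )
    return model


# ---------------------------------------------------------------------------
# Membrane tiling
# ---------------------------------------------------------------------------

def fibonacci_sphere(n: int, radius: float, center=np.zeros(3)) -> np.ndarray:
    """n near-uniform points on a sphere (golden-angle spiral)."""
    if n == 0:
        return np.empty((0, 3))
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    pts = np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)], axis=1
    )
    return np.asarray(center) + radius * pts


def tile_membrane(
    surface: SphereSDF,
    lipid_volume_a3: float = LIPID_VOLUME_A3,
    bilayer_thickness_nm: float = 5.0,
) -> PlacementSet:
    """Tile the membrane shell with lipids, two leaflets.

    The area per lipid is derived from the molecular volume and the leaflet
    thickness (``a = V / (t/2)``), so the bilayer shell volume is filled by
    exactly the placed lipid volume.  Leaflet mid-radii sit a quarter
    thickness inside/three quarters inside the outer surface.  Placement is
    a Fibonacci lattice per leaflet (idealisation of patch-based tiling).
    """
    r_out_mid = surface.radius - bilayer_thickness_nm / 4.0
    r_in_mid = surface.radius - 3.0 * bilayer_thickness_nm / 4.0
    if surface.radius <= 0:
        return PlacementSet("lipid", np.empty((0, 3)), np.empty((0, 4)))
    leaflet_t_a = bilayer_thickness_nm / 2.0 * 10.0  # Angstrom
    area_per_lipid_a2 = lipid_volume_a3 / leaflet_t_a
    counts = []
    for r_mid in (r_out_mid, r_in_mid):
        area_a2 = 4.0 * np.pi * (r_mid * 10.0) ** 2
        counts.append(int(round(area_a2 / area_per_lipid_a2)))
    pts = np.vstack(
        [
            fibonacci_sphere(counts[0], r_out_mid, surface.center),
            fibonacci_sphere(counts[1], r_in_mid, surface.center),
        ]
    )
    quats = np.tile(IDENTITY_QUAT, (len(pts), 1))
    return PlacementSet("lipid", pts, quats)


def lipid_count(surface_radius_nm: float, bilayer_thickness_nm: float = 5.0,
                lipid_volume_a3: float = LIPID_VOLUME_A3) -> int:
    """Total lipid count for a spherical membrane (both leaflets)."""
    surface = SphereSDF(np.zeros(3), surface_radius_nm, role="membrane-surface")
    return len(tile_membrane(surface, lipid_volume_a3, bilayer_thickness_nm))


# ---------------------------------------------------------------------------
# Maturation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MaturationState:
    """Partition of the granule's insulin among its three chemical forms.

    Step 1 is fully immature (all proinsulin), step 6 fully mature (all
    crystalline insulin).  The default intermediate schedule moves mass from
    proinsulin to crystal linearly, with a transient free-monomer pool
    ``m = p (1 - p)`` that vanishes at both endpoints.
    """

    step: int
    crystal: float
    proinsulin: float
    monomer: float

    def __post_init__(self):
        if not 1 <= self.step <= 6:
            raise ValueError("step must be in 1..6")
        total = self.crystal + self.proinsulin + self.monomer
        if abs(total - 1.0) > 1e-9 or min(self.crystal, self.proinsulin, self.monomer) < -1e-12:
            raise ValueError("fractions must be nonnegative and sum to 1")

    @classmethod
    def from_step(cls, step: int) -> "MaturationState":
        p = (6 - step) / 5.0
        m = p * (1.0 - p)
        return cls(step=step, crystal=1.0 - p - m, proinsulin=p, monomer=m)


def partition_maturation(total_insulin: int, state: MaturationState) -> tuple:
    """Integer (crystal, proinsulin, monomer) counts by largest remainder."""
    fractions = np.array([state.crystal, state.proinsulin, state.monomer])
    raw = fractions * total_insulin
    counts = np.floor(raw).astype(int)
    remainder = total_insulin - counts.sum()
    order = np.argsort(-(raw - counts))
    for idx in order[:remainder]:
        counts[idx] += 1
    return tuple(int(c) for c in counts)


# ---------------------------------------------------------------------------
# Library grid
# ---------------------------------------------------------------------------

# ---------------------------------------------------------------------------
# Granule assembly
# ---------------------------------------------------------------------------

@dataclass
class GranuleBudget:
    """Mass bookkeeping of one idealised granule at a maturation step.

    The total insulin monomer count is the capacity of the mature crystal;
    a maturation state partitions it among crystal, lumenal proinsulin and
    lumenal free monomer.  Crystalline and cleaved insulin leave their
    cleavage peptides (C-peptide plus linker dipeptides) in the lumen.  The
    non-insulin 20% of the granule protein mass is split between a lumenal
    and a membrane-bound pool.
    """

    total_insulin: int
    n_crystal: int
    n_proinsulin: int
    n_monomer: int
    crystal_radius_nm: float
    lumen_mass_g: float
    membrane_mass_g: float
    lumen_concentration: float  # g ml^-1


def granule_budget(
    geometry,
    step: int = 6,
    membrane_protein_share: float = 0.25,
    crystal_fraction_of_mass: float = 0.8,
) -> GranuleBudget:
    """Partition the granule's protein mass for one maturation step."""
    from .recipe import (
        C_PEPTIDE_MW,
        INSULIN_MONOMER_MW,
        PROINSULIN_MW,
        crystal_mass_g,
        insulin_copies,
    )
    from .util import DALTON_G

    n_total = insulin_copies(geometry)
    state = MaturationState.from_step(step)
    n_c, n_p, n_m = partition_maturation(n_total, state)
    # crystal shrinks with the cube root of its monomer content
    r_c = geometry.crystal_radius * (n_c / n_total) ** (1 / 3) if n_c else 0.0

    m_total = crystal_mass_g(geometry) / crystal_fraction_of_mass
    non_insulin = (1.0 - crystal_fraction_of_mass) * m_total
    membrane_mass = membrane_protein_share * non_insulin
    lumen_noninsulin = non_insulin - membrane_mass
    lumen_mass = (
        n_p * PROINSULIN_MW + n_m * INSULIN_MONOMER_MW + (n_c + n_m) * C_PEPTIDE_MW
    ) * DALTON_G + lumen_noninsulin
    lumen_volume_cm3 = (sphere_volume(geometry.lumen_radius) - sphere_volume(r_c)) * 1e-21
    return GranuleBudget(
        total_insulin=n_total,
        n_crystal=n_c,
        n_proinsulin=n_p,
        n_monomer=n_m,
        crystal_radius_nm=r_c,
        lumen_mass_g=lumen_mass,
        membrane_mass_g=membrane_mass,
        lumen_concentration=lumen_mass / lumen_volume_cm3,
    )


def build_granule_model(
    geometry,
    step: int = 6,
    seed: int = 0,
    with_lipids: bool = True,
    membrane_protein_share: float = 0.25,
    lattice: LatticeSpec | None = None,
    center=(0.0, 0.0, 0.0),
    lumen_mix_mw: float = 50000.0,
    membrane_mix_mw: float = 60000.0,
) -> ModelInstanceSet:
    """Build one idealised granule as placed instances.

    The crystal is placed procedurally on the H3 lattice inside its
    spherical boundary (one hexamer per lattice point, coherent orientation);
    lumenal species are grid-packed with random orientations; membrane
    proteins sit on the anchoring shell; lipids tile the two leaflets.
    """
    from .recipe import (
        C_PEPTIDE_MW,
        INSULIN_MONOMER_MW,
        PROINSULIN_MW,
        KNOWN_CRYSTAL_FORMS,
    )
    from .structures import BeadModel
    from .util import DALTON_G

    lattice = lattice or LatticeSpec()
    center = np.asarray(center, dtype=float)
    budget = granule_budget(geometry, step, membrane_protein_share)
    rng = rng_for(seed, "packing")

    model = ModelInstanceSet(geometry=geometry, maturation_step=step)

    # hexamer mass from the lattice: one third of the cell's protein mass
    form = KNOWN_CRYSTAL_FORMS["1trz"]
    hexamer_mw = form.asym_mw * form.z / lattice.sites_per_cell
    if budget.n_crystal > 0:
        boundary = SphereSDF(center, budget.crystal_radius_nm, role="crystal-boundary")
        crystal = place_crystal(lattice, boundary)
        model.add(
            Ingredient(
                "insulin_hexamer",
                BeadModel(np.zeros((1, 3)), mass_share=np.array([hexamer_mw])),
                mw=hexamer_mw,
            ),
            crystal,
        )

    def single_bead(mw):
        # one bead sized to the molecule's compact volume at protein density
        from .structures import globule_radius_angstrom

        return BeadModel(
            np.zeros((1, 3)),
            radius=globule_radius_angstrom(mw),
            mass_share=np.array([float(mw)]),
        )

    lumen = SphereSDF(center, geometry.lumen_radius, role="lumen")
    if budget.crystal_radius_nm > 0:
        lumen_free = lumen.difference(
            SphereSDF(center, budget.crystal_radius_nm, role="crystal-boundary")
        )
    else:
        lumen_free = lumen
    lumen_noninsulin = budget.lumen_mass_g - (
        budget.n_proinsulin * PROINSULIN_MW
        + budget.n_monomer * INSULIN_MONOMER_MW
        + (budget.n_crystal + budget.n_monomer) * C_PEPTIDE_MW
    ) * DALTON_G
    fragment = [
        (Ingredient("proinsulin", single_bead(PROINSULIN_MW), PROINSULIN_MW), budget.n_proinsulin),
        (Ingredient("insulin_monomer", single_bead(INSULIN_MONOMER_MW), INSULIN_MONOMER_MW), budget.n_monomer),
        (
            Ingredient("cleavage_peptides", single_bead(C_PEPTIDE_MW), C_PEPTIDE_MW),
            budget.n_crystal + budget.n_monomer,
        ),
        (
            Ingredient("lumen_mix", single_bead(lumen_mix_mw), lumen_mix_mw),
            int(round(lumen_noninsulin / (lumen_mix_mw * DALTON_G))),
        ),
    ]
    bbox = (center - geometry.lumen_radius, center + geometry.lumen_radius)
    placements = pack_compartment(fragment, lumen_free, seed, bbox=bbox, rng=rng)
    for ing, _ in fragment:
        model.add(ing, placements[ing.ingredient_id])

    n_membrane = int(round(budget.membrane_mass_g / (membrane_mix_mw * DALTON_G)))
    anchor_radius = geometry.lumen_radius + geometry.membrane_thickness / 2.0
    model.add(
        Ingredient(
            "membrane_mix", single_bead(membrane_mix_mw), membrane_mix_mw, anchored=True
        ),
        place_on_shell("membrane_mix", n_membrane, anchor_radius, center, rng),
    )

    if with_lipids:
        surface = SphereSDF(center, geometry.vesicle_radius, role="membrane-surface")
        lipids = tile_membrane(surface, bilayer_thickness_nm=geometry.membrane_thickness)
        model.add(
            Ingredient("lipid", single_bead(LIPID_MW), LIPID_MW),
            lipids,
        )
    return model


@dataclass
class LibraryGrid:
    """Axes of the fitting library (Cartesian product of four axes)."""

    diameters: np.ndarray = None  # nm
    crystal_fractions: tuple = (0.2, 0.3, 0.4, 0.5, 0.6, 0.7)
    maturation_steps: tuple = (1, 2, 3, 4, 5, 6)
    cyto_concentrations: np.ndarray = None  # g ml^-1

    def __post_init__(self):
        if self.diameters is None:
            # 16 diameters, geometric spacing 130 -> 473 nm inclusive
            self.diameters = np.geomspace(130.0, 473.0, 16)
        if self.cyto_concentrations is None:
            self.cyto_concentrations = np.linspace(0.06, 0.2, 6)


@dataclass(frozen=True)
class ModelSpec:
    """One library entry before building."""

    vesicle_diameter: float
    crystal_diameter: float
    maturation_step: int
    cyto_concentration: float


def build_library(grid: LibraryGrid) -> list:
    """Enumerate the model specs of the library (default 16x6x6x6 = 3,456).

    Crystal sizes are fractions of the vesicle diameter, capped so the
    crystal plus membrane fits the vesicle.  Protein counts scale with the
    insulin content when a spec is built into a model.
    """
    specs = []
    for d in grid.diameters:
        for f in grid.crystal_fractions:
            cd = min(f * d, d - 2 * 5.0)
            for step in grid.maturation_steps:
                for conc in grid.cyto_concentrations:
                    specs.append(
                        ModelSpec(
                            vesicle_diameter=float(d),
                            crystal_diameter=float(cd),
                            maturation_step=int(step),
                            cyto_concentration=float(conc),
                        )
                    )
    return specs
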