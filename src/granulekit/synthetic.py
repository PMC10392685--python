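"""Synthetic-data generators: every pipeline stage testable with no downloads.

Two families of fixtures:

* annotation catalogs emulating the evidence structure of curated
  protein-localisation databases (keyword enrichment controlled by odds
  ratios, proteome membership probabilities, interactor keyword draws), and
* voxel phantoms: idealised granules with a closed-form concentric-shell LAC
  volume (crystal core / lumen / membrane shell / cytoplasm) for oracle
  comparisons against the instance-based voxelisation.

All generators are reproducible under a fixed master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .confidence import AnnotationCatalog, LabelledSet
from .recipe import VesicleGeometry
from .util import rng_for

#: Default keyword roster with enrichment odds (positives : negatives).
DEFAULT_KEYWORD_ODDS = {
    "secretory vesicle": 12.0,
    "cytoplasmic vesicle": 8.0,
    "secreted": 3.0,
    "membrane": 1.5,
    "cytoplasm": 1.0,
    "mitochondrion": 0.15,
    "nucleus": 0.1,
}


@dataclass
class SyntheticCatalogSpec:
    """Controls for the annotation-catalog generator."""

    n_positives: int = 30
    n_negatives: int = 240
    keyword_odds: dict = field(default_factory=lambda: dict(DEFAULT_KEYWORD_ODDS))
    base_rate: float = 0.15  # keyword rate among negatives
    membership_p_pos: float = 0.55  # per-proteome inclusion prob., positives
    membership_p_neg: float = 0.35
    n_proteomes: int = 3
    interactor_mean: float = 3.0  # Poisson mean interactors per protein
    interactor_fidelity: float = 0.7  # interactor shares the protein's class
    interactor_keyword_odds: dict | None = None  # defaults to keyword_odds
    seed: int = 0

    def __post_init__(self):
        if any(odds <= 0 for odds in self.keyword_odds.values()):
            raise ValueError("odds ratios must be positive")
        for p in (self.membership_p_pos, self.membership_p_neg, self.base_rate):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must be in [0, 1]")

    def positive_rate(self, keyword: str) -> float:
        """Keyword rate among positives implied by the odds ratio.

        An infinite odds ratio gives a positives-only keyword; a zero base
        rate makes the keyword absent from negatives entirely.
        """
        return _enriched_rate(self.keyword_odds[keyword], self.base_rate)


def _enriched_rate(odds: float, base_rate: float) -> float:
    if np.isinf(odds):
        return 1.0
    if base_rate == 0.0:
        return 0.0
    odds_neg = base_rate / (1.0 - base_rate)
    odds_pos = odds * odds_neg
    return odds_pos / (1.0 + odds_pos)


def _draw_keywords(
    keyword_odds: dict, base_rate: float, positive: bool, rng
) -> frozenset:
    kws = []
    for kw, odds in keyword_odds.items():
        rate = _enriched_rate(odds, base_rate) if positive else base_rate
        if rng.random() < rate:
            kws.append(kw)
    return frozenset(kws)


def generate_catalog(spec: SyntheticCatalogSpec):
    """Generate an :class:`AnnotationCatalog` plus its labels.

    Keywords are Bernoulli draws at odds-ratio-controlled rates; interactor
    keywords come from simulated partners that share the protein's class
    with probability ``interactor_fidelity``; proteome membership is i.i.d.
    per proteome with at least one membership enforced.
    """
    rng = rng_for(spec.seed, "catalog")
    proteome_ids = [f"P{i + 1}" for i in range(spec.n_proteomes)]
    int_odds = spec.interactor_keyword_odds or spec.keyword_odds
    loc, intloc, proteomes = {}, {}, {}
    positives, negatives = set(), set()
    for i in range(spec.n_positives + spec.n_negatives):
        positive = i < spec.n_positives
        pid = f"prot{i:04d}"
        (positives if positive else negatives).add(pid)
        loc[pid] = _draw_keywords(spec.keyword_odds, spec.base_rate, positive, rng)
        partner_kws = []
        for _ in range(rng.poisson(spec.interactor_mean)):
            partner_positive = (
                positive if rng.random() < spec.interactor_fidelity else not positive
            )
            partner_kws.extend(
                sorted(_draw_keywords(int_odds, spec.base_rate, partner_positive, rng))
            )
        intloc[pid] = tuple(partner_kws)
        p_member = spec.membership_p_pos if positive else spec.membership_p_neg
        members = [pr for pr in proteome_ids if rng.random() < p_member]
        if not members:
            members = [proteome_ids[rng.integers(spec.n_proteomes)]]
        proteomes[pid] = frozenset(members)
    catalog = AnnotationCatalog(loc=loc, intloc=intloc, proteomes=proteomes)
    labels = LabelledSet(frozenset(positives), frozenset(negatives))
    return catalog, labels


def generate_proteome_tables(
    n_proteins: int = 40,
    n_proteomes: int = 3,
    seed: int = 0,
    detection_p: float = 0.7,
):
    """Synthetic abundance tables, one per proteome study.

    Returns ``(tables, mw_map)``: per-proteome DataFrames indexed by protein
    id with columns ``raw_abundance`` (log-normal, study-scaled), ``length``
    and ``mw`` (length x 110 Da).
    """
    import pandas as pd

    rng = rng_for(seed, "proteome")
    ids = [f"prot{i:04d}" for i in range(n_proteins)]
    lengths = rng.integers(80, 1500, size=n_proteins)
    mw = lengths * 110.0
    true_abundance = rng.lognormal(mean=2.0, sigma=1.5, size=n_proteins)
    tables = {}
    for j in range(n_proteomes):
        scale = 10.0 ** rng.uniform(-1, 1)  # study-specific metric scale
        detected = rng.random(n_proteins) < detection_p
        noise = rng.lognormal(mean=0.0, sigma=0.3, size=n_proteins)
        sub = pd.DataFrame(
            {
                "raw_abundance": true_abundance * noise * scale,
                "length": lengths,
                "mw": mw,
            },
            index=pd.Index(ids, name="protein_id"),
        )[detected]
        tables[f"P{j + 1}"] = sub
    mw_map = dict(zip(ids, mw))
    return tables, mw_map


# ---------------------------------------------------------------------------
# Phantoms
# ---------------------------------------------------------------------------

@dataclass
class PhantomSpec:
    """One idealised granule embedded in cytoplasm."""

    vesicle_diameter: float = 320.0  # nm
    crystal_diameter: float = 200.0  # nm (mature capacity)
    maturation_step: int = 6
    cyto_concentration: float = 0.2  # g ml^-1, in [0.06, 0.2] for the library
    voxel_nm: float = 37.42
    box_shape: tuple = (17, 17, 17)

    @property
    def geometry(self) -> VesicleGeometry:
        return VesicleGeometry(
            vesicle_diameter=self.vesicle_diameter,
            crystal_diameter=self.crystal_diameter,
        )


def analytic_granule_lac(
    spec: PhantomSpec,
    center_nm=(0.0, 0.0, 0.0),
    origin_nm=None,
    with_lipids: bool = True,
    supersample: int = 3,
    membrane_protein_share: float = 0.25,
):
    """Closed-form concentric-shell LAC volume of an idealised granule.

    Regions from the centre out: crystalline core (protein at the crystal
    occupancy), lumen (protein solution at the maturation-step
    concentration), lipid bilayer shell, cytoplasm.  Voxels are supersampled
    to resolve partial-volume at the region boundaries.  Returns a
    :class:`granulekit.xray.LacVolume`.
    """
    from .builder import granule_budget
    from .recipe import KNOWN_CRYSTAL_FORMS, crystal_occupancy
    from .util import PROTEIN_DENSITY, WATER_DENSITY
    from .xray import (
        CM_TO_UM_LAC,
        LacVolume,
        dopc_mac,
        protein_mac,
        protein_solution_lac,
        water_mac,
    )

    geometry = spec.geometry
    budget = granule_budget(geometry, spec.maturation_step, membrane_protein_share)
    occ = crystal_occupancy(KNOWN_CRYSTAL_FORMS["1trz"])
    p_mac, w_mac, l_mac = protein_mac().mac, water_mac().mac, dopc_mac()

    crystal_lac = (
        occ * PROTEIN_DENSITY * p_mac + (1.0 - occ) * WATER_DENSITY * w_mac
    ) * CM_TO_UM_LAC
    # membrane shell: solid lipid plus the anchored membrane-protein mass
    shell_volume_cm3 = (
        4.0 / 3.0 * np.pi
        * (geometry.vesicle_radius**3 - geometry.lumen_radius**3) * 1e-21
    )
    mem_protein_density = budget.membrane_mass_g / shell_volume_cm3
    if with_lipids:
        membrane_lac = (
            l_mac.density * l_mac.mac + mem_protein_density * p_mac
        ) * CM_TO_UM_LAC
    else:
        # lipids removed: the shell is membrane protein in water
        membrane_lac = protein_solution_lac(mem_protein_density)
    lumen_lac = protein_solution_lac(budget.lumen_concentration)
    cyto_lac = protein_solution_lac(spec.cyto_concentration)

    shape = tuple(int(s) for s in spec.box_shape)
    if origin_nm is None:
        origin_nm = -0.5 * (np.array(shape) - 1) * spec.voxel_nm
    origin_nm = np.asarray(origin_nm, dtype=float)
    center_nm = np.asarray(center_nm, dtype=float)

    s = supersample
    sub = (np.arange(s) + 0.5) / s - 0.5
    axes = [
        (origin_nm[d] + (np.arange(shape[d])[:, None] + sub[None, :]) * spec.voxel_nm).ravel()
        for d in range(3)
    ]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    r = np.sqrt(
        (gx - center_nm[0]) ** 2 + (gy - center_nm[1]) ** 2 + (gz - center_nm[2]) ** 2
    )
    lac = np.full(r.shape, cyto_lac)
    lac[r <= geometry.vesicle_radius] = membrane_lac
    lac[r <= geometry.lumen_radius] = lumen_lac
    if budget.crystal_radius_nm > 0:
        lac[r <= budget.crystal_radius_nm] = crystal_lac
    lac = lac.reshape(shape[0], s, shape[1], s, shape[2], s).mean(axis=(1, 3, 5))
    return LacVolume(data=lac, voxel_nm=spec.voxel_nm, origin_nm=origin_nm)


def generate_phantom(spec: PhantomSpec, seed: int = 0, with_lipids: bool = True):
    """Build the idealised granule and its analytic LAC volume.

    Returns ``(model, analytic_volume)``; the model can be voxelised with
    :func:`granulekit.xray.voxelize` and compared against the closed form.
    """
    from .builder import SphereSDF, build_granule_model
    from .xray import concentration_for_lac, protein_solution_lac

    model = build_granule_model(
        spec.geometry, step=spec.maturation_step, seed=seed, with_lipids=with_lipids
    )
    # surrounding cytoplasm as a homogeneous region outside the vesicle
    vesicle = SphereSDF(np.zeros(3), spec.geometry.vesicle_radius, role="exterior")
    outside = _Everywhere().difference(vesicle)
    model.uniform_regions.append((outside, spec.cyto_concentration, None))
    analytic = analytic_granule_lac(spec, with_lipids=with_lipids)
    return model, analytic


class _Everywhere:
    """SDF covering all space (building block for 'outside X' regions)."""

    role = "exterior"

    def sdf(self, points):
        points = np.atleast_2d(points)
        return np.full(points.shape[0], -1.0)

    def contains(self, points, tol=0.0):
        return self.sdf(points) <= tol

    def difference(self, other):
        from .builder import _Combined, _Negated

        return _Combined(self, _Negated(other), np.maximum)


# ---------------------------------------------------------------------------
# Round-trip checks
# ---------------------------------------------------------------------------

def read_write_roundtrips(workdir) -> dict:
    """Exercise the MRC / TSV / JSON round-trips; returns max discrepancies.

    Raises on any lossy round-trip (floats compared at 1e-6 relative).
    """
    import os

    from .builder import build_granule_model
    from .recipe import Recipe, RecipeEntry, VesicleGeometry
    from .xray import LacVolume, read_mrc, write_mrc

    rng = rng_for(0, "phantom")
    report = {}

    vol = LacVolume(rng.random((9, 7, 9)) * 0.5 + 0.1, voxel_nm=37.42)
    mrc_path = os.path.join(workdir, "roundtrip.mrc")
    write_mrc(vol, mrc_path)
    back = read_mrc(mrc_path)
    err = float(np.abs(back.data - vol.data).max() / np.abs(vol.data).max())
    if err > 1e-6:
        raise ValueError(f"MRC roundtrip lossy: {err}")
    report["mrc"] = err

    recipe = Recipe(
        entries=[
            RecipeEntry("insulin", "crystal", 363430, 0.8, mw=5808.0),
            RecipeEntry("chga", "lumen", 5000, 0.15, mw=48000.0),
            RecipeEntry("ptprn", "membrane", 800, 0.05, mw=64000.0),
        ],
        geometry=VesicleGeometry(),
    )
    json_path = os.path.join(workdir, "recipe.json")
    recipe.to_json(json_path)
    back_recipe = Recipe.from_json(json_path)
    if [e.__dict__ for e in back_recipe.entries] != [e.__dict__ for e in recipe.entries]:
        raise ValueError("recipe JSON roundtrip lossy")
    report["recipe"] = 0.0

    model = build_granule_model(
        VesicleGeometry(120.0, 60.0), step=6, seed=1, with_lipids=False
    )
    json_model = model.to_json()
    import json as _json

    payload = _json.loads(json_model)
    for iid, pl in model.placements.items():
        got = np.asarray(payload["instances"][iid]["positions"]).reshape(-1, 3)
        if got.size and np.abs(got - pl.positions).max() > 1e-6:
            raise ValueError("model JSON roundtrip lossy")
    report["model"] = 0.0
    return report
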