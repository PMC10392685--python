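"""From proteome abundance tables to a buildable vesicle recipe.

The chain of estimates:

1. Per proteome, study-specific abundance metrics are length-normalised and
   renormalised to a *normalised spectral abundance factor* (NSAF), roughly a
   molar fraction.
2. NSAF times molecular weight, renormalised, gives a per-proteome mass
   fraction; cross-proteome consensus is the mean of per-proteome mass
   fractions over the proteomes that detected the protein (manual per-proteome
   exclusions are applied first).
3. Non-insulin mass fractions are rescaled to a total of 0.2, with the
   insulin crystal carrying the remaining 0.8 of the intra-granule protein
   mass.
4. Absolute copy numbers follow from a reference geometry: the crystal is a
   200 nm sphere packed at the volume occupancy of the rhombohedral (H3)
   insulin crystal form, from which the total protein mass of the granule is
   fixed and every mass fraction becomes a molecule count.

Copy-number exception hooks reproduce the manual curation steps: IAPP pinned
to 1% of insulin, multi-subunit complexes averaged with their stoichiometry,
and per-proteome outlier measurements excluded from the consensus.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .util import DALTON_G, PROTEIN_DENSITY, sphere_volume

#: Insulin monomer molecular weight, Da.
INSULIN_MONOMER_MW = 5808.0
#: Human proinsulin (insulin + C-peptide + dipeptide linkers), Da.
PROINSULIN_MW = 9388.0
#: C-peptide left in the lumen after maturation, Da.
C_PEPTIDE_MW = PROINSULIN_MW - INSULIN_MONOMER_MW

COMPARTMENTS = ("lumen", "membrane", "cytoplasm", "crystal")


# ---------------------------------------------------------------------------
# Crystal forms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CrystalForm:
    """Metadata of an insulin crystal form sufficient to derive packing.

    ``occupancy`` is the protein volume fraction of the unit cell:
    ``z * asym_mw / (N_A * protein_density * cell_volume)`` in consistent
    units (``asym_mw`` in Da, ``cell_volume`` in A^3, density in g cm^-3).
    """

    pdb_id: str
    space_group: str
    asym_mw: float  # Da
    z: int  # asymmetric units per cell
    cell_volume: float  # A^3
    protein_density: float = PROTEIN_DENSITY  # g cm^-3

    def __post_init__(self):
        for name in ("asym_mw", "z", "cell_volume", "protein_density"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def crystal_occupancy(form: CrystalForm) -> float:
    """Protein volume fraction of the crystal unit cell, in (0, 1]."""
    cell_volume_cm3 = form.cell_volume * 1e-24
    protein_volume_cm3 = form.z * form.asym_mw * DALTON_G / form.protein_density
    occ = protein_volume_cm3 / cell_volume_cm3
    if not 0.0 < occ <= 1.0:
        raise ValueError(
            f"inconsistent crystal metadata for {form.pdb_id}: occupancy {occ:.3f}"
        )
    return occ


#: Synthetic stand-in metadata for the two reference insulin crystal forms.
#: The live PDB entry pages are not consulted; cell constants are
#: literature-typical values for the rhombohedral T3R3 (hexagonal setting,
#: here labelled H3) and monoclinic insulin forms, and the asymmetric-unit
#: weights (protein + zinc + ligands) were reconstructed to be consistent
#: with the published volume occupancies of these forms (0.686 and 0.584).
KNOWN_CRYSTAL_FORMS = {
    "1trz": CrystalForm(
        pdb_id="1trz", space_group="H3", asym_mw=11875.0, z=9, cell_volume=212063.0
    ),
    "1ev6": CrystalForm(
        pdb_id="1ev6", space_group="P21", asym_mw=36554.0, z=2, cell_volume=170392.0
    ),
}


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VesicleGeometry:
    """Spherical idealisation of one granule (all lengths in nm)."""

    vesicle_diameter: float = 320.0
    crystal_diameter: float = 200.0
    membrane_thickness: float = 5.0  # bilayer shell thickness

    def __post_init__(self):
        if self.crystal_diameter + 2 * self.membrane_thickness > self.vesicle_diameter:
            raise ValueError("crystal plus membrane exceeds vesicle diameter")

    @property
    def vesicle_radius(self) -> float:
        return self.vesicle_diameter / 2.0

    @property
    def crystal_radius(self) -> float:
        return self.crystal_diameter / 2.0

    @property
    def lumen_radius(self) -> float:
        """Inner radius of the membrane shell."""
        return self.vesicle_radius - self.membrane_thickness

    @property
    def lumen_volume_nm3(self) -> float:
        return sphere_volume(self.lumen_radius)


# ---------------------------------------------------------------------------
# Fractions
# ---------------------------------------------------------------------------

def nsaf(entries: pd.DataFrame) -> pd.Series:
    """Normalised spectral abundance factors for one proteome table.

    ``entries`` needs columns ``raw_abundance`` and ``length`` indexed by
    protein id.  Returns molar fractions summing to 1.
    """
    raw = entries["raw_abundance"].astype(float)
    if (raw < 0).any() or not np.isfinite(raw).all():
        raise ValueError("abundances must be finite and nonnegative")
    if (entries["length"] <= 0).any():
        raise ValueError("lengths must be positive")
    per_length = raw / entries["length"].astype(float)
    total = per_length.sum()
    if total == 0:
        raise ValueError("all abundances are zero")
    return per_length / total


def mass_fractions(nsaf_map: pd.Series, mw_map: Mapping[str, float]) -> pd.Series:
    """Convert molar fractions to mass fractions (sum to 1)."""
    missing = [p for p in nsaf_map.index if p not in mw_map]
    if missing:
        raise KeyError(f"missing molecular weight for {missing[0]!r}")
    mw = pd.Series({p: float(mw_map[p]) for p in nsaf_map.index})
    weighted = nsaf_map * mw
    return weighted / weighted.sum()


def pooled_mass_fractions(
    proteome_tables: Mapping[str, pd.DataFrame],
    mw_map: Mapping[str, float],
    exclusions: Iterable[tuple] = (),
) -> pd.Series:
    """Cross-proteome consensus mass fractions.

    Mass fractions are computed within each proteome first; a protein's
    consensus is the mean over the proteomes that report it.  ``exclusions``
    is an iterable of ``(protein_id, proteome_id)`` measurements dropped
    before pooling (outliers).  The pooled map is renormalised to sum to 1.
    """
    excluded = set(exclusions)
    per_proteome = {}
    for pid, table in proteome_tables.items():
        keep = [p for p in table.index if (p, pid) not in excluded]
        sub = table.loc[keep]
        if len(sub) == 0:
            continue
        per_proteome[pid] = mass_fractions(nsaf(sub), mw_map)
    stacked = pd.DataFrame(per_proteome)
    pooled = stacked.mean(axis=1, skipna=True)
    return pooled / pooled.sum()


def with_curated_floor(
    fractions: pd.Series, curated_ids: Iterable[str], floor: float = 1e-4
) -> pd.Series:
    """Add curated proteins missing from the proteomes at a floor fraction.

    Each absent curated protein receives ``floor`` of the total mass; the
    result is renormalised to 1.
    """
    out = fractions.copy()
    for pid in curated_ids:
        if pid not in out.index:
            out.loc[pid] = floor
    return out / out.sum()


def scale_noninsulin(
    fractions: pd.Series,
    insulin_ids: Iterable[str],
    noninsulin_total: float = 0.2,
    crystal_total: float = 0.8,
) -> pd.Series:
    """Impose the granule mass split: crystal 0.8, everything else 0.2.

    Insulin entries share ``crystal_total`` proportionally to their incoming
    fractions; non-insulin entries are rescaled to sum to
    ``noninsulin_total``.
    """
    insulin_ids = [p for p in insulin_ids if p in fractions.index]
    if not insulin_ids:
        raise ValueError("no insulin entries present")
    non = fractions.drop(insulin_ids)
    if len(non) == 0:
        raise ValueError("no non-insulin proteins to scale")
    out = fractions.copy()
    out.loc[non.index] = non * (noninsulin_total / non.sum())
    ins = fractions.loc[insulin_ids]
    out.loc[insulin_ids] = ins * (crystal_total / ins.sum())
    return out


# ---------------------------------------------------------------------------
# Copy numbers
# ---------------------------------------------------------------------------

def insulin_copies(
    geometry: VesicleGeometry,
    form: CrystalForm = KNOWN_CRYSTAL_FORMS["1trz"],
    monomer_mw: float = INSULIN_MONOMER_MW,
) -> int:
    """Number of insulin monomers in the crystal of the reference geometry."""
    if geometry.crystal_diameter == 0:
        return 0
    volume_cm3 = sphere_volume(geometry.crystal_radius) * 1e-21  # nm^3 -> cm^3
    mass_g = volume_cm3 * crystal_occupancy(form) * form.protein_density
    return int(round(mass_g / (monomer_mw * DALTON_G)))


def crystal_mass_g(geometry: VesicleGeometry, form: CrystalForm | None = None) -> float:
    """Protein mass of the crystal, grams."""
    form = form or KNOWN_CRYSTAL_FORMS["1trz"]
    volume_cm3 = sphere_volume(geometry.crystal_radius) * 1e-21
    return volume_cm3 * crystal_occupancy(form) * form.protein_density


def copy_numbers(
    fractions: pd.Series,
    mw_map: Mapping[str, float],
    total_protein_mass_g: float,
    must_include: Iterable[str] = (),
) -> pd.Series:
    """Convert mass fractions to integer copy numbers.

    Uses round-half-to-even; curated must-include proteins whose count rounds
    to 0 are floored at 1 copy.
    """
    if total_protein_mass_g < 0 or not np.isfinite(total_protein_mass_g):
        raise ValueError("total mass must be finite and nonnegative")
    if (fractions < 0).any() or not np.isfinite(fractions).all():
        raise ValueError("fractions must be finite and nonnegative")
    counts = {}
    must = set(must_include)
    for pid, frac in fractions.items():
        if pid not in mw_map:
            raise KeyError(f"missing molecular weight for {pid!r}")
        n = float(np.rint(frac * total_protein_mass_g / (float(mw_map[pid]) * DALTON_G)))
        if n < 1 and pid in must:
            n = 1
        counts[pid] = int(n)
    return pd.Series(counts, dtype=int)


def iapp_hook(counts: pd.Series, insulin_id: str, iapp_id: str, ratio: float = 0.01) -> pd.Series:
    """Pin islet amyloid polypeptide to a fixed ratio of insulin copies."""
    out = counts.copy()
    out.loc[iapp_id] = int(round(ratio * counts.loc[insulin_id]))
    return out


def complex_hook(
    counts: pd.Series, complex_id: str, subunit_stoichiometry: Mapping[str, float]
) -> pd.Series:
    """Replace subunit counts by one complex count.

    The complex count is the mean of the stoichiometry-normalised subunit
    counts (round-half-to-even); subunits are removed from the table.
    """
    normalised = [counts.loc[s] / st for s, st in subunit_stoichiometry.items()]
    out = counts.drop(list(subunit_stoichiometry))
    out.loc[complex_id] = int(np.rint(float(np.mean(normalised))))
    return out


# ---------------------------------------------------------------------------
# Cytoplasm
# ---------------------------------------------------------------------------

def cytoplasm_recipe(
    entries: pd.DataFrame,
    target_concentration: float = 0.2,  # g ml^-1
    top_n: int = 50,
) -> pd.DataFrame:
    """Concentration recipe for the crowded cytoplasm.

    Takes the ``top_n`` most abundant proteins (columns ``raw_abundance``,
    ``length``, ``mw``) and scales their mass concentrations so the total is
    ``target_concentration``.  Returns columns ``mass_fraction`` and
    ``concentration`` (g ml^-1).
    """
    if len(entries) < top_n:
        warnings.warn(
            f"only {len(entries)} cytoplasmic proteins available (< {top_n}); using all"
        )
        top_n = len(entries)
    top = entries.sort_values("raw_abundance", ascending=False).head(top_n)
    fracs = mass_fractions(nsaf(top), top["mw"])
    out = pd.DataFrame({"mass_fraction": fracs})
    out["concentration"] = fracs * target_concentration
    return out


# ---------------------------------------------------------------------------
# Recipe container
# ---------------------------------------------------------------------------

@dataclass
class RecipeEntry:
    protein_id: str
    compartment: str
    copy_number: int
    mass_fraction: float
    structure_ref: str = ""
    mw: float = 0.0  # Da, carried for mass bookkeeping

    def __post_init__(self):
        if self.compartment not in COMPARTMENTS:
            raise ValueError(f"unknown compartment {self.compartment!r}")
        if self.copy_number < 0:
            raise ValueError("copy numbers are nonnegative")


@dataclass
class Recipe:
    """Buildable ingredient list for one granule plus surrounding cytoplasm."""

    entries: list = field(default_factory=list)
    geometry: VesicleGeometry = field(default_factory=VesicleGeometry)

    def by_compartment(self, compartment: str) -> list:
        return [e for e in self.entries if e.compartment == compartment]

    def granule_mass_check(self, tol: float = 1e-6) -> None:
        """Verify the 0.8 / 0.2 crystal / non-crystal split of vesicle mass."""
        crystal = sum(e.mass_fraction for e in self.by_compartment("crystal"))
        other = sum(
            e.mass_fraction
            for e in self.entries
            if e.compartment in ("lumen", "membrane")
        )
        if abs(crystal - 0.8) > tol or abs(other - 0.2) > tol:
            raise ValueError(
                f"granule mass split violated: crystal {crystal:.4f}, other {other:.4f}"
            )

    def to_json(self, path=None) -> str:
        payload = {
            "geometry": asdict(self.geometry),
            "ingredients": [asdict(e) for e in self.entries],
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "Recipe":
        if isinstance(source, (str, bytes)) and not str(source).lstrip().startswith("{"):
            with open(source) as fh:
                payload = json.load(fh)
        elif isinstance(source, (str, bytes)):
            payload = json.loads(source)
        else:
            payload = json.load(source)
        geometry = VesicleGeometry(**payload["geometry"])
        entries = [RecipeEntry(**e) for e in payload["ingredients"]]
        return cls(entries=entries, geometry=geometry)
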