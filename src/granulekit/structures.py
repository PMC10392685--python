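"""Atomic structures reduced to coarse beads, with composition bookkeeping.

Structures enter as PDB or mmCIF files (or as synthetic globular decoys) and
leave as bead models: a handful of spheres per protein whose centres are
k-means centroids of the atom coordinates and whose mass shares sum exactly
to the protein's molecular weight.  The elemental composition tallied here
feeds the X-ray attenuation calculation, so hydrogens - almost always absent
from experimental coordinate files - are restored from per-residue template
counts.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .util import DALTON_G, PROTEIN_DENSITY, rng_for, sphere_volume

#: Standard atomic weights (Da), IUPAC 2021 abridged.
ATOMIC_WEIGHTS = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "P": 30.974,
    "S": 32.06, "ZN": 65.38, "FE": 55.845, "MG": 24.305, "CA": 40.078,
    "NA": 22.990, "CL": 35.45, "K": 39.098, "SE": 78.971,
}

#: Hydrogen counts of internal (chain-linked) amino-acid residues, neutral
#: side chains.  A free amino acid is the internal residue plus H2O, so a
#: single-residue chain of glycine tallies to C2H5NO2.
RESIDUE_HYDROGENS = {
    "GLY": 3, "ALA": 5, "SER": 5, "CYS": 5, "THR": 7, "VAL": 9, "PRO": 7,
    "LEU": 11, "ILE": 11, "MET": 9, "PHE": 9, "TYR": 9, "TRP": 10,
    "ASP": 5, "GLU": 7, "ASN": 6, "GLN": 8, "LYS": 12, "ARG": 12, "HIS": 7,
}

#: Average elemental composition of protein by atom count (H:C:N:O:S),
#: used for synthetic decoys and for proteins lacking structures.
AVERAGE_PROTEIN_ATOM_FRACTIONS = {
    "H": 0.498, "C": 0.320, "N": 0.085, "O": 0.095, "S": 0.002,
}

DEFAULT_BEAD_RADIUS = 17.0  # Angstrom

#: Mass held by one bead of the default radius at protein density; sets the
#: deterministic default bead count n = ceil(mw / M_PER_BEAD).
M_PER_BEAD = sphere_volume(DEFAULT_BEAD_RADIUS * 1e-8) * PROTEIN_DENSITY / DALTON_G


def average_protein_mac_weights() -> dict:
    """Mass fractions of the average protein composition."""
    masses = {el: f * ATOMIC_WEIGHTS[el] for el, f in AVERAGE_PROTEIN_ATOM_FRACTIONS.items()}
    total = sum(masses.values())
    return {el: m / total for el, m in masses.items()}


@dataclass
class StructureRecord:
    """Atom coordinates plus derived mass and elemental composition."""

    id: str
    coords: np.ndarray  # (n_atoms, 3), Angstrom
    elements: list  # element symbol per atom (uppercase)
    composition: Counter  # element -> count, hydrogens included
    chains: list = field(default_factory=list)

    def __post_init__(self):
        if len(self.coords) == 0:
            raise ValueError(f"structure {self.id!r} has no atoms")
        if any(c <= 0 for c in self.composition.values()):
            raise ValueError("composition counts must be positive")

    @property
    def mw(self) -> float:
        """Molecular weight (Da) from the full composition."""
        return float(sum(ATOMIC_WEIGHTS[el] * n for el, n in self.composition.items()))


def read_structure(path, fmt: str | None = None) -> StructureRecord:
    """Read a PDB or mmCIF file into a :class:`StructureRecord`.

    Coordinates are kept in Angstrom.  If the file carries no hydrogens,
    template hydrogens are added to the *composition* (not the coordinates):
    per-residue counts for the 20 standard amino acids plus two terminal
    hydrogens per polymer chain, and one terminal oxygen when no OXT atom is
    present.
    """
    import gemmi

    if fmt is None:
        st = gemmi.read_structure(str(path))
    else:
        st = gemmi.read_structure(str(path), format=getattr(gemmi.CoorFormat, fmt))
    st.setup_entities()
    coords, elements = [], []
    composition: Counter = Counter()
    chains = []
    n_hydrogens_present = 0
    for model in st:
        for chain in model:
            chains.append(chain.name)
            has_oxt = False
            n_template_h = 0
            for residue in chain:
                for atom in residue:
                    el = atom.element.name.upper()
                    if el == "H" or el == "D":
                        n_hydrogens_present += 1
                        composition[("H")] += 1
                        continue
                    coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                    elements.append(el)
                    composition[el] += 1
                    if atom.name == "OXT":
                        has_oxt = True
                n_template_h += RESIDUE_HYDROGENS.get(residue.name, 0)
            if n_hydrogens_present == 0:
                composition["H"] += n_template_h + 2  # chain termini
                if not has_oxt and n_template_h > 0:
                    composition["O"] += 1
        break  # first model only
    if not coords:
        raise ValueError(f"no atoms found in {path}")
    return StructureRecord(
        id=st.name or str(path),
        coords=np.asarray(coords, dtype=float),
        elements=elements,
        composition=composition,
        chains=chains,
    )


@dataclass
class BeadModel:
    """Coarse-grained representation: spheres with mass shares.

    The sum of ``mass_share`` equals the structure's molecular weight
    exactly; positions are in the structure frame (Angstrom).
    """

    centers: np.ndarray  # (n_beads, 3), Angstrom
    radius: float = DEFAULT_BEAD_RADIUS
    mass_share: np.ndarray = None  # (n_beads,), Da

    def __post_init__(self):
        if len(self.centers) < 1:
            raise ValueError("bead model needs at least one bead")
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        if self.mass_share is None:
            self.mass_share = np.full(len(self.centers), 1.0)
        self.mass_share = np.asarray(self.mass_share, dtype=float)

    @property
    def total_mass(self) -> float:
        return float(self.mass_share.sum())

    @property
    def bounding_radius(self) -> float:
        """Radius (Angstrom) of the sphere bounding all beads, from the centroid."""
        centroid = self.centers.mean(axis=0)
        dist = np.linalg.norm(self.centers - centroid, axis=1)
        return float(dist.max() + self.radius)


def default_bead_count(mw: float) -> int:
    """Deterministic bead count: one default-radius bead per ~15 kDa."""
    return max(1, int(np.ceil(mw / M_PER_BEAD)))


def bead_model(
    structure: StructureRecord, n_beads: int | None = None, seed: int = 0,
    radius: float = DEFAULT_BEAD_RADIUS,
) -> BeadModel:
    """Cluster atom coordinates into ``n_beads`` beads with k-means.

    Bead centres are plain (unweighted) k-means centroids; mass enters only
    through the per-bead shares, which are proportional to the atomic mass
    assigned to each cluster and rescaled so their sum equals the structure
    molecular weight (template hydrogens included).
    """
    if n_beads is None:
        n_beads = default_bead_count(structure.mw)
    if n_beads < 1:
        raise ValueError("n_beads must be >= 1")
    if n_beads > len(structure.coords):
        raise ValueError("n_beads exceeds atom count")

    atom_masses = np.array([ATOMIC_WEIGHTS[el] for el in structure.elements])
    if n_beads == 1:
        centers = structure.coords.mean(axis=0, keepdims=True)
        labels = np.zeros(len(structure.coords), dtype=int)
    elif n_beads == len(structure.coords):
        centers = structure.coords.copy()
        labels = np.arange(len(structure.coords))
    else:
        from sklearn.cluster import KMeans

        km = KMeans(n_clusters=n_beads, init="k-means++", n_init=1, random_state=seed)
        labels = km.fit_predict(structure.coords)
        centers = km.cluster_centers_
    shares = np.bincount(labels, weights=atom_masses, minlength=n_beads)
    shares = shares * (structure.mw / shares.sum())
    return BeadModel(centers=centers, radius=radius, mass_share=shares)


def synthetic_globule(mw: float, seed: int = 0, name: str | None = None) -> StructureRecord:
    """Synthetic globular decoy of the requested molecular weight.

    Pseudo-atoms with the average protein composition are placed uniformly in
    a sphere whose volume matches ``mw`` at protein density 1.22 g cm^-3.
    Stands in for proteins without an experimental structure.
    """
    if mw <= 0:
        raise ValueError("mw must be positive")
    rng = rng_for(seed, "structure")
    mean_atom_mass = sum(
        f * ATOMIC_WEIGHTS[el] for el, f in AVERAGE_PROTEIN_ATOM_FRACTIONS.items()
    )
    n_atoms = max(2, int(round(mw / mean_atom_mass)))
    # integer element counts, largest remainder
    targets = {el: f * n_atoms for el, f in AVERAGE_PROTEIN_ATOM_FRACTIONS.items()}
    counts = {el: int(np.floor(t)) for el, t in targets.items()}
    short = n_atoms - sum(counts.values())
    for el in sorted(targets, key=lambda e: targets[e] - counts[e], reverse=True)[:short]:
        counts[el] += 1
    elements = [el for el, n in counts.items() for _ in range(n)]

    radius_a = globule_radius_angstrom(mw)
    # uniform sampling in the sphere
    xyz = rng.normal(size=(n_atoms, 3))
    xyz /= np.linalg.norm(xyz, axis=1, keepdims=True)
    xyz *= radius_a * rng.random(n_atoms)[:, None] ** (1 / 3)
    return StructureRecord(
        id=name or f"globule_{int(mw)}",
        coords=xyz,
        elements=elements,
        composition=Counter({el: n for el, n in counts.items() if n > 0}),
    )


def globule_radius_angstrom(mw: float) -> float:
    """Closed-form radius of a compact globule of mass ``mw`` at density 1.22."""
    volume_cm3 = mw * DALTON_G / PROTEIN_DENSITY
    return (volume_cm3 * 3.0 / (4.0 * np.pi)) ** (1 / 3) * 1e8
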