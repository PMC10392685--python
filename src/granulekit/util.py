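"""Shared physical constants and seeded random-stream handling.

Every stochastic stage of the pipeline draws from its own named stream derived
from a single master seed, so stages can be re-run independently and the whole
pipeline is reproducible bit-for-bit under a fixed seed.
"""

from __future__ import annotations

import numpy as np

# Physical constants (CODATA 2018)
AVOGADRO = 6.02214076e23  # mol^-1
ELECTRON_RADIUS_CM = 2.8179403262e-13  # classical electron radius, cm
HC_EV_ANGSTROM = 12398.41984  # h*c, eV * Angstrom

#: Mean protein mass density, g cm^-3 (Andersson & Hovmoller value used
#: throughout for converting protein mass to excluded volume).
PROTEIN_DENSITY = 1.22

WATER_DENSITY = 1.0  # g cm^-3
DALTON_G = 1.0 / AVOGADRO  # 1 Da in grams

# Registry of named random streams.  Each maps to a fixed spawn key so that
# adding a stream never perturbs the others.
_STREAMS = {
    "catalog": 0,
    "proteome": 1,
    "structure": 2,
    "packing": 3,
    "relax": 4,
    "tomogram": 5,
    "phantom": 6,
    "library": 7,
    "detection": 8,
}


def rng_for(seed: int, stream: str) -> np.random.Generator:
    """Return the named random stream derived from ``seed``.

    Streams are independent PCG64 generators obtained from
    ``SeedSequence(seed, spawn_key=(k,))`` with a fixed per-stream key ``k``.
    """
    if stream not in _STREAMS:
        raise KeyError(f"unknown random stream {stream!r}")
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(_STREAMS[stream],))
    return np.random.Generator(np.random.PCG64(ss))


def sphere_volume(radius: float) -> float:
    """Volume of a sphere (same cubed unit as ``radius``)."""
    return 4.0 / 3.0 * np.pi * radius**3
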