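"""Per-residue physical constants used by the coarse-grained representation.

Volumes are mean residue volumes in folded proteins (Pontius-style table, A^3);
masses are average residue (minus water) masses in Da. Bead radii are derived
from volume additivity: a bead covering residues r1..rn is the sphere whose
volume equals the summed residue volumes.
"""
from __future__ import annotations

import numpy as np

RESIDUE_VOLUME_A3: dict[str, float] = {
    "A": 91.5, "R": 196.1, "N": 138.3, "D": 135.2, "C": 114.4,
    "Q": 156.4, "E": 154.6, "G": 67.5, "H": 163.2, "I": 162.6,
    "L": 163.4, "K": 162.5, "M": 165.9, "F": 198.8, "P": 123.4,
    "S": 102.0, "T": 126.0, "W": 237.2, "Y": 209.8, "V": 138.4,
}

RESIDUE_MASS_DA: dict[str, float] = {
    "A": 71.08, "R": 156.19, "N": 114.10, "D": 115.09, "C": 103.14,
    "Q": 128.13, "E": 129.12, "G": 57.05, "H": 137.14, "I": 113.16,
    "L": 113.16, "K": 128.17, "M": 131.19, "F": 147.18, "P": 97.12,
    "S": 87.08, "T": 101.10, "W": 186.21, "Y": 163.18, "V": 99.13,
}


def bead_radius(aas: str) -> float:
    """Radius (A) of the sphere with volume equal to the summed residue volumes."""
    vol = sum(RESIDUE_VOLUME_A3[a] for a in aas)
    return float((3.0 * vol / (4.0 * np.pi)) ** (1.0 / 3.0))


def bead_mass(aas: str) -> float:
    return float(sum(RESIDUE_MASS_DA[a] for a in aas))
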