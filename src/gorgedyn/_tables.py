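"""Element property tables and side-chain dihedral definitions.

van der Waals radii follow Bondi's element-wise compilation (values in Å);
masses are standard atomic weights in Da. Geometry throughout the package
uses heavy atoms only, so the hydrogen entries exist mainly for
completeness when a file does carry them.
"""

from __future__ import annotations

# Bondi vdW radii, Å
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "SE": 1.90,
    "ZN": 1.39,
    "FE": 1.40,
    "MG": 1.73,
    "NA": 2.27,
    "K": 2.75,
    "CA": 2.31,
}
DEFAULT_VDW = 1.70

ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998,
    "P": 30.974,
    "S": 32.06,
    "CL": 35.45,
    "BR": 79.904,
    "I": 126.904,
    "SE": 78.971,
    "ZN": 65.38,
    "FE": 55.845,
    "MG": 24.305,
    "NA": 22.990,
    "K": 39.098,
    "CA": 40.078,
}
DEFAULT_MASS = 12.011

# Side-chain dihedral atom names (N-terminal to distal). chi1 is
# N-CA-CB-XG for every residue that has one; chi2 extends one bond further.
# Proline is deliberately restricted to chi1: its ring makes the higher
# chi angles redundant with chi1 for conformational-entropy purposes.
CHI1_ATOMS: dict[str, tuple[str, str, str, str]] = {
    "ARG": ("N", "CA", "CB", "CG"),
    "ASN": ("N", "CA", "CB", "CG"),
    "ASP": ("N", "CA", "CB", "CG"),
    "CYS": ("N", "CA", "CB", "SG"),
    "GLN": ("N", "CA", "CB", "CG"),
    "GLU": ("N", "CA", "CB", "CG"),
    "HIS": ("N", "CA", "CB", "CG"),
    "ILE": ("N", "CA", "CB", "CG1"),
    "LEU": ("N", "CA", "CB", "CG"),
    "LYS": ("N", "CA", "CB", "CG"),
    "MET": ("N", "CA", "CB", "CG"),
    "PHE": ("N", "CA", "CB", "CG"),
    "PRO": ("N", "CA", "CB", "CG"),
    "SER": ("N", "CA", "CB", "OG"),
    "THR": ("N", "CA", "CB", "OG1"),
    "TRP": ("N", "CA", "CB", "CG"),
    "TYR": ("N", "CA", "CB", "CG"),
    "VAL": ("N", "CA", "CB", "CG1"),
}

CHI2_ATOMS: dict[str, tuple[str, str, str, str]] = {
    "ARG": ("CA", "CB", "CG", "CD"),
    "ASN": ("CA", "CB", "CG", "OD1"),
    "ASP": ("CA", "CB", "CG", "OD1"),
    "GLN": ("CA", "CB", "CG", "CD"),
    "GLU": ("CA", "CB", "CG", "CD"),
    "HIS": ("CA", "CB", "CG", "ND1"),
    "ILE": ("CA", "CB", "CG1", "CD1"),
    "LEU": ("CA", "CB", "CG", "CD1"),
    "LYS": ("CA", "CB", "CG", "CD"),
    "MET": ("CA", "CB", "CG", "SD"),
    "PHE": ("CA", "CB", "CG", "CD1"),
    "TRP": ("CA", "CB", "CG", "CD1"),
    "TYR": ("CA", "CB", "CG", "CD1"),
}


def vdw_radius(element: str) -> float:
    return VDW_RADII.get(element.upper(), DEFAULT_VDW)


def atomic_mass(element: str) -> float:
    return ATOMIC_MASSES.get(element.upper(), DEFAULT_MASS)
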