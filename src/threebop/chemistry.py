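"""Chemical reference tables: van der Waals radii, polar-atom classification,
and sidechain chi-angle definitions for the 20 standard amino acids.

Polar atoms are labelled with coarse atom-type categories (NH1, NH2, NH3,
carbonyl_O, carboxylate_O, hydroxyl, imidazole, indole) so that penalty
coefficients can be assigned per type. Histidine is treated in the neutral
NE2-H tautomer (ND1 accepts, NE2 donates).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

__all__ = [
    "PolarClass",
    "PolarInfo",
    "VDW_RADII",
    "STANDARD_AA",
    "CHI_ATOMS",
    "SIDECHAIN_POLAR",
    "BACKBONE_POLAR",
    "polar_info",
    "vdw_radius",
]


class PolarClass(Enum):
    NONE = "none"
    DONOR_HEAVY = "donor_heavy"
    ACCEPTOR = "acceptor"
    DONOR_AND_ACCEPTOR = "donor_and_acceptor"


@dataclass(frozen=True)
class PolarInfo:
    """Classification of one polar heavy atom."""

    type_label: str
    is_donor: bool
    is_acceptor: bool
    hydrogen_names: tuple  # template hydrogen atom names bonded to this atom
    acceptor_capacity: int = 2

    @property
    def polar_class(self) -> PolarClass:
        if self.is_donor and self.is_acceptor:
            return PolarClass.DONOR_AND_ACCEPTOR
        if self.is_donor:
            return PolarClass.DONOR_HEAVY
        return PolarClass.ACCEPTOR


# Bondi element radii, Angstroms.
VDW_RADII = {"H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}
DEFAULT_VDW = 1.70

STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

# Heavy-atom quadruples defining chi dihedrals, in rotation order.
CHI_ATOMS = {
    "ARG": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "NE"), ("CG", "CD", "NE", "CZ")],
    "ASN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "ASP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "CYS": [("N", "CA", "CB", "SG")],
    "GLN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "GLU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "HIS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "ILE": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "LEU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "LYS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "CE"), ("CG", "CD", "CE", "NZ")],
    "MET": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"),
            ("CB", "CG", "SD", "CE")],
    "PHE": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "SER": [("N", "CA", "CB", "OG")],
    "THR": [("N", "CA", "CB", "OG1")],
    "TRP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TYR": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "VAL": [("N", "CA", "CB", "CG1")],
    "ALA": [], "GLY": [], "PRO": [],
}

_HYDROXYL = PolarInfo("hydroxyl", True, True, (), acceptor_capacity=2)

# Sidechain polar heavy atoms, keyed (residue name, atom name).
SIDECHAIN_POLAR = {
    ("SER", "OG"): PolarInfo("hydroxyl", True, True, ("HG",)),
    ("THR", "OG1"): PolarInfo("hydroxyl", True, True, ("HG1",)),
    ("TYR", "OH"): PolarInfo("hydroxyl", True, True, ("HH",)),
    ("ASN", "OD1"): PolarInfo("carbonyl_O", False, True, ()),
    ("ASN", "ND2"): PolarInfo("NH2", True, False, ("HD21", "HD22")),
    ("GLN", "OE1"): PolarInfo("carbonyl_O", False, True, ()),
    ("GLN", "NE2"): PolarInfo("NH2", True, False, ("HE21", "HE22")),
    ("ASP", "OD1"): PolarInfo("carboxylate_O", False, True, ()),
    ("ASP", "OD2"): PolarInfo("carboxylate_O", False, True, ()),
    ("GLU", "OE1"): PolarInfo("carboxylate_O", False, True, ()),
    ("GLU", "OE2"): PolarInfo("carboxylate_O", False, True, ()),
    ("LYS", "NZ"): PolarInfo("NH3", True, False, ("HZ1", "HZ2", "HZ3")),
    ("ARG", "NE"): PolarInfo("NH1", True, False, ("HE",)),
    ("ARG", "NH1"): PolarInfo("NH2", True, False, ("HH11", "HH12")),
    ("ARG", "NH2"): PolarInfo("NH2", True, False, ("HH21", "HH22")),
    ("HIS", "ND1"): PolarInfo("imidazole", False, True, ()),
    ("HIS", "NE2"): PolarInfo("imidazole", True, False, ("HE2",)),
    ("TRP", "NE1"): PolarInfo("indole", True, False, ("HE1",)),
}

# Backbone amide N (donor when the preceding residue provides geometry for
# the amide H) and carbonyl O (acceptor).
BACKBONE_POLAR = {
    "N": PolarInfo("NH1", True, False, ("H",)),
    "O": PolarInfo("carbonyl_O", False, True, ()),
}

HYDROXYL_ATOMS = {("SER", "OG"), ("THR", "OG1"), ("TYR", "OH")}


def polar_info(res_name: str, atom_name: str, backbone: bool) -> PolarInfo | None:
    """Look up the polar classification of an atom, or None if apolar."""
    if backbone:
        return BACKBONE_POLAR.get(atom_name)
    return SIDECHAIN_POLAR.get((res_name, atom_name))


def vdw_radius(element: str) -> float:
    return VDW_RADII.get(element.upper(), DEFAULT_VDW)
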