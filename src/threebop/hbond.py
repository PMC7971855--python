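"""Geometric hydrogen-bond detection between polar sites.

An h-bond requires donor-heavy-to-acceptor distance in [2.5, 3.5] A and a
D-H...A angle of at least 120 degrees. Quality is the product of a
distance term (1 at 2.8 A, falling linearly to 0 at either window edge)
and an angle term (0 at 120 degrees, 1 at 180, linear), giving a score in
[0, 1]. The ``quality_threshold`` knob plays the role of an h-bond energy
stringency cutoff; the default 0.37 corresponds to accepting bonds at
roughly a third of the ideal score. Rotatable hydroxyl protons are
represented by staggered position samples, and a bond counts if any
sample passes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chemistry import PolarClass, polar_info, STANDARD_AA
from .errors import UsageError
from .geometry import angle_deg
from .structure import Atom, Residue

__all__ = ["PolarSite", "HBond", "classify_polar_atoms", "detect_hbond",
           "hbond_between", "candidate_satisfiers", "sites_for_atom",
           "DEFAULT_QUALITY_THRESHOLD"]

DEFAULT_QUALITY_THRESHOLD = 0.37

DIST_MIN = 2.5
DIST_IDEAL = 2.8
DIST_MAX = 3.5
ANGLE_MIN = 120.0


@dataclass
class PolarSite:
    atom: Atom
    role: str  # "donor" | "acceptor"
    max_hbonds: int = 2

    def __post_init__(self):
        if self.role not in ("donor", "acceptor"):
            raise UsageError(f"bad site role {self.role!r}")
        if self.role == "donor" and not self.atom.bound_hydrogens:
            raise UsageError(
                f"donor site on {self.atom.name} has no hydrogens")


@dataclass
class HBond:
    donor_site: PolarSite
    acceptor_site: PolarSite
    d_a_distance: float
    dha_angle: float
    quality: float


def sites_for_atom(atom: Atom):
    """Donor/acceptor sites implied by an atom's polar class."""
    sites = []
    info = polar_info(atom.res_name, atom.name, atom.is_backbone)
    cap = info.acceptor_capacity if info is not None else 2
    if atom.polar_class in (PolarClass.DONOR_HEAVY,
                            PolarClass.DONOR_AND_ACCEPTOR):
        if atom.bound_hydrogens:
            sites.append(PolarSite(atom, "donor",
                                   max_hbonds=len(atom.bound_hydrogens)))
    if atom.polar_class in (PolarClass.ACCEPTOR,
                            PolarClass.DONOR_AND_ACCEPTOR):
        sites.append(PolarSite(atom, "acceptor", max_hbonds=cap))
    return sites


def classify_polar_atoms(residue: Residue):
    """Canonical donor/acceptor assignment for a standard residue,
    backbone amide and carbonyl included."""
    if residue.name not in STANDARD_AA:
        raise UsageError(f"cannot classify nonstandard residue "
                         f"{residue.name!r}")
    sites = []
    for atom in residue.atoms:
        sites.extend(sites_for_atom(atom))
    return sites


def detect_hbond(donor: PolarSite, acceptor: PolarSite,
                 quality_threshold: float = DEFAULT_QUALITY_THRESHOLD):
    """Return an HBond if the geometric criterion passes at the given
    quality threshold, else None."""
    if donor.role != "donor" or acceptor.role != "acceptor":
        raise UsageError("detect_hbond needs a donor site and an "
                         "acceptor site, in that order")
    if donor.atom is acceptor.atom or (
            donor.atom.key == acceptor.atom.key):
        raise UsageError("an atom cannot hydrogen-bond to itself")
    d_pos = donor.atom.position
    a_pos = acceptor.atom.position
    dist = float(np.linalg.norm(d_pos - a_pos))
    if not (DIST_MIN <= dist <= DIST_MAX):
        return None
    if dist <= DIST_IDEAL:
        dist_term = (dist - DIST_MIN) / (DIST_IDEAL - DIST_MIN)
    else:
        dist_term = (DIST_MAX - dist) / (DIST_MAX - DIST_IDEAL)
    best = None
    for h in donor.atom.bound_hydrogens:
        ang = angle_deg(d_pos, h, a_pos)
        if ang < ANGLE_MIN:
            continue
        quality = dist_term * (ang - ANGLE_MIN) / (180.0 - ANGLE_MIN)
        if best is None or quality > best[0]:
            best = (quality, ang)
    if best is None or best[0] < quality_threshold:
        return None
    return HBond(donor, acceptor, dist, best[1], best[0])


def hbond_between(a: Atom, b: Atom,
                  quality_threshold: float = DEFAULT_QUALITY_THRESHOLD):
    """Best h-bond between two atoms considering both donor/acceptor
    directions, or None. Same-residue backbone pairs (the i->i amide to
    carbonyl contact) are excluded."""
    if a.key == b.key:
        return None
    if (a.is_backbone and b.is_backbone and a.res_index == b.res_index
            and a.chain_id == b.chain_id):
        return None
    best = None
    for donor_atom, acceptor_atom in ((a, b), (b, a)):
        donor = [s for s in sites_for_atom(donor_atom) if s.role == "donor"]
        acceptor = [s for s in sites_for_atom(acceptor_atom)
                    if s.role == "acceptor"]
        if not donor or not acceptor:
            continue
        hb = detect_hbond(donor[0], acceptor[0], quality_threshold)
        if hb is not None and (best is None or hb.quality > best.quality):
            best = hb
    return best


def candidate_satisfiers(b_atom: Atom, b_origin, context,
                         quality_threshold: float = DEFAULT_QUALITY_THRESHOLD):
    """Polar atoms in the context that h-bond to a buried atom B.

    ``context`` is an iterable of (atom, origin) pairs where origin is
    None for fixed atoms or a (position, rotamer ordinal) pair. Atoms in
    a *different* rotamer at B's own position are excluded (mutually
    exclusive alternatives cannot coexist); atoms of B's own rotamer are
    included. Order is preserved.
    """
    out = []
    for q_atom, q_origin in context:
        if q_atom.key == b_atom.key:
            continue
        if (b_origin is not None and q_origin is not None
                and q_origin[0] == b_origin[0] and q_origin != b_origin):
            continue
        if hbond_between(b_atom, q_atom, quality_threshold) is not None:
            out.append((q_atom, q_origin))
    return out
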