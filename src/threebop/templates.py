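"""Ideal amino-acid geometry from bundled CCD component templates.

Sidechains are built by superimposing a template residue's N/CA/C frame
onto the target backbone and then rotating about each chi bond to the
requested dihedral. Hydrogens ride with the heavy atoms they are bonded
to; only hydrogens on polar heavy atoms are retained (as bound-hydrogen
positions), since apolar hydrogens play no role here.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import biotite.structure.info as struc_info

from .chemistry import CHI_ATOMS, HYDROXYL_ATOMS, STANDARD_AA, polar_info
from .errors import StructureError, UsageError
from .geometry import (dihedral_deg, kabsch_transform, place_atom,
                       rotate_about_axis)

__all__ = ["build_sidechain", "ideal_chi", "template_residue"]

# Atoms belonging to the backbone in CCD amino-acid components.
_BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT", "H", "H2", "H3", "HXT",
                   "HA", "HA2", "HA3"}


@lru_cache(maxsize=32)
def template_residue(res_name: str):
    """Return (names, elements, coords, adjacency) for an ideal residue."""
    if res_name not in STANDARD_AA:
        raise UsageError(f"not a standard amino acid: {res_name!r}")
    res = struc_info.residue(res_name)
    names = list(res.atom_name)
    elements = list(res.element)
    coords = np.array(res.coord, dtype=float)
    adjacency = {i: set() for i in range(len(names))}
    for i, j, _ in res.bonds.as_array():
        adjacency[int(i)].add(int(j))
        adjacency[int(j)].add(int(i))
    return names, elements, coords, adjacency


def _downstream(adjacency, start: int, blocked: int) -> set:
    """Atoms reachable from ``start`` without crossing ``blocked``."""
    seen = {blocked, start}
    stack = [start]
    while stack:
        cur = stack.pop()
        for nxt in adjacency[cur]:
            if nxt not in seen:
                seen.add(nxt)
                stack.append(nxt)
    seen.discard(blocked)
    return seen


@lru_cache(maxsize=32)
def ideal_chi(res_name: str) -> tuple:
    """Chi dihedrals of the undisturbed template, in template order."""
    names, _, coords, _ = template_residue(res_name)
    idx = {n: i for i, n in enumerate(names)}
    return tuple(
        dihedral_deg(*(coords[idx[a]] for a in quad))
        for quad in CHI_ATOMS[res_name]
    )


def build_sidechain(res_name: str, n_xyz, ca_xyz, c_xyz, chi=None):
    """Build an ideal sidechain on a backbone frame.

    Parameters
    ----------
    res_name : three-letter code of a standard amino acid.
    n_xyz, ca_xyz, c_xyz : backbone N, CA, C coordinates (Angstroms).
    chi : sequence of chi dihedrals in degrees, one per rotatable bond
        (padded with template values if shorter); None keeps template chi.

    Returns
    -------
    list of (atom_name, element, position, hydrogen_positions) for each
    sidechain heavy atom (CB first, template order). ``hydrogen_positions``
    lists riding hydrogens for polar heavy atoms, else is empty.
    """
    names, elements, coords, adjacency = template_residue(res_name)
    idx = {n: i for i, n in enumerate(names)}
    for req in ("N", "CA", "C"):
        if req not in idx:
            raise StructureError(f"template {res_name} lacks {req}")
    coords = coords.copy()

    rot, trans = kabsch_transform(
        coords[[idx["N"], idx["CA"], idx["C"]]],
        np.array([n_xyz, ca_xyz, c_xyz], dtype=float),
    )
    coords = coords @ rot.T + trans
    # pin the frame atoms to the actual backbone so chi dihedrals are
    # measured (and set) against the true N/CA/C, not the least-squares fit
    coords[idx["N"]] = np.asarray(n_xyz, float)
    coords[idx["CA"]] = np.asarray(ca_xyz, float)
    coords[idx["C"]] = np.asarray(c_xyz, float)

    chi_defs = CHI_ATOMS[res_name]
    if chi is not None:
        if len(chi) > len(chi_defs):
            raise UsageError(
                f"{res_name} has {len(chi_defs)} chi angles, got {len(chi)}")
        for k, target in enumerate(chi):
            a, b, c, d = (idx[x] for x in chi_defs[k])
            current = dihedral_deg(coords[a], coords[b], coords[c], coords[d])
            moving = sorted(_downstream(adjacency, c, b))
            coords[moving] = rotate_about_axis(
                coords[moving], coords[b], coords[c] - coords[b],
                float(target) - current)

    out = []
    for i, name in enumerate(names):
        if name in _BACKBONE_NAMES or elements[i] == "H":
            continue
        info = polar_info(res_name, name, backbone=False)
        hydrogens = []
        if (res_name, name) in HYDROXYL_ATOMS:
            hydrogens = hydroxyl_hydrogen_samples(
                res_name, name, {n: coords[j] for n, j in idx.items()},
                adjacency, idx, elements)
        elif info is not None and info.hydrogen_names:
            hydrogens = [coords[idx[h]].copy()
                         for h in info.hydrogen_names if h in idx]
        out.append((name, elements[i], coords[i].copy(), hydrogens))
    return out


_HYDROXYL_FRAME = {
    # hydroxyl oxygen -> (antecedent heavy atom, torsion reference atom)
    ("SER", "OG"): ("CB", "CA"),
    ("THR", "OG1"): ("CB", "CA"),
    ("TYR", "OH"): ("CZ", "CE1"),
}

_OH_BOND = 0.96
_COH_ANGLE = 109.5
_OH_TORSIONS = (60.0, 180.0, 300.0)


def staggered_hydroxyl_hydrogens(ref_xyz, antecedent_xyz, oxygen_xyz):
    """Three staggered hydroxyl-H positions about the C-O bond.

    The hydroxyl proton is rotatable, so donation is evaluated against
    each sample and an h-bond counts if any sample passes.
    """
    return [place_atom(ref_xyz, antecedent_xyz, oxygen_xyz,
                       _OH_BOND, _COH_ANGLE, t) for t in _OH_TORSIONS]


def hydroxyl_hydrogen_samples(res_name, atom_name, coords_by_name,
                              adjacency=None, idx=None, elements=None):
    frame = _HYDROXYL_FRAME.get((res_name, atom_name))
    if frame is None:
        return []
    antecedent, ref = frame
    if antecedent not in coords_by_name or ref not in coords_by_name:
        return []
    return staggered_hydroxyl_hydrogens(
        coords_by_name[ref], coords_by_name[antecedent],
        coords_by_name[atom_name])
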