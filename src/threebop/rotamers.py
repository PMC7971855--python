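"""Discrete rotamer sets and a minimal base force field.

Rotamers are enumerated from canonical staggered chi values (60/180/300
per rotatable bond; the "extra" level adds +-10 degree subsamples on chi1
and chi2). The base energy is intentionally minimal -- a capped soft
steric repulsion plus a hydrogen-bond bonus of -2 x quality, the
approximate depth of an ideal h-bond well in kcal/mol -- so that packing
is meaningful while the oversaturation penalty stays purely additive on
top of it.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .chemistry import CHI_ATOMS, PolarClass, polar_info, vdw_radius
from .errors import UsageError
from .hbond import DEFAULT_QUALITY_THRESHOLD, hbond_between
from .structure import Atom, Pose
from .templates import build_sidechain

__all__ = ["Rotamer", "RotamerSet", "build_rotamer_set",
           "native_rotamer_set", "base_one_body", "base_two_body",
           "precompute_base_energies", "apply_assignment"]

STAGGERED_CHI = (60.0, 180.0, 300.0)
EXTRA_OFFSETS = (-10.0, 0.0, 10.0)
STERIC_CUTOFF = 8.0
STERIC_CAP = 100.0
HBOND_WEIGHT = -2.0
PRUNE_CUTOFF = 25.0


@dataclass
class Rotamer:
    position: int
    residue_type: str
    chi: tuple
    atoms: list
    ordinal: int = 0

    @property
    def id(self):
        return (self.position, self.ordinal)

    @property
    def polar_atoms(self):
        return [a for a in self.atoms if a.polar_class is not PolarClass.NONE]


@dataclass
class RotamerSet:
    """Per-position rotamer alternatives plus the fixed context.

    ``fixed_atoms`` holds every atom that does not move during packing:
    all backbone atoms and the sidechains of non-designable residues.
    """

    rotamers: dict  # position -> list[Rotamer]
    fixed_atoms: list = field(default_factory=list)

    @property
    def positions(self):
        return sorted(self.rotamers)

    @property
    def fixed_polar_atoms(self):
        return [a for a in self.fixed_atoms
                if a.polar_class is not PolarClass.NONE]

    def rotamer(self, position: int, ordinal: int) -> Rotamer:
        return self.rotamers[position][ordinal]

    def total_rotamers(self) -> int:
        return sum(len(v) for v in self.rotamers.values())

    def polar_context(self):
        """All polar atoms with their origins: (atom, None) for fixed,
        (atom, (position, ordinal)) for rotamer atoms."""
        out = [(a, None) for a in self.fixed_polar_atoms]
        for pos in self.positions:
            for rot in self.rotamers[pos]:
                out.extend((a, rot.id) for a in rot.polar_atoms)
        return out


def _finalize_rotamer_atoms(atoms, position, res_type, chain_id):
    for atom in atoms:
        atom.res_index = position
        atom.res_name = res_type
        atom.chain_id = chain_id
        atom.is_backbone = False
        atom.vdw_radius = vdw_radius(atom.element)
        info = polar_info(res_type, atom.name, backbone=False)
        if info is None:
            atom.polar_class = PolarClass.NONE
        elif info.is_donor and info.is_acceptor:
            atom.polar_class = PolarClass.DONOR_AND_ACCEPTOR
        elif info.is_donor:
            atom.polar_class = (PolarClass.DONOR_HEAVY
                                if atom.bound_hydrogens else PolarClass.NONE)
        else:
            atom.polar_class = PolarClass.ACCEPTOR
    return atoms


def _make_rotamer(pose, position, res_type, chi, serial_start=90000):
    res = pose.residue_at(position)
    chain = pose.chain_ids[pose.residues.index(res)]
    built = build_sidechain(res_type,
                            res.atom("N").position,
                            res.atom("CA").position,
                            res.atom("C").position,
                            chi=chi)
    atoms = [Atom(serial_start + k, name, element, xyz,
                  bound_hydrogens=list(hydrogens))
             for k, (name, element, xyz, hydrogens) in enumerate(built)]
    return Rotamer(position, res_type, tuple(chi or ()),
                   _finalize_rotamer_atoms(atoms, position, res_type, chain))


def _chi_values(res_type: str, level: str):
    n_chi = len(CHI_ATOMS[res_type])
    if n_chi == 0:
        yield ()
        return
    per_bond = []
    for k in range(n_chi):
        if level == "extra" and k < 2:
            per_bond.append(tuple(base + off for base in STAGGERED_CHI
                                  for off in EXTRA_OFFSETS))
        else:
            per_bond.append(STAGGERED_CHI)
    yield from itertools.product(*per_bond)


def build_rotamer_set(pose: Pose, designable: dict,
                      chi_level: str = "standard",
                      include_native: bool = False,
                      quality_threshold: float = DEFAULT_QUALITY_THRESHOLD,
                      prune_cutoff: float = PRUNE_CUTOFF) -> RotamerSet:
    """Enumerate staggered-chi rotamers for the designable positions.

    ``designable`` maps residue index -> iterable of allowed residue
    types. Rotamers clashing irreparably with the fixed context (base
    one-body above ``prune_cutoff``) are pruned, always keeping at least
    one rotamer per position. ``include_native`` appends the pose's
    current sidechain as an extra rotamer when its type is allowed.
    """
    if chi_level not in ("standard", "extra"):
        raise UsageError(f"unknown chi level {chi_level!r}")
    valid = {r.index for r in pose.residues}
    for pos in designable:
        if pos not in valid:
            raise UsageError(f"designable position {pos} not in pose")
    designable_set = set(designable)

    fixed_atoms = []
    for res, chain in zip(pose.residues, pose.chain_ids):
        fixed_atoms.extend(res.backbone_atoms)
        if res.index not in designable_set:
            fixed_atoms.extend(res.sidechain_atoms)

    rset = RotamerSet({}, fixed_atoms)
    for pos in sorted(designable):
        types = designable[pos]
        if isinstance(types, str):
            types = [types]
        rotamers = []
        for res_type in types:
            if res_type not in CHI_ATOMS:
                raise UsageError(f"not a standard residue type: {res_type!r}")
            for chi in _chi_values(res_type, chi_level):
                rotamers.append(_make_rotamer(pose, pos, res_type, chi))
        if include_native:
            native = native_rotamer(pose, pos)
            if native is not None and native.residue_type in set(
                    t for t in types):
                rotamers.append(native)
        scored = [(base_one_body(r, fixed_atoms, quality_threshold), r)
                  for r in rotamers]
        kept = [r for e, r in scored if e <= prune_cutoff]
        if not kept:
            kept = [min(scored, key=lambda er: er[0])[1]]
        for ordinal, rot in enumerate(kept):
            rot.ordinal = ordinal
        rset.rotamers[pos] = kept
    return rset


def native_rotamer(pose: Pose, position: int):
    """The pose's current sidechain as a Rotamer, or None if absent."""
    res = pose.residue_at(position)
    if not res.sidechain_atoms:
        return None
    chain = pose.chain_ids[pose.residues.index(res)]
    atoms = [a.copy() for a in res.sidechain_atoms]
    return Rotamer(position, res.name, (),
                   _finalize_rotamer_atoms(atoms, position, res.name, chain))


def native_rotamer_set(pose: Pose, positions) -> RotamerSet:
    """Singleton rotamer set holding only the pose's own sidechains."""
    designable_set = set(positions)
    fixed_atoms = []
    for res, chain in zip(pose.residues, pose.chain_ids):
        fixed_atoms.extend(res.backbone_atoms)
        if res.index not in designable_set:
            fixed_atoms.extend(res.sidechain_atoms)
    rset = RotamerSet({}, fixed_atoms)
    for pos in sorted(designable_set):
        rot = native_rotamer(pose, pos)
        if rot is None:
            raise UsageError(f"position {pos} has no sidechain to adopt")
        rset.rotamers[pos] = [rot]
    return rset


def _steric_pair_energy(a: Atom, b: Atom) -> float:
    d = float(np.linalg.norm(a.position - b.position))
    if d >= STERIC_CUTOFF:
        return 0.0
    # polar-polar contacts at hydrogen-bond range sit inside the vdW-sum
    # distance by nature; they are not clashes
    if (2.5 <= d <= 3.5 and a.polar_class is not PolarClass.NONE
            and b.polar_class is not PolarClass.NONE):
        return 0.0
    sigma = a.vdw_radius + b.vdw_radius
    if d >= sigma:
        return 0.0
    if d < 1e-6:
        return STERIC_CAP
    return min(STERIC_CAP, (sigma / d) ** 12 - 1.0)


def _hbond_bonus(atoms_a, atoms_b, quality_threshold) -> float:
    energy = 0.0
    for a in atoms_a:
        if a.polar_class is PolarClass.NONE:
            continue
        for b in atoms_b:
            if b.polar_class is PolarClass.NONE:
                continue
            hb = hbond_between(a, b, quality_threshold)
            if hb is not None:
                energy += HBOND_WEIGHT * hb.quality
    return energy


def base_one_body(rot: Rotamer, fixed_atoms,
                  quality_threshold: float = DEFAULT_QUALITY_THRESHOLD
                  ) -> float:
    """Soft steric repulsion plus h-bond bonus against the fixed context.

    Sterics against the rotamer's own backbone are skipped (covalently
    attached atoms are within bonding distance by construction)."""
    energy = 0.0
    context = [a for a in fixed_atoms
               if not (a.res_index == rot.position and a.is_backbone)]
    positions = np.array([a.position for a in context]) if context else None
    for atom in rot.atoms:
        if positions is not None:
            dists = np.linalg.norm(positions - atom.position, axis=1)
            for j in np.nonzero(dists < STERIC_CUTOFF)[0]:
                energy += _steric_pair_energy(atom, context[j])
    energy += _hbond_bonus(rot.atoms, context, quality_threshold)
    return energy


def base_two_body(rot_i: Rotamer, rot_j: Rotamer,
                  quality_threshold: float = DEFAULT_QUALITY_THRESHOLD
                  ) -> float:
    """Same functional form between two rotamers; symmetric."""
    if rot_i.position == rot_j.position:
        raise UsageError("two-body energy needs rotamers at distinct "
                         "positions")
    energy = 0.0
    for a in rot_i.atoms:
        for b in rot_j.atoms:
            energy += _steric_pair_energy(a, b)
    energy += _hbond_bonus(rot_i.atoms, rot_j.atoms, quality_threshold)
    return energy


def precompute_base_energies(rset: RotamerSet,
                             quality_threshold: float =
                             DEFAULT_QUALITY_THRESHOLD):
    """Return (one_body, two_body) dicts keyed by rotamer id / id pair."""
    one = {}
    for pos in rset.positions:
        for rot in rset.rotamers[pos]:
            one[rot.id] = base_one_body(rot, rset.fixed_atoms,
                                        quality_threshold)
    two = {}
    positions = rset.positions
    for i, p in enumerate(positions):
        for q in positions[i + 1:]:
            for ri in rset.rotamers[p]:
                for rj in rset.rotamers[q]:
                    e = base_two_body(ri, rj, quality_threshold)
                    if e != 0.0:
                        two[(ri.id, rj.id)] = e
    return one, two


def apply_assignment(pose: Pose, rset: RotamerSet, assignment) -> Pose:
    """Realize an assignment: replace designable sidechains with the
    chosen rotamers' atoms, returning a new pose."""
    missing = [p for p in rset.positions if p not in assignment]
    if missing:
        raise UsageError(f"assignment missing positions {missing}")
    out = pose.copy()
    for pos in rset.positions:
        rot = rset.rotamer(pos, assignment[pos])
        res = out.residue_at(pos)
        res.name = rot.residue_type if rot.residue_type else res.name
        res.sidechain_atoms = [a.copy() for a in rot.atoms]
    return out.finalize()
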