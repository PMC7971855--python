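"""Protein structure container, PDB I/O, and the poly-Leucine conversion.

The poly-Leucine conversion makes the burial computation sequence
independent: every residue's sidechain is replaced by an ideal leucine at
chi1=240, chi2=120 built on the native backbone, so the molecular volume
used to define the buried region no longer depends on sequence or rotamer
choice. Glycine (no CB) and proline (ring-constrained chi1) are left
unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np

from .chemistry import HYDROXYL_ATOMS, PolarClass, polar_info, vdw_radius
from .errors import FormatError, StructureError
from .templates import build_sidechain, hydroxyl_hydrogen_samples

__all__ = ["Atom", "Residue", "Pose", "read_pdb", "write_pdb",
           "mutate_to_polyleu", "POLYLEU_CHI1", "POLYLEU_CHI2"]

POLYLEU_CHI1 = 240.0
POLYLEU_CHI2 = 120.0

# Peptide-bond N-H length used for ideal amide hydrogen placement.
_NH_BOND = 1.01
_PEPTIDE_BOND_MAX = 1.8


@dataclass
class Atom:
    """A heavy atom; hydrogens appear only as riding positions."""

    serial: int
    name: str
    element: str
    position: np.ndarray
    vdw_radius: float = 1.7
    polar_class: PolarClass = PolarClass.NONE
    bound_hydrogens: list = field(default_factory=list)
    # provenance (set by the owning Pose; used in reports)
    res_index: int = 0
    res_name: str = ""
    chain_id: str = "A"
    is_backbone: bool = False

    def copy(self) -> "Atom":
        return Atom(self.serial, self.name, self.element,
                    self.position.copy(), self.vdw_radius, self.polar_class,
                    [h.copy() for h in self.bound_hydrogens],
                    self.res_index, self.res_name, self.chain_id,
                    self.is_backbone)

    @property
    def key(self):
        """Stable identity: (chain, residue index, atom name)."""
        return (self.chain_id, self.res_index, self.name)


@dataclass
class Residue:
    index: int  # 1-based chain position
    name: str
    backbone_atoms: list
    sidechain_atoms: list

    def atom(self, name: str) -> Atom:
        for a in self.backbone_atoms + self.sidechain_atoms:
            if a.name == name:
                return a
        raise KeyError(f"residue {self.index} {self.name}: no atom {name!r}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name
                   for a in self.backbone_atoms + self.sidechain_atoms)

    @property
    def atoms(self):
        return self.backbone_atoms + self.sidechain_atoms

    def copy(self) -> "Residue":
        return Residue(self.index, self.name,
                       [a.copy() for a in self.backbone_atoms],
                       [a.copy() for a in self.sidechain_atoms])


@dataclass
class Pose:
    residues: list
    chain_ids: list

    def __post_init__(self):
        if len(self.residues) != len(self.chain_ids):
            raise StructureError("one chain id per residue required")

    def __len__(self):
        return len(self.residues)

    @property
    def n_res(self) -> int:
        return len(self.residues)

    def all_atoms(self):
        for res in self.residues:
            yield from res.atoms

    def copy(self) -> "Pose":
        return Pose([r.copy() for r in self.residues], list(self.chain_ids))

    def residue_at(self, index: int) -> Residue:
        for res in self.residues:
            if res.index == index:
                return res
        raise KeyError(f"no residue with index {index}")

    def finalize(self) -> "Pose":
        """Place ideal backbone amide hydrogens, classify polar atoms, and
        stamp provenance metadata. Call after any structural edit."""
        _place_amide_hydrogens(self)
        for res, chain in zip(self.residues, self.chain_ids):
            for atom in res.backbone_atoms:
                _classify(atom, res, chain, backbone=True)
            for atom in res.sidechain_atoms:
                _classify(atom, res, chain, backbone=False)
                if (res.name, atom.name) in HYDROXYL_ATOMS:
                    _add_hydroxyl_samples(atom, res)
        return self


def _classify(atom: Atom, res: Residue, chain: str, backbone: bool) -> None:
    atom.res_index = res.index
    atom.res_name = res.name
    atom.chain_id = chain
    atom.is_backbone = backbone
    atom.vdw_radius = vdw_radius(atom.element)
    info = polar_info(res.name, atom.name, backbone)
    if info is None:
        atom.polar_class = PolarClass.NONE
    elif info.is_donor and not info.is_acceptor:
        # A donor with no available hydrogen (e.g. a chain-break amide N)
        # cannot donate and is treated as apolar.
        atom.polar_class = (PolarClass.DONOR_HEAVY if atom.bound_hydrogens
                            else PolarClass.NONE)
    elif info.is_donor and info.is_acceptor:
        atom.polar_class = PolarClass.DONOR_AND_ACCEPTOR
    else:
        atom.polar_class = PolarClass.ACCEPTOR


def _add_hydroxyl_samples(atom: Atom, res: Residue) -> None:
    """Extend a hydroxyl oxygen's hydrogens with the three staggered
    rotatable-proton samples (idempotent: near-duplicates are dropped)."""
    coords = {a.name: a.position for a in res.atoms}
    samples = hydroxyl_hydrogen_samples(res.name, atom.name, coords)
    for s in samples:
        if all(np.linalg.norm(s - h) > 0.15 for h in atom.bound_hydrogens):
            atom.bound_hydrogens.append(s)


def _place_amide_hydrogens(pose: Pose) -> None:
    """Ideal amide H from the local peptide frame, for chain-internal
    residues whose N lacks an explicit hydrogen. Proline has none."""
    for prev, (res, chain) in zip([None] + list(pose.residues[:-1]),
                                  zip(pose.residues, pose.chain_ids)):
        if prev is None or res.name == "PRO":
            continue
        try:
            n = res.atom("N")
            ca = res.atom("CA")
            c_prev = prev.atom("C")
        except KeyError:
            continue
        if n.bound_hydrogens:
            continue
        if np.linalg.norm(n.position - c_prev.position) > _PEPTIDE_BOND_MAX:
            continue  # not covalently continuous; leave N bare
        u = n.position - c_prev.position
        v = n.position - ca.position
        direction = u / np.linalg.norm(u) + v / np.linalg.norm(v)
        direction /= np.linalg.norm(direction)
        n.bound_hydrogens = [n.position + _NH_BOND * direction]


_BACKBONE_NAMES = ("N", "CA", "C", "O", "OXT")


def read_pdb(path) -> Pose:
    """Read a PDB file into a Pose.

    HETATM records (waters, ligands) are skipped. Alternate locations are
    resolved to the highest occupancy, ties broken alphabetically by altloc
    id. Hydrogen records are folded into ``bound_hydrogens`` of the nearest
    polar heavy atom in the same residue; other hydrogens are dropped.
    """
    try:
        st = gemmi.read_structure(str(path))
    except (OSError, RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot read PDB file {path}: {exc}") from exc
    residues = []
    chain_ids = []
    serial = 0
    for chain in st[0]:
        for gres in chain:
            if gres.het_flag != "A":
                continue  # HETATM / water
            best = {}
            for ga in gres:
                prev = best.get(ga.name)
                if prev is None or (ga.occ, -ord(ga.altloc or "~")) > (
                        prev.occ, -ord(prev.altloc or "~")):
                    best[ga.name] = ga
            heavies, hydrogens = [], []
            for ga in best.values():
                pos = np.array([ga.pos.x, ga.pos.y, ga.pos.z])
                if ga.element.name == "H":
                    hydrogens.append(pos)
                    continue
                serial += 1
                heavies.append(Atom(serial, ga.name, ga.element.name, pos))
            if not heavies:
                continue
            for hpos in hydrogens:
                dists = [np.linalg.norm(hpos - a.position) for a in heavies]
                nearest = heavies[int(np.argmin(dists))]
                if min(dists) < 1.3 and nearest.element in ("N", "O", "S"):
                    nearest.bound_hydrogens.append(hpos)
            backbone = [a for a in heavies if a.name in _BACKBONE_NAMES]
            sidechain = [a for a in heavies if a.name not in _BACKBONE_NAMES]
            residues.append(Residue(len(residues) + 1, gres.name,
                                    backbone, sidechain))
            chain_ids.append(chain.name)
    if not residues:
        raise FormatError(f"{path}: no ATOM records")
    return Pose(residues, chain_ids).finalize()


def write_pdb(pose: Pose, path) -> None:
    """Write heavy atoms as standard ATOM records (TER between chains)."""
    if pose.n_res == 0:
        raise StructureError("cannot write an empty pose")
    st = gemmi.Structure()
    st.name = "threebop"
    model = gemmi.Model("1")
    chain = None
    for res, chain_id in zip(pose.residues, pose.chain_ids):
        if chain is None or chain.name != chain_id:
            chain = gemmi.Chain(chain_id)
            model.add_chain(chain)
            chain = model[-1]
        gres = gemmi.Residue()
        gres.name = res.name
        gres.seqid = gemmi.SeqId(res.index, " ")
        for atom in res.atoms:
            ga = gemmi.Atom()
            ga.name = atom.name
            ga.element = gemmi.Element(atom.element)
            ga.pos = gemmi.Position(*atom.position)
            ga.occ = 1.0
            ga.b_iso = 0.0
            gres.add_atom(ga)
        chain.add_residue(gres)
    st.add_model(model)
    st.setup_entities()
    for ch in st[0]:
        for gres in ch:
            gres.het_flag = "A"  # short synthetic chains are still polymer
    try:
        st.write_pdb(str(path))
    except (OSError, RuntimeError) as exc:
        raise OSError(f"cannot write PDB file {path}: {exc}") from exc


def mutate_to_polyleu(pose: Pose) -> Pose:
    """Replace every non-GLY, non-PRO sidechain with an ideal leucine at
    chi1=240, chi2=120, keeping backbone coordinates untouched."""
    out = pose.copy()
    serial = max((a.serial for a in out.all_atoms()), default=0)
    for res in out.residues:
        if res.name in ("GLY", "PRO"):
            continue
        missing = [nm for nm in ("N", "CA", "C") if not res.has_atom(nm)]
        if missing:
            raise StructureError(
                f"residue {res.index} {res.name}: missing backbone "
                f"atom(s) {', '.join(missing)}")
        built = build_sidechain(
            "LEU",
            res.atom("N").position, res.atom("CA").position,
            res.atom("C").position,
            chi=(POLYLEU_CHI1, POLYLEU_CHI2),
        )
        res.name = "LEU"
        res.sidechain_atoms = []
        for name, element, xyz, hydrogens in built:
            serial += 1
            res.sidechain_atoms.append(
                Atom(serial, name, element, xyz, bound_hydrogens=hydrogens))
    return out.finalize()
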