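"""Deterministic synthetic test structures.

These fixtures are not chemically refined proteins: they are engineered
scaffolds whose burial and hydrogen-bond geometry is known by
construction, so every downstream quantity (depths, satisfier counts,
penalty tables) can be checked against independent oracles without any
external input files.

Scaffold ("filler") residues are glycines carrying only N, CA and C and
no amide hydrogen: they contribute van der Waals volume to the molecular
surface but no polar atoms, which keeps the polar bookkeeping of each
fixture exactly as designed. The polar residues of interest carry
hand-placed sidechains (and, likewise, bare N/CA/C backbones), so the
only donors and acceptors present are the ones the fixture is about.

Available fixtures
------------------
glu_two_ser
    The worked oversaturation example: one buried glutamate carboxylate
    oxygen at the bottom of a narrow surface pocket, satisfied by two
    serine hydroxyls higher in the pocket (outside the buried region).
buried_triad
    Three serine positions around a deep cavity; staggered chi1 choices
    exist that mutually satisfy the hydroxyls and ones that leave them
    unsatisfied. Contains atoms deeper than 5.5 A.
two_helix_bundle
    Two ideal antiparallel polyalanine helices with full backbones.
surface_polar
    A short extended serine peptide: every polar atom is close to the
    surface (depth < 3.5 A).

``random_polar_cluster`` generates randomized concrete structures on a
fixed scaffold (shared burial grid) for property testing.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from .errors import UsageError
from .geometry import place_atom
from .structure import Atom, Pose, Residue, mutate_to_polyleu
from .templates import build_sidechain

__all__ = ["build_fixture_pose", "FIXTURE_SPECS", "build_helix",
           "random_polar_cluster", "random_cluster_grid_pose"]

FIXTURE_SPECS = ("buried_triad", "two_helix_bundle", "surface_polar",
                 "glu_two_ser")

_LATTICE_SPACING = 2.8
_JITTER = 0.05

# glu_two_ser layout (Angstroms). The pocket is a vertical cylinder in a
# slab; the carboxylate oxygen sits near the pocket floor, the serine
# hydroxyls higher up where the solvent-distance field is shallow.
_GTS_SLAB_XY = 11.2
_GTS_SLAB_Z = (-8.4, 4.2)
_GTS_POCKET_RADIUS = 3.8
_GTS_POCKET_FLOOR = -4.2
_GTS_OE1 = np.array([0.0, 0.0, -1.0])
_GTS_OE2 = np.array([0.0, 1.0, 1.25])
_GTS_CD = np.array([0.0, 0.8, 0.05])
_GTS_OG = 1.9, 1.2  # |x| and z of the two hydroxyl oxygens

# buried_triad layout: a deep cavity holding a glutamate carboxylate
# receiving one serine hydroxyl on each oxygen
_TRIAD_BALL_RADIUS = 10.5
_TRIAD_CLEARANCE = 3.2

# random_polar_cluster layout
_CLUSTER_BALL_RADIUS = 9.8
_CLUSTER_CAVITY_RADIUS = 4.6
_CLUSTER_CA_RADIUS = 4.4
_CLUSTER_TYPES = ("SER", "THR", "ASN", "GLN", "ASP", "GLU", "LYS")


def build_fixture_pose(spec: str, seed: int) -> Pose:
    """Build a named fixture; deterministic for fixed (spec, seed)."""
    builders = {
        "glu_two_ser": _build_glu_two_ser,
        "buried_triad": _build_buried_triad,
        "two_helix_bundle": _build_two_helix_bundle,
        "surface_polar": _build_surface_polar,
    }
    try:
        builder = builders[spec]
    except KeyError:
        raise UsageError(
            f"unknown fixture {spec!r}; available: "
            f"{', '.join(FIXTURE_SPECS)}") from None
    return builder(int(seed))


# ---------------------------------------------------------------------------
# scaffold helpers

def _atom(serial, name, element, xyz):
    return Atom(serial, name, element, np.asarray(xyz, dtype=float))


_serial_counter = None


def _filler_residue(index: int, center, rng) -> Residue:
    """A bare glycine (N, CA, C only) clustered around ``center``."""
    center = np.asarray(center, float)
    jitter = rng.uniform(-_JITTER, _JITTER, size=(3, 3)) if rng else 0.0
    offsets = np.array([[1.45, 0.0, 0.0],
                        [0.0, 0.0, 0.0],
                        [-0.72, 1.26, 0.0]]) + jitter
    base = index * 10
    names = ("N", "CA", "C")
    elements = ("N", "C", "C")
    atoms = [_atom(base + k, nm, el, center + off)
             for k, (nm, el, off) in enumerate(zip(names, elements, offsets))]
    return Residue(index, "GLY", atoms, [])


def _bare_backbone(index, name, ca, inward, up, sidechain_atoms):
    """Residue with a bare N/CA/C frame oriented so that a built CB
    points along ``inward``."""
    ca = np.asarray(ca, float)
    inward = np.asarray(inward, float) / np.linalg.norm(inward)
    up = np.asarray(up, float)
    up = up - np.dot(up, inward) * inward
    up /= np.linalg.norm(up)
    outward = -inward
    u_n = 0.5 * outward + 0.87 * up
    u_c = 0.5 * outward - 0.87 * up
    n_pos = ca + 1.46 * u_n / np.linalg.norm(u_n)
    c_pos = ca + 1.53 * u_c / np.linalg.norm(u_c)
    base = index * 10
    backbone = [_atom(base, "N", "N", n_pos), _atom(base + 1, "CA", "C", ca),
                _atom(base + 2, "C", "C", c_pos)]
    return Residue(index, name, backbone, sidechain_atoms)


def _lattice_points(rng, keep):
    span = np.arange(-12, 12.1) * _LATTICE_SPACING
    pts = []
    for x in span:
        for y in span:
            for z in span:
                p = np.array([x, y, z])
                if keep(p):
                    pts.append(p)
    return pts


def _assemble(central_residues, filler_centers, rng) -> Pose:
    residues = list(central_residues)
    for center in filler_centers:
        residues.append(_filler_residue(len(residues) + 1, center, rng))
    return Pose(residues, ["A"] * len(residues)).finalize()


# ---------------------------------------------------------------------------
# glu_two_ser

def _build_glu_two_ser(seed: int) -> Pose:
    rng = np.random.default_rng(seed)
    og_x, og_z = _GTS_OG
    oe1 = _GTS_OE1

    centrals = []
    # glutamate: bare backbone high on the +y wall, carboxylate reaching
    # into the pocket
    glu_side = [_atom(11, "CD", "C", _GTS_CD), _atom(12, "OE1", "O", oe1),
                _atom(13, "OE2", "O", _GTS_OE2)]
    centrals.append(_bare_backbone(1, "GLU", [0.0, 5.6, -2.0],
                                   inward=[0.0, -1.0, -0.35],
                                   up=[1.0, 0.0, 0.0],
                                   sidechain_atoms=glu_side))
    # two serines: hydroxyls in the pocket mouth, donating down to OE1
    for k, sign in enumerate((-1.0, 1.0)):
        og = np.array([sign * og_x, 0.0, og_z])
        h = og + 0.96 * (oe1 - og) / np.linalg.norm(oe1 - og)
        cb = np.array([sign * 3.2, 0.0, 1.4])
        side = [_atom(21 + 10 * k, "CB", "C", cb)]
        og_atom = _atom(22 + 10 * k, "OG", "O", og)
        og_atom.bound_hydrogens.append(h)
        side.append(og_atom)
        centrals.append(_bare_backbone(2 + k, "SER",
                                       [sign * 5.6, 0.0, 1.5],
                                       inward=[-sign, 0.0, 0.0],
                                       up=[0.0, 1.0, 0.0],
                                       sidechain_atoms=side))

    central_atoms = np.array([a.position
                              for res in centrals for a in res.atoms])

    def keep(p):
        if abs(p[0]) > _GTS_SLAB_XY or abs(p[1]) > _GTS_SLAB_XY:
            return False
        if not (_GTS_SLAB_Z[0] <= p[2] <= _GTS_SLAB_Z[1]):
            return False
        if (np.hypot(p[0], p[1]) < _GTS_POCKET_RADIUS
                and p[2] > _GTS_POCKET_FLOOR):
            return False
        if np.min(np.linalg.norm(central_atoms - p, axis=1)) < 2.3:
            return False
        return True

    return _assemble(centrals, _lattice_points(rng, keep), rng)


# ---------------------------------------------------------------------------
# buried_triad

def _build_buried_triad(seed: int) -> Pose:
    rng = np.random.default_rng(seed)
    centrals = []
    clearance_points = []

    # glutamate: hand-placed carboxylate at the cavity center
    oe1 = np.array([0.0, 1.1, 0.0])
    oe2 = np.array([0.0, -1.1, 0.0])
    glu_side = [_atom(101, "CD", "C", [0.65, 0.0, 0.0]),
                _atom(102, "OE1", "O", oe1), _atom(103, "OE2", "O", oe2)]
    glu_ca = np.array([3.4, 0.0, 0.0])
    centrals.append(_bare_backbone(1, "GLU", glu_ca,
                                   inward=[-1.0, 0.0, 0.0],
                                   up=[0.0, 0.0, 1.0],
                                   sidechain_atoms=glu_side))

    # two serines donating onto OE1 / OE2 from opposite sides
    for k, (sign, target) in enumerate(((1.0, oe1), (-1.0, oe2))):
        og = np.array([0.0, sign * 3.9, 0.0])
        h = og + 0.96 * (target - og) / np.linalg.norm(target - og)
        cb = np.array([0.0, sign * 4.8, 1.1])
        og_atom = _atom(121 + 10 * k, "OG", "O", og)
        og_atom.bound_hydrogens.append(h)
        side = [_atom(120 + 10 * k, "CB", "C", cb), og_atom]
        centrals.append(_bare_backbone(2 + k, "SER",
                                       [0.0, sign * 6.2, 1.2],
                                       inward=[0.0, -sign, -0.2],
                                       up=[1.0, 0.0, 0.0],
                                       sidechain_atoms=side))

    for res in centrals:
        clearance_points.extend(a.position for a in res.atoms)
    # keep the filler clear of the staggered chi1 serine alternatives so
    # rotamer enumeration offers real (unsatisfied) decoys
    for res in centrals[1:]:
        nac = tuple(res.atom(nm).position for nm in ("N", "CA", "C"))
        for chi1 in (60.0, 180.0, 300.0):
            for _, _, xyz, _ in build_sidechain("SER", *nac, chi=(chi1,)):
                clearance_points.append(xyz)
    clearance_points = np.array(clearance_points)

    def keep(p):
        r = np.linalg.norm(p)
        if r > _TRIAD_BALL_RADIUS:
            return False
        if np.min(np.linalg.norm(clearance_points - p,
                                  axis=1)) < _TRIAD_CLEARANCE:
            return False
        return True

    return _assemble(centrals, _lattice_points(rng, keep), rng)


def _frame_nac(ca, inward, up=(0.0, 0.0, 1.0)):
    """(N, CA, C) coordinates of a bare frame, matching _bare_backbone."""
    ca = np.asarray(ca, float)
    inward = np.asarray(inward, float) / np.linalg.norm(np.asarray(inward))
    up = np.asarray(up, float)
    up = up - np.dot(up, inward) * inward
    up /= np.linalg.norm(up)
    outward = -inward
    u_n = 0.5 * outward + 0.87 * up
    u_c = 0.5 * outward - 0.87 * up
    return (ca + 1.46 * u_n / np.linalg.norm(u_n), ca,
            ca + 1.53 * u_c / np.linalg.norm(u_c))


# ---------------------------------------------------------------------------
# helices

_HELIX_PHI, _HELIX_PSI, _HELIX_OMEGA = -57.0, -47.0, 180.0


def build_helix(n_res: int, res_name: str = "ALA",
                phi: float = _HELIX_PHI, psi: float = _HELIX_PSI) -> Pose:
    """Ideal-geometry backbone chain (alpha-helical by default) with
    template sidechains."""
    if n_res < 1:
        raise UsageError("need at least one residue")
    n = np.array([0.0, 0.0, 0.0])
    ca = np.array([1.458, 0.0, 0.0])
    c = place_atom(np.array([-0.5, 0.87, 0.0]), n, ca, 1.525, 111.2, phi)
    residues = []
    serial = 0
    for i in range(n_res):
        backbone = [_atom(serial + 1, "N", "N", n),
                    _atom(serial + 2, "CA", "C", ca),
                    _atom(serial + 3, "C", "C", c)]
        n_next = place_atom(n, ca, c, 1.329, 116.2, psi)
        backbone.append(_atom(serial + 4, "O", "O",
                              place_atom(n_next, ca, c, 1.231, 122.7, 180.0)))
        serial += 4
        side = []
        if res_name != "GLY":
            for nm, el, xyz, hyd in build_sidechain(res_name, n, ca, c):
                serial += 1
                atom = _atom(serial, nm, el, xyz)
                atom.bound_hydrogens = list(hyd)
                side.append(atom)
        residues.append(Residue(i + 1, res_name, backbone, side))
        if i + 1 < n_res:
            ca_next = place_atom(ca, c, n_next, 1.458, 121.7, _HELIX_OMEGA)
            c_next = place_atom(c, n_next, ca_next, 1.525, 111.2, phi)
            n, ca, c = n_next, ca_next, c_next
    return Pose(residues, ["A"] * n_res).finalize()


def _build_two_helix_bundle(seed: int) -> Pose:
    rng = np.random.default_rng(seed)
    helix_a = build_helix(12)
    helix_b = build_helix(12)
    # antiparallel: flip the second helix and set the axes ~10 A apart
    for atom in helix_b.all_atoms():
        x, y, z = atom.position
        atom.position = np.array([-x + 10.0, -y + 2.0, z + 1.0])
    offset = helix_a.n_res
    jitter = rng.uniform(-_JITTER, _JITTER, size=3)
    for res in helix_b.residues:
        res.index += offset
        for atom in res.atoms:
            atom.serial += 200
            atom.position = atom.position + jitter
            atom.bound_hydrogens = [h + jitter for h in atom.bound_hydrogens]
    residues = helix_a.residues + helix_b.residues
    chains = ["A"] * offset + ["B"] * helix_b.n_res
    return Pose(residues, chains).finalize()


# ---------------------------------------------------------------------------
# surface_polar

def _build_surface_polar(seed: int) -> Pose:
    pose = build_helix(4, res_name="SER", phi=-120.0, psi=120.0)
    rng = np.random.default_rng(seed)
    shift = rng.uniform(-_JITTER, _JITTER, size=3)
    for atom in pose.all_atoms():
        atom.position = atom.position + shift
        atom.bound_hydrogens = [h + shift for h in atom.bound_hydrogens]
    return pose


# ---------------------------------------------------------------------------
# randomized concrete structures on a fixed scaffold

def _cluster_frames():
    directions = [np.array(v, dtype=float) for v in
                  ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                   (0, 0, 1), (0, 0, -1))]
    frames = []
    for d in directions:
        up = np.array([0.0, 0.0, 1.0]) if abs(d[2]) < 0.5 else \
            np.array([1.0, 0.0, 0.0])
        frames.append((_CLUSTER_CA_RADIUS * d, -d, up))
    return frames


@lru_cache(maxsize=1)
def _cluster_scaffold():
    """Fixed filler lattice + bare frames; identical for every seed so
    the poly-Leu burial grid can be shared."""
    frames = _cluster_frames()
    frame_atoms = np.array([p for ca, inward, up in frames
                            for p in _frame_nac(ca, inward, up)])

    def keep(p):
        r = np.linalg.norm(p)
        if r > _CLUSTER_BALL_RADIUS or r < _CLUSTER_CAVITY_RADIUS:
            return False
        if np.min(np.linalg.norm(frame_atoms - p, axis=1)) < 2.3:
            return False
        return True

    return frames, _lattice_points(None, keep)


def random_polar_cluster(seed: int, n_sites: int | None = None) -> Pose:
    """A concrete structure with randomized polar residues around a
    buried cavity. The scaffold (and hence the poly-Leu burial grid) is
    identical across seeds; only residue types and chi angles vary."""
    rng = np.random.default_rng(seed)
    frames, filler = _cluster_scaffold()
    if n_sites is None:
        n_sites = len(frames)
    if not (1 <= n_sites <= len(frames)):
        raise UsageError(f"n_sites must be in 1..{len(frames)}")
    centrals = []
    for k, (ca, inward, up) in enumerate(frames[:n_sites]):
        res_type = str(rng.choice(_CLUSTER_TYPES))
        from .chemistry import CHI_ATOMS
        chi = tuple(rng.uniform(0.0, 360.0)
                    for _ in CHI_ATOMS[res_type])
        built = build_sidechain(res_type, *_frame_nac(ca, inward, up),
                                chi=chi)
        side = []
        for j, (nm, el, xyz, hyd) in enumerate(built):
            atom = _atom(500 + 20 * k + j, nm, el, xyz)
            atom.bound_hydrogens = list(hyd)
            side.append(atom)
        centrals.append(_bare_backbone(k + 1, res_type, ca, inward, up,
                                       sidechain_atoms=side))
    residues = list(centrals)
    for center in filler:
        residues.append(_filler_residue(len(residues) + 1, center, None))
    return Pose(residues, ["A"] * len(residues)).finalize()


def random_cluster_grid_pose() -> Pose:
    """Poly-Leu conversion of the (seed-independent) cluster scaffold,
    suitable for computing one shared burial grid."""
    return mutate_to_polyleu(random_polar_cluster(0))
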