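"""Shared fixtures: synthetic structures, their burial grids, and
hand-built rotamer scenarios used across the suite."""

import numpy as np
import pytest

from threebop.burial import BurialGrid, compute_burial_grid
from threebop.chemistry import PolarClass
from threebop.fixtures import build_fixture_pose, random_cluster_grid_pose
from threebop.penalty import PolarScheme
from threebop.rotamers import Rotamer, RotamerSet
from threebop.structure import Atom, mutate_to_polyleu


@pytest.fixture(scope="session")
def glu_two_ser_pose():
    return build_fixture_pose("glu_two_ser", 0)


@pytest.fixture(scope="session")
def glu_two_ser_grid(glu_two_ser_pose):
    return compute_burial_grid(mutate_to_polyleu(glu_two_ser_pose))


@pytest.fixture(scope="session")
def triad_pose():
    return build_fixture_pose("buried_triad", 0)


@pytest.fixture(scope="session")
def triad_grid(triad_pose):
    return compute_burial_grid(mutate_to_polyleu(triad_pose))


@pytest.fixture(scope="session")
def surface_pose():
    return build_fixture_pose("surface_polar", 0)


@pytest.fixture(scope="session")
def surface_grid(surface_pose):
    return compute_burial_grid(mutate_to_polyleu(surface_pose))


@pytest.fixture(scope="session")
def cluster_grid():
    return compute_burial_grid(random_cluster_grid_pose())


@pytest.fixture(scope="session")
def uniform1_scheme():
    """Uniform beta=1, sigma=-1, omega=1 across every atom type."""
    labels = ("NH1", "NH2", "NH3", "carbonyl_O", "carboxylate_O",
              "hydroxyl", "imidazole", "indole")
    return PolarScheme("uniform1", {lab: (1.0, -1.0, 1.0) for lab in labels})


def make_deep_grid(depth_value=10.0, half_extent=10.0, voxel=0.5):
    """Synthetic grid: uniformly deep interior, solvent boundary shell."""
    n = int(2 * half_extent / voxel) + 1
    depth = np.full((n, n, n), float(depth_value))
    for axis in range(3):
        index = [slice(None)] * 3
        for edge in (0, -1):
            index[axis] = edge
            depth[tuple(index)] = 0.0
    return BurialGrid(origin=np.array([-half_extent] * 3), voxel_size=voxel,
                      dims=(n, n, n), depth=depth)


def synthetic_acceptor(position_index, xyz, name="OD1", res_name="ASN"):
    return Atom(0, name, "O", np.asarray(xyz, float),
                polar_class=PolarClass.ACCEPTOR, res_index=position_index,
                res_name=res_name)


def synthetic_donor(position_index, xyz, aim_at, name="NE1",
                    res_name="TRP"):
    atom = Atom(0, name, "N", np.asarray(xyz, float),
                polar_class=PolarClass.DONOR_HEAVY,
                res_index=position_index, res_name=res_name)
    direction = np.asarray(aim_at, float) - atom.position
    atom.bound_hydrogens = [
        atom.position + direction / np.linalg.norm(direction)]
    return atom


@pytest.fixture
def deep_grid():
    return make_deep_grid()


@pytest.fixture
def bridge_scenario(deep_grid):
    """Two singleton donors plus a position whose native rotamer makes one
    h-bond while a non-native rotamer bridges both donors.

    The donor-to-bridge geometries are tuned so the two bridging bonds
    have distinct qualities, letting threshold sweeps peel them off one
    at a time.
    """
    q1 = synthetic_donor(2, [2.8, 0.0, 0.0], [0.0, 0.0, 0.0])
    q2 = synthetic_donor(3, [-2.8, 0.0, 0.0], [0.0, 0.0, 0.0])
    # native rotamer at position 1: accepts only from q1, at 3.3 A so the
    # bond is weak (quality ~0.29) and disappears under stricter
    # thresholds while the 2.8 A bridging bonds (quality 1.0) persist
    direction = np.array([0.2, 1.0, 0.0])
    direction /= np.linalg.norm(direction)
    native_pos = np.array([2.8, 0.0, 0.0]) + 3.3 * direction
    q1.bound_hydrogens.append(np.array([2.8, 0.0, 0.0]) + direction)
    native_b = synthetic_acceptor(1, native_pos)
    # non-native rotamer at position 1: accepts from both donors
    bridge_b = synthetic_acceptor(1, [0.0, 0.0, 0.0])
    rot_native = Rotamer(1, "ASN", (), [native_b], 0)
    rot_bridge = Rotamer(1, "ASN", (), [bridge_b], 1)
    rset = RotamerSet({1: [rot_native, rot_bridge],
                       2: [Rotamer(2, "TRP", (), [q1], 0)],
                       3: [Rotamer(3, "TRP", (), [q2], 0)]}, [])
    return rset, deep_grid, {1: 0, 2: 0, 3: 0}
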