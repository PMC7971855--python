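"""Simulated-annealing sidechain packer and a brute-force reference.

The packer consumes precomputed one-body/two-body energies (base force
field plus an optional penalty table), makes single-rotamer substitution
moves under Metropolis acceptance, and cools geometrically. All
randomness flows from one integer seed through one generator, so runs
are bit-reproducible.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .errors import UsageError
from .penalty import PenaltyTable, table_total
from .rotamers import RotamerSet

__all__ = ["AnnealSchedule", "PackResult", "anneal_pack",
           "brute_force_pack", "combined_energy"]

BRUTE_FORCE_LIMIT = 10 ** 6


@dataclass
class AnnealSchedule:
    start_temperature: float = 5.0
    end_temperature: float = 0.3
    n_sweeps: int = 200

    def __post_init__(self):
        if not (self.start_temperature > self.end_temperature > 0):
            raise UsageError("need start_temperature > end_temperature > 0")
        if self.n_sweeps < 1:
            raise UsageError("need at least one sweep")

    @property
    def decay(self) -> float:
        if self.n_sweeps == 1:
            return 1.0
        return (self.end_temperature / self.start_temperature) ** (
            1.0 / (self.n_sweeps - 1))

    def temperatures(self):
        t = self.start_temperature
        for _ in range(self.n_sweeps):
            yield t
            t *= self.decay


@dataclass
class PackResult:
    assignment: dict
    total_energy: float
    base_energy: float
    threebop_energy: float
    accepted_moves: int
    seed: int

    @property
    def breakdown(self):
        return (self.base_energy, self.threebop_energy)


def _merge_tables(rset: RotamerSet, base_one, base_two,
                  table: PenaltyTable | None):
    one = {}
    for pos in rset.positions:
        for rot in rset.rotamers[pos]:
            e = base_one.get(rot.id, 0.0)
            if table is not None:
                e += table.one_body(rot.id)
            one[rot.id] = e
    two = dict(base_two)
    if table is not None:
        for key in table.two_body_keys():
            two[key] = two.get(key, 0.0) + table.two_body(*key)
    return one, two


def combined_energy(rset: RotamerSet, base_one, base_two,
                    table: PenaltyTable | None, assignment) -> float:
    """Recompute base + penalty energy of an assignment from scratch."""
    one, two = _merge_tables(rset, base_one, base_two, table)
    total = table.constant_offset if table is not None else 0.0
    chosen = [(pos, assignment[pos]) for pos in rset.positions]
    for rid in chosen:
        total += one[rid]
    for ra, rb in itertools.combinations(chosen, 2):
        total += two.get(PenaltyTable.canonical(ra, rb), 0.0)
    return total


def anneal_pack(rset: RotamerSet, base_one, base_two,
                table: PenaltyTable | None, schedule: AnnealSchedule,
                seed: int, n_restarts: int = 1) -> PackResult:
    """Metropolis simulated annealing over rotamer substitutions.

    Returns the best assignment seen across all restarts. Deterministic
    for a fixed seed: one generator, draws in documented order (initial
    assignment, then per move: position, ordinal, acceptance uniform).
    """
    positions = rset.positions
    if not positions:
        raise UsageError("empty rotamer set")
    one, two = _merge_tables(rset, base_one, base_two, table)
    offset = table.constant_offset if table is not None else 0.0
    n_rot = {pos: len(rset.rotamers[pos]) for pos in positions}
    moves_per_sweep = max(1, rset.total_rotamers())
    rng = np.random.default_rng(seed)

    def energy_of(assignment):
        total = offset
        chosen = [(pos, assignment[pos]) for pos in positions]
        for rid in chosen:
            total += one[rid]
        for ra, rb in itertools.combinations(chosen, 2):
            total += two.get(PenaltyTable.canonical(ra, rb), 0.0)
        return total

    best_assignment = None
    best_energy = math.inf
    accepted = 0
    for _ in range(max(1, n_restarts)):
        assignment = {pos: int(rng.integers(n_rot[pos]))
                      for pos in positions}
        current = energy_of(assignment)
        if current < best_energy:
            best_energy, best_assignment = current, dict(assignment)
        for temperature in schedule.temperatures():
            for _ in range(moves_per_sweep):
                pos = positions[int(rng.integers(len(positions)))]
                new_ord = int(rng.integers(n_rot[pos]))
                old_ord = assignment[pos]
                if new_ord == old_ord:
                    continue
                old_rid, new_rid = (pos, old_ord), (pos, new_ord)
                delta = one[new_rid] - one[old_rid]
                for other in positions:
                    if other == pos:
                        continue
                    other_rid = (other, assignment[other])
                    delta += two.get(
                        PenaltyTable.canonical(new_rid, other_rid), 0.0)
                    delta -= two.get(
                        PenaltyTable.canonical(old_rid, other_rid), 0.0)
                if delta <= 0 or rng.random() < math.exp(
                        -delta / temperature):
                    assignment[pos] = new_ord
                    current += delta
                    accepted += 1
                    if current < best_energy - 1e-12:
                        best_energy = current
                        best_assignment = dict(assignment)
    base_part = combined_energy(rset, base_one, base_two, None,
                                best_assignment)
    penalty_part = (table_total(table, best_assignment)
                    if table is not None else 0.0)
    return PackResult(best_assignment, base_part + penalty_part,
                      base_part, penalty_part, accepted, seed)


def brute_force_pack(rset: RotamerSet, base_one, base_two,
                     table: PenaltyTable | None = None) -> PackResult:
    """Exhaustive enumeration; ties broken by lexicographic assignment."""
    positions = rset.positions
    if not positions:
        raise UsageError("empty rotamer set")
    size = 1
    for pos in positions:
        size *= len(rset.rotamers[pos])
        if size > BRUTE_FORCE_LIMIT:
            raise UsageError(
                f"instance too large for brute force (> {BRUTE_FORCE_LIMIT}"
                " assignments)")
    one, two = _merge_tables(rset, base_one, base_two, table)
    offset = table.constant_offset if table is not None else 0.0
    best = None
    best_energy = math.inf
    for combo in itertools.product(
            *[range(len(rset.rotamers[pos])) for pos in positions]):
        assignment = dict(zip(positions, combo))
        chosen = [(pos, assignment[pos]) for pos in positions]
        total = offset + sum(one[rid] for rid in chosen)
        for ra, rb in itertools.combinations(chosen, 2):
            total += two.get(PenaltyTable.canonical(ra, rb), 0.0)
        if total < best_energy:  # strict: first minimum is lexicographic
            best_energy = total
            best = assignment
    base_part = combined_energy(rset, base_one, base_two, None, best)
    penalty_part = table_total(table, best) if table is not None else 0.0
    return PackResult(best, best_energy, base_part, penalty_part, 0, -1)
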