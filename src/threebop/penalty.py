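"""Pairwise-decomposable penalty for buried unsatisfied polar atoms.

A buried polar atom making H hydrogen bonds is assigned the quadratic
pseudoenergy

    P = beta + sigma * H + omega * H * (H - 1) / 2

where beta is the cost of burying the atom, sigma the bonus per
satisfying h-bond, and omega the penalty per pair of simultaneous
h-bonds (oversaturation). The scheme is projected onto a rotamer
interaction graph: for every buried polar atom B (over all rotamers and
the fixed context), beta accumulates to B's rotamer, sigma to each
B<->satisfier edge, and omega to each satisfier-pair edge. Because all
rotamers at a position contribute while only one can be selected, the
naive projection overcounts omega; the corrected variant limits each
omega target to the maximum one rotamer at a position can generate.

Contributions whose endpoints collapse (satisfier fixed, or in the same
rotamer as its partner) are demoted to one-body terms or to a constant
offset; satisfier pairs split across two rotamers at the same position
are skipped, as those rotamers are mutually exclusive.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .burial import BurialGrid, is_buried
from .chemistry import PolarClass, polar_info
from .errors import ParameterError, UsageError
from .hbond import DEFAULT_QUALITY_THRESHOLD, hbond_between
from .rotamers import RotamerSet
from .structure import Pose

__all__ = ["PolarScheme", "PenaltyTable", "eval_penalty", "assign_naive",
           "assign_corrected", "table_total", "oracle_total",
           "count_buried_unsat", "extraneous_fraction", "SCHEME_PRESETS",
           "get_scheme", "with_lysine_override"]

TERMS = ("beta", "sigma", "omega")

ATOM_TYPE_LABELS = ("NH1", "NH2", "NH3", "carbonyl_O", "carboxylate_O",
                    "hydroxyl", "imidazole", "indole")


@dataclass(frozen=True)
class PolarScheme:
    """Per-atom-type (beta, sigma, omega) coefficient triples."""

    name: str
    coefficients: dict  # label -> (beta, sigma, omega)

    def coeffs(self, label: str):
        try:
            return self.coefficients[label]
        except KeyError:
            raise ParameterError(
                f"scheme {self.name!r} has no coefficients for atom type "
                f"{label!r}") from None

    def to_text(self) -> str:
        lines = [f"# scheme {self.name}: label = beta sigma omega"]
        for label in sorted(self.coefficients):
            b, s, w = self.coefficients[label]
            lines.append(f"{label} = {b:g} {s:g} {w:g}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str, name: str = "custom") -> "PolarScheme":
        coeffs = {}
        for line in text.splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ParameterError(f"bad scheme line: {line!r}")
            label, values = line.split("=", 1)
            parts = values.split()
            if len(parts) != 3:
                raise ParameterError(f"need 3 coefficients: {line!r}")
            coeffs[label.strip()] = tuple(float(v) for v in parts)
        if not coeffs:
            raise ParameterError("empty scheme file")
        return cls(name, coeffs)


def _uniform(name, beta, sigma, omega, overrides=None):
    coeffs = {label: (beta, sigma, omega) for label in ATOM_TYPE_LABELS}
    coeffs.update(overrides or {})
    return PolarScheme(name, coeffs)


def with_lysine_override(scheme: PolarScheme, beta: float, sigma: float
                         ) -> PolarScheme:
    """Copy a scheme with stronger ammonium (NH3) burial coefficients."""
    coeffs = dict(scheme.coefficients)
    omega = coeffs["NH3"][2]
    coeffs["NH3"] = (beta, sigma, omega)
    return PolarScheme(scheme.name + "_lysnz", coeffs)


# The published example rows plus package defaults for the remaining
# donor/acceptor categories (off-by-one penalty of 1 around 1-2 bonds).
_TABLE1 = PolarScheme("table1", {
    "NH1": (1.0, -1.0, 2.0),
    "carbonyl_O": (1.0, -1.0, 1.0),
    "NH2": (4.0, -3.0, 2.0),
    "carboxylate_O": (3.0, -2.0, 1.0),
    "NH3": (9.0, -5.0, 2.0),
    "hydroxyl": (1.0, -1.0, 1.0),
    "imidazole": (1.0, -1.0, 2.0),
    "indole": (1.0, -1.0, 2.0),
})

SCHEME_PRESETS = {
    "table1": _TABLE1,
    "uniform5": _uniform("uniform5", 5.0, -5.0, 5.0),
    "uniform5_noover": _uniform("uniform5_noover", 5.0, -5.0, 0.0),
    "uniform10": _uniform("uniform10", 10.0, -10.0, 10.0),
}
SCHEME_PRESETS["uniform5_lysnz"] = with_lysine_override(
    SCHEME_PRESETS["uniform5"], 15.0, -10.0)
SCHEME_PRESETS["uniform10_lysnz"] = with_lysine_override(
    SCHEME_PRESETS["uniform10"], 30.0, -20.0)


def get_scheme(name_or_scheme) -> PolarScheme:
    if isinstance(name_or_scheme, PolarScheme):
        return name_or_scheme
    try:
        return SCHEME_PRESETS[name_or_scheme]
    except KeyError:
        raise ParameterError(
            f"unknown scheme {name_or_scheme!r}; available: "
            f"{', '.join(sorted(SCHEME_PRESETS))}") from None


def eval_penalty(params, n_hbonds: int) -> float:
    """The quadratic burial penalty at H hydrogen bonds."""
    if n_hbonds < 0:
        raise ParameterError(f"H must be non-negative, got {n_hbonds}")
    beta, sigma, omega = params
    return beta + sigma * n_hbonds + omega * n_hbonds * (n_hbonds - 1) / 2.0


@dataclass
class PenaltyTable:
    """One-body / two-body pseudoenergies, tracked per term.

    Two-body keys are canonicalized with the lower position first; an
    absent key means zero energy.
    """

    positions: tuple = ()
    one_body_terms: dict = field(
        default_factory=lambda: {t: {} for t in TERMS})
    two_body_terms: dict = field(
        default_factory=lambda: {t: {} for t in TERMS})
    offset_terms: dict = field(
        default_factory=lambda: {t: 0.0 for t in TERMS})
    stats: dict = field(default_factory=dict)

    @staticmethod
    def canonical(rid_a, rid_b):
        return (rid_a, rid_b) if rid_a <= rid_b else (rid_b, rid_a)

    def add_one_body(self, term, rid, value):
        table = self.one_body_terms[term]
        table[rid] = table.get(rid, 0.0) + value

    def add_two_body(self, term, rid_a, rid_b, value):
        key = self.canonical(rid_a, rid_b)
        table = self.two_body_terms[term]
        table[key] = table.get(key, 0.0) + value

    def add_offset(self, term, value):
        self.offset_terms[term] += value

    # ---- merged views -------------------------------------------------
    @property
    def constant_offset(self) -> float:
        return sum(self.offset_terms.values())

    def one_body(self, rid) -> float:
        return sum(self.one_body_terms[t].get(rid, 0.0) for t in TERMS)

    def two_body(self, rid_a, rid_b) -> float:
        key = self.canonical(rid_a, rid_b)
        return sum(self.two_body_terms[t].get(key, 0.0) for t in TERMS)

    def one_body_keys(self):
        keys = set()
        for t in TERMS:
            keys.update(self.one_body_terms[t])
        return keys

    def two_body_keys(self):
        keys = set()
        for t in TERMS:
            keys.update(self.two_body_terms[t])
        return keys


def table_total(table: PenaltyTable, assignment, terms=TERMS) -> float:
    """Offset + chosen one-body + chosen two-body energies."""
    missing = [p for p in table.positions if p not in assignment]
    if missing:
        raise UsageError(f"assignment missing positions {missing}")
    chosen = {pos: (pos, assignment[pos]) for pos in table.positions}
    total = sum(table.offset_terms[t] for t in terms)
    for rid in chosen.values():
        total += sum(table.one_body_terms[t].get(rid, 0.0) for t in terms)
    for pa, pb in itertools.combinations(sorted(chosen), 2):
        key = PenaltyTable.canonical(chosen[pa], chosen[pb])
        total += sum(table.two_body_terms[t].get(key, 0.0) for t in terms)
    return total


def _type_label(atom):
    info = polar_info(atom.res_name, atom.name, atom.is_backbone)
    if info is None:
        raise UsageError(f"atom {atom.key} is not a classified polar atom")
    return info.type_label


def _check_in_grid(atom, grid: BurialGrid):
    if grid.voxel_index(atom.position) is None:
        raise UsageError(
            f"atom {atom.key} lies outside the burial grid; the grid was "
            f"computed for a different structure")


def _buried_iter(rset: RotamerSet, grid: BurialGrid):
    """Yield (B, origin) for every buried polar atom over fixed context
    and all rotamers."""
    for atom in rset.fixed_polar_atoms:
        _check_in_grid(atom, grid)
        if is_buried(grid, atom.position):
            yield atom, None
    for pos in rset.positions:
        for rot in rset.rotamers[pos]:
            for atom in rot.polar_atoms:
                _check_in_grid(atom, grid)
                if is_buried(grid, atom.position):
                    yield atom, rot.id


class _ContextIndex:
    """Distance-prefiltered satisfier lookup over all polar atoms."""

    def __init__(self, rset: RotamerSet, quality_threshold: float):
        self.entries = rset.polar_context()
        self.quality_threshold = quality_threshold
        self.positions = (np.array([a.position for a, _ in self.entries])
                          if self.entries else np.empty((0, 3)))

    def satisfiers(self, b_atom, b_origin):
        """Distinct context atoms h-bonding to B, honoring the
        mutual-exclusion rule for B's own position."""
        if not self.entries:
            return []
        dists = np.linalg.norm(self.positions - b_atom.position, axis=1)
        out = []
        for j in np.nonzero(dists <= 3.5)[0]:
            q_atom, q_origin = self.entries[j]
            if q_atom.key == b_atom.key and q_origin == b_origin:
                continue
            if (b_origin is not None and q_origin is not None
                    and q_origin[0] == b_origin[0] and q_origin != b_origin):
                continue
            if hbond_between(b_atom, q_atom, self.quality_threshold):
                out.append((q_atom, q_origin))
        return out


def _sigma_target(table, term, value, origin_a, origin_b):
    if origin_a is None and origin_b is None:
        table.add_offset(term, value)
    elif origin_a is None:
        table.add_one_body(term, origin_b, value)
    elif origin_b is None or origin_a == origin_b:
        table.add_one_body(term, origin_a, value)
    else:
        table.add_two_body(term, origin_a, origin_b, value)


def _omega_target_key(origin_a, origin_b):
    """Accumulation target for an omega pair, or None when the pair is
    impossible (two different rotamers at one position)."""
    if origin_a is None and origin_b is None:
        return ("offset",)
    if origin_a is None:
        return ("one", origin_b)
    if origin_b is None:
        return ("one", origin_a)
    if origin_a == origin_b:
        return ("one", origin_a)
    if origin_a[0] == origin_b[0]:
        return None  # mutually exclusive rotamers
    return ("two", PenaltyTable.canonical(origin_a, origin_b))


def _apply_omega(table, key, value):
    kind = key[0]
    if kind == "offset":
        table.add_offset("omega", value)
    elif kind == "one":
        table.add_one_body("omega", key[1], value)
    else:
        table.add_two_body("omega", key[1][0], key[1][1], value)


def _assign(rset: RotamerSet, grid: BurialGrid, scheme: PolarScheme,
            quality_threshold: float, corrected: bool) -> PenaltyTable:
    scheme = get_scheme(scheme)
    table = PenaltyTable(positions=tuple(rset.positions))
    context = _ContextIndex(rset, quality_threshold)
    omega_pairs = 0
    # per-rotamer omega accumulation: rotamer id -> target key -> sum
    per_rotamer = {}

    for b_atom, b_origin in _buried_iter(rset, grid):
        beta, sigma, omega = scheme.coeffs(_type_label(b_atom))
        if b_origin is None:
            table.add_offset("beta", beta)
        else:
            table.add_one_body("beta", b_origin, beta)
        sats = context.satisfiers(b_atom, b_origin)
        for q_atom, q_origin in sats:
            _sigma_target(table, "sigma", sigma, b_origin, q_origin)
        for (_, o1), (_, o2) in itertools.combinations(sats, 2):
            key = _omega_target_key(o1, o2)
            if key is None:
                continue
            omega_pairs += 1
            if not corrected or b_origin is None:
                # fixed B: only one copy exists, no correction needed
                _apply_omega(table, key, omega)
            else:
                targets = per_rotamer.setdefault(b_origin, {})
                targets[key] = targets.get(key, 0.0) + omega
    if corrected:
        # Each omega target receives, per sequence position, the maximum
        # accumulation any single rotamer at that position generated.
        maxima = {}
        for rid, targets in per_rotamer.items():
            for key, value in targets.items():
                mkey = (rid[0], key)
                if mkey not in maxima or value > maxima[mkey]:
                    maxima[mkey] = value
        for (_, key), value in maxima.items():
            _apply_omega(table, key, value)
    table.stats["omega_pair_contributions"] = omega_pairs
    return table


def assign_naive(rset: RotamerSet, grid: BurialGrid, scheme,
                 quality_threshold: float = DEFAULT_QUALITY_THRESHOLD
                 ) -> PenaltyTable:
    """Project the penalty onto the interaction graph by plain summation
    (overcounts omega when a position offers several mediating rotamers)."""
    return _assign(rset, grid, scheme, quality_threshold, corrected=False)


def assign_corrected(rset: RotamerSet, grid: BurialGrid, scheme,
                     quality_threshold: float = DEFAULT_QUALITY_THRESHOLD
                     ) -> PenaltyTable:
    """Projection with the oversaturation correction: every omega target
    receives at most the largest contribution a single rotamer at each
    position generates."""
    return _assign(rset, grid, scheme, quality_threshold, corrected=True)


def _polar_atoms_of(pose: Pose):
    return [a for a in pose.all_atoms()
            if a.polar_class is not PolarClass.NONE]


def _per_atom_hbond_counts(pose: Pose, quality_threshold: float):
    """H (number of distinct h-bonded partners) for every polar atom of a
    concrete structure, by exhaustive pairwise detection."""
    polar = _polar_atoms_of(pose)
    counts = {a.key: 0 for a in polar}
    if not polar:
        return polar, counts
    coords = np.array([a.position for a in polar])
    for i, a in enumerate(polar):
        dists = np.linalg.norm(coords[i + 1:] - coords[i], axis=1)
        for off in np.nonzero(dists <= 3.5)[0]:
            b = polar[i + 1 + off]
            if hbond_between(a, b, quality_threshold):
                counts[a.key] += 1
                counts[b.key] += 1
    return polar, counts


def oracle_total(pose: Pose, grid: BurialGrid, scheme,
                 quality_threshold: float = DEFAULT_QUALITY_THRESHOLD):
    """Exact, non-pairwise ground truth on a realized structure.

    Counts H per buried polar atom by exhaustive h-bond detection and
    sums the quadratic penalty. Returns (total, report) where report is
    a list of (atom, H, P) rows for every buried polar atom.
    """
    scheme = get_scheme(scheme)
    polar, counts = _per_atom_hbond_counts(pose, quality_threshold)
    total = 0.0
    report = []
    for atom in polar:
        if not is_buried(grid, atom.position):
            continue
        h = counts[atom.key]
        p = eval_penalty(scheme.coeffs(_type_label(atom)), h)
        total += p
        report.append((atom, h, p))
    return total, report


def oracle_components(pose: Pose, grid: BurialGrid, scheme,
                      quality_threshold: float = DEFAULT_QUALITY_THRESHOLD):
    """Per-term (beta, sigma, omega) decomposition of the oracle total."""
    scheme = get_scheme(scheme)
    polar, counts = _per_atom_hbond_counts(pose, quality_threshold)
    parts = {t: 0.0 for t in TERMS}
    for atom in polar:
        if not is_buried(grid, atom.position):
            continue
        beta, sigma, omega = scheme.coeffs(_type_label(atom))
        h = counts[atom.key]
        parts["beta"] += beta
        parts["sigma"] += sigma * h
        parts["omega"] += omega * h * (h - 1) / 2.0
    return parts


def count_buried_unsat(pose: Pose, grid: BurialGrid,
                       quality_threshold: float = DEFAULT_QUALITY_THRESHOLD
                       ) -> int:
    """Number of buried polar heavy atoms with no hydrogen bond."""
    polar, counts = _per_atom_hbond_counts(pose, quality_threshold)
    return sum(1 for a in polar
               if is_buried(grid, a.position) and counts[a.key] == 0)


def extraneous_fraction(native_assignment, expanded_set: RotamerSet,
                        grid: BurialGrid, scheme,
                        quality_threshold: float = DEFAULT_QUALITY_THRESHOLD
                        ) -> float:
    """Fraction of h-bond-network native rotamers hit by oversaturation
    edges that exist only because of non-native rotamers.

    Builds corrected tables for (a) the native-only singleton set and
    (b) the expanded set, and counts native<->native omega-bearing edges
    present in (b) but absent in (a), normalized by the number of native
    rotamers participating in the native h-bond network.
    """
    from .rotamers import RotamerSet as _RS

    for pos in expanded_set.positions:
        if pos not in native_assignment:
            raise UsageError(f"no native rotamer given for position {pos}")
        if not (0 <= native_assignment[pos]
                < len(expanded_set.rotamers[pos])):
            raise UsageError(
                f"native ordinal {native_assignment[pos]} out of range at "
                f"position {pos}")

    native_rots = {pos: expanded_set.rotamer(pos, native_assignment[pos])
                   for pos in expanded_set.positions}
    singles = {}
    for pos, rot in native_rots.items():
        singles[pos] = [type(rot)(rot.position, rot.residue_type,
                                  rot.chi, rot.atoms, ordinal=0)]
    native_set = _RS(singles, expanded_set.fixed_atoms)

    table_a = assign_corrected(native_set, grid, scheme, quality_threshold)
    table_b = assign_corrected(expanded_set, grid, scheme, quality_threshold)

    def omega_edges(table, ordinal_of):
        edges = set()
        for (ra, rb), value in table.two_body_terms["omega"].items():
            if value != 0.0 and ra[1] == ordinal_of(ra[0]) \
                    and rb[1] == ordinal_of(rb[0]):
                edges.add((ra[0], rb[0]))
        return edges

    edges_a = omega_edges(table_a, lambda pos: 0)
    edges_b = omega_edges(table_b, lambda pos: native_assignment[pos])
    extraneous = edges_b - edges_a

    # Native rotamers participating in the h-bond network: any polar atom
    # with a detected partner among the native context.
    context = native_set.polar_context()
    participants = set()
    for i, (a, oa) in enumerate(context):
        for b, ob in context[i + 1:]:
            if oa is None and ob is None:
                continue
            if np.linalg.norm(a.position - b.position) > 3.5:
                continue
            if hbond_between(a, b, quality_threshold):
                if oa is not None:
                    participants.add(oa[0])
                if ob is not None:
                    participants.add(ob[0])
    if not participants:
        return 0.0
    return len(extraneous) / len(participants)
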