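# Methods

This note documents the models, approximations, parameters and design
choices behind the package, in the order a packing calculation uses
them. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Penalty model

A buried polar heavy atom with H hydrogen bonds contributes

    P(H) = β + σ·H + ω·H·(H−1)/2.

The second difference of P is exactly ω, so the curve is the general
quadratic in H; (β, σ, ω) are chosen per atom-type label (NH1, NH2,
NH3, carbonyl_O, carboxylate_O, hydroxyl, imidazole, indole) and looked
up by the label of the *buried* atom only, never of its partners.

Shipped schemes:

| name              | values |
|-------------------|--------|
| `table1`          | the five published example rows (NH1 1/−1/2, carbonyl 1/−1/1, NH2 4/−3/2, carboxylate 3/−2/1, NH3 9/−5/2) plus package defaults for hydroxyl (1/−1/1), imidazole and indole (1/−1/2) |
| `uniform5`        | β=5, σ=−5, ω=5 for every type |
| `uniform5_noover` | β=5, σ=−5, ω=0 |
| `uniform10`       | β=10, σ=−10, ω=10 |
| `*_lysnz`         | as above with NH3 overridden to β=15/σ=−10 (5×) or β=30/σ=−20 (10×) |

The `table1` targets are illustrative, not claimed optimal; the
hydroxyl/imidazole/indole rows are package defaults chosen to penalize
being off-by-one from 1–2 bonds, matching the spirit of the published
rows. Energies are in the same arbitrary units as the base force field,
scaled so an ideal hydrogen bond is worth −2.

## Burial field

Burial must not depend on sequence or rotamer choice, so it is computed
once on a poly-leucine conversion of the input: every non-GLY/PRO
sidechain is replaced by an ideal leucine at χ1=240°, χ2=120° built on
the native backbone (GLY has no CB and PRO's ring constrains χ1; both
are left unchanged, erring toward less burial). Ideal residue geometry
comes from bundled chemical-component templates; chi dihedrals are set
by rotation about the chi bonds after superimposing the template N/CA/C
frame, with the frame atoms pinned to the actual backbone so dihedrals
are exact against the true atoms.

The depth field is a three-stage voxel approximation of
depth-below-the-solvent-excluded-surface:

1. *probe-center space*: voxel centers farther than (vdW + probe) from
   every atom, restricted to the connected component touching the grid
   boundary. Interior cavities unreachable by the probe are molecular
   volume — cavity waters are out of scope.
2. *solvent* = probe-center space dilated by the probe radius
   (implemented as a distance-transform threshold).
3. *depth* = Euclidean distance transform of the complement, in Å.

Defaults: 0.5 Å voxels, 2.3 Å probe, Bondi element radii (C 1.70,
N 1.55, O 1.52, S 1.80). A point is buried when the voxel containing
the heavy atom (hydrogens are ignored for burial) has depth ≥ X; the
comparison is inclusive, X defaults to 4.5 Å and is exposed over
3.5–5.5. On grids small enough to enumerate, the distance-transform
depth equals an all-pairs nearest-solvent-voxel search exactly (tested).
Known limitation, inherited from the depth definition: a polar atom
just below the surface but covered laterally (e.g. under an aromatic
ring) is not considered buried.

## Hydrogen bonds

Detection is geometric: donor-heavy-to-acceptor distance within
[2.5, 3.5] Å and D-H…A angle ≥ 120°. Quality is the product of a
distance term (1 at 2.8 Å, linear to 0 at the window edges) and an
angle term (0 at 120°, 1 at 180°), giving a score in [0, 1]; a bond
counts when quality ≥ the stringency threshold (default 0.37, i.e.
roughly a third of ideal — the analog of a −0.75 cutoff on a −2
maximum-energy scale). Choices:

- Hydroxyl protons are rotatable: they are represented by three
  staggered position samples about the C–O bond and a bond counts if
  any sample passes. Explicitly provided hydroxyl protons are kept in
  addition to the samples.
- Backbone amide H is placed ideally from the local peptide frame; a
  residue with no covalently continuous predecessor gets no amide H and
  its N is treated as apolar (it cannot donate).
- H for an atom counts *distinct partner atoms*. A hydroxyl may donate
  in one bond and accept in another; each partner counts once.
- Same-residue backbone amide-to-carbonyl contacts are excluded;
  everything else, including (i, i+1) sidechain pairs, is eligible.
- σ is applied as a constant per detected bond, not scaled by quality.

## Interaction-graph projection

For every buried polar atom B (over the fixed context and all rotamers
at all positions): β accumulates to B's one-body term (constant offset
when B is fixed); for each satisfier Q, σ accumulates to the r_B↔r_Q
edge; for each unordered satisfier pair (Q1, Q2), ω accumulates to the
r_Q1↔r_Q2 edge. Candidate satisfiers exclude atoms in a *different*
rotamer at B's own position (mutually exclusive alternatives), and ω
pairs whose endpoints are different rotamers at one position are
skipped for the same reason. Contributions whose endpoints collapse are
demoted: fixed↔rotamer to the rotamer's one-body term, fixed↔fixed to
the constant offset, intra-rotamer to that rotamer's one-body term.
These demotion rules are forced by the interaction-graph formalism.

The **correction** addresses ω overcounting when several rotamers at
one position each bridge the same satisfier pair: contributions are
first accumulated per (position of B, rotamer, target), then each
target receives the *maximum* over rotamers at that position (a running
max in practice, so memory stays per-target). The published rule covers
two-body edge targets; the same double-count arises for demoted one-body
and offset targets, so the maximum is applied uniformly to every ω
target — for pure edges this reduces exactly to the published rule.
Contributions from fixed buried atoms bypass the correction (only one
copy of a fixed atom exists). Ties in the max need no policy since only
the value is used.

Consequences, all verified by the tests against the exhaustive oracle:
with one rotamer per position the corrected table equals the oracle
exactly; for any assignment with ω ≥ 0, naive ≥ corrected ≥ oracle; and
the β and σ components of the table always match the oracle term by
term — only ω can be extraneous. Satisfier capacity is not enforced
during accumulation; the quadratic ω term is the soft capacity
mechanism.

The extraneous-penalty diagnostic builds corrected tables for the
native-only singleton set and for an expanded set, counts
native↔native ω-bearing edges present only in the latter, and divides
by the number of native rotamers participating in the native h-bond
network (0 when no native rotamer participates).

## Rotamers and base force field

Rotamers are enumerated from staggered chi values (60/180/300 per
rotatable bond; the "extra" level adds ±10° subsamples on χ1 and χ2
only, keeping combinatorics bounded). No backbone-dependent rotamer
library is shipped: the penalty algorithm only requires that all
rotamers exist before packing, not where they come from. The pose's
current sidechain can be appended as a native rotamer.

The base force field is intentionally minimal, since the package's
subject is the penalty bookkeeping, not folding accuracy: a capped soft
steric repulsion ((Σ vdW / d)¹² − 1, capped at 100, cutoff 8 Å) plus
−2 × quality per hydrogen bond. Polar-polar contacts at h-bond range
(2.5–3.5 Å) are exempt from the steric term — hydrogen-bond distances
sit inside the vdW sum by nature. Sterics against a rotamer's own
backbone are skipped (covalently attached geometry). Rotamers whose
one-body energy exceeds 25 are pruned, always keeping at least one per
position. Base energies never depend on penalty coefficients; the
penalty is purely additive.

## Packer

Single-rotamer substitution moves under Metropolis acceptance with
geometric cooling from T=5 to T=0.3 over 200 sweeps of (total rotamer
count) moves — small instances converge well within this budget; all
three numbers are exposed. One integer seed drives one generator with a
documented draw order, so runs are bit-reproducible. The best-seen
assignment is returned; a brute-force enumerator (lexicographic
tie-break, 10⁶-assignment guard) serves as the optimality oracle. No
attempt is made to mimic any particular production packer's trajectory;
only the penalty-table semantics matter here.

## Synthetic fixtures: what they do and do not show

Fixtures are engineered scaffolds, not refined proteins. Bulk filler
residues are glycines carrying only N/CA/C and no amide proton, so the
scaffold contributes van der Waals volume but zero polar atoms, and the
polar bookkeeping of each fixture is exactly what was designed in
(hand-placed sidechains may have slightly non-ideal internal geometry;
only their polar-atom positions matter to the algorithms). Layout
constants were chosen so the designed depths clear their thresholds by
comfortable margins on the 0.5 Å grid:

- `glu_two_ser`: a slab with a narrow open pocket; the carboxylate
  oxygen at the pocket floor is 5.0 Å deep (buried at X=4.5) while the
  two donating hydroxyls higher in the pocket are at ≈3 Å (not buried).
- `buried_triad`: a ≈10 Å sphere enclosing a cavity with a glutamate
  carboxylate (deepest atom 8 Å) and two serines whose native rotamers
  satisfy both oxygens; staggered decoy rotamers leave them
  unsatisfied.
- `surface_polar`: a thin extended serine peptide (all depths < 2 Å).
- `two_helix_bundle`: two ideal antiparallel polyalanine helices with
  full backbones, for I/O and conversion tests.
- `random_polar_cluster`: a fixed scaffold (hence one shared burial
  grid) with per-seed random polar residue types and continuous chi
  angles, used for the singleton-equivalence and bound properties.

Passing tests on these fixtures demonstrate the *bookkeeping*
guarantees — projection exactness, bounds, correction semantics,
optimizer correctness — under fully controlled burial and h-bond
geometry. They do not demonstrate design quality on real proteins:
real sidechain packing needs a production force field and rotamer
library, and real structures contain waters, ions and backbone
flexibility that the fixtures deliberately omit.

## Numerical choices and degenerate inputs

- Depth lookups use the voxel nearest the query point; points outside
  the grid have depth 0 (solvent).
- Burial comparison is inclusive (≥ X); tested explicitly.
- Table keys are canonicalized with the lower position first; absent
  keys mean zero.
- Alternate locations in PDB input resolve to highest occupancy, ties
  alphabetically; HETATM records and waters are skipped; hydrogens in
  the input attach to the nearest polar heavy atom within 1.3 Å.
- Zero-length simulations, empty poses, empty rotamer sets, unknown
  scheme or fixture names, negative H, and grid/structure mismatches
  raise typed errors rather than returning defaults.

## Problem sizes

The test suite and the worked examples run on structures of roughly
200–400 residues' worth of scaffold atoms with 3–6 designable
positions, grids of ≈60–75 voxels per axis, and rotamer sets of up to a
few dozen rotamers; the randomized property checks use 100 singleton
structures and 12 multi-rotamer structures with 3 assignments each.
These sizes were chosen so that every guarantee is exercised end to end
while the whole suite stays interactive.
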