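# threebop

A pairwise-decomposable pseudoenergy that penalizes **buried unsatisfied
polar atoms** during rotamer-based protein sidechain packing, with the
three-body oversaturation correction (3BOP), plus everything needed to
use and validate it: PDB I/O, a sequence-independent burial field,
geometric hydrogen-bond detection, rotamer machinery, a simulated-
annealing packer, and an exact non-pairwise oracle.

## The problem

Polar groups at a protein surface hydrogen-bond to water. When design or
packing buries such a group without giving it a protein partner, the
lost water hydrogen bonds are not compensated — a *buried unsatisfied*
polar atom, which real proteins almost never tolerate. Penalizing this
during combinatorial sidechain packing is awkward because satisfaction
is a collective property (it depends on all neighbors at once), while
fast packers require energies that decompose into one-body and two-body
rotamer terms.

## The method

Each buried polar atom B making H hydrogen bonds is assigned the
quadratic pseudoenergy

    P(H) = β + σ·H + ω·H·(H−1)/2

where β is the burial penalty, σ the per-bond satisfaction bonus, and ω
the penalty per *pair* of simultaneous bonds (oversaturation). Choosing
(β, σ, ω) per atom type shapes the curve so that its minimum sits at any
target bond count — e.g. (9, −5, 2) for an ammonium nitrogen puts the
minimum at H = 3.

Because all rotamers exist before the Monte Carlo trajectory starts, the
non-pairwise quantity H can be projected onto the rotamer interaction
graph ahead of time: for every buried polar atom B over all rotamers and
the fixed context, β accumulates to B's one-body energy, σ to each
B↔satisfier edge, and ω to each satisfier-pair edge. Since several
alternative rotamers at one position can each bridge the same satisfier
pair — while only one of them can be selected — the summed ω overcounts;
the **corrected** assignment instead gives each ω target the maximum a
single rotamer at that position generates. The corrected table is exact
for singleton rotamer sets and an upper bound in general (only the ω
term can be extraneous; β and σ are always exact), which this package
verifies against its own exhaustive oracle.

Burial itself is made sequence-independent by first converting the
structure to poly-leucine (χ1=240°, χ2=120°), voxelizing space at 0.5 Å,
approximating the solvent-excluded volume with a 2.3 Å probe, and taking
the Euclidean distance transform to the nearest solvent voxel; atoms at
least X Å below the surface (default X = 4.5, sensible range 3.5–5.5)
count as buried.

## Worked example

All fixtures are generated by the package itself — no downloads. The
`buried_triad` fixture is a deeply buried glutamate carboxylate whose
two oxygens can each receive a serine hydroxyl, if the packer picks the
right rotamers:

```sh
threebop fixtures --spec buried_triad --seed 0 --out triad.pdb
threebop design --pdb triad.pdb --scheme uniform5 --penalty-mode corrected --seed 0
```

prints

```
# design report (scheme=uniform5, mode=corrected, seed=0, X=4.5, probe=2.3, voxel=0.5, hbond_quality=0.37)
total_energy -0.1017
base_energy -0.1017
threebop_energy 0.0000
table_total 0.0000
oracle_total 0.0000
buried_unsat 0
extraneous_fraction 0.0000
assignment 1:3 2:3 3:3
```

Every buried polar atom found a partner (`buried_unsat 0`), the penalty
table evaluated on the chosen rotamers agrees with the exact oracle
(`table_total` = `oracle_total` = 0: each buried atom sits at the
minimum of its penalty curve), and no extraneous oversaturation edges
touch the chosen rotamers. Running the same design with
`--penalty-mode off` reaches a slightly better base energy (−1.0162)
but leaves `buried_unsat 1` — exactly the failure mode the penalty
exists to prevent.

The `burial` and `report-unsats` subcommands expose the per-atom depth
table and the per-atom (H, P) breakdown for any PDB file.

## Library surface

```python
from threebop import (build_fixture_pose, mutate_to_polyleu,
                      compute_burial_grid, build_rotamer_set,
                      assign_corrected, anneal_pack, oracle_total)
```

`assign_naive` / `assign_corrected` build `PenaltyTable`s (per-term
one-body, two-body and constant entries); `oracle_total` recomputes the
exact non-pairwise total on any concrete structure for validation;
`eval_penalty` evaluates P(H) directly.

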