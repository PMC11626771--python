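# metalgeom

Stereochemical restraints around metal atoms are the weak spot of most
macromolecular refinement pipelines: bond lengths and angles at a metal
centre depend on the metal's charge, its coordination geometry and the
chemistry of its surroundings, and a metal-containing ligand only becomes
complete once it sits inside a protein.  `metalgeom` is a toolkit for
crystallographers and model builders that addresses this in three steps:

1. **Classify** the coordination geometry of a metal site by *combinatorial
   Procrustes matching* against a library of idealized coordination classes
   (octahedral, tetrahedral, sandwich_5_5, ...) whose metal–ligand distances
   are normalized to 1.
2. **Mine** metal environments from small-molecule crystal structures
   (CIF): quality filters, crystallographic symmetry expansion, neighbour
   capture at three covalent-radius multiples, and accumulation of
   per-(metal, ligand element, class) bond-length and angle statistics.
3. **Generate restraints**: update a monomer dictionary around its metal
   atoms and emit a JSON document with the full per-site statistics
   (all matching classes, multimodal bond-length distributions,
   symmetrized von Mises angle summaries) for downstream refinement.

## The core statistic

A metal site with ligand positions `x_1..x_n` (metal at the origin) is
compared against a reference class `y_1..y_n` (unit-length vertices) by the
normalized full Procrustes distance, minimized over vertex correspondences
π, rotations R (improper allowed by default) and scale s:

    d = min_{π, R, s}  sqrt( Σ_i ‖ s·R·x_i − y_{π(i)} ‖² / Σ_i ‖ y_i ‖² )

The permutation search is exhaustive up to 8 vertices (8! = 40 320
correspondences, evaluated in a single vectorized pass) and a seeded
assignment/refinement heuristic above that.  A site is assigned to the
class with the **highest possible coordination number** whose distance is
strictly below 0.3: neighbours are captured at `d12 ≤ α(r1+r2)` with
α = 1.3 first, descending to 1.2 and 1.1 only when no class fits, so a
stretched octahedron stays octahedral while a genuinely four-coordinate
site falls back to square-planar.

Bond-length populations are summarized by a small Gaussian mixture (BIC
model selection with weight and separation guards) because metal–ligand
distances are frequently multimodal; angles on [0°, 180°] are fitted with
a von Mises likelihood folded about the half-circle boundaries so that
near-linear coordination does not wrap.  Nominal charges are assigned by
valence bookkeeping with ionic counting of metal–ligand links, choosing
each metal's oxidation state from its common states so the local net
charge is as close to zero as possible.

## Worked example

Classify a noisy synthetic magnesium site (angular noise 0.03 rad, 2%
bond-length jitter) against the packaged class library:

```python
from metalgeom import load_class_library, classify_environment
from metalgeom.fixtures import SiteRecipe, site_environments

lib = load_class_library()
envs = site_environments(
    SiteRecipe("Octahedral", seed=7, metal="Mg", sigma=0.03, jitter=0.02), lib
)
res = classify_environment(envs, lib)
print(res.best.class_name, round(res.best.distance, 4), res.best.alpha)
```

prints

```
Octahedral 0.0476 1.3
```

i.e. the site is assigned to the octahedral class with Procrustes distance
0.048 (well under the 0.3 acceptance bound) using the neighbours captured
at α = 1.3; the nearest wrong class, trigonal-prism, sits at 0.394 and is
rejected.  The same machinery drives the command-line tool:

```sh
metalgeom mine   CIF_DIR -o mined/            # filter, extract, classify, tabulate
metalgeom stats  -m model.pdb -l HEM -t mined/restraint_table.json -o hem.json
metalgeom update -d HEM.cif -m model.pdb -t mined/restraint_table.json -o HEM_new.cif
metalgeom coord  -n 6                         # list six-coordinate classes
```

`stats` writes one JSON block per component instance with every matching
class ranked; `update` rewrites only the metal-involving bond/angle ideals
of the dictionary (most probable mode only) and reports every change.
A `-c N` option caps the coordination number by dropping the longest
bonds in units of `d12/(r1+r2)`, which is how spurious near-in atoms
(e.g. a stray carbon near a chlorophyll magnesium) are excluded.

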