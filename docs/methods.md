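# Methods

## Shape matching

Coordination geometry is the arrangement of ligand atoms about a metal, so
both the observed site and the reference class are anchored with the metal
at the origin and the metal itself is excluded from the point set.
Translation is removed by this anchoring, **not** by centroid subtraction:
with centroid centring a single long bond would drag the frame and distort
every other vertex's residual.  For a fixed vertex correspondence the
optimal rotation and scale have the closed-form orthogonal (SVD) solution;
improper rotations are allowed by default because coordination polyhedra
are treated as achiral (a config flag restricts the fit to proper
rotations).  The residual is normalized by the reference sum of squares,
which equals the coordination number for unit-normalized references — this
makes the 0.3 acceptance threshold comparable across coordination numbers.
The distance is asymmetric in its two arguments (scale freedom sits on the
observed side only); all consumers use the observed-vs-reference direction.

The correspondence search is exhaustive for n ≤ 8.  All n! permutations
are scored in one vectorized pass: the objective reduces to maximizing the
(det-corrected) nuclear norm of the 3×3 cross-covariance, computed for the
full permutation stack with closed-form (Cardano) eigenvalues of AᵀA.  The
winning permutation is then re-fitted with the standard SVD path, so the
reported distance is a directly measured residual rather than the scan's
closed form.  For n > 8 (the larger sandwich classes), rotation seeds are
generated from all ordered reference vertex pairs aligned against a fixed
non-collinear observed pair (both handedness variants when reflections are
allowed); each seed is completed by minimum-cost bipartite assignment on
inter-point distances and refined by alternating closed-form fit and
re-assignment to convergence.  A plain-loop brute-force enumeration (cap
n ≤ 8) serves as an independent oracle in the tests and never backs the
production path.

Ties between equal-distance classes resolve lexicographically by class
name; distances are compared with absolute tolerance 1e-9.

## Class library

The packaged library regenerates the idealized classes from documented
constructions: the classical polyhedra (octahedron, tetrahedron, trigonal
bipyramid, square antiprism with equal edges, the D2d triangulated
dodecahedron at the favourable 36.85°/69.46° vertex angles, a square-face
trigonal prism, bipyramids, cube) plus sandwich classes built as two
parallel regular rings at unit metal–vertex distance.  Ring polar angles
follow a single chord convention — the in-ring nearest-neighbour chord is
0.70, about a 1.4 Å aromatic C–C bond over a 2.0 Å metal–carbon bond — so
every `Sandwich_n_m` is fully determined (m = 1 degenerates to an axial
cap, m = 2 to a symmetric near-axial pair; the smaller ring is staggered).
Named classes whose geometry is not derivable from their name (e.g.
"Bicapped-linear", the `_h/_i/_v` sandwich variants, "Paired-octahedral")
are omitted; the library version tag records this regenerated provenance.
Classes carry a `used` flag mirroring which geometries the classifier
consults.  Within every coordination number all packaged classes are
mutually separated by a Procrustes distance well above the 0.01 duplicate
guard (the closest pair, dodecahedral vs square-antiprismatic, sits at
0.17).

The class-definition file is plain structured text (name, coordination,
provenance, used flag, one unit vector per line) so the library diffs and
versions cleanly; user libraries load from the same format.

## Mining small-molecule structures

Entries must have resolution strictly better than 0.82 Å, a conventional R
factor strictly below 0.1, no partially occupied non-hydrogen atoms and at
least one metal in the asymmetric unit; a missing quality datum fails the
filter explicitly ("missing metadata").  Resolution is taken from the
reflection statistics tag when present, else derived from θ_max and the
wavelength.  Symmetry expansion applies every operator over lattice
translations {−1, 0, +1}³ — bonding distances (< ~4 Å) are far below
typical cell dimensions, so one shell suffices; the range is a config
knob.  Duplicate images of the same element within 0.1 Å are merged
keep-first by (site, operator, translation) order.  Around each metal of
the asymmetric unit all atoms with d12 ≤ α(r1 + r2) are captured at
α = 1.1, 1.2, 1.3 using single-bond covalent radii; hydrogens are stripped
as preprocessing.  Environments containing a metal–metal contact are set
aside and never enter the statistics.  Since any partial occupancy already
fails the entry filter, mined environments cannot contain alternate
conformations.

Covalent radii are shipped as versioned TSV package data.  For the
spin-state ambiguous first-row metals (Mn, Fe, Co) the packaged default is
the high-spin (larger) value: capture stays permissive and the α-descent
tightens selection afterwards; an override table is accepted everywhere a
radius is looked up.

## Classification policy

Capture radii are tried in descending order (1.3 → 1.2 → 1.1).  At each
radius only classes whose coordination number equals the current neighbour
count are candidates; "unsuccessful" means no candidate is strictly below
the threshold, and only then is the next smaller radius consulted.  This
realizes highest-coordination-first assignment and the reclassification
behaviour (octahedral → square-planar when two opposite bonds fall out of
capture).  With a `max_coordination` cap, neighbours are dropped longest
first in units of d12/(r1+r2), the same normalized distance that defines
capture.  When several classes pass, ranking is (higher coordination,
smaller distance, class name).  Review criteria — coordination ≤ 4, small
class membership N_class ≤ min(30, 0.05·N_metal), bond-length outliers
above q3 + 1.5·IQR (quartiles by linear interpolation), distances in the
0.2–0.3 band — are surfaced as flags for human inspection and never
trigger automatic re-decisions.

## Restraint statistics

Bond lengths are keyed by (metal element, ligand element, class); angles
by (class, metal element, reference-vertex pair), with the pair obtained
through the accepted match's permutation — cis and trans octahedral angles
are therefore separate populations.  Mode detection fits 1..3 Gaussian
components, selects the count by BIC, rejects fits with any component
weight under 5%, and pools components closer than one pooled standard
deviation; samples are assigned to components by maximum responsibility,
so mode counts always sum to n.  Below 5 samples a single "low data" mode
with a floored esd is returned.  Angles are fitted by maximizing the
folded von Mises likelihood f(θ) ∝ exp(κ·cos(θ−μ)) + exp(κ·cos(θ+μ)) on
[0°, 180°] (coarse μ grid, then L-BFGS-B on (μ, log κ)); for μ well inside
the interval and large κ the mirror term is negligible and the fit
coincides with the plain von Mises MLE, while mass near 180° (linear
sites) stays at the boundary instead of wrapping.  The derived esd is
deg(1/√κ).  Esd floors are 0.02 Å for bonds and 3° for angles (config
knobs); κ is capped at 1e6 for degenerate samples.  All stochastic fits
take an explicit seed.

## Charges

Ligand formal charges come from valence bookkeeping: aromatic systems are
first Kekulized by maximum matching (carbons always eligible for a double
bond, nitrogens only with free sigma capacity, oxygens contribute lone
pairs), then each atom's charge is its incident bond-order sum minus the
best-fitting default valence (B3 C4 N3 O2 P3/5 S2/4/6 halogens 1), ties
resolving to the anionic reading.  Per-atom placement inside an aromatic
ring is representation-dependent; ring totals are the tested contract.
Metal–ligand links are counted ionically — they never enter a ligand
valence sum — which is exactly what makes the haem arithmetic work (two
anionic pyrrole nitrogens → Fe²⁺; one more anionic axial ligand → Fe³⁺).
Each metal then takes the common oxidation state minimizing the absolute
local net charge of its bonded component, ties toward the smaller state,
with a warning when nothing balances exactly; adding an anionic ligand can
therefore only push the chosen state up.  Missing hydrogens are not added;
graphs must arrive complete.  Known limitation: the default-valence rule
misassigns electron-poor boron (borate would come out +1 rather than −1);
boron clusters are outside this package's scope.

## Dictionary and model handling

Monomer dictionaries use the CCP4 monomer-library mmCIF categories
(`_chem_comp_atom/_bond/_angle` with ideal values and esds).  Writing is
deterministic row-by-row, so a dictionary update is byte-identical outside
the metal-involving rows.  Metal removal keeps an exact reversal record
(atoms, bonds, angles with their original indices); reinsertion restores
the dictionary field-for-field and, given coordinates, places each metal
at the arithmetic mean of its bonding partners with tentative bond lengths
r1 + r2 (a single-partner metal is flagged degenerate).  When a model
holds several instances of a component, the one with the highest occupancy
and then the smallest mean B is selected, ties broken by chain/residue
order.  Site extraction for models draws neighbours from the entire model
(protein and solvent included), drops hydrogens and other metals, and
applies the `-c` cap.  The restraint JSON (schema shipped as package data,
validated on every write) contains **all** matching classes per site with
full mode lists; a dictionary update consumes only the most probable mode
of the top class, and when no class matched, only bond lengths are updated
(pooled over classes).

## Synthetic data

The generator produces what the pipeline would see from well-determined
small-molecule structures: ideal class geometries at uniformly random
orientation, tangent-plane Gaussian angular noise (default study
conditions 0.03 rad), relative bond-length jitter (2%), embedded into toy
P1/P-1 cells with settable quality metadata, plus toy dictionaries
(porphyrin-like macrocycle, metallocene, aquo complexes) and toy PDB
models.  It does not emulate real-database element frequencies,
temperature effects, disorder, or systematic coordinate error, so passing
recovery tests demonstrate correctness of the matching and statistics
machinery, not classification accuracy on real crystal structures.  All
generators are pure functions of (recipe, seed).

## Problem sizes and test design

The test and acceptance workloads use 100 replicates per class for noisy
recovery (classes up to coordination 8), 200 random shapes for the
exhaustive-search oracle check (n = 3..7), n = 500 samples for bimodal
bond-length recovery and n = 1000 angles at κ = 50 for the angle fit —
sizes at which the expected estimation error is several times smaller
than the asserted tolerances.  Mining runs use toy corpora of ~10
single-site crystals per scenario.
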