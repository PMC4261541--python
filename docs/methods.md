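# Methods

This note documents the models and procedures the package implements, the
parameters that matter, what the synthetic generators do and do not emulate,
and the numerical choices made where the design was genuinely open.

## Structure model and annotation

Structures are held as an ordered list of residues keyed by
`(chain, author_seq_id + insertion_code)`, kept verbatim from the input file;
all selections are sets of such keys, never index ranges. This protects the
bound/unbound correspondence: unbound and bound crystal structures of the
same molecule routinely use different numbering conventions, so residue
pairing between two structures is always established by a global sequence
alignment of each role's chain (match 2, mismatch −1, gap open −5, extend
−0.5), with het-groups paired by residue name and order. Roles
(`tcr_alpha`, `tcr_beta`, `mhc_platform`, `mhc_other`, `antigen`, `other`)
come from a per-case JSON manifest; non-amino-acid residues inside receptor
chains are promoted to `antigen` automatically. Alternate locations resolve
to the highest-occupancy copy; waters are dropped; hydrogens are read if
present but never built — electrostatics uses whatever charged atoms exist,
and a structure's provenance records which charge sources were applied.
γδ TCRs are handled by assigning the δ chain the α role and γ the β role.

CDR definitions are taken from the manifest (`cdr_overrides`) when given;
the toy generator always writes them. For real structures IMGT-style loop
boundaries should be supplied the same way.

## Contact typing

Every protein heavy atom maps to one of 18 ACE/IFACE-style contact classes
through a shipped `(residue, atom) → class` table. The class grouping —
backbone N/CA/C/O, Gly CA, Cβ, aliphatic carbons, aromatic carbons,
hydroxyl-bearing aromatic carbon, amine-adjacent carbons, carboxylate
oxygens, amide N/O, guanidinium/ring/amine nitrogens, hydroxyl oxygens,
sulfur — reconstructs the chemical logic of atomic-contact-energy typing.
Antigen (het) atoms are typed by *congruence*: bonds are inferred from
covalent radii (+0.45 Å slack), and the element plus its one- and two-bond
heavy-neighbor environment is matched to the closest amino-acid atom class
(e.g. a carbon bonded to two oxygens types as the carboxylate carbon class;
a short 1.23 Å C–O oxygen as carbonyl; phosphate oxygens as carboxylate-like
oxygens), falling back to an element default. Exotic elements stay untyped,
are warned about, and are excluded from the contact-potential sums.

The *pair-energy values* of the shipped ACE and IFACE tables are synthetic
stand-ins (so labelled in their filenames and headers): an additive model
over chemistry-motivated per-class propensities, with the IFACE variant
compressing hydrophobic rewards and favoring polar–polar interface contacts.
They are deterministic and ordinally sensible (hydrophobic–hydrophobic
contacts favorable, charged-group burial penalized) but are not fitted to
crystal-structure statistics; absolute energies on real complexes will
differ from statistics-derived tables. Users with access to fitted ACE/IFACE
tables can drop them in — the file format is a three-column TSV and every
operation takes the table as data.

Protein partial charges likewise come from a shipped formal-charge template
(Asp/Glu carboxylates −0.5 per oxygen, Lys +1 on NZ, Arg +0.2/+0.4/+0.4 on
NE/NH1/NH2, C-terminal OXT −0.5); antigen charges always come from a Mol2
file's charge column.

## Scoring function

A docking model's score is `Σ wᵢ·termᵢ` over eight inter-partner terms; more
negative ranks better (the energy-funnel convention). All terms run over
TCR-partner × receptor-partner atom pairs only — intra-partner geometry
never contributes, which the tests verify directly.

| term | form | cutoff |
|---|---|---|
| vdW attractive/repulsive | Lennard-Jones 6-12, ε and r_min from a generic per-element table, Lorentz–Berthelot combination; negative pair energies accumulate into the attractive term, positive into the repulsive | 8 Å |
| electrostatics SR attr/rep | Coulomb `k·qᵢqⱼ/r`, k = 332.0637 kcal·Å/(mol·e²) | r < 5 Å |
| electrostatics LR attr/rep | same | 5 ≤ r < 12 Å |
| ACE / IFACE | pair-table sum over typed heavy atoms | 6 Å |

Each pair energy is clamped to ±100 to keep steric clashes from dominating a
score without distorting ordinary contact energies. All cutoffs, the clamp
and the Coulomb constant live in `ScoringConfig`, so exact parity with other
implementations of this family of scores is a configuration matter, not a
code change.

Two weight presets are shipped: `ZR2` = (1.0, 0.23, 0.57, 0.56, 1.09, 0.29,
0.7, 0.38) for general protein–protein rescoring and the TCR-retrained
`ZRT` = (0.027, 1.33, 0.35, 0.29, 0.30, 0.21, 0.64, 0.27), whose strikingly
low vdW-attractive weight reflects the lower shape complementarity of
TCR-style interfaces.

## Groove frame and start poses

The groove frame is built from the platform-helix Cα atoms: origin at their
centroid; groove axis = first principal axis, oriented along the α1 helix
N→C direction (α1 comes from the manifest, defaulting to the first half of
the platform residues in file order); normal = smallest principal axis
(perpendicular to the best-fit helix plane), oriented toward the
TCR-accessible face; third axis = normal × groove axis. The normal's sign is
fixed by the antigen centroid when an antigen is present, else by pointing
away from the `mhc_other` (β-sheet floor) centroid, else toward +z. On real
class-I-like platforms the sheet-based rule is the more robust one; deeply
buried lipids could in principle put their centroid below the helix-Cα
plane, in which case tag the α3/β2m layers `mhc_other` and omit the antigen
from the receptor file used for frame construction.

The TCR pseudo-two-fold axis is the rotation axis of the transform
superposing the Vα framework Cα trace onto Vβ (framework = variable-domain
residues minus CDR selections; the traces are truncated to a common length,
exact for the symmetric toys, an approximation for real domains that a
manifest-supplied pairing can replace). Its sign points toward the CDR
loops — the face that engages the platform.

`place_start` composes, in this order: (1) orient the TCR axis anti-parallel
to the groove normal and the Vα→Vβ inter-domain direction (projected on the
helix plane) at the crossing angle from the groove axis —
counter-clockwise positive viewed down the normal, which makes +45° the
canonical diagonal pose; (2) translate the variable-domain Cα centroid to
`origin + height·normal + shift·groove_axis`; (3) tilt about the third axis
through the TCR centroid, positive toward the groove-axis C-terminus. The
composition order matters and is therefore fixed and documented;
`measure_start_pose` inverts it exactly (tilt read from the axis deflection
in the normal/groove plane, then un-tilted before reading the crossing
angle), so the spec → pose → measured-spec loop closes to machine precision
(tested at 0.1 Å / 0.5°). The "25 Å distance" of the standard sites is
interpreted as the variable-domain centroid height above the helix centroid
along the normal; the crossing-angle convention uses domain centroids, not
the inter-chain disulfide. If reproduction of published start-pose RMSDs on
real cases disagrees systematically, the disulfide-anchored convention is
the first alternative to try — both conventions differ only in the in-plane
reference vector.

## CAPRI assessment

Native contacts are residue pairs (TCR side × receptor side, antigen
included on the receptor side) with any heavy-atom distance < 5 Å in the
bound reference. fnat is the fraction of those pairs preserved (< 5 Å) in
the model, via the alignment correspondence. Ligand RMSD superposes the
receptor protein backbone and measures TCR backbone deviation; interface
RMSD is backbone RMSD over the bound-defined interface residues (any protein
residue with a heavy atom within 10 Å of the other partner, antigen atoms
included in the measurement but antigen residues never contributing RMSD
atoms), fit on the interface itself. The interface set is computed once from
the bound reference and reused for every model. Classification: high if
fnat ≥ 0.5 and (L-RMSD ≤ 1 or I-RMSD ≤ 1); medium if fnat ≥ 0.3 and
(L-RMSD ≤ 5 or I-RMSD ≤ 2); acceptable if fnat ≥ 0.1 and (L-RMSD ≤ 10 or
I-RMSD ≤ 4); else incorrect. Hits = medium or high. All thresholds live in
`CapriThresholds` should a different criteria revision be needed.

Case reports rank models ascending by score with ties broken by model id
(recorded because the first-hit rank depends on it) and report hit counts,
first-hit and first-acceptable ranks (absent ranks print as `--`), the
lowest interface RMSD in the top min(20, n) models, and per-model funnel
rows. Pooling merges several start sites' reports into one joint ranking,
each model keeping its metrics and start-site provenance; mixed bound
references are rejected. A chain subset (e.g. TCR α chain + receptor only)
restricts assessment when bound and unbound β chains differ in sequence.

## Weight retraining

The training signal is the mean, over decoy cases, of the hit/non-hit ROC
AUC among each case's top-30 ranked models, with AUC in Mann–Whitney form:
P(random hit scores lower than random non-hit), ties 0.5, computed from
average ranks. Two top-30 selection modes exist because "top-30 ranked" is
ambiguous: `self` (default) re-selects by the candidate weights' own
ranking at every evaluation — the self-consistent reading — while
`baseline` uses a fixed prior ranking column. Cases whose selected models
are single-class have undefined AUC and are excluded from the mean (not
scored 0.5, which would reward degenerate weightings that push all hits out
of their own top-30); this is warned about loudly.

Optimization is Nelder–Mead from many random starting points drawn uniformly
in [0, 2] per weight (bracketing both shipped presets), keeping the best
restart; the reference protocol is 12,000 restarts and the default config
matches it. Non-negativity is enforced by clamping candidate vectors at zero
inside the objective — equivalent, for a ranking objective, to reflecting
simplex moves at the boundary. Because the objective is piecewise constant
(it changes only when a pair of models swaps rank order), scipy's default
initial simplex (5% coordinate perturbations) collapses prematurely; the
config therefore builds an explicit initial simplex of edge 0.5 with
xatol 1e-3, fatol 1e-6 and a 1000-evaluation cap per restart. Everything is
deterministic given the seed.

Cross-validation groups cases by TCR identity and assigns whole groups to
folds (shuffled by seed, then greedily to the smallest fold), so cases
sharing a TCR never appear in train and test of the same split; fold counts
exceeding the number of distinct TCRs are an error.

The interactive surface is a model/results pair: `WeightTraining(cases,
config).fit()` returns a results object carrying the fitted `WeightVector`,
the objective value, the per-restart trace, per-case AUCs and a `summary()`
table comparing the fit against both shipped presets.

## Model comparison

`model_distance` superposes one model's receptor platform backbone onto the
other's and measures backbone RMSD over a shared loop selection with no
further fitting — the distance captures where the loops sit over the groove.
Backbone atoms (not all heavy atoms) are used, consistent with every other
RMSD in the package. Loop residues must be sequence-identical between
models; mismatches are reported by position. The joint distance matrix over
one or two model sets feeds (a) single-linkage flat clusters cut at 4 Å —
the radius within which independently docked models of clonally related
TCRs are considered to share a binding topology — and (b) a neighbor-joining
unrooted tree serialized as newick, mirroring the APE-style analysis this
workflow is usually plotted with. Neighbor joining and single linkage were
chosen where the workflow itself does not dictate an algorithm.

## Synthetic generators

`make_toy_complex` builds, deterministically per seed: a platform of two
antiparallel idealized α-helices (1.5 Å rise, 2.3 Å radius, 100°/residue,
20 residues each by default) along x at y = ±5.5 Å on one chain, with the
first helix playing α1; an antigen of ~6 atoms with user-specified partial
charges seated just above the helix plane in the groove mouth; and a TCR of
two 12-residue rigid pseudo-domains related by an exact 180° rotation about
z, CDR residues marked at the platform-facing end. Backbone geometry is
idealized (N/C interpolated on the Cα trace, O and Cβ radial); side chains
stop at Cβ except for a single charged tip atom (NZ/OD1/OE1/NH1) on
Lys/Asp/Glu/Arg, and two charged residues are planted per helix and per
domain so every energy term is exercised. The bound complex realizes the
planted pose exactly through `place_start` itself (default: height 10 Å,
45° crossing — close enough for genuine 5 Å contacts); unbound copies add
Gaussian coordinate noise of σ Å. What the toys do **not** emulate: real
side-chain chemistry and packing, loop flexibility, realistic interface
complementarity, or meaningful absolute energies. Passing tests on them
demonstrate geometric and statistical correctness of the machinery —
invariances, round-trips, classification logic, recovery — not docking
accuracy on crystal structures.

`make_planted_decoys` draws per-model 8-term vectors i.i.d. normal (σ = 1)
and labels the 10 lowest-scoring models per case under a known weight
vector as hits, over 20 cases of 1000 models (two consecutive cases share a
TCR identity); a label-noise rate flips labels independently, and a
`baseline_score` column (true score + unit noise) supports the fixed-prior
selection mode. With labels from a pure threshold the perfect-AUC optimum
has a vanishingly narrow basin — any weight perturbation reorders models
adjacent to the threshold — so exact recovery "by construction" uses
`hit_margin > 0`, which pushes hit models down-score along the true-weight
direction and opens a clean gap. Recovery checks: mean AUC 1.0 on margin-6
noiseless decoys, and Spearman ≥ 0.9 between true and recovered score
rankings at 5% label noise with 200 restarts — the problem sizes the
acceptance script uses, chosen so the whole recovery block runs in about
two minutes on one CPU while keeping the full 20 × 1000 decoy geometry.

## Known limitations

* The ACE/IFACE pair values and protein charges are synthetic stand-ins
  (above); rankings on real complexes will differ from implementations using
  statistics-fitted tables, even though every structural and statistical
  operation is exact.
* Vα/Vβ framework pairing truncates to a common length rather than aligning
  structurally; supply an explicit pairing for unusual domain pairs.
* The antigen-based normal orientation can misfire for fully buried antigens
  (use the sheet-based rule via `mhc_other` tagging instead).
* The congruence typing rule covers C/N/O/S/P environments found in lipids
  and small metabolites; halogenated or organometallic antigens fall back to
  element defaults or stay untyped.
* `scripts/reproduce_external.py` computes the crystal-structure benchmark
  numbers but requires user-downloaded PDB files and user-verified chain
  maps; it ships unvalidated against the originals.
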