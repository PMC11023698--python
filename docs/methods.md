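# Methods

`geomsite` predicts, for every residue of a protein chain, the
probability that it binds each of ten ligand classes (DNA, RNA, peptide,
protein, ATP, HEM, Zn2+, Ca2+, Mg2+, Mn2+). This note records the model,
its assumptions, the parameters that matter, and the design choices made
where the design was genuinely open.

## Structure representation

A chain is reduced to five points per residue: the backbone N, CA, C, O
atoms and R, the arithmetic centroid of the heavy sidechain atoms,
giving a coordinate matrix X of shape (n, 5, 3) in Angstroms. Glycine
has no heavy sidechain atoms; we set R = CA so the matrix stays
rectangular. Residues missing any backbone atom are dropped with a
warning; common modified residues (MSE, SEP, PTR, ...) are mapped to
their parent amino acid; alternate locations keep the highest-occupancy
conformer (ties prefer altloc A).

The residue graph connects residues i and j whenever |CA_i - CA_j| <
15 A (strictly), in both directions, plus a self-loop at every node —
the attention update aggregates over N(i) and i itself. All distance
comparisons in the package use strict `<`.

## Geometric featurization

Each residue gets a local right-handed frame Q_i = [b_i, n_i, b_i x n_i]
where, with u = CA - N and v = C - CA, b_i is the unit negative bisector
(u - v)/|u - v| and n_i = (u x v)/|u x v|. Frames are undefined when N,
CA, C are collinear within 1e-8; such residues receive the identity
frame and a flag rather than aborting a run.

Node features (per residue): RBF-encoded distances of the 10 unordered
atom pairs among {N, CA, C, O, R}; unit directions of N, C, O, R from CA
expressed in frame i (zero vector when the atom coincides with CA);
sines and cosines of three bond angles (N-CA-C; CA_i-C_i-N_{i+1};
C_i-N_{i+1}-CA_{i+1}) and the backbone torsions phi, psi, omega. Angles
needing an absent neighbor are encoded as (sin, cos) = (0, 0), a
sentinel no real angle can produce. The bond-angle atom triples are an
interpretation — the three angles are standard backbone angles chosen to
use only the five stored points.

Edge features (per directed edge j -> i, in the receiver's frame):
RBF-encoded distances for all 25 atom pairs (A of i) x (B of j); unit
directions of j's five atoms from CA_i in frame i; and the relative
orientation quaternion q(Q_i^T Q_j), sign-canonicalized so the first
nonzero component is non-negative. Self-loop edges need no special
casing: distances are intra-residue, the CA direction is the zero
vector, and the orientation is the identity quaternion.

RBF encoding uses 16 Gaussian bases with centers evenly spaced on
[0, 20] A and width equal to the center spacing — wide enough to cover
the 15 A graph radius with overlap. Feature ordering (atom order N, CA,
C, O, R; pair order lexicographic) is frozen and versioned
(`FEATURE_VERSION`); checkpoints refuse to load across versions.

Every feature is a distance, a frame-relative direction component, or an
angle function, so the full set is invariant under rotation and
translation but *not* under reflection: mirroring a structure flips
torsion signs and orientation quaternions (asserted in the tests).

## Residue features

Non-geometric residue features are a pluggable per-residue embedding
(any provider returning an (n, dim) matrix; the self-contained default
is a 20-dim one-hot; a file-backed and an external-command provider
exist for precomputed language-model embeddings), plus structural
properties: relative solvent accessibility (RSA) and an 8-state
secondary-structure one-hot. Embedding blocks are min-max normalized to
[0, 1] per dimension with statistics fitted on training folds only;
values outside the training range are clipped, and constant features map
to 0. Bounded blocks (RBF, sin/cos, one-hot, RSA) are not re-normalized.

Structural properties come from a DSSP output file when available.
Otherwise a geometric fallback estimates ASA by Shrake-Rupley sphere
sampling (960 points by default, probe 1.4 A) over the five pseudo-atoms
with radii N 1.55, CA/C 1.70, O 1.52, R 2.00 A, normalizes by
theoretical max-ASA per amino acid (capped at 1), and assigns H/E/C from
phi/psi basins. The fallback is coarse: RSA from five points
underestimates bulky sidechains, and only three of the eight secondary
structure states are populated. Training pipelines use 240 sample points
for speed; the difference from 960 points is well below the labeling
signal.

## Network

Initial node and edge features are projected to d dimensions by 2-layer
MLPs. Each of the L layers then applies:

1. **Edge-enhanced multi-head attention.** For edge j -> i and each of H
   heads (d split into H subspaces), the logit is
   q_i . (k_j + W_E e_ji) / sqrt(d/H), softmax-normalized over incoming
   edges (self-loop included); the message is alpha_ji (v_j + W_E e_ji).
   Heads are concatenated, passed through an output projection, and
   added residually to h_i. The multi-head composition (per-head slices,
   concatenation, output projection) is standard transformer practice;
   the underlying update is written single-head.
2. **Edge update.** e_ji <- e_ji + EdgeMLP(h_j || e_ji || h_i), with the
   concatenation ordered (source, edge, target).
3. **Global context gating.** c = mean of the protein's node states;
   h_i <- h_i * sigmoid(GateMLP(c)). Batches of several proteins keep
   per-protein partitions, so context never mixes proteins.

Layer normalization is applied after the attention residual and after
the edge residual (configurable; unstated in the source architecture but
needed for stable training), and dropout (default 0.2) acts on attention
weights and MLP hidden layers during training only. The single smooth
nonlinearity throughout is ELU. Ligand-specific heads are 2-layer MLPs
(d -> d/2 -> 1); sigmoid is applied downstream. Defaults: d = 128, L =
4, H = 4, T = 10 tasks.

No autodiff framework is a dependency: the package carries a small
reverse-mode tape over numpy arrays (`geomsite.autodiff`) providing
exactly the operations the architecture needs; all gradients are
verified against central finite differences in the test suite, and the
sparse message-passing forward pass is verified against a literal
dense per-node reference implementation.

## Training

Multi-task masking: each protein carries labels only for its annotated
ligand tasks; the loss is mean binary cross-entropy over unmasked
(residue, task) cells, so masked tasks contribute exactly zero to the
value and to every gradient — a protein annotated only for DNA never
moves the ATP head.

Epochs draw proteins uniformly with replacement (25,000 draws per epoch
at production scale, batches of 16 protein graphs), optimized with Adam
under a one-cycle schedule (linear warmup over the first 30% of steps
from lr_max/25 to lr_max = 1e-3, cosine decay to lr_max/1e4; weight
decay 0). Training runs at most 25 epochs with early stopping on mean
validation AUPR across tasks (AUPR is the model-selection metric
throughout). Cross-validation splits proteins (never residues) into five
folds stratified by task-annotation pattern; the ensemble prediction is
the arithmetic mean of the five models' sigmoid outputs. Per-task
decision thresholds maximize MCC over the midpoints of adjacent sorted
unique scores on pooled out-of-fold predictions (ties resolve to the
lowest threshold). Desk-scale experiments use a scaled schedule
(640 draws per epoch, at most 6-8 epochs, hidden sizes 16-32) chosen so
a full experiment runs in minutes on one CPU.

## Evaluation

AUC is the Mann-Whitney probability that a positive outranks a negative
(ties one half); AUPR is average precision with step interpolation and
grouped ties (not trapezoidal — the choice is documented because either
is defensible). Thresholded metrics binarize by score >= threshold; with
zero predicted positives, precision and F1 are reported as 0 with a
degeneracy flag, and MCC is 0 whenever a marginal count vanishes.
Protein-level binding scores average the top-k residue probabilities,
k = 5 for metal ions and 10 for other ligands (all residues when n < k).
Surface residues are those with RSA strictly above 5%.

Binding labels from complexes follow the van-der-Waals contact rule: a
residue binds if some heavy-atom pair (residue atom, ligand atom) is
closer than the sum of the two vdW radii plus 0.5 A. The radius table is
Bondi-style (C 1.70, N 1.55, O 1.52, S 1.80, P 1.80, plus common metals
and halogens); no authoritative table is attached to the rule's source,
so the table is a documented choice. Unknown elements either raise (strict
mode) or fall back to 1.7 A with a warning; hydrogens are ignored.

## Synthetic data

The generator builds backbones by sequential natural-extension placement
with ideal bond lengths (N-CA 1.458, CA-C 1.525, C-N 1.329 A) and
fold-specific torsions: helix (-57, -47), strand (-139, 135), random
coil, or mixed chains alternating helix runs (6-14 residues) and strand
runs (4-10). O sits in the peptide plane anti to the next amide
nitrogen; R lies along the pseudo-C-beta direction at 1.5-2.5 A from CA.
Gaussian jitter (default sigma 0.05 A) emulates coordinate noise.

Binding sites are planted as featureless probe pseudo-atoms offset
6.5 A outward from the sidechain centroids of *anchor* residues, with
0.5 A seeded jitter; a residue is labeled positive when any of its five
points lies within the rule radius (default 8 A) of a probe. Anchors are
chosen by deterministic predicates on the backbone conformation —
strand-interior, helix-boundary, and helix-interior residues for tasks
0, 1, 2 (mod 3) — so labels are a function of geometry that a
structure-aware model can learn but a sequence-only model cannot:
sequences are drawn independently of the fold. Planting guarantees at
least one positive and one negative per annotated (protein, task) by
re-jittering, and fails loudly when the radius makes mixed labels
impossible. Task masks are Bernoulli per (protein, task) with density
0.7, redrawn so every protein keeps at least one annotated task.

Default study conditions: 200 proteins of 30-100 residues, mixed fold,
3 tasks. Under these conditions a toy model (2 layers, d = 32, one-hot
embeddings) reaches held-out AUPR ~0.95 in a few CPU-minutes, a
pooled-permutation control sits at prevalence, and a windowed one-hot
logistic-regression baseline sits ~0.45 AUPR lower.

What the generator does not emulate: real sidechain chemistry and
rotamers, tertiary packing beyond what the torsion walk produces, ligand
chemistry (probes are featureless points), label noise from crystal
artifacts, and sequence-structure correlation. Passing these tests
therefore demonstrates that the geometric pathway works end to end, not
that benchmark-level accuracy transfers to real proteins.

### Multi-task benefit at desk scale

With tasks whose geometric predicates are *distinct*, single-task
training on even two proteins already masters the easy local predicates,
and multi-task training shows no advantage at this scale. The benefit
direction reproduces robustly (9-10/10 seeded repetitions) when two
tasks probe the same geometric binding concept with independent probe
jitter and one task is annotated on only two proteins — the analogue of
a scarce ligand class sharing binding geometry with a well-annotated
one. The directional test is operationalized that way; this is a known
limitation of the synthetic conditions, not of the training code.

## Numerical choices

- Degenerate frames: epsilon 1e-8 on |u x v|; identity frame + flag.
- Zero-length directions return the zero vector, never NaN.
- Quaternion sign: first nonzero component non-negative; 180-degree
  rotations (w = 0) are exercised explicitly in tests.
- Softmax is stabilized by subtracting per-segment maxima.
- BCE uses the log1p(exp(-|z|)) form; logits are clipped at +-500 inside
  the sigmoid only.
- All randomness flows from explicit integer seeds (generator, model
  initialization, dropout, samplers); two runs with the same seed
  produce byte-identical metrics files.

## Known limitations

- The geometric RSA/SS fallback is a coarse stand-in for DSSP output;
  use real DSSP files when available.
- The one-hot default embedding carries no evolutionary information; the
  provider interface accepts precomputed language-model embeddings, but
  none ships with the package.
- Training is CPU-bound numpy; production-scale datasets (thousands of
  proteins, d = 128, 25k draws per epoch) are out of reach without a GPU
  framework behind the same interfaces.
- Hydrogens never participate in the binding-distance rule.
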