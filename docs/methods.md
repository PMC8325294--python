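# Methods

## Model

The package predicts the solvation free energy ΔG°_sol (kcal/mol) of a
solvent–solute pair as a sum of pairwise atomistic interaction terms.  Each
molecule is reduced to its heavy-atom graph; hydrogens remain implicit.
Atom α of the solvent and atom β of the solute are embedded as D-vectors
(x_α, y_β) from a token lookup table, encoded into feature vectors
(p_α, q_β) of width N by an encoder network, and combined through
unnormalized dot-product attention:

    I[α, β] = − p_α · q_β
    ΔG°_sol = Σ_α Σ_β I[α, β]

Column sums of the interaction map are per-solute-atom group contributions
I_β; row sums are the solvent-side mirror.  Equivalently, with molecular
feature vectors u = Σ_α p_α and v = Σ_β q_β, the energy is ΔG = −u·v.

**Sign convention.**  The per-pair terms carry the minus sign and the
feature-vector route is −u·v, so all four routes to the energy (grand sum,
column sums, row sums, feature dot product) agree identically.  The global
sign is absorbable into the learned encoder weights, so training is
indifferent to it; internal consistency is what the conservation tests
check (tolerance 1e-10 on float64).

**Assumptions.**  The decomposition is a learned regression structure, not
a physical energy decomposition: per-pair entries are in kcal/mol only in
the sense that their sum is supervised against kcal/mol targets.
Contributions are meaningful to the extent that the encoder respects
molecular symmetry — which is why the graph encoder, not the sequence
encoder, is the default (see below).

## Tokens and embeddings

Atom tokens are Morgan (circular-substructure) identifiers at radius 1 in
the canonical atom order of the RDKit SMILES canonicalization; an isolated
heavy atom (e.g. the oxygen of water) falls back to its radius-0
identifier.  When both the radius-1 and radius-0 identifiers of an atom are
present in the table, their vectors are summed, following Mol2Vec practice
while keeping one vector per atom.  Canonical ordering is pinned because
recurrent-encoder outputs depend on atom order.

Unknown tokens share a single `unk` vector (trainable when the table is
trainable).  This matters in practice: water's oxygen identifier never
occurs among alcohol hydroxyl oxygens, so a model trained without water
must degrade gracefully rather than fail.

Defaults: D = 128 to match common pretrained tables; randomly initialized
tables are trainable, loaded tables frozen (both overridable).  A toy
skip-gram trainer (NumPy, negative sampling, single-threaded) is provided
for small corpora; production-scale pretraining is expected to arrive as a
word2vec-format text file.

## Encoders

Both encoders map M×D to M×N preserving rows, and both end with a
trainable weighted sum over stacked layer outputs, P = Σ_i c_i H^(i),
including the (projected) input as level 0.  The c_i are unconstrained
scalars initialized to 1/(L+1); when D ≠ N a learned linear projection
bridges the input to width N.  Solvent and solute encoders are independent
instances by default (weight sharing is available but the two roles are
asymmetric).

**GCN.**  Skip-connected graph convolution

    GCN(H, A) = tanh(D^{-1/2} A D^{-1/2} H W1 + H W2 + b)

with binary adjacency A and degree matrix D.  Atoms of degree 0 get a zero
normalized-adjacency row (avoiding 0^{-1/2}), so single-atom molecules are
well defined: their output reduces to tanh(H W2 + b).  The GCN is
permutation-equivariant, hence atoms in the same automorphism orbit with
equal tokens receive equal feature rows — benzene's six contributions are
equal and n-hexane's contribution vector is reversal-symmetric, by
construction rather than by training.

**BiLM.**  Stacked forward and backward recurrences (vanilla RNN, GRU or
LSTM cells; unshared per direction) over the canonical atom sequence, with
the embedded sequence feeding both directions at level 0 and the two
directions summed per level.  The BiLM sees no bonding information, so it
does not respect ring symmetry: benzene's contributions come out unequal.
The test suite asserts this asymmetry as an expected property of the
architecture, making the case for graph encoders in group-contribution
work.

Default width N = 128 with 3 stacked layers for real data; the synthetic
benchmarks use smaller widths (16–32) that are ample for the latent
dimension of the generator and keep runs at minute scale on one CPU.

## Training

Mean-squared-error loss plus an optional L2 penalty λ Σ w² over all
trainable parameters (a frozen embedding table is excluded because it is
not a parameter).  Optimization is RMSprop,

    G_t = ρ G_{t−1} + (1 − ρ) (∇L)²,   w_t = w_{t−1} − η ∇L / sqrt(G_t + ε)

with defaults η = 0.01, ρ = 0.9, ε = 1e-8.  The update is a descent step.
An optional multiplicative per-epoch decay of η is available: RMSprop's
normalized steps oscillate with amplitude ~η once the loss is near a
minimum, so tight interpolation (e.g. memorizing a single record) requires
annealing.  Early stopping on validation MUE is available but off by
default.

Variable-size molecules are batched by zero-row padding with masks applied
to the encoder output before the molecular sums, so padded pairs contribute
exactly zero and batched predictions equal unbatched ones to machine
precision (asserted in tests).  For the BiLM, each sequence is reversed
individually before the backward recurrence, so real positions never see
padding.  Everything runs single-threaded on float64; a fixed seed gives
bit-identical loss traces.

The networks and their gradients are implemented on a compact reverse-mode
automatic-differentiation core written on NumPy; gradients of both encoder
families are verified against central finite differences (relative error
< 1e-6 in tests).

## Cross-validation

`nested_cv` runs an inner hyperparameter-selection loop (mean validation
MUE over inner folds; ties broken by smaller parameter count, then
candidate order) inside every outer fold, retrains the winner on the full
outer-training split, and evaluates on the untouched outer test fold.
Disjointness and coverage of every split are asserted structurally at run
time.  Repeats re-randomize both fold membership and weight initialization
from `base_seed + r`; aggregates report per-fold means and pooled residual
MUE per repeat (both conventions, since averaging order is a real choice).
The hyperparameter search is a declared candidate list (seeded random or
exhaustive), which keeps the protocol deterministic and verifiable.  Inner
folds are plain random splits even when the outer split is scaffold-based:
clustering the small outer-training subsets again would often leave
clusters too small to train on.

Scaffold splits cluster the distinct compounds on one side (solvent or
solute) by K-means (k-means++, Euclidean metric on raw 0/1 MACCS bits, 10
restarts, seeded) over their 166-bit MACCS fingerprints; every record
follows its compound, so no compound straddles folds and test folds contain
unseen chemotypes.

## Synthetic data generator

The generator defines the study conditions for all learnability and
protocol tests.  Each latent atom type t has a solvent-role vector φ_t and
a solute-role vector ψ_t (drawn once per spec seed, N(0, 1/√latent_dim)
entries, latent_dim = 8, 6 types); the noiseless energy of a pair is
Σ_αβ −φ_{t(α)}·ψ_{t(β)}, optionally plus Gaussian noise.  Molecules are
connected paths, cycles or random trees of 1–9 heavy atoms with i.i.d.
uniform types.  Per-pair terms land around 0.1–0.5 kcal/mol and record
energies have SD ≈ 2 kcal/mol, comparable to small-molecule solvation
scales.

This process is *exactly* representable by the model class (a perfect
encoder maps each type to φ/ψ), which is the generator's purpose: a
sufficiently wide GCN must drive noiseless error toward zero, and the
stored true per-solute-atom contributions (column sums of the planted
pairwise terms) ground the contribution-recovery test.  In `hard_mode`,
effective latents are shifted by the mean of a second per-type table over
bonded neighbours, so truth depends on the environment and
composition-only models cannot represent it.  `smiles_mode` maps types to
a fixed element alphabet under valence constraints and emits real SMILES,
exercising the full RDKit pipeline; there the Morgan tokens are finer than
the latent types, so exact representability is deliberately given up.

What the generator does **not** emulate: experimental noise structure,
chemically realistic thermodynamics, tautomers/stereochemistry, the
long-tailed size distribution of real databases, or correlations between
solvent identity and measurement availability.  Passing the recovery tests
therefore shows the estimator and protocol are sound, not that real-data
accuracies are reproduced.

## Benchmark problem sizes

The parameter-recovery benchmark trains on 2000 noiseless records (400
held out) with a width-32, depth-2 GCN, embedding dim 16, 300 epochs of
RMSprop at η = 0.01, batch 64 — about a minute per seed on one CPU; three
training seeds are run and at least two must reach held-out MUE < 10% of
the target SD with contribution Pearson r > 0.9.  The planted-
hyperparameter experiment uses 200 records, 5 outer × 3 inner folds and a
two-candidate space (working width 16 vs. crippled width 1).  The
scaffold-gap experiment uses two 150-record chemotype families (C/O
solutes vs. C/N solutes sharing one ground truth) and compares 2-fold
scaffold-solute CV against 2-fold random CV; the gap is directional, with
no fixed margin.

## Visualization export

`embed-viz` computes, per molecule, the encoded molecular feature vector v
and the pre-encoder embedding sum Σ_β y_β, projects each set to 2-D with
seeded t-SNE (perplexity 30 clipped to (n−1)/3, 1000 iterations, PCA
init), and attaches predicted ΔG.  The class-separation test compares the
two projections by *normalized* inter-class separation (centroid distance
divided by mean within-class distance) because absolute t-SNE coordinates
carry no comparable scale across two independent embeddings.

## Numerical choices and degenerate inputs

- Tolerances: algebraic identities 1e-10; symmetry/equivariance properties
  1e-6 (accumulated float error over deep encoders); optimizer limit 1e-3
  after 500 steps.
- Checkpoints round-trip bit-exactly (`.npz` with exact float64 arrays).
- A dataset row with an unparseable SMILES is dropped with a logged
  warning and counted, not fatal; an empty dataset or missing column is.
- Duplicate (solvent, solute) pairs are kept by default; `deduplicate`
  drops exact duplicates keeping the first.
- `contrib` output uses canonical 0-based atom indices with element
  symbols, which is reproducible where picture-based indexing is not.
- Fold sizes from random splits differ by at most one; scaffold fold sizes
  follow the clusters.

## Known limitations

- CPU-only, float64, no GPU kernels; practical for datasets up to a few
  thousand records at the default widths.
- The BiLM is trained per-batch over padded sequences; very long molecules
  (tens of atoms) make it noticeably slower than the GCN.
- Pretraining at database scale is out of scope; the package consumes
  externally produced embedding tables instead.
- Group contributions inherit the caveat above: they are learned chemical
  similarity scores, not measured energies.
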