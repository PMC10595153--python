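# Methods

## Problem and model

`fragsol` predicts aqueous solubility — logS, the base-10 logarithm of a
compound's molar solubility in water — from a SMILES string. The model is a
fragment-pair graph-attention network: instead of embedding the whole
molecular graph once, every acyclic single bond is broken in turn, each
break producing a pair of connected fragments, and the molecule's
representation is the average over all pairs of the fused pair embeddings.

For a molecule G with m acyclic single (non-ring, non-aromatic) bonds:

1. **Fragmentation.** Deleting breakable bond i yields connected components
   (G¹ᵢ, G²ᵢ). Fragments inherit the parent's atom and bond feature vectors
   unchanged — no hydrogen caps or dummy atoms are added, so the split is
   purely graph-topological. A single heavy atom is a legal fragment.
2. **Atom featurization.** Heavy atoms carry 40-d vectors: element one-hot
   over the 15-symbol vocabulary [B, C, N, O, F, Si, P, S, Cl, As, Se, Br,
   Te, I, At], heavy-atom degree one-hot (8 slots, degrees 0–7), formal
   charge and radical-electron scalars, hybridization one-hot (sp, sp², sp³,
   sp³d, sp³d², other), aromaticity flag, attached-hydrogen one-hot (0–4),
   chiral-centre flag, and an R/S one-hot that is all-zero for achiral
   atoms. Bonds carry 10-d vectors: type one-hot (single/double/triple/
   aromatic), conjugation flag, ring flag, stereo one-hot (Z/none/E/any).
   Elements outside the vocabulary, degrees above 7 and hydrogen counts
   above 4 raise errors rather than truncating.
3. **Atom embedding stack** (depth l, default 3). Initial target states are
   a linear projection of the 40-d atom features to width F; in the first
   layer each neighbor message instead projects the 50-d concatenation of
   the neighbor's atom features with the connecting bond's features, which
   is the only place bond features enter. Each layer scores every directed
   edge (t ← i) as ε = leakyrelu(s·[W aₜ, W aᵢ]) with a per-layer
   projection W: F→F and scoring vector s ∈ R²ᶠ, normalizes ε by softmax
   over each target's neighborhood, forms the context
   Cₜ = elu(Σᵢ αₜᵢ W aᵢ) — the same W carries score and message — and
   updates the state with a per-layer GRU cell, aₜˡ = GRU(aₜˡ⁻¹, Cₜˡ).
   Atoms with no neighbors receive a zero context so the GRU still runs.
4. **Supernode readout** (depth T, default 2). A virtual supernode connected
   to every atom of the fragment is initialized to the mean final atom
   state; T further attention+GRU steps update the supernode alone (atom
   rows stay fixed) and its final state is the fragment embedding y.
5. **Fusion and averaging.** Pair embedding ŷᵢ = y¹ᵢ + y²ᵢ (elementwise);
   molecule embedding ŷ = (1/m) Σᵢ ŷᵢ; prediction = wᵀŷ + b, a single
   affine head with no output activation.

One parameter set is shared by both fragments of every pair and across all
pairs (a siamese design), so the parameter count is independent of molecule
size and of m, and fragment order cannot affect the prediction.

Molecules with m = 0 (single atoms, pure ring systems such as benzene) are
embedded by the identical network applied once to the whole molecule. The
same whole-molecule path is exposed as the **null-fragment** mode, used as
the ablation baseline that quantifies what fragment pairing adds.

## Training

Batch-mean MSE is minimized with Adam. Defaults: 300 epochs, batch size
256, learning rate 2.5e-3, weight decay 5e-3 (L2 added to the raw
gradient), dropout 0.002 on attention weights and GRU inputs (training
mode only), early stopping on validation RMSE with patience 40 — training
halts once the monitored metric has not improved for 40 consecutive
epochs, and the returned parameters are those of the best-validation
epoch, not the last. No learning-rate schedule is used. The last short
batch of an epoch is kept.

Splitting is either a seeded random shuffle with floor-sized validation and
test partitions (remainder to train) or a deterministic Bemis–Murcko
scaffold split: molecules are grouped by scaffold, the acyclic
(empty-scaffold) group is assigned to train first, and remaining groups are
placed largest-first into whichever partition is furthest below its target
ratio (ties resolved train > val > test), so no scaffold ever straddles
partitions.

Metrics are MAE = (1/n) Σ|ŷᵢ − yᵢ| and RMSE = sqrt((1/n) Σ(ŷᵢ − yᵢ)²);
RMSE ≥ MAE always, with equality only when all absolute errors are equal.

## Numerical implementation

The network, its gradients and Adam are implemented directly on NumPy with
a small reverse-mode autodiff engine (`fragsol._autodiff`). Per-target
attention softmax is computed with segment operations (per-segment max
subtracted as a constant for stability; softmax is shift-invariant so
gradients are exact), and whole minibatches of fragments are flattened
into one disjoint-union graph so every layer is a handful of dense matrix
operations. Gradients of every primitive and of the end-to-end loss are
verified against central finite differences in the test suite.
Computation defaults to float32; float64 is available (and used by the
gradient-check tests). Evaluation-mode forward passes are deterministic;
training is bitwise-reproducible under a fixed seed in this single-threaded
implementation.

Parameters are initialized with uniform Glorot fan-based scaling from the
run seed; biases start at zero. Checkpoints are single JSON files carrying
the parameters, the model configuration and a digest of the featurization
scheme; loading refuses a checkpoint whose digest does not match.

## Design choices where the architecture was open

- The attention score's bilinear form is realized in the standard
  graph-attention way — per-layer W applied to both states, concatenated,
  reduced by a learned vector, then leakyrelu (slope 0.01) — which also
  makes "the same W inside the score and the message" dimensionally exact.
- The fragment readout is the supernode's state after the T
  molecule-level attention+GRU steps, not a direct pooling of atom states:
  the supernode graphs exist precisely to be processed by those layers.
- The affine head is applied after pair averaging; for an affine map this
  equals averaging per-pair heads, so the order is benign.
- All m pairs are enumerated deterministically (bond-index order) and
  averaged; sampling a random single cut would make evaluation stochastic
  and the mean over pairs requires all of them anyway.
- Degree gets 8 one-hot slots (degrees 0–7) even though only 0–5 occur in
  common organic molecules; higher degrees error out.
- Hidden width F defaults to 128 and is freely configurable; F is not
  fixed by the architecture. The test suite and the acceptance script run
  at F = 32 (and smaller in unit tests), which this package treats as its
  reference desk-scale configuration: on the synthetic benchmark the
  recovery results at F = 32 and F = 64 are indistinguishable (held-out
  MAE 0.232 vs 0.224 on one probe) while training is several times faster.

## Synthetic data: what it does and does not show

The generator emits random chains of 1–`max_chain` heavy atoms over
{C, N, O} (always starting on carbon, at most 4 heteroatoms per molecule,
15% carbonyl decoration) with probability `ring_prob` of one terminal
benzene ring, and labels them with an exactly linear law:

    logS = 0.5 − 0.45·(#C) + 0.8·(#N + #O) − 1.2·(#aromatic rings) + N(0, σ)

The coefficients mirror the qualitative hydrophobicity trend of real
aqueous-solubility data (carbons and rings depress solubility, polar
heteroatoms raise it) and are sized so the noiseless label range stays
inside [−11.6, 6.04] — the span of the standard experimental benchmark —
for all chains up to 12 heavy atoms (worst cases: 18 carbons plus a ring
→ −8.8; four heteroatoms and one carbon → +3.25). Defaults: 400 molecules,
σ = 0.1, max_chain 8, ring_prob 0.3. Duplicate SMILES are allowed by
construction (cleaning is part of what the fixture exercises), so a
400-draw dataset contains roughly 230–260 unique structures.

Every feature the law depends on is visible to the network through the
atom/bond encodings, so the benchmark tests whether the architecture and
optimizer can recover a known structure–property law through the full
fragmentation/attention/readout path under label noise. Passing it shows
the pipeline learns what it should be able to learn; it does not show
performance on real solubility data, whose label law is not linear, whose
chemistry is far more diverse (stereochemistry, charged species, fused
rings, the full element vocabulary), and whose measurement noise is not
Gaussian or homoscedastic.

## Degenerate inputs and tie-breaks

- Empty neighbor sets: zero context vector (an empty softmax is undefined).
- m = 0 molecules: whole-molecule path, identical parameters.
- Cleaning never raises: missing structures/labels are dropped, duplicates
  are detected by canonical-structure equality (first occurrence kept),
  and unparseable strings are deduplicated by raw text and left for the
  featurizer to reject with a named error.
- Scaffold-split ties go train > val > test; split-size rounding floors
  validation and test and gives the remainder to train.

## Known limitations

- No 3D/conformer information, tautomer or protonation handling, or salt
  splitting; multi-fragment SMILES outside the element vocabulary are
  rejected rather than partially encoded.
- The NumPy implementation is single-threaded; it is sized for datasets of
  order 10³–10⁴ molecules, not 10⁶.
- Training on a real benchmark (e.g. the 1,128-compound Delaney set) is
  supported through the same CSV interface but is not part of the offline
  test suite, which is intentionally download-free.
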