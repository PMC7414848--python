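# Methods

This note documents the models, conventions and numerical choices behind
`distnet`, in the spirit of a methods appendix: what is computed, under
which assumptions, and where the genuinely open design choices were decided.

## Labels: Cβ distance maps

A target's label is the *L* × *L* matrix of pairwise Euclidean distances
between Cβ atoms, computed from the chain's coordinates after cleaning:
residues with non-standard amino-acid names (e.g. selenomethionine) are
dropped, and the remaining residues are renumbered against the reference
FASTA sequence — first by exact substring match, otherwise by a global
alignment with match +1 / mismatch −1 / gap −2, keeping only identically
matched columns.  Positions absent from the structure carry `valid = False`
and the pair mask (`valid[i] AND valid[j]`) excludes them from every loss
and metric; unobserved pairs are never imputed.

Conventions the source data do not fix, decided here:

* **Glycine** has no Cβ; its Cα is the standard surrogate.  Any other
  residue missing a Cβ also falls back to Cα, with a warning, rather than
  being discarded.
* Indices are 0-based internally; all emitted artefacts (restraints,
  contact lists) are 1-based, following PDB convention.
* Altloc handling is "first wins" (Biopython's default disorder
  resolution); multi-model NMR files and mmCIF are out of scope.

## Reciprocated labels and the regression loss

Real-valued distance regression uses the reciprocal log-cosh loss

    Loss = log(cosh(K/(P+e) − K/(T+e))),  K = 100,  e = 1e-6,

whose gradient magnitude at fixed absolute error grows as the true distance
shrinks: the optimiser is pushed to fix short (structurally decisive)
distances first.  Training uses the equivalent label-space form: label
matrices are reciprocated once (`K/(T+e)`, after replacing the zero diagonal
with the mean of its in-bounds horizontal/vertical neighbours so `1/d` is
defined) and a plain log-cosh is applied to the difference.  Both forms
vanish exactly at P = T and share minimisers; the acceptance suite verifies
this by running Adam descent on random 10 × 10 problems from a common
initialisation and checking the two solutions agree to 1e-3.

Reduction is the **mean** over masked cells (not the sum), so crop size does
not rescale the effective learning rate.  Probabilities in the
cross-entropy losses are clipped to [1e-7, 1 − 1e-7] before logarithms; for
the binned loss the unclipped softmax cross-entropy gradient is used even
when the clip is active.  ``log(cosh(x))`` is evaluated as
``|x| + log1p(e^{−2|x|}) − log 2`` to avoid overflow at the large arguments
reciprocation can produce.

## Distance bins

Bin edges start at 4 Å and advance in 0.2 Å steps to 8 Å, then each
successive width grows by 0.2 Å (0.4, 0.6, …) until the 26 Å edge, followed
by an open 26+ bin — 33 bins in total (derived from the rule, not asserted
externally).  Intervals are half-open [lower, upper): a distance of exactly
8.0 Å belongs to the bin starting at 8.0 and is *not* a contact.  Distances
below 4 Å merge into the first bin.  Decoding takes the argmax bin's
midpoint; the open terminal bin decodes to 27.3 Å (26.0 plus half of the
2.6 Å width continued past the last edge), configurable via
`BinScheme.terminal_value`.  Contact probabilities are the summed mass of
bins whose upper edge is ≤ 8 Å.

## Input features

Seven features, 55 channels.  2D channels come first (CCMpred-style,
FreeContact-style, contact potential — parsed from whitespace-delimited
square matrices and symmetrised by averaging); each 1D feature then
contributes two L × L channels per component (row-tiled and column-tiled):
profile (21), secondary structure (3), solvent accessibility (1), Shannon
entropy (1).  The external predictors themselves are not run; their outputs
are consumed as files.  Choices made where common practice varies:

* Profiles normalise over residues only — gaps are excluded from the
  denominator; the alphabet is the 20 standard amino acids plus X.
* Entropy is a plain per-column Shannon entropy in bits (log₂), without
  sequence weighting (weighted variants exist in alignment-statistics
  tools; the potential channel is parse-only for the same reason).
* Alignment cleaning removes rows that are entirely gaps and exact
  duplicate rows (first kept, query always kept), and is idempotent.

## Architecture and training

Entry 3×3 convolution (C → F), `num_blocks` residual blocks (BN → ReLU →
3×3 conv → dropout 0.3 → ReLU → 3×3 conv, identity skip), and a 1×1 head
convolution; head activations are sigmoid (contact), per-pair softmax
(binned) and ReLU (distance).  The entry/head convolutions are standard
residual-network entry/exit layers; the production-scale configuration is
128 blocks × 64 filters, while tests and examples use 1–4 blocks and 8–16
filters of the identical architecture.  The engine is written in numpy with
explicit backpropagation (im2col convolutions, batch-norm running
statistics, inverted dropout) and an Adam optimiser (default lr 1e-3, batch
size 2); gradients are verified against central finite differences in the
test suite.

Each training visit draws a random crop: the volume and label map are
zero-padded by `pad` (default 5) on all sides, a `crop` × `crop` window
(default 128) is cut at offsets drawn uniformly and independently for the
two axes, and the padding is masked out of the loss.  If the padded frame
is smaller than the crop, it is zero-filled up to the crop.  Prediction
never crops — the network is fully convolutional — and the output is
symmetrised as (P + Pᵀ)/2 since distance maps are symmetric.  The distance
head's ReLU output lives in reciprocated space and is back-transformed to
Ångström (`d = K/r − e`, with `r` floored at K/1000 to keep the inverse
finite).

## Evaluation

Sequence-separation classes: local 0–5, short 6–11, medium 12–23, long 24+
(|i − j|).  MAE_t averages |pred − true| over masked long-range pairs whose
*true* distance is below t ∈ {8, 12} Å; an empty selection reports NaN
(not-applicable), never 0.  For precision, real-valued predictions are
ranked via P_ij = 4/D_ij (D ≥ 4; 1 otherwise) — a strictly monotone
transform, so rankings equal the raw-distance order — and the top L or top
NC long-range upper-triangle pairs are counted against the <8 Å truth.
Ties break by (i, j) lexicographic order after a stable sort, for
reproducibility.  Targets with NC = 0 are excluded from precision
aggregates, which are unweighted means over the remaining targets.  A
"medium and long" MAE variant is available through the `ranges` argument.

## Restraints

δ = 0.03·d², l = d − δ/2, u = d + δ/2; the quadratic error range mirrors the
loss's preference for short distances.  Selection defaults to
medium+long-range pairs with predicted d ≤ 12 Å (restraint utility decays
with distance), one restraint per unordered pair, sorted by d.  The lower
bound is clamped positive; for distances under ~66 Å the clamp is inactive
and u − l = 0.03·d² holds exactly.  Output is TSV and Rosetta-style
`AtomPair CB i CB j BOUNDED l u 1 0.5` lines; running a modelling protocol
is out of scope.

## Synthetic data

The generator emulates the *shape* of the real task, not its biology.
Chains are walks with steps drawn uniformly in [3.75, 3.85] Å (consecutive
Cα spacing), directional persistence (tighter for the "helix-bundle" style),
and a pull toward the origin outside a confinement radius 2.5·L^(1/3) Å
(globular scaling), which guarantees genuine long-range contacts from ~50
residues up.  Feature volumes follow the full 55-channel manifest; the
three coevolution-like channels are `signal_strength · contact + N(0,
noise_sd)` (defaults 1.0 and 0.1), the 1D channels are valid random
probabilities.  Alignments are mutated copies of the query with optional
planted duplicate rows, all-gap rows and conserved columns.  Everything is
bit-reproducible per seed.

What passing on this generator does and does not show: it validates the
pipeline — label construction, feature plumbing, optimisation, decoding and
metrics — under a planted, perfectly recoverable signal.  It says nothing
about precision on real proteins, where coevolution signals are noisy,
phylogenetically biased and only indirectly related to contacts, and where
chains have real secondary structure, self-avoidance and missing density.

The end-to-end smoke test trains the 4-block/16-filter contact model for 10
epochs on 20 synthetic chains of length 80 and requires held-out top-L
long-range precision ≥ 90%.  Length 80 matters: P_L takes the top *L*
pairs, so a target with fewer than *L* true long-range contacts caps P_L at
NC/L even for a perfect predictor; at L = 80 the generator's folds always
carry NC > L and the ceiling cannot bind.  Problem sizes throughout the
tests (crop 64, 1–4 blocks, dozens of targets) are chosen so the whole
suite runs in well under a minute of training per test on one CPU.

## Known limitations

* The numpy engine is single-threaded apart from BLAS matmuls; the
  128-block production configuration is architecturally supported but not
  practical to train here.
* No dilation schedules, ensembling, or distogram-potential construction.
* The PDB writer emits minimal single-chain files (CA/CB only) intended for
  round-trips through this package, not for general consumers.
* Chain cleaning trusts sequence identity; a chain whose observed sequence
  disagrees with the FASTA at aligned positions simply marks those
  positions unobserved.
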