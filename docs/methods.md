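# Methods

## Problem and data model

The classification unit is a fixed-length RNA *site window*: `window_length`
nucleotides (default 51, always odd) over {A,C,G,U} with the central
position an adenosine. Label 1 means the central A is methylated (m⁶A),
label 0 that it is not. Published yeast benchmarks follow exactly this
layout (balanced positive/negative sets of 51-nt windows, 25 nt of flank on
each side of the site, redundancy-reduced to <85% pairwise similarity by
the dataset authors — this package applies no similarity filter of its
own). DNA input is converted losslessly (T→U); any other character is
rejected with its position. Central-A enforcement is on by default and can
be disabled for corpora whose negative windows were not centred on A.

## Gapped k-mer patterns and mining

A gapped k-mer has exactly `k` matched positions and any number of
wildcards (`N`) strictly between them; leading/trailing wildcards are
disallowed because they do not constrain anything, so the canonical text is
a unique identity. The total span is capped at `max_span` (default `2k`),
which bounds the candidate space at Σ_s C(s−2, k−2)·4^k patterns.

Support is **per-sequence presence**: a pattern occurring five times in one
window still contributes 1. This choice keeps mining and encoding on the
same 0/1 semantics, so the design-matrix column mean over the mining corpus
equals the mined support exactly (asserted in tests).

`mine_frequent` counts only patterns actually instantiated by corpus
substrings: for every sequence, every (gap-layout, offset) pair yields one
pattern key, and per-sequence sets are tallied. A pattern never
instantiated has support 0 and cannot be frequent, so this is exactly
equivalent to enumerating all candidates and filtering by support — the
test suite asserts equality against that brute-force oracle across random
small corpora.

Decisions taken where the convention was open:

* γ is a **fraction** of the mining corpus; an absolute minimum count can
  be converted via `MiningConfig.from_absolute_count`.
* Mining scope defaults to the full training partition (both classes);
  positives-only mining is available via `corpus_scope="positives"`.
* Canonical feature order is lexicographic with A<C<G<U<N, giving every
  downstream vector a deterministic column index.
* Mining happens **inside each CV training fold only**. Mining on the full
  dataset before cross-validation would leak held-out information into
  feature selection; published headline numbers that mined globally would
  be slightly optimistic relative to this harness.

## Encoding

c(S, P) = 1 iff P occurs at ≥1 offset in S, N matching any base.
"Matches" is occurrence as a gapped substring, not whole-sequence
equality — mined patterns span ≤ 2k ≤ 10 nt and could never equal a 51-nt
window. Encoding a corpus costs O(sequences × gap-layouts × offsets),
independent of the feature count, by reusing the same layout-indexed scan
as the miner.

## Classifier

Logistic regression with intercept; mean cross-entropy cost (natural log)
with an optional ridge penalty λ/(2m)·Σ_{j≥1}θⱼ² that never touches the
intercept. Training is deterministic full-batch gradient descent from
θ = 0 using the **mean** gradient, so the step size α is invariant to
corpus size.

Step-size policy: α starts at `alpha` (default 0.1); a step that would
increase the cost halves α and is retried, and every accepted epoch grows
α by 1.1×. The realized cost sequence is therefore non-increasing, while
convergence does not stall at a conservatively small fixed step: on the
500+500 benchmark a fixed α = 0.1 was still descending at the 5,000-epoch
cap (final cost 0.0136), whereas the adaptive step converges in ≈330
epochs to a lower cost (0.0131). Stopping: cost change < `tolerance`
(default 1e-8) or `max_epochs` (default 5,000).

Defaults α = 0.1, λ = 1.0 (the liblinear-style default strength, with 0
allowed), threshold 0.5 with ties classified positive. No published values
exist for these optimizer settings, so they are surfaced in `TrainConfig`.
The gradient is verified against central finite differences (relative
error < 1e-6), and the reached optimum against an established solver with
matching regularization; the shipped path remains the from-equations
implementation. The nominally "linear regression" predictor in this
problem area is in fact logistic regression (logistic cost, LIBLINEAR
"LR"); this package implements the logistic model.

Numerics: the cost uses the stable identity −y·z + log(1+e^z) via
`logaddexp`; the sigmoid is evaluated branch-wise to avoid overflow; the
training loop maintains z = θ₀ + Xθ incrementally (two mat-vec products
per epoch) and the reported final cost is recomputed from θ directly.

## Evaluation

SN = TP/(TP+FN), SP = TN/(TN+FP), ACC = (TP+TN)/total,
MCC = (TP·TN−FP·FN)/√((TP+FN)(TN+FP)(TP+FP)(TN+FN)), all as fractions in
the API (the CLI and acceptance script print percentages). MCC is defined
as 0 when its denominator vanishes; SN/SP are NaN when their class is
absent from the evaluation set. On balanced data ACC = (SN+SP)/2 exactly.

ROC uses the universal axis convention (x = FPR, y = TPR), sweeping the
threshold over distinct scores with tied scores grouped. AUROC is computed
both as the Mann–Whitney statistic (ties ½) and as the trapezoidal area
under the ROC points; the identity is asserted on every call.

Cross-validation is stratified and seeded. Records are canonically sorted
before the seeded shuffle, so fold membership depends only on record
content and the seed — permuting the input order changes nothing.
Per-fold: mine on the training partition, encode both partitions with that
fold's feature set, fit, predict held-out. Aggregates are reported under
**both** rules — metrics of the pooled confusion counts/scores and the
mean of per-fold metrics — because benchmark tables in this area rarely
state which rule they used; no exact-match claim is made against any
published table, also because fold assignment and mining scope are
unstated there.

## Synthetic generator

`generate_corpus` emulates the benchmark layout: `n_pos` + `n_neg` windows
of i.i.d. background (default uniform over A/C/G/U) with the central base
forced to A; each positive receives, with probability `plant_rate`
(default 0.9), one instantiation of a motif (default `GGACU`, the
GAC-containing yeast consensus; wildcards in the motif are filled from the
background) at a uniformly chosen offset that cannot overwrite the central
A with a non-A character. Identical configs give byte-identical corpora.

What it does **not** emulate: positional preference of the motif around
the site (offsets are uniform), flank composition bias, correlated
neighbouring positions, sequence-similarity structure between windows, and
class overlap beyond background chance. Passing the planted-signal tests
therefore demonstrates that the pipeline recovers a known enrichment
signal end to end — not that real-data accuracy will match the synthetic
numbers.

Benchmark sizes used by the tests and the acceptance script, chosen as
standing conditions: 500+500 windows at plant rate 0.9 for the
planted-signal benchmark (k = 4, γ = 0.025, 10 folds); 60+60 windows at
k = 3, γ = 0.05 for the 20-reseed label-shuffle null, where only the
absence of signal matters and a small corpus estimates the chance-level
AUROC just as well.

## Known limitations

* Exhaustive pattern semantics only: no mismatch tolerance, no
  position-specific weighting, no count-valued features.
* Full-batch descent materializes the dense design matrix; at k = 4 the
  feature space is ~9,000 columns, fine for 10³–10⁴ windows but not for
  genome-scale corpora.
* The γ threshold is global; class-conditional or discriminative pattern
  selection is out of scope.
* SVM / random-forest baselines are not bundled; the encoder's design
  matrix can be handed directly to any scikit-learn estimator.
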