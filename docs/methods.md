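# Methods

## Problem setting

Phosphorylation is a reversible post-translational modification of
serine (S), threonine (T) and tyrosine (Y) residues.  Given a protein
sequence, the task is residue-level binary classification: for every
S/T/Y site, predict whether it is phosphorylated (P) or not (NP).
`phoskan` implements a bimodal approach: each residue is represented by
the concatenation of an amino-acid-aware embedding (1024 dimensions,
computed from the protein sequence) and a codon-aware embedding (768
dimensions, computed from the protein's verified coding DNA sequence).
The rationale is that the genetic code is degenerate — up to six
synonymous codons per amino acid — so the codon sequence can carry
information (codon-usage, translation-kinetics correlates) that the
amino-acid sequence alone does not.

## Reverse translation and CDS verification

Because codon degeneracy makes naive reverse translation ambiguous, the
coding sequence for each protein is recovered from a curated nucleotide
record rather than guessed.  CDS candidates are read from local
GenBank-format files (feature type `CDS`; `join(...)` locations are
spliced; the `/translation` qualifier is carried along when present).
Each candidate is translated under the standard genetic code and
globally aligned to the target protein with Needleman–Wunsch.  Only
pairs at exactly 100% identity are accepted; a single terminal stop
codon (TAA/TAG/TGA) is stripped, and an internal stop is a hard
rejection.  An accepted record therefore satisfies `len(cds) == 3N` and
`translate(cds) == protein` character for character.

Alignment details (the accept/reject decision is invariant to all of
them, since 100% identity coincides with exact equality):

* scoring defaults: match +1, mismatch −1, linear gap −2 (configurable);
* identity denominator = full alignment length, so gap columns count
  against identity and 100% ⟺ exact equality;
* traceback ties break diagonal > up > left, giving a deterministic
  reported alignment;
* empty-vs-empty aligns at score 0 with identity 100 by convention;
  empty-vs-nonempty has identity 0.

Records with several CDS features are resolved by accepting the first
candidate that passes the filter.  Retrieval from remote databases is
out of scope: the pipeline takes a directory of GenBank files keyed by
protein id.

## Labels, splits, balancing

Every S/T/Y residue of a verified protein yields exactly one site
record; experimentally annotated positions are P, all remaining S/T/Y
are NP.  Train/test splits are drawn at protein granularity (default
9:1) so no protein contributes sites to both sides.  Training sets are
balanced to a 1:1 class ratio by randomly undersampling the negatives
(all positives retained, sampling without replacement, seeded).
Cross-validation uses protein-grouped stratified folds: all sites of a
protein land in one fold while per-fold label proportions stay close to
the global proportion (grouped stratification is the feasible compromise
between per-site stratification and protein exclusivity, which conflict
at protein granularity; we use scikit-learn's `StratifiedGroupKFold`).

## Architecture

One sample is the window of W = 9 consecutive residues centered on a
candidate site (four flanking residues each side), as a 9 × 1792 matrix
of fused embeddings.  Sites within four residues of a terminus are
zero-padded and the padded rows flagged in a mask.  Because each row
comes from a full-sequence encoder, the window is local in position but
global in context.

* **Convolution** — 16 kernels of 5 × 5 on the single input channel,
  valid cross-correlation (no kernel flip), stride 1, ReLU; a 9 × 1792
  window yields 16 feature maps of 5 × 1788.
* **BiGRU** — the 5-row axis of the conv output is the sequence axis.
  Per step the 16 × 1788 channel/width block is flattened to one input
  vector (the only construction that uses every conv feature and
  reproduces a 5 × 16 output without an extra pooling stage; a
  width-mean-pool alternative is available behind
  `bigru_input_mode="meanpool"`).  Eight hidden units per direction;
  the per-step output is forward ∥ backward state → 5 × 16.
* **Wav-KAN head** — the 5 × 16 matrix flattens to an 80-vector.  A
  batch-normalization layer precedes each hidden Kolmogorov–Arnold
  layer; the S+T variant uses hidden layers of 128 and 32 nodes, the Y
  variant a single hidden layer of 24.  Every edge (j, i) carries a
  learnable univariate wavelet function

      y_j = Σ_i ω_ji · ψ((x_i − τ_ji) / s_ji) + (W_base x)_j + b_j

  with per-edge coefficient ω, scale s (parameterized as exp(log s) to
  stay positive, initialized at 1) and translation τ (initialized at 0),
  plus a per-layer linear base term.  A strict mode freezes s and τ,
  leaving only ω trainable per edge, for ablation.  The output unit
  produces a logit mapped to a probability by the sigmoid
  p = 1/(1 + e^(−z)); hard labels default to p ≥ 0.5.

### Mother wavelets

Five real-valued mother wavelets are registered; all are bounded,
decaying and (numerically) zero-mean:

| name | ψ(t) |
|---|---|
| DoG | t · e^(−t²/2) (first derivative of a Gaussian; maximum e^(−1/2) at t = 1) |
| Mexican Hat | (2/(√3·π^¼)) (1 − t²) e^(−t²/2) |
| Morlet | cos(5t) · e^(−t²/2) |
| Shannon | sinc(t/2) · cos(3πt/2) under a Gaussian window (σ = 6) that tempers the sinc tails |
| Meyer | sin(πt) · aux(\|t\|) with the standard quartic auxiliary polynomial ν(x) = x⁴(35 − 84x + 70x² − 20x³); the odd factor sin(πt) (rather than sin(π\|t\|)) makes the form exactly zero-mean |

The Shannon window and the odd Meyer factor are this package's choices
where common implementations vary; both are recorded here because they
slightly change values far from the origin while preserving the
wavelets' character.

## Numerical core

No GPU tensor framework is assumed: the network runs on a small
reverse-mode automatic-differentiation engine over numpy arrays written
for this package (broadcast arithmetic, matmul, elementwise
transcendentals, reductions, slicing, concatenation, an im2col-based
valid 2D cross-correlation primitive, and a numerically stable
BCE-with-logits primitive whose gradient is σ(z) − y).  Analytic
gradients are verified against central finite differences end-to-end at
1e-3 relative tolerance (and per-op at much tighter tolerance) in the
test suite.

Precision modes: "full" (the default correctness surface) stores
parameters and activations in IEEE single precision; "double" uses
float64 (used by gradient-verification work); "mixed" keeps
single-precision storage and applies a fixed loss scale (default 1024)
before backpropagation, undone at the optimizer step, the standard
guard against gradient underflow when a reduced-precision backend is in
play.  All modes are bit-deterministic given the seed.

## Training protocol

Binary cross-entropy on logits, Adam with base step 9e-4 and moment
decays 0.9/0.999, default batch size 1024.  The encoder stage is frozen
by construction (embeddings are pure functions of sequence and seed).
Early stopping monitors validation loss with patience 5 and min-delta 0
(the monitored quantity and patience are this package's defaults; they
are configurable), returning the best-validation parameter snapshot.
When no validation set is supplied, a 10% protein-grouped holdout is
carved from the training set.

**Batch-norm recalibration.**  With small batches the exponential
running average of batch-norm statistics can drift badly from the
statistics the features actually have under the current parameters,
making eval-mode inference inconsistent with the trained model (we
observed eval-mode loss spikes an order of magnitude above train-mode
loss).  After each epoch the running statistics are therefore replaced
by a cumulative average computed in a dedicated forward pass over the
training windows ("precise" batch norm).  Inference then uses these
population statistics and is invariant to batch composition.

## Synthetic data and what it shows

The toy-study generator emulates the upstream data: random proteins
(S/T frequency ≈ 12%, Y ≈ 3%; lengths 60–120), coding sequences built
by sampling synonymous codons per residue plus a terminal stop (so each
CDS verifies at 100% identity by construction), GenBank wrappers with
correct `/translation` qualifiers, and P/NP labels at roughly one
positive per five negatives before balancing — the order of magnitude
of curated phosphosite sets.

Labels are driven by a plantable signal: a two-letter motif ("WC" by
default; its letters are excluded from the background alphabet) is
written into the upstream flank (offset −4) of selected sites, and the
synthetic encoder adds a fixed offset (default +3) on designated
embedding coordinates (default the first 16 of the amino-acid track)
wherever the motif occurs.  A site is labeled P exactly when a motif
occurrence lies within its window reach.  Sites are eligible for
planting only when no other candidate site's window would overlap the
planted region, so each motif is visible in exactly one window: positive
windows carry the offset on their two flank rows, negative windows carry
none, and the designated coordinates separate the classes by
construction.  The site's own (center) row never carries the offset,
which is why a window-aware model must beat a center-row-only logistic
baseline — the parameter-recovery check.

The synthetic encoder draws each residue's base vector from a generator
seeded by a hash of (modality, residue/codon identity, position, seed).
It is deliberately free of any other sequence structure: no real
co-evolution, no attention-derived context, no correlation between the
amino-acid and codon tracks beyond their shared motif offsets.  Passing
the planted-signal benchmark therefore demonstrates that the window
framing, convolution, recurrence, wavelet head, training loop and
metrics are wired correctly and can recover a known localized signal —
it says nothing about predictive performance on real phosphosite data,
which depends on real pretrained encoders and the curated datasets.

Benchmark problem sizes are desk-scale by design: 160 proteins
(≈ 2,000 sites, ≈ 550 balanced training windows), batch 32, up to 30
epochs — chosen so a full run completes in minutes on one CPU while the
planted signal remains comfortably recoverable.  The label-shuffled
negative control runs the same pipeline with permuted labels and is
expected to score near the evaluation prevalence.

## Metrics

Threshold metrics (confusion counts, MCC, precision, recall,
specificity, F1, support-weighted F1) are computed at p ≥ 0.5 by
default.  MCC uses the standard formula with the 0-by-convention value
when a confusion row or column is empty.  AUPR is step-wise average
precision (precision summed over recall increments, not trapezoidal);
AUROC is the Mann–Whitney rank statistic.  With single-class labels the
rank metrics are reported as undefined (`None`), never as silent zeros.
The wavelet-comparison harness reports k-fold mean ± sd per metric per
wavelet plus a max-scaled table (each column divided by its maximum) for
radar-style display.

## Known limitations

* Adapters to real pretrained encoders are deliberately out of the test
  surface; the encoder contract (shape, determinism, special-token
  stripping) is the integration point.
* Homology reduction (CD-HIT-style clustering) is not implemented; the
  dataset metadata records the threshold an upstream tool applied.
* The "mixed" precision mode provides the loss-scaling contract but, on
  the numpy backend, no actual 16-bit arithmetic, hence no speed gain.
* Training the full-width model at small batch sizes is sensitive to
  initialization: on separable toy data occasional runs settle into
  noise-fitting basins, which the validation-based early stop then
  freezes.  The benchmark protocol mitigates this with the batch-norm
  recalibration above and validation-based model selection.
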