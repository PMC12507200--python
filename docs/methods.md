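# Methods

This note documents the model, the numerical choices, the synthetic data
generator, and the limits of what the test suite demonstrates.

## Problem setting

Adaptive immunosequencing of the TCRβ CDR3 region yields, per subject, a
repertoire of thousands of clonotypes with abundances.  Cancer-associated
receptors (caTCRs) are believed to share biochemical features and to occur
in correlated groups within patient repertoires.  The package frames
repertoire classification as multi-instance learning: the bag is the
repertoire, instances are CDR3 amino-acid sequences, and only the bag label
is observed.  The bag score is an affine function of the vector of
per-instance scores (slot j = abundance rank j), passed through a sigmoid;
a repertoire is called cancer-associated when the probability strictly
exceeds the decision threshold (default 0.5; equality classifies negative).

## Preprocessing

Five rules, in order: (1) drop CDR3s of length < 10 or > 24; (2) drop
sequences with characters outside the 20-letter alphabet (X, *, +, …);
(3) drop sequences that do not start with C or do not end with F (IMGT
junction convention); (4) keep the top 100 clones by frequency; (5) reject
samples with fewer than 10 surviving clones.  Two choices the rules leave
open are fixed here: sequence filters run *before* top-100 selection, so
every retained clone is valid; and frequency ties in the top-100 cut are
broken by ascending lexicographic CDR3, making the selection deterministic
(required for reproducible cross-validation).  Duplicate CDR3 rows in an
input file are merged by summing frequency at read time, since top-k must
rank distinct clonotypes.  Rejected samples are reported in an attrition
table, not silently dropped.

## Encoding

Residues are embedded with a packaged 20×15 matrix of PCA-compressed
physicochemical descriptors.  The shipped file
(`data/aa_pca_embedding_synthetic.tsv`) is a synthetic stand-in generated
in-repo (`scripts/make_embedding_matrix.py`) from classical property
scales (hydropathy, mass, volume, charge, aromaticity, secondary-structure
propensities, …), z-scored and reduced to 15 unit-variance components.  Any
embedding with distinct, physicochemically structured rows serves the
architecture; users can substitute their preferred 20×15 matrix via
`load_embedding_matrix(path)`.

Sequences are right-zero-padded to 24 rows.  Sinusoidal positional
encodings are added residue-wise (0-based positions).  With the odd model
width d = 15, sine occupies columns 0, 2, …, 14 and cosine columns
1, 3, …, 13; the final sine column has no cosine partner — the standard
index-wise extension of the sinusoid formulas.  The table is built to 100
positions (a configuration cap) though only rows 0–23 are consumed.
Padding rows also receive the positional signal; instance validity is
handled by the bag mask, not by zeroing residue rows.  Dropout (rate 0.3,
inverted scaling) is applied to the encoded input during training only.

## Network

* **Convolutional stage.**  The 15 embedding dimensions are treated as
  input channels over 24 positions.  Two blocks of conv(kernel 8, stride 1,
  no padding) → batch-norm → ReLU map 15→30→30 channels (output lengths
  17 then 10), followed by adaptive max pooling to spatial size 1.  The
  "two-layer CNN" is realized as two identical-kernel blocks; batch
  normalization flattens all instances of a mini-batch into one
  normalization batch (statistics over N×L per channel), maximizing
  statistic stability at small bag counts.  Running estimates (momentum
  0.1, unbiased variance) are used at inference.
* **Transformer stage.**  One post-norm encoder layer over the bag's
  instance tokens: multi-head scaled dot-product attention (d_model 30,
  h = 10, d_k = 3), residual + layer-norm, position-wise FFN 30→60→30
  (width 2·d_model; the reference width was unspecified) with residual +
  layer-norm.  Masked (padded) instances are excluded as attention keys via
  a −10⁹ logit offset and zeroed as outputs.  Attention operates across
  instances — the CNN feature of each instance is one token — matching the
  d_model = 30 channel count and the model's stated purpose of modeling
  interactions among TCR sequences.  No positional encoding is added across
  instance slots; slot-order information enters only through the
  aggregation weights (slots are abundance ranks).
* **Heads.**  Dropout 0.4 (training only) precedes a shared linear map
  30→1 per instance; the bag logit is `W_fᵀ s + b_f` over the score vector
  zero-filled at masked slots, with `W_f ∈ R^100`.

All conv and linear weights are Xavier-normal, N(0, 2/(fan_in + fan_out));
biases start at zero (the conv biases are subsequently absorbed by batch
norm and receive exactly-zero gradients — they are kept for architectural
fidelity).  The whole network runs in float32 by default; `ModelConfig
(dtype="float64")` is used where tests need tight numerical comparisons.

## Training and evaluation

Loss: mean BCE-with-logits, computed in the overflow-safe form
`max(z,0) − z·y + ln(1+e^{−|z|})`.  Optimizer: Adam exactly as configured
above; a unit test pins one hand-computed scalar update.  Mini-batch order,
dropout masks and initialization all derive from explicit seeds (CRC32
mixing of stage names into 31-bit integers); single-threaded runs are
bitwise reproducible.  Early stopping monitors validation loss by default
(configurable to validation AUC, or any callable); the best-epoch
parameters are restored, not the last-epoch ones.  Validation loss was
chosen over validation AUC deliberately: on the small validation sets this
protocol produces (~20 bags), AUC is a coarse, high-variance monitor that
can hit a spuriously perfect value in early epochs and freeze an immature
model, whereas the loss degrades more smoothly.  Neither monitor is immune
— the loss can also bottom out during the network's overconfidence phase
while the ranking is still improving — so held-out results on small
cohorts retain seed-to-seed variance; the evaluation protocol addresses
this by aggregating over repeats rather than trusting single runs.

Cross-validation: each of n repeats shuffles the bags, splits them into K
folds (the first |dataset| mod K folds get one extra bag), holds each fold
out in turn, splits the remainder 8:2 stratified into train/validation
(seeded per repeat and fold), trains fresh, and evaluates the held-out
fold.  Metrics are averaged over all n·K evaluations; a 95% interval is
formed from empirical 2.5/97.5 percentiles of iteration-level means.
Folds containing a single class yield an undefined AUC flag that is
excluded from the mean but counted in the report — silent zeros would
corrupt the averages.  Fresh derived seeds are used per (repeat, fold);
the alternative of one shared initialization was rejected as it couples
fold results.

Metric conventions: predicted positive iff probability > threshold;
SEN/SPE with zero denominators are flagged undefined; the combined score
(ACC+SEN+SPE)/3 is scanned over thresholds 0.00–1.00 in steps of 0.01
(the grid granularity was an open choice) and the argmax is reported as
contiguous grid intervals [θ_min, θ_max].

## Synthetic data

The generator emulates the structure the classifier assumes: bags of
80–150 clones (pre-filter), CDR3 lengths uniform on [10, 24], interior
residues i.i.d. uniform over the 20 letters (an empirical distribution can
be plugged in), anchors C…F by construction, and Zipf-like clone
frequencies `rank^(−1)` normalized to sum 1 over a random permutation —
echoing the heavy-tailed abundances that motivate top-100 selection.
Positive bags carry ⌈0.3·count⌉ instances with a 4-mer motif (default
WQDR) overwritten into a uniformly chosen interior window; overwriting
rather than inserting keeps the length distributions of the two classes
identical, so a classifier must learn composition, not length.  With
planted fraction 0 the class generators are identical in distribution,
giving a null benchmark.

What passing the synthetic benchmark does **not** show: real repertoires
have position-dependent residue usage from V(D)J recombination, shared
public clones, batch effects between cohorts, and far weaker and more
heterogeneous cancer signal than a single planted 4-mer.  The benchmark
demonstrates that the implementation can learn a distributed instance-level
signal through the full pipeline, not that the architecture reaches any
particular accuracy on clinical data.

## Problem sizes and defaults used in checks

The signal-recovery check trains on 60 + 60 simulated bags with a reduced
budget (epochs 300, patience 60, single CPU) and requires held-out
AUC ≥ 0.95 with the planted motif and AUC within [0.35, 0.65] for the
null, by majority over up to three seeds.  The acceptance script runs one
signal and one null experiment at the same sizes, plus a 48-subject
preprocessing count and closed-form numerical anchors.

## Known limitations

* The CNN→transformer fusion is sequential; no concatenation variant is
  implemented (the reference description leaves the fusion operator open).
* A learned (uniform-random-initialized) residue embedding is not trained
  end-to-end; the fixed PCA-style matrix is used as the instance
  representation throughout.
* Attention is instance-level only; a residue-level transformer within
  each CDR3 is out of scope.
* Batch-norm statistics include every unmasked instance of a batch; very
  uneven bag sizes could bias statistics toward large bags.
* The numpy implementation is single-threaded and CPU-bound; it is sized
  for hundreds of bags, not thousands.
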