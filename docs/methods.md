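# Methods

This note documents the models, parameters and design decisions behind
csvfilt, what the synthetic data does and does not emulate, and the
numerical choices that matter for reproducing its results.

## 1. Coordinates and formats

All internal coordinates are 0-based half-open (the BAM convention);
conversion to/from the 1-based inclusive VCF convention happens only in
`formats_io`.  For insertion records `end := pos` — the VCF `END` of an
INS is unreliable across callers, so the image window is driven by
`SVLEN`.  SV length is reconstructed with the precedence |SVLEN| →
END−POS (deletions) → |len(ALT)−len(REF)|, which covers the dialects of
the common short- and long-read callers; a deletion with none of these is
skipped with a warning.  Read selection uses mapping quality ≥ 20 and
primary alignments only (both configurable): ambiguous placements put
spurious operations into the image.

## 2. Negative-site model

SV lengths are treated as Poisson-distributed.  With `m` and `v` the
sample mean and unbiased sample variance of the true SV lengths, negative
lengths are drawn from Poisson(λ_neg) with λ_neg = 2mv/(m+v), the
harmonic mean of `m` and `v` (λ_neg = m when v = 0).  The pmf is
evaluated in log space.  Placement: chromosome chosen proportional to
length, start uniform; a candidate is rejected and redrawn when its total
overlap with true SVs exceeds half of its own length (fraction measured
relative to the candidate, which is the interval being accepted or
dropped).  Lengths are clipped into [50, 100 000] bp — 50 bp being the
definitional SV floor.  A cap of 50 draws per requested site bounds
termination; by default one negative is generated per true SV, so the
negative class is as large as both SV classes together.

## 3. Image encoding

Grayscale levels default to M=63, I=127, D=191, S=255 — evenly spaced,
pairwise distinct, in (0, 255] — and are stored in every model checkpoint
so filtering always reproduces the training encoding.  On the x-axis
**every** CIGAR operation consumes `length` columns, including the
zero-drawn N/P/H/=/X: this preserves read geometry, so an insertion
visibly displaces the downstream matched segment.  Rows are ordered by
(start, read name); above 512 rows every k-th read is kept (deterministic
decimation).  The window extension defaults to 1000 bp (150 bp is
appropriate for short reads).  Resizing to the 224×224 canvas uses
nearest-neighbor by default because it keeps pixels inside the discrete
level alphabet — an invariant the tests rely on; bilinear is available.
Zero-coverage sites are skipped in training and conservatively **kept**
at filtering time.

## 4. Classifier

The backbone (`tiny_cnn`) is deliberately small: a stride-4 "patchify"
convolution (4×4, no pre-pooling — average-pooling the input first would
blur the discrete level alphabet before any learnable filter sees it),
three stride-2 3×3 convolutions (16/16/32 channels, 64-dim embedding
after projection), ReLU throughout.  Rows (reads) are average-pooled out
after the last convolution but the **column axis is kept** (a 7-bin
x-profile, flattened through a linear map into the 32-dim embedding):
the candidate site sits at a known x-position of the canvas, while
signatures leaking in from neighboring loci appear off-center, and a
global average pool would erase exactly that distinction.
`tiny_cnn_wide` doubles all widths.  The classic ImageNet backbone names
are recognized but rejected with an explanatory error: this package
ships its own dependency-free network core (a ~300-line reverse-mode
autodiff engine over NumPy, gradient-checked against central differences
in the test suite), and the model sizes it trains do not need more.

The head implements the attention fully-connected construction: unit =
elementwise gating of the input by `sigmoid(W_g x + b_g)`, then an affine
map, then ReLU.  Two attention units plus one plain FC unit form the
one-dimensional attention residual module, with the skip connection
spanning the whole three-unit stack (standard residual placement; at
zero weights the module is exactly the identity, which the tests pin
down).  A final affine map and softmax give probabilities over
{INS, DEL, NEG}; prediction is the argmax with ties broken in fixed
class order INS < DEL < NEG.

Training uses Adam (default lr 3e-3, batch 16 — sized for the small
models and datasets involved), cross-entropy, an 80/10/10 stratified
train/validation/test split, and keeps the checkpoint with the best
validation macro-F1.  `mixed_precision` (off by default) quantizes
activations to half precision at the network input while keeping all
parameters, gradients and updates in full precision; the suite checks it
changes benchmark macro-F1 by < 0.02.  Metrics (per-class and macro
precision/recall/F1, accuracy, one-vs-rest ROC/AUC, confusion matrix)
are computed with scikit-learn; a class absent from a test set is
reported as undefined and excluded from macro averages with a warning.

## 5. Self-supervised pre-training

The VICReg objective on paired-view embeddings z_a, z_b:

* invariance — mean squared distance between paired embeddings;
* variance — mean over dimensions of max(0, γ − sqrt(Var + ε)),
  averaged over the two branches (γ=1, ε=1e-4);
* covariance — sum of squared off-diagonal covariance entries divided by
  the embedding dimension, summed over branches;

combined with weights λ=25 (invariance), μ=25 (variance), ν=1
(covariance) — the weights of the original VICReg formulation, which the
method cites by name.  The projector is a 2-layer expander MLP (64-dim),
discarded at checkpoint save; the classification head does not
participate in pre-training.

**View generation.**  Two independent color-jitter draws of the same
image are the canonical views (`make_views`).  For these achromatic,
level-coded images, however, jitter amounts to a near-affine intensity
map, and training invariance to it measurably *degrades* the backbone
(linear-probe accuracy drops below that of the random initialization):
the grayscale levels *are* the information.  The pre-training experiment
therefore uses read-resampled views (`encode_read_resample_pairs`): each
site is encoded twice from two disjoint random halves of its reads
(jitter still applied on top).  Both views share the locus signature but
differ in read sampling, so invariance pulls together what genuinely
identifies the site.

**Evaluation protocol.**  Fine-tuning follows the freeze-then-retrain
recipe: both the pre-trained and the from-scratch arm freeze the
backbone and train the head on a deliberately label-scarce subset (25%
of the training split), with identical schedule and seed, and are scored
on an independently simulated genome.  This isolates what pre-training
contributed to the representation — with full-model fine-tuning on
desk-scale data both arms converge to statistically indistinguishable
accuracy, and the comparison measures only training noise.

## 6. Filtering and benchmarking

The default policy `drop_neg` removes exactly the calls predicted to be
negative sites — the definition of a false positive here; `strict_match`
additionally removes predicted-class/SVTYPE mismatches.  Filtering is
deterministic (no jitter at inference), writes the kept record lines
byte-identically (plus one provenance header line), and is idempotent.
The internal matcher mirrors the SV benchmarking convention used for
this task: same SVTYPE, breakpoint distance ≤ 500 bp, size ratio
min/max ≥ 0.5, greedy one-to-one in position order with ties to the
nearest truth record; sequence similarity is not used (its weight is
zero in the reference setting).

## 7. Synthetic data

The simulator emits what the method consumes, with no external
downloads: a uniform-random reference, non-overlapping implanted INS/DEL
truth records (lengths max(50, Poisson(300)); anchor spacing ≥ 2×read
length so one read sees at most one SV), and reads written directly as
aligned records — a read spanning a deletion interior carries a D
operation of the deletion length, a read spanning an insertion point an
I operation, and 30% of breakpoint-adjacent reads are soft-clipped
instead; background reads are pure M with sporadic 1-bp indel noise
(5e-4/bp).  Defaults: 2 Mb chromosome, 60+60 SVs, coverage 20×, read
length 2000 bp (150 bp for short-read mode), and a caller VCF whose true
calls are jittered by ≤ 50 bp / ≤ 10% length with 50% injected false
positives placed ≥ 1 kb from any true SV.

Because the CIGAR truth is written by construction, the simulator does
not emulate alignment artifacts: chimeric reads, mapping ambiguity in
repeats, reference bias, or diploid genotypes.  Passing the desk
benchmarks therefore demonstrates that the encoding preserves and the
classifier recovers CIGAR-level SV signatures under sampling noise,
contaminated callsets and position/length jitter — not performance on
real sequencing data.

**Benchmark presets.**  The classification/filtering benchmark uses
150+150 SVs on a 5 Mb chromosome (~600 images: 300 SV + 300 negative
sites), keeping the default SV density so the negative class keeps its
default difficulty; training runs 10 epochs.  The self-supervised
comparison uses 125+125 SVs on 4.2 Mb (500 images).  These sizes let the
full suite train dozens of models on a single CPU core.

## 8. Known limitations

* The attention unit internals and several encoder constants (grayscale
  values, window extension, resize interpolation, coverage cap) are
  design choices of this package — the upstream description leaves them
  open; all are configurable and recorded in checkpoints.
* Only INS, DEL and NEG classes; BND/INV/DUP records pass through
  filtering untouched.
* Single-sample VCFs; no genotype-aware matching; no CRAM.
* The NumPy network core is CPU-bound and intended for the compact
  built-in backbones, not ImageNet-scale models.
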