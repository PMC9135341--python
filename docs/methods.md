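# Methods

## Model

### Meta-feature extractor

A 1-kb one-hot sequence (L × 4, columns A/C/G/T, ambiguous bases as all-zero
rows) passes through three stages of `conv1d(kernel 7) → ReLU → maxpool(4)`
with channel sizes 320, 480 and 960 at full scale, then a flatten and two
dense layers emitting one value per reference track (919 at full scale).
Convolutions use 'same' padding; pooling is non-overlapping with the
trailing partial window dropped, so a 1000-bp input traces
1000 → 250 → 62 → 15 spatial positions.

### Residual sequence encoder

A stem convolution (kernel 4, 48 channels) followed by eight residual
blocks (channels 96, 96, 128, 128, 256, 256, 512, 512; kernel 7), a flatten
and two dense layers emitting one value per target track (31 at full scale).
Each block computes `ReLU(conv(ReLU(conv(x))) + shortcut(x))`. When a
block's output channel count differs from its input (blocks 1, 3, 5, 7 at
full scale) the first convolution uses stride 2 and the shortcut is a
width-1 stride-2 projection; otherwise the shortcut is the identity. With
'same' padding the spatial trace is 1000 → 500 → 500 → 250 → 250 → 125 →
125 → 63 → 63. Whether the original downsampling happened inside the
blocks is not derivable from the architecture description alone; stride-2
at the channel-changing blocks is this package's documented choice (it is
the minimal scheme that keeps eight blocks computable on 1-kb input at the
stated widths).

### Joint model

The extractor's output (pre-sigmoid, by default) and the encoder's output
are concatenated (919 + 31 = 950 wide at full scale) and passed through
three dense layers with a terminal sigmoid, one probability per target
track. Feeding pre-sigmoid activations avoids saturated gradients during
joint fine-tuning; a spec flag (`meta_post_sigmoid`) switches to
post-sigmoid. Dense hidden widths are not anchored by anything in the
method, so they are configurable with defaults of the same order as the
output widths (925 for the extractor's first dense layer, 256 for the
encoder's, (512, 256) for the head).

Other architecture decisions: forward strand only (no reverse-complement
averaging); no normalization layers; optional inverted dropout in the head
(off by default). Batch normalization is deliberately not provided — the
flat-weight checkpoint format stores parameters only, and nothing in the
method requires running statistics.

### NumPy engine

The models run on a small layer engine (`seqepi.nn`): im2col-based 1-D
convolution, max pooling with argmax routing, dense layers, residual
blocks, Adam, and Nesterov-momentum SGD, all in float64 with exact
backpropagation through to the input. Input gradients are first-class
because the saliency module consumes them. Correctness is established in
the test suite by central-finite-difference checks on every layer type and
through the full two-branch graph.

## Training

Both phases minimise multi-label binary cross-entropy (probabilities
clamped at 1e-7; the training path uses the numerically stable
logits formulation). Phase one fits the extractor with Adam on the
reference label set; phase two fine-tunes all weights of the joint model —
the meta branch is not frozen — with Nesterov-momentum SGD on the target
set. Model selection is early stopping on validation loss (patience 5 by
default) with best-epoch weight restoration; the original stopping rule is
unreported, and this stands in for it. Defaults (batch 64, Adam lr 1e-4,
SGD lr 1e-3 with momentum 0.9) sit inside the hyperparameter ranges that
were searched at full scale (batch sizes 16–256, learning rates 1e-5 to
1e-3 on a log grid); the grid search itself is out of scope. Gradients are
clipped to a global norm of 5.0 — without clipping, from-scratch SGD on the
eight-block encoder occasionally diverges at desk scale.

AUROC/AUPRC are reported per track; tracks with a single class in a split
are flagged undefined and excluded from macro averages.

## Data pipeline

The genome is tiled into consecutive 200-bp bins (trailing partial bins
dropped; 0-based half-open coordinates throughout). A bin is positive for a
track when the union of that track's peaks covers at least 50% of the bin —
overlapping peaks are merged before computing coverage, which is the
conservative reading of per-assay peak intersection; covering exactly half
counts. Bins with no positive track are discarded (a flag keeps them; the
single-track benchmark needs its negatives). Whole chromosomes (chr7/chr8
by convention) are held out as the test set and the rest is split randomly
into train/validation with a seeded generator; the validation fraction is
exposed as a parameter because no specific value is reported. Each
retained bin is extended symmetrically to the model window; windows that
would leave the chromosome are dropped rather than padded, so every
example is a real genomic sequence. VCF positions are converted from
1-based on read; 'N' encodes as an all-zero row so row sums act as a
validity indicator.

## Variant scoring

For a SNV, two window-length sequences centred on the variant (the variant
base at offset window/2, 0-indexed — an explicit convention, since an even
window has no centre base) differing only there are predicted separately.
Reported per track: `|A_ref − A_alt|` (the default ranking score),
`|logit(A_ref) − logit(A_alt)|` with probabilities clamped to
[1e-6, 1 − 1e-6], and the signed effect `log(A_ref/A_alt)` (natural log
throughout) for direction analyses. The reference allele is checked
against the genome; a mismatch is an error, while variants too close to a
chromosome end are skipped and reported in a sidecar table. Ranking ties
break by variant id for reproducibility.

## Validation statistics

* **ASC enrichment** — 2×2 (top vs control) × (ASC vs not); two-sided
  Fisher exact test. "Fold enrichment" is reported as the ratio of ASC
  proportions, with the odds ratio alongside, since the headline number
  could be read either way. Controls are drawn uniformly without
  replacement from in-peak variants; overlap with the top set is removed.
* **Allelic-imbalance concordance** — Spearman correlation between observed
  `log(R_ref/R_alt)` and predicted `log(A_ref/A_alt)`; records with a zero
  count on either allele are excluded (no pseudocount by default), and a
  sign-agreement curve over score cutoffs is returned.
* **Constraint comparison** — two-sided Wilcoxon rank-sum on constraint
  scores (GERP/PhyloP-style, consumed as user-supplied tables): exact
  enumeration for tie-free groups of ≤ 50, tie-corrected normal
  approximation otherwise.
* **MAF by score bin** — left-closed right-open bins (last bin closed) with
  the two default edge sets (0, 0.05, 0.1, 0.15, 0.2, 1.0) and
  (0, 0.01, 0.02, 0.03, 0.04, 1.0). The second set's first edge is printed
  inconsistently in the source material ("0–0.05" followed by "0.01–0.02");
  0–0.01 is the only reading that makes five contiguous bins.

## Prioritization

A credible-set SNP is a candidate when (i) PIP > 0.1, (ii) its score
reaches the top 1% of a user-supplied background score distribution in at
least one cell type (threshold = k-th largest with k = ⌊pct·n⌋, minimum 1),
and (iii) it attains the maximum score within its locus's credible set in
at least one cell type. "Very top" is read as the maximum with ties
qualifying all tied SNPs; a single-SNP locus satisfies (iii) trivially.
The stage call is F, A, or FA according to the stages of the cell types in
which the SNP is the credible-set maximum. Annotation joins (eQTL,
contact-map targets) are left joins; absence is recorded as missing, never
as negative.

## Interpretation

Saliency is the gradient of a track's **pre-sigmoid** output with respect
to the one-hot input (taken pre-sigmoid to avoid saturation flattening the
gradients; the source material does not specify). The gradient is gated by
the observed nucleotide — entries off the observed base are exactly zero.
Candidate sequences are sampled from test-set examples whose label vector
has exactly one positive track. Seqlets are greedy non-overlapping
sliding-window maxima above a threshold in units of the window-sum
standard deviation; full motif-discovery clustering is external, with a
lossless array export (importance + one-hot + JSON manifest) as the
interface and a small PWM matcher (best Pearson correlation over ±3 column
offsets) for synthetic-data checks only.

## Synthetic data

The generator emulates the statistical structure the framework assumes:
i.i.d. background genomes; per-task peak sets where every peak carries at
least one planted instance of a motif from the task's subset (tasks sharing
motifs share determinants — what transfer exploits); functional variants
that substitute the highest-information PWM column with its least-probable
base; neutral variants in peak background; binomial allelic read counts
with `logit(p_ref) = scale × magnitude × sign` and a Benjamini–Hochberg
flag from a two-sided exact binomial test. The signed true effect is
`log pwm[ref] − log pwm[alt]` (natural log) — positive when the alternative
allele weakens the motif — so the truth, the expected allelic imbalance
`log(R_ref/R_alt)`, and the model's signed prediction `log(A_ref/A_alt)`
all share a sign convention. Placements are forward-strand by default (a
flag enables both strands); outputs are uppercase FASTA, 0-based half-open
BED, and TSV, byte-identical under a fixed seed.

What the generator does *not* emulate: realistic nucleotide composition
(isochores, repeats), diploid genomes, indels, cooperative or distal
regulation, and graded (non-binary) accessibility. Passing tests therefore
demonstrate that the machinery is correct and that the transfer/variant/
saliency claims hold when their assumptions hold — not performance on real
epigenomes.

## Desk-scale study conditions

The benchmark studies (`seqepi.benchmarks`) fix the problem sizes used by
the test suite and `scripts/acceptance.py`:

* **Window 400 bp** (bin 200): a 200-bp peak overlapping a bin by ≥ 100 bp
  always lies inside the bin's 400-bp window, so every positive example
  contains its motif evidence.
* **Single-motif study**: one track, 850 peaks of 200 bp on a 400-kb
  training chromosome plus a 130-kb held-out chromosome; one 18-bp motif
  instance per peak (dominant base probability 0.97); 2,000 training and
  ≤ 500 test examples. Extractor channels (64, 64, 96), kernel 11, hidden
  64; encoder stem 8 with blocks (8, 8, 12, 12, 16, 16, 24, 24); head
  (48, 24). Pretrain 12 epochs (Adam 3e-3, batch 32), joint 8 epochs
  (SGD 3e-3, momentum 0.9). One instance per peak keeps variant effects
  unbuffered — with redundant instances, disrupting one leaves the peak
  predicted open and the variant signal vanishes; the wide motif is what
  makes a lone instance learnable.
* **Transfer study**: an 8-motif vocabulary (12 bp each, fixed internal
  seed so reference and target share it); 10 reference tracks (8
  single-motif + 2 composite, 280 peaks each, two instances per peak,
  ~2,300 training examples) on one genome and 3 two-motif target tracks
  (550 peaks each) on another, with target training capped at 1,000
  examples. Extractor channels (32, 48, 64). The extractor is pre-trained
  15 epochs on the reference tracks; transfer and from-scratch joint models
  are then fine-tuned 8 epochs on the identical target data.
* **Variant study**: 200 motif-disrupting + 200 neutral variants on the
  single-motif genome; allelic counts at depth 100 with imbalance scale 1.

These sizes were chosen once as the smallest configurations at which the
single-motif track is reliably learnable and the transfer contrast is
expressed; they are the package's reference conditions, not tunable
test knobs.

## Numerical choices and degenerate inputs

Probability clamps: 1e-7 in the loss, 1e-6 in log-odds variant scores.
Finite-difference checks on the piecewise-linear networks are only valid at
locally smooth points; the tests verify one-sided-difference agreement
before comparing. Empty peak files label nothing; peaks on unknown
chromosomes warn and are ignored; single-class tracks yield NaN metrics;
all-N input yields finite probabilities. Checkpoints are a JSON spec plus
one flat float64 weight vector, so they are self-describing and
byte-stable.

## Known limitations

* Desk-scale models use reduced widths and a 400-bp window; absolute
  metric values are not comparable to full-scale training on real
  compendia.
* The engine is single-threaded NumPy; full-scale (919-track, 4.4M
  example) training is out of its intended range.
* From-scratch SGD at desk scale underfits within the epoch budget — which
  is precisely the low-data regime the transfer comparison is designed to
  expose.
* Learnability of a lone motif instance depends on initialisation; the
  multi-seed protocol (≥ 2 of 3 seeds) absorbs this variance.
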