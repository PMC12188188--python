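# Methods

## Prediction task and model family

A promoter is a string over {A,C,G,T,N} standardised to 110 nt: fixed 17-nt
5′ flank, ~80-nt variable insert (positions 18–97, 1-based), fixed 13-nt 3′
flank. The model learns f : sequence → expression, where expression is in
weighted-mean-bin units (0-based bins, 18 bins in the default readout).

The architecture family is a stack of same-length (zero-padded, odd-kernel)
1-D convolutions with per-layer batch normalisation and ReLU, additive
identity skips over two-layer blocks, one max pooling (width 11) before
flattening, and a fully connected head ending in a scalar. A skip into the
block ending at layer *i* adds the input of layer *i−1* to the
pre-activation of layer *i*; when the source is narrower than the target
(only the first block, whose source is the encoded sequence), it is
zero-padded along channels — a parameter-free projection, so skips
contribute no parameters. Activation order in a block-final layer is
conv → batchnorm → add skip → ReLU.

### Presets

| preset          | conv channels | kernels            | residuals | FC        | parameters |
| --------------- | ------------- | ------------------ | --------- | --------- | ---------- |
| camformer       | 512 × 6       | 13,13,11,11,9,9    | 2,4,6     | 512,64,1  | 16,584,321 |
| camformer_small | 256 × 6       | 9,9,9,9,7,7        | 2,4,6     | 256,64,1  | 3,372,929  |
| camformer_mini  | 184 × 4       | 9,9,9,9            | none      | 256,64,1  | 1,410,753  |
| camformer_tiny  | 32 × 2        | 9,9                | 2         | 32,1      | 20,865     |

The kernel widths, FC widths, dropout (0.1 on FC hidden layers of the large
presets) and pool width are this package's design choices within the stated
family; the two large presets are pinned by their trainable-parameter totals
(16.6 M and 3.4 M), which the test suite checks against an independent
closed-form count. Note that the totals force the small preset to differ
from the full one in more than channel width: halving every width can reduce
a network's size by at most 4×, while 16.6 M/3.4 M ≈ 4.9, so the small
preset carries its own kernel and FC widths. `camformer_tiny` exists so the
full pipeline — training, ISM, Grad-CAM, motif analyses — runs in minutes on
one CPU; it is the preset used by the test suite's recovery experiments.

### Numerical engine

Layers, backpropagation, losses (L1 default, MSE, Huber δ=1), optimizers
(AdamW; Lion with decoupled weight decay on matrices only) and LR schedules
(none, step ×0.5 every 10 epochs, cosine) are implemented in numpy
(float32 by default; float64 available and used by the finite-difference
gradient tests, which check every layer type to 1e-5). Convolution uses an
im2col GEMM; batch statistics make training-mode forward passes depend on
the minibatch, so evaluation always uses running statistics and is
deterministic given weights. Minibatches of fewer than 2 sequences are
skipped (batch normalisation is undefined there).

## Encodings

Channels 1–4 are A,C,G,T one-hot. `onehot` maps N to all-zeros;
`onehotWithP` to uniform 0.25; `onehotWithN` adds a binary N channel;
`onehotWithInt` adds a constant per-record uncertainty channel 1/√support
(1 when support is missing); `onehotWithBoth` carries both extra channels.
The uncertainty definition is a design choice: it decreases with read/cell
support like a standard error, is 1 for the unsupported case, and is
broadcast across positions because support is a per-record quantity.

## Preprocessing

Filters run in order: keep lengths 110±3, then among survivors keep records
with at most 3 N; short survivors are padded with N at the 3′ end, long ones
truncated at the 3′ end (padding is defined at the 3′ end, so truncation
mirrors it). The N count excludes the trailing N run, which is
indistinguishable from padding; this makes the operation idempotent without
changing the behaviour on interior or leading Ns. The report counts each
discard reason with length applied first.

## Training recipe

Default: L1 loss, AdamW (lr 1e-3 default; the desk-scale experiments use
2e-3, batch 128), at most 50 epochs, early stopping on validation r + ρ with
patience 5 and best-epoch weight restoration. Validation fraction defaults
to 0.10 (0.08 available via config). Zero-variance correlations are defined
as 0 (with a warning) so the early-stopping score stays totally ordered.
Splits draw a seeded permutation; validation size is round(n·fraction).
Subsampling curves fix one held-out set first and use nested subsets (a
seeded permutation prefix) so the curve isolates data volume. The grid
generator emits the Cartesian product 5 encodings × 3 losses {L1, MSE,
Huber} × 2 optimizers {AdamW, Lion} × 3 schedulers = 90 combinations per
structure, 270 over the three main presets; the axis composition is a
reconstruction and is configurable.

## Synthetic reporter assay

The generator emulates the assay that motivates the model:

* inserts are i.i.d. uniform over {A,C,G,T}; flanks are fixed, configurable,
  with documented arbitrary defaults (only their fixedness matters);
* each motif is independently planted with probability `plant_prob` at a
  uniform non-overlapping position in the insert (rejection sampling, 100
  attempts), on a uniform strand, with the site sampled column-wise from the
  PWM and written over the insert (replacement keeps length 110);
* latent expression = baseline + Σ planted effects + Σ co-planted
  interaction effects + gc_coeff × GC fraction of the insert — additive by
  construction, which the tests exploit;
* the readout simulates `cells_per_promoter` values latent + N(0, sd), bins
  them on an equal-width 18-bin grid (default range: mean ± 2 sd of the
  latent distribution, estimated from 10,000 seeded draws, since real bin
  edges are a property of the instrument and not reconstructed here), clips
  to the range and returns the mean 0-based bin — the weighted mean
  expression bin. Observed noise then scales as 1/cells, emulating shallow
  (~2 cells) training data versus deep (≥100 cells) test data.

What it does not model: sequencing depth, PCR bias, plasmid copy number,
the real library's base composition, or empirical bin calibration. Passing
recovery tests therefore demonstrates that the estimator and attribution
machinery work when the generative assumptions hold, not that the model
attains any particular accuracy on real assay data.

### Demonstration conditions

The fixed demo library (20,000 promoters, 18 bins, 100 cells/promoter,
cell noise sd 1.0, GC coefficient 1.0) plants ACT (TGACTCAT, +2.0, p=0.5),
REP (CCGGAAGT, −2.0, p=0.5), IME (GCCGCC, +0.8, p=0.35) and UME
(TAGCCGCCGA, −2.2, p=0.35) with a −1.2 IME×UME interaction. UME's consensus
contains IME's, so scanner hits of IME inside UME sites physically overlap —
the synthetic analogue of an activator core enclosed by a repressor motif,
which is what the overlap-grouped ISM analysis is designed to detect.
Effect sizes are roughly ±1–2 latent standard deviations: large enough that
a 21 k-parameter model trained for 10 epochs can recover them, small enough
that the binned readout, GC trend and motif interactions all remain visible
in the data. The 100-cell readout corresponds to the precise (test-like)
sequencing regime; the 2-vs-100-cell asymmetry is tested separately.

## Evaluation

Pearson r (product-moment), Spearman ρ (average ranks, so ties from binned
expression are handled), r². Per-category reports compute both within each
category and form weighted Pearson/Spearman scores Σw·r/Σw; categories with
fewer than 2 observations are excluded and flagged. Category weights are an
input (uniform default) because competition weightings are not public.
Baseline-normalised improvement Δnormρ = (ρ₂−ρ₁)/(1−ρ₁) expresses a gain as
the fraction of remaining headroom closed. Bootstrap comparison resamples
observations with replacement (default 10,000 replicates), computes both
correlations for both prediction sets per replicate, redraws degenerate
resamples (counted), and applies a paired t-test to the per-replicate
differences.

## Explainability

ISM evaluates the model on the original sequence and on all 3×80 = 240
single-base variants across positions 18–97 (N positions are skipped and
reported; results are batching-invariant because evaluation is
deterministic). Importance at a position is the negative mean of the three
substitution deltas, so positive importance marks bases whose mutation
lowers the prediction. The ISM-logo entropy is −Σp·ln p over the normalised
absolute importances (log base configurable); low entropy flags profiles
concentrated on few positions, i.e. candidate motifs. An all-zero profile is
defined as the maximum ln(80), with a warning. Whether entropy should
instead be computed per-position over bases and averaged is an open choice;
the position-profile definition was chosen because it directly measures
positional concentration.

Grad-CAM for this regression model weights each channel of a conv block's
post-activation feature map by the position-averaged gradient of the raw
scalar output (no class score exists), sums over channels, rectifies, and
linearly interpolates to input coordinates — maps are nonnegative and
length 110 at every layer. Activation embeddings flatten a block's
(positions × 1 × channels) output to d = h·w·c per sequence for use with
t-SNE/UMAP from standard libraries.

## Motif logic

The scanner scores every window on both strands with Σ log(p′/background),
p′ pseudocount-renormalised (default 0.001); N contributes zero information
(log-odds 0), a neutral treatment of padding. Default threshold 0 (better
than background); the grouped-ISM analyses in the tests use ~70% of the
maximal score, which for near-deterministic PWMs admits only exact matches.
Enrichment assigns records to expression quantiles (value-based; a constant
library is an error), tests motif presence in top vs bottom quantile with
Fisher's exact test, and adjusts across motifs by Benjamini–Hochberg. The
co-occurrence matrix M[i,j] is the mean prediction over sequences carrying
both motifs (diagonal: the motif's own baseline), D[i,j] = M[i,j] − M[i,i];
cells with support below `min_n` (default 5) are reported empty. Grouped
ISM profiles orient each motif-A window 5′→3′ along the motif (minus-strand
windows reversed), classify it as overlapping when any motif-B hit shares
≥1 position on either strand, and average per group. These components are
method-analogous to, not bit-compatible with, the MEME-suite tools (SEA,
FIMO) they mirror.

## Problem sizes used by the checks

The recovery experiments train the tiny preset on 20,000 simulated
promoters for 10 epochs (held-out ρ, ISM sign recovery over ≥80 planted
instances per motif, overlap-grouped profiles over ≥150 scanned sites); the
ensemble comparison trains five 4-epoch seeds on 6,000 promoters and uses
10 bootstrap resamples of a 1,000-sequence test set; Grad-CAM localization
uses 100 sequences. These sizes were chosen so every property is measured
with comfortable statistical margin while the whole suite stays desk-scale.

## Known limitations

* The two large presets are validated by parameter counts and forward-pass
  contracts, not by full-scale training, which is out of desk-scale reach.
* The preprocessing check against the published discard counts of the real
  6.7 M-sequence table runs only when that external download is present.
* The numpy engine is single-device and unbatched across processes; it is
  sized for the tiny preset, not for training the 16.6 M-parameter model.
* The simulator's bin grid is a stand-in, not a reconstruction of the real
  bin-to-expression calibration.
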