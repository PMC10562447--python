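# Methods

## The design problem

A promoter's activity is set jointly by its transcription-factor binding
sites (TFBSs) and by the flanking sequence around them.  Practitioners know
which motifs encode a desired behaviour — sigma-70 −35/−10 elements for
constitutive strength, lacO or tetO operators for inducibility — but the
flanks are usually chosen arbitrarily, and they matter.  seedflank treats
design probabilistically: write the sequence as s = (m, f) with m the
expert-fixed "seed" motifs at fixed positions and f the flanks, and maximize
P(f | m*, T) ∝ P(f | m*) · P(T | f, m*) for the target property T.  The
first factor is modelled by a conditional adversarial generator G(m*, z)
that fills flanks compatible with the seed; the second by a
sequence-to-activity predictor F.  Design then maximizes F(G(m*, z), m*)
over the latent z with a genetic algorithm, so the search never leaves the
generator's manifold of promoter-like sequences.

## Models

**Generator.**  Input is an L×4 relaxed one-hot matrix: hard rows at seed
positions, random row-stochastic rows elsewhere.  The random rows *are* the
latent draw z; each is the softmax of four standard normals.  The network is
a per-position linear embedding into d_k channels, one multi-head
self-attention layer (head_i = softmax(X A_i^Q (X A_i^K)^T / √d_k) X A_i^V,
concatenated over heads, no output projection), two channel-preserving
convolutional residual blocks (kernel 3), and a row-softmax projection back
to L×4.  Seed rows of the output are overwritten with the hard seed encoding
inside the computation graph, so seed preservation is a structural
guarantee, not a training outcome, and the seed rows contribute zero
gradient.

**Critic.**  Same front end on the channel-wise concatenation of the motif
encoding and the (real or generated) sequence encoding (L×8), global average
pooling, scalar head.  Training is Wasserstein with gradient penalty
E[(‖∇_x D(m, x̂)‖−1)²] at per-sample uniform interpolates between real and
generated encodings, plus an L1 reconstruction term λ·E‖f − G(m, z)‖
computed over flanking positions only (seed rows are constrained and their
residual is identically zero).  The vanilla log-loss form is available
behind `loss_form="log"`.  Defaults: λ=10 and gradient-penalty weight 10
(the usual Pix2Pix / WGAN-GP conventions), 5 critic steps per generator
step, Adam with learning rate 1e-4, β₁=0.5, β₂=0.9, batch 32; full-scale
runs train for 50,000 generator steps, the packaged benchmarks for 60–300.

**Predictor.**  1-D convolution (64 channels at full scale), bidirectional
LSTM, then four densely connected convolutional blocks of 2, 2, 4 and 2
layers with growth rate 32; each dense layer is a kernel-1 bottleneck (2×
growth channels) followed by a kernel-3 convolution emitting `growth_rate`
channels concatenated onto the running feature map.  Kernel-1 transitions
halve the channel count and average-pool length by 2 between blocks.  Global
average pooling yields the penultimate embedding; one dense unit predicts
activity.  Training minimizes squared error on z-scored activities with
early stopping (patience 10 at full scale).  Unstated details we fixed:
LSTM is a single bidirectional layer (hidden 64 default), first-conv kernel
7, pooling is global average; all configurable.  The predictor sees the
sequence only; an optional motif-mask channel is not enabled by default.

**Autodiff.**  No deep-learning framework is assumed: the models run on a
small reverse-mode engine (`seedflank.autodiff`) whose vector-Jacobian
products are themselves traced operations, so the gradient penalty's
second-order term is exact (verified against central differences to ~1e-10).
Everything is float64.

**Saliency and embeddings.**  Saliency is the input gradient of the
prediction, by default multiplied elementwise by the one-hot input
(attribution restricted to observed bases; the plain gradient is available).
Saliency maps are clustered by k-means (seeded; 7 clusters in the standard
analysis, with a seeded random subsample of 30 members per cluster as
representatives).  The penultimate-layer embedding doubles as the feature
space for promoter population analysis.

**Genetic algorithm.**  The latent coordinates (pre-softmax flank rows) are
binary-encoded at 8 bits per coordinate into [-3, 3]; search uses tournament
selection (size 3), single-point crossover (p=0.9), bit-flip mutation
(p=0.005), and elitism 1, with fitness evaluated on whole populations in
vectorized batches.  Full-scale defaults are population 5120 and 100
generations.  With elitism ≥ 1 the best-fitness trace is non-decreasing by
construction.  Designs are decoded by per-row argmax (ties break A<C<G<T),
deduplicated exactly, passed through an optional filter chain (PWM motif
filter on both strands outside seed positions; second-promoter scan), and
ranked by predicted activity.

## Analysis suite

* **k-mer spectra** are pooled overlapping counts normalized to probability
  vectors; region restriction splits the window at the midpoint by default
  (distal = first half, proximal = second half).
* **Edit distance** is unit-cost Levenshtein, computed with edlib; diversity
  profiles are all cross-group pairwise distances.  The template-difference
  score is s = ed(design, template) / flanking_length, in two modes: `full`
  (whole sequences; indels may couple seed and flank regions) and
  `flanking` (concatenated flank positions only).  Both divide by the
  flanking length.
* **PWM scanning** scores log2 odds with a pseudocount-adjusted probability
  matrix against a background; p-values are exact, from a dynamic program
  over the score distribution discretized at 1e-3 log2-odds units with
  rounding toward −∞ (conservative).  The second-promoter scan builds a
  combined −35 / uniform-spacer / −10 matrix (spacer 17 bp by default;
  uniform columns contribute zero log-odds under a uniform background),
  scans the forward strand by default (promoters are directional; both
  strands optional), and flags any significant hit outside the intended
  promoter's own region.
* **DNA shape** uses a sliding-pentamer table.  MGW/ProT attach to the
  pentamer's center base (positions 2..L−3, i.e. L−4 defined values).
  Roll/HelT attach to steps: step i (between bases i and i+1), for i in
  2..L−3, averages the second central-step value of the pentamer centered
  at i with the first central-step value of the pentamer centered at i+1
  (single-sided at the last step) — exactly L−4 defined steps.  Under this
  convention MGW/ProT tracks are exactly reverse-complement symmetric and
  interior Roll/HelT steps mirror as step i ↔ step L−2−i.
  The packaged table (`data/pentamer_shape_synthetic.tsv`) is a synthetic,
  reverse-complement-consistent stand-in whose MGW narrows with AT content;
  it has plausible ranges but is not an experimental prediction table.  A
  loader accepts externally supplied tables in the same TSV format.
* **Shape embedding** concatenates the four defined tracks per sequence,
  z-scores features, and embeds with seeded t-SNE (PCA available).

## Synthetic data and what it shows

`simulate_dataset` plants seed motifs (consensus or PWM-sampled) into i.i.d.
background sequence and assigns activity by a known formula:

    activity = w_motif · Σ PWM log-odds of the planted motifs
             + w_flank · (GC(flank) − 0.5 + kmer_bonus · #bonus-kmer / windows)
             + N(0, noise_sd²)

Defaults: uniform background, w_motif=1, w_flank=4, bonus 4-mer "TGAC" with
weight 2, noise_sd=0.1, window 165 bp with a −35 TTGACA / 17-bp spacer /
−10 TATAAT seed ending 8 bp upstream of a TSS 20 bp before the window end.
The oracle is deterministic and recomputable per sequence, which is what
makes parameter recovery, design benefit, and seed preservation testable
without any external data.  The simulator emulates fixed-length promoters
with planted elements and composition-dependent activity; it does not
emulate positional epistasis, TF co-binding, or measurement-specific noise
of real MPRA data, so passing benchmarks demonstrate that the machinery
works, not that real promoters will behave accordingly.

Promoter geometry filtering keeps records whose window extends >75 bp
distal of the TSS, whose −10 element ends 1–21 bp and −35 element 25–45 bp
upstream of the TSS, and whose spacer is 10–24 bp, tagging each rejection
with the first failed rule; unannotated elements are located by maximal PWM
log-odds within the allowed windows.

## Benchmark problem sizes

The packaged benchmarks (`seedflank.benchmarks`) use scaled-down sizes
chosen to run on one CPU core in minutes: predictor parameter recovery
trains on n=2000 simulated 50-bp promoters (reduced widths: 16 conv
channels, LSTM hidden 12, blocks (1,1,2,1), growth 8, ≤25 epochs) and is
scored against the noise-free oracle on 400 held-out sequences; the
shuffled-label control permutes activities before training and evaluates on
400 held-out pairs.  The design benchmark briefly trains the generator (60
steps), runs the GA at population 256 for 30 generations, and compares the
oracle activity of the top 16 designs with 64 random-flank controls
carrying the same seed (Cohen's d).  Distribution matching trains the
adversarial pair for 300 generator steps on 200 AT-biased 32-bp sequences
and compares flank 4-mer spectra; the spectra are computed on flanking
regions because the planted motif is shared by every set and would dominate
a full-sequence correlation.

## Numerical choices and edge cases

0-based, half-open coordinates; channel order A,C,G,T; decode ties break
lexicographically; 'N' encodes as the uniform row and is never emitted.
Row-stochasticity is enforced to 1e-6 on relaxed matrices.  The p-value DP
is limited to widths ≤ 30.  Sequences shorter than k are skipped (with a
warning) in k-mer counting; zero-variance spectra make correlations an
error rather than a NaN.  Empty motif libraries pass sequences through with
a warning.  Activities must be finite; degenerate (constant) activity
vectors refuse to train.  Checkpoints are single-file npz archives with the
model config embedded.

## Known limitations

Training at the published scale (50,000 batches, 165-bp windows, 29k
sequences) is possible but slow on this numpy engine; the packaged
benchmarks are deliberately small.  The GA searches the latent space only —
no direct sequence mutation.  Multi-objective design (e.g. penalizing leaky
expression) is out of scope.  BLAST-based genome-similarity screening and
the unsupervised sequence-semantics encoder are not included; the
predictor's penultimate embedding serves as the functional feature space.
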