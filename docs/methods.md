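# Methods

This note records the models implemented, the conventions and parameter
choices behind them, and what the synthetic test bed does and does not
establish.

## Adversarial super-resolution objective

The generator loss is the unweighted sum of four terms (weights are exposed
because they are natural hyperparameter-search variables, defaults all 1.0):

* **Charbonnier** `mean sqrt((y - x)^2 + eps^2)`, `eps = 1e-3` by default.
  A smooth L1: equals MAE at `eps = 0`, bounded below by `eps`, robust to
  outliers.
* **Frequency-domain L1** — per sample, the 2D FFT of prediction and target;
  amplitudes and phases are compared with L1 and **averaged over frequency
  bins**, then averaged over the batch.  Bin-averaging (rather than
  summation) keeps the term on the same O(1) scale as the other unit-weight
  terms; with summation the spectrum term is ~10^3 times larger and
  dominates training.  Phase is `atan2` with the phase of an exactly-zero
  bin defined as 0; no unwrapping.
* **Wasserstein adversarial** — the critic scores a batch and the score is
  the per-image mean of its output map.  The *standard* convention is the
  default: the critic minimizes `mean(fake) - mean(real)`, the generator
  minimizes `-mean(fake)`.  A `flipped_sign` switch provides the
  sign-flipped form (`+mean(fake)` / `mean(real) - mean(fake)`); the two are
  equal in magnitude and opposite in sign.  The default is chosen because
  literally minimizing the flipped form inverts the optimization.
* **Perceptual (LPIPS)** — mean over layers of the MSE between feature
  maps.  The reference extractor is a fixed, seeded, randomly initialized
  convolutional stack (deterministic and self-contained); a pretrained
  backbone can be plugged through the same `FeatureExtractor` interface.  No
  learned per-channel calibration is applied.

**Lipschitz control.**  The critic uses weight clipping (default `c = 0.01`,
switchable off).  Clipping needs only first-order gradients, which keeps the
training loop exactly reproducible on the package's compact reverse-mode
stack; a gradient penalty would require double backward.

**Frequency-loss backward.**  The phase derivative carries a `1/A` factor
that explodes on near-empty spectrum bins.  The training-side backward damps
it with a Tikhonov denominator `A^2 + (0.01 * A_max)^2`; the forward value
is unaffected and the raw derivative is available with `rel_damp = 0`.

## Degradation pipeline

Low-resolution training inputs are synthesized by a seeded plan: per pass
(default 2 passes), the operator order is shuffled, each operator is
included with probability 0.5, and parameters are drawn from configured
ranges — blur sigma 0.2–3.0 px, Gaussian noise sigma 1–25/255, speckle
variance 0.001–0.02, JPEG quality 30–95, brightness ±0.1 / contrast
0.8–1.2, sharpening amount 0.3–1.0, gamma 0.7–1.5, cutout ≤ 10% area,
rotation ±15°.  These ranges follow common real-world-SR practice and are
all configurable.  Stochastic operators store a private sub-seed in the
plan, so replay is bit-identical and plans round-trip through JSON exactly.
JPEG is realized as an in-memory baseline encode/decode via Pillow at the
sampled integer quality (dialect fixed for bit-exactness).

**Geometric pairing.**  Rotation and cutout are applied to the HR image
before any photometric corruption, and `apply_plan_paired` returns the
transformed HR together with the LR output, so HR/LR training pairs remain
geometrically aligned — unpaired rotation would break supervision.

The classifier-side preset (affine, brightness/contrast, sharpening, blur
and motion blur, Gaussian noise, gamma, compression) is shape-preserving
and draws every parameter regardless of inclusion, so the random stream is
identical across inclusion patterns of one seed.

## Image-quality conventions

The canonical intensity range is [0, 1]; PSNR and SSIM rescale internally
by `peak` (default 255) so the conventional 8-bit constants apply.  SSIM
defaults to an 11x11 Gaussian window (sigma 1.5), constants
`C1 = (0.01*peak)^2`, `C2 = (0.03*peak)^2`, `C3 = C2/2` — the metric's
original convention; a `global` single-window mode evaluates the plain
formulas and serves as the transcription oracle in tests.  In windowed mode
the similarity map is cropped by one window radius before averaging, since
the filter response inside the border depends on the padding rule.  PSNR of
identical images is `+inf`.

## POMB machinery

* **d-separation** is the standard three-case criterion (chains and forks
  blocked by conditioning on the middle node; colliders blocked unless the
  collider or a descendant is conditioned on), implemented as Bayes-ball
  reachability.  The test suite checks it against an exhaustive
  path-enumeration oracle and against networkx's implementation.
* **Markov blanket** = parents ∪ children ∪ spouses (co-parents of
  children).
* **Candidate enumeration**: per hyperparameter node `h`, the candidate is
  `{h} ∪ parents(h) ∪ children(h) ∪ spouses(h)` restricted to the trial
  table's hyperparameter columns (the target and other metric nodes are
  dropped), plus the blanket of the target itself.  Including `h` in its
  own candidate makes each candidate a self-contained predictor set and
  lets the dominance-degree ranking separate the true blanket from its
  redundant supersets instead of falling through to tie-breaks.
* **Scores**: `f_perf` is K-fold (default 5) cross-validated explained
  variance of predicting the target from the joint discrete assignment with
  conditional means shrunk toward the training mean by one
  pseudo-observation (unseen assignments fall back to the training mean).
  The shrinkage means a noiseless deterministic target scores ≈ 0.999
  rather than exactly 1.  `f_red` is the mean pairwise normalized mutual
  information among the candidate's variables; singletons score 0.  Both
  are pluggable.
* **Ranking**: Pareto front first (non-dominated under fperf-max/fred-min
  with at least one strict inequality); within each group the keys are
  dominance degree (count of candidates dominated, descending), crowding
  distance (descending), then lexicographic variable names — a
  deterministic total order.  Crowding follows the usual multi-objective
  convention: per objective the group is sorted, boundary members get
  `+inf`, interior members accumulate the absolute neighbour gap, summed
  over both objectives; ties in an objective are broken by input position.
* **Refinement** keeps members of V-structures pointing into the target (or
  its children) together with their spouses, then repeatedly removes any
  member d-separated from the target given the remainder.  For any
  candidate containing the structural blanket this provably converges to
  exactly the blanket.
* **Relevance taxonomy**: strongly relevant = blanket member; irrelevant =
  graph-disconnected from the target; redundant = outside the blanket with
  `MB(X) ⊆ MB(T) ∪ {T}`; otherwise the smallest separating set found
  (subsets searched in increasing size, lexicographic) is reported.  The
  classification is graph-structural; faithfulness of the network to the
  data is an assumption, with `check_faithfulness` offered purely as a
  diagnostic (chi-squared conditional-independence tests per stratum,
  Bonferroni across strata, warning on disagreement).
* CPTs `P(node | parents)` can be attached to the network (row sums
  validated to 1e-9) and estimated from trials by Laplace-smoothed counting
  with quantile-binned metrics — they are descriptive; scoring uses the
  trial table directly.

## Synthetic test bed

* **Phantoms** are procedural: an elliptical skull rim, band-limited
  Fourier-filtered tissue texture, two ventricle-like dark lobes and one
  bright blob, all jittered by seed.  Volumes stack smoothly rescaled
  slices.  Mid-slice index is `floor(dim/2)`; slice resizing uses bilinear
  interpolation with anti-aliasing (the interpolation is this package's
  choice — nothing canonical exists to match).
* **Trial tables** draw `h1 ∈ {0..3}`, `h2 ∈ {0..2}`, `h4 ∈ {0..3}`
  uniformly and set `accuracy = 0.6*(h1/3) + 0.3*(h2/2) + N(0, 0.05^2)`,
  with `h3` an exact copy of `h1`.  The coefficients make the relevance
  ground truth analytic: signal variance ≈ 0.065 against noise variance
  0.0025, so the true blanket explains ≈ 96% of the variance.
* What passing these tests shows: the machinery is correct on data whose
  generating process is known exactly.  What it does not show: anatomical
  realism, scanner physics (no k-space modelling), pathology, or that the
  SR model reaches clinically useful quality — those require real MRI data
  and full-scale training, which are out of scope here.

## Desk-scale training configuration

The full-scale defaults follow standard practice for this model family:
batch 4, cosine-annealed learning rate 1e-4 → 1e-7, Adam with weight decay
1e-3.  The package's test-bed runs use a deliberately small configuration —
8 phantom pairs at 32x32, scale 2, 200 iterations, batch 4 — chosen so the
whole adversarial loop runs in tens of seconds on one CPU.  At 200
iterations the full-scale learning rate barely moves a fresh network, so
the `toy_train_config` preset scales it to 3e-3 → 3e-6 while keeping
everything else at the defaults.  Batches cycle round-robin through the
fixture so that early and late windows of the loss log see the same sample
mix and window means are comparable.  The generator's output convolution is
zero-initialized on top of a global nearest-neighbour skip, so the
untrained model exactly reproduces the nearest-neighbour baseline and
training can only be measured upward from it.

Determinism: every source of randomness in a run descends from one seed;
training twice with the same config and data yields bit-identical loss
curves and checkpoints, and checkpoint save → load → infer is bit-identical
to pre-save inference.

## Known limitations

* The generator is a small reference CNN; a full attention-based SR
  backbone is a pluggable contract, not included.
* Critic families mirror the named architectures structurally (style and
  width parameterization), without weight-level equivalence to the
  originals.
* LPIPS with the seeded random extractor is a deterministic stand-in;
  values are not comparable to pretrained-backbone LPIPS numbers.
* The Bayesian network over hyperparameters is an explicit input; this
  package does not learn graph structure from trials.
* `f_perf` assumes discrete (or discretized) hyperparameter assignments;
  continuous hyperparameters must be binned by the caller.
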