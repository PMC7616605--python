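# Methods

This note documents the models, simulator and numerical choices behind
`videoaf`, in the spirit of a model-description appendix: what is computed,
under which assumptions, and where the genuinely open design choices were
made.

## The autofocus problem

A camera with a tunable lens exposes one control, the normalised focal
power f ∈ [0, 1].  At each video frame there is an (unknown) optimal focal
power f\* that brings the observed patch into sharpest focus; both the
scene and f\* drift over time.  A contrast-based autofocus policy sees only
the image content at its current f and must keep |f\* − f| small.  Policies
here act on a discrete step grid: each frame they move f by one of
{−h, 0, +h} with h = 0.05 (clamped to [0, 1]).

Performance is summarised by the mean absolute focal error (MAE, on the
0–1 focal scale) and the percentage of in-focus frames, a frame counting as
in focus when its error is below 0.1.  Frame 0 of an episode carries no
policy action (the initial f is drawn uniformly) and is not scored; every
later frame contributes its post-action error.

## Simulated focal-time scans

A *focal-time scan* is a time series of focal stacks — a dynamic scene
renderable at any f at every frame.  Scans are simulated from sharp frames:

* **Scene sources.**  Synthetic textures (three families: low-pass filtered
  noise, Gaussian blobs, and a grid-plus-noise family), a still image, or a
  directory of video frames.  Camera motion is emulated by stepping a crop
  rectangle across the source with a smooth random walk: integrated
  Gaussian velocity noise, velocity magnitude clipped to the `smoothness`
  bound (default 1 px/frame), positions reflecting at the valid-rectangle
  bounds.  The bound holds on the continuous trajectory; pixel extraction
  rounds to integer offsets.  Synthetic frames target mean 0.5 and standard
  deviation 0.15·contrast, so even full contrast rarely clips the [0, 1]
  range.
* **Defocus model.**  The observed frame at focal power f is the sharp
  frame blurred by an isotropic Gaussian with σ = σ₀·|f\* − f| pixels.  The
  blur gain σ₀ is drawn uniformly in [2, 8] per scan, so scans vary from
  forgiving to sharp focal falloff.  Below σ = 0.3 px the kernel is
  numerically degenerate and the sharp frame is returned unchanged; this
  also defines the metric's blind zone |f\* − f| < 0.3/σ₀ inside which
  contrast carries no focal information.  Blur borders are reflective,
  avoiding vignette artefacts at patch edges.  This is an idealised blur —
  no depth-dependent point-spread function, no bokeh shape, no noise.
* **Optimal-focal-power walk.**  f\* follows a reflected Gaussian random
  walk with per-step standard deviation 0.01 (configurable), slow relative
  to the h = 0.05 action step so tracking is feasible.  Episodes default to
  200 frames, i.e. a 10-second clip at 20 fps.
* **Timing.**  The action chosen from the observation at frame t adjusts f
  before frame t+1 is rendered — one step of actuation latency, no lens
  settling model.  The reward r = −|f\* − f| uses the post-action f and the
  new f\*, the standard control formulation.

Scans can be materialised to disk as a `scan.yaml` plus per-frame focal
stacks on a power grid, and reloaded with nearest-power rendering; a
`stack.csv` reader ingests externally captured focal stacks.  Ground truth
for a stack is the focal power maximising mean gradient magnitude on the
observation patch (global search; ties to the lowest power).

For snapshot-mosaic hyperspectral frames, grayscale reconstruction averages
each 4×4 mosaic tile (one full spectral sample set) into one super-pixel,
e.g. 2048×1088 → 512×272.

## Focus metrics

Both metrics operate on a 32×32 patch, by default centred on the detected
content area (intensity-threshold mask, largest connected component,
centroid; geometric centre fallback for full-content frames — a deliberate
simplification of dedicated endoscopic content-area detectors, with a
manual override).

* **MGM** — mean over pixels of the Sobel gradient magnitude
  √(I_x² + I_y²), standard 3×3 kernels, reflective borders.  The magnitude
  is conventionally defined with the square root and that is the default;
  a squared-gradient variant is exposed as an option since both appear in
  the focus-measure literature.  MGM is zero exactly on constant patches
  and scale-equivariant.
* **MLR** — mean over pixels of max((G_σI+1)/(I+1), (I+1)/(G_σI+1)) with a
  Gaussian blur G of scale σ = 4.  Always ≥ 1, equal to 1 only when
  blurring leaves the patch unchanged.  The "+1" offsets fix the dynamic
  range, so the intensity scale they apply at matters: the default applies
  them to [0, 1] floats; `intensity_scale=255` reproduces 8-bit-count
  behaviour.  The choice changes the score's numeric range but not its
  ordering-in-blur behaviour.

## Policies

* **Fixed** — never moves; the clinical status quo.
* **Modified hill-climber** — continue in the previous direction
  d_prev = sign(f_t − f_{t−1}) while the metric improved and f is
  interior; otherwise reverse:
  f_{t+1} = f_t + d_prev·h if 0 < f_t < 1 and φ_t > φ_{t−1}, else
  f_t − d_prev·h (clamped).  Unlike a textbook hill climber it never
  stops — necessary in a drifting environment.  At episode start d_prev is
  initialised to +1 and the previous metric to −∞ (sign(0) = 0 would
  freeze the rule; a fixed convention keeps behaviour deterministic).
* **Learned scalar-state policy** — a Q-network (MLP, two hidden layers of
  256 rectified units, 3 outputs) over the state of the N = 8 most recent
  (φ, f) pairs, ordered newest-first; histories shorter than N repeat the
  earliest pair so the input dimension is fixed from the first frame.
  Action selection is greedy (ε-greedy during training), ties breaking to
  the lowest action index (−h) for determinism.
* **End-to-end CNN policy** — replaces φ with an 8-logit patch encoding
  from 4 stride-2 convolutions of 8 3×3 filters (kernel size is a package
  choice; unspecified upstream).  After four stride-2 stages a 32×32 patch
  leaves a 2×2×8 map, compressed to 8 logits by spatial global averaging.
  At inference only the newest patch is encoded; previous encodings are
  cached in the agent state.

### Metric normalisation in the learned state

The absolute scale of MGM/MLR varies by an order of magnitude across
textures while carrying no focal information.  The learned policies
therefore support a running min–max normaliser: φ is mapped to
(φ − min)/(max − min) over the extrema seen so far in the episode (0.5
before any spread exists).  Raw values are the historical formulation and
remain available (`normalise_metric=False`); the desk-scale preset enables
normalisation because without it a policy trained on one texture family
does not transfer to a held-out family, which the built-in train/validate
split requires.

## DQN training

Standard deep Q-learning: uniform experience replay (FIFO), ε-greedy
exploration decaying exponentially 1.0 → 0.1, an EMA target network
(target ← β·online + (1−β)·target, β = 0.005, every update), discount
γ = 0.99, smoothed-L1 TD loss and RMSProp.  "RMSProp momentum 0.95" is
implemented as the squared-gradient decay constant ρ = 0.95 (no heavy-ball
term).  Scan end is treated as terminal for bootstrapping.  Unstated
details follow common DQN practice and sit in config: batch size 64, one
gradient update per environment step, warm-up 1000 transitions,
gradient-norm clip 10.  A divergence guard aborts with a diagnostic if the
mean |Q| on a batch exceeds a configurable bound.

Two presets:

* **paper scale** — replay 2.5×10⁶, ε horizon 2×10⁶ experiences, learning
  rate 1×10⁻⁵, γ = 0.99: the full-scale recipe, impractical on a desktop
  CPU.
* **desk scale** — 10⁵ experiences total (≈500 episodes over ≥50 distinct
  scans), replay sized to the run, ε horizon 80% of the run (preserving
  the full-scale ratio), learning rate 1×10⁻³, and a shorter credit
  horizon (γ = 0.8, ~5 effective steps).  The rate is raised because
  total weight displacement scales with rate × steps; at 1/25 of the
  experiences the full-scale rate leaves the network essentially at
  initialisation.  The discount is shortened because with γ = 0.99
  (100-step horizon) the action values of near-optimal states differ by a
  fraction of a percent of their magnitude — resolvable with millions of
  updates but not with 10⁵; a horizon matched to the tracking timescale
  (the f\* drift forces a correction every ~5 frames) preserves the
  control problem while making it learnable at this budget.  Runs in a
  few CPU-minutes.

Two stabilisation features, both optional and off at paper scale:

* **Best-snapshot selection** (`eval_every`): periodically the greedy
  policy is probed on a handful of held-aside episodes whose initial focal
  powers are spread across [0, 1], and the best-scoring weights seen are
  returned instead of the final ones — the usual guard against
  late-training policy churn.  With `probe_target` (desk default) the EMA
  target network is probed and snapshotted rather than the raw online
  network; its averaged weights give a steadier greedy policy.  The desk
  preset probes every 2500 steps on 8 episodes.
* **Learning-rate decay** (`lr_end`): optional exponential decay of the
  RMSProp rate over the run, for final-precision polishing.

One behavioural convention matters at inference: with the running
normaliser, an episode's first state has no metric spread and is therefore
degenerate (all normalised values 0.5).  If the greedy action there is
"stay", the state never changes and the policy is frozen — a deterministic
fixed point.  Learned policies therefore take a single probing +h step on
the first frame of an episode (`probe_start`), the exact analogue of the
hill-climber's d_prev = +1 start convention.

For the end-to-end variant, replay stores one patch per step and
reconstructs N-frame windows on sampling (padding at episode starts
matches the inference-time state exactly); the encoder is run on all N
window patches per update and receives gradients from each, while acting
encodes only the newest patch.

Training is deterministic given the seed: network initialisation,
exploration, replay sampling and per-episode environment seeds all derive
from one `SeedSequence`.

## Train/validation split and the desk-scale study

Training scans are synthetic-texture sources (filtered-noise and blobs
families) with crop-walk motion; held-out evaluation scans are still-image
walks over the disjoint grid-plus-noise family — so evaluation never sees
a training texture, mirroring a train-on-video / validate-on-other-domain
protocol.  The desk-scale study trains the MGM-state policy for 10⁵
experiences and compares it against the fixed policy and both hill
climbers on 20 held-out scans, with a paired two-sided Wilcoxon
signed-rank test over per-scan MAEs (the choice of paired nonparametric
test is this package's; alternatives exist).

What the synthetic generator does *not* emulate: imaging noise, dynamic
scene content (moving subjects), exposure changes, chromatic effects and
physically based defocus.  Passing desk-scale tests therefore demonstrates
correct mechanics and the claimed orderings under idealised conditions,
not clinical performance.

## Numerical choices and degenerate inputs

* Blur below σ = 0.3 px returns the sharp frame (documented threshold).
* All frames are float64 in [0, 1]; integer inputs are normalised by their
  dtype maximum, colour inputs reduced by an unweighted channel mean.
* Q-value ties break to the lowest action index; the Wilcoxon test is
  skipped (NaN) for identical per-scan scores; ground-truth ties in focal
  stacks go to the lowest power.
* Trajectory smoothing (window 5, visualisation only) is a centred moving
  average whose window shrinks symmetrically at the series ends, so the
  length is preserved and no phase shift is introduced.
* Checkpoints are single-file `.npz` archives with a versioned JSON
  header.

## Known limitations

* The Gaussian defocus model ignores depth-of-field asymmetries; more
  rigorous defocus simulation would change the metric-vs-error curves
  quantitatively.
* The blind zone |f\* − f| < 0.3/σ₀ bounds every contrast-based policy's
  achievable error from below; with σ₀ near 2 it spans ±0.15.
* Desk-scale DQN training is ~4% of the full-scale experience budget;
  learned-policy scores here are not estimates of full-scale performance.
* The content-area finder is an intensity-threshold centroid, adequate for
  circular vignettes but not a general surgical-field detector.
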