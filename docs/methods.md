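# Methods

This note records the modelling choices behind `kinvae`: what the synthetic
cohort generator does and does not emulate, how the kinematic features are
defined, how the supervised VAE is trained and evaluated, and the numerical
decisions a user re-deriving results should know about.

## 1. Synthetic cohort generator

### What it emulates

The generator reproduces the *design* of a tablet-based card-dragging study:
two groups (ASD-like and TD-like) of `n_per_group` children (default 30),
each performing 25 tasks (5 difficulty levels × 5 tasks) with 5 drag
trajectories per task, finger position sampled at 40 Hz on a 1280 × 800
screen-unit canvas (origin bottom-left). Task geometry (card start near the
bottom, placeholder target near the top, chord length ≥ 300 units) is drawn
once per task and shared by all participants, as in a fixed test battery.

Two generation paths exist deliberately:

* **Trajectory path** (`generate_cohort`): every drag is simulated as a
  minimum-jerk reach s(τ) = 10τ³ − 15τ⁴ + 6τ⁵ along the start→target chord,
  optionally blended with a constant-velocity ramp (`profile_flat`,
  weight f/(1+f)), with two noise processes superimposed:
  multiplicative log-normal jitter on the path increments (amplitude
  `speed_jitter`, correlation length `jitter_corr` as a fraction of the
  samples; increments are renormalized so the finger still ends exactly on
  the target) and smooth lateral tremor orthogonal to the chord (`tremor`,
  screen units, pinned to zero at tap and lift). Movement duration is
  0.75 s × `duration_scale` × log-normal participant and trajectory
  jitter. This path exists to exercise the feature extractor on data with
  realistic speed/acceleration profiles.
* **Feature path** (`sample_feature_table`): per-task rows are drawn
  directly from a group-conditional multivariate normal over the 12
  features, with within-group variance split 30% participant intercepts /
  70% task noise and the group mean difference equal to the requested
  standardized effect sizes exactly. This path is the canonical input for
  model-level experiments because its statistical structure is controlled.

Default effect sizes (ASD-like minus TD-like, pooled-SD units): +1.5 on
`sdSpeed`, `MaxAcceleration`, `sdAcceleration`; −1.5 on `MaxSpeed`,
`MinAcceleration`; 0 elsewhere — i.e., the ASD-like group drags with more
variable speed, sharper acceleration peaks and harder decelerations, but
lower peak speed.

`latent_rank = r` switches the feature path to a low-rank covariance:
class-conditional variation (and the group-separation direction) is
confined to r orthonormal directions in feature space plus isotropic noise
of SD 0.15 (in the generator's standardized units). This is the testbed
for latent-dimensionality experiments. Note that in this mode the
*empirical* per-feature standardized effects deviate slightly from the
requested values, because per-feature within-group SDs are no longer 1.

### Trajectory-path calibration

The mapping from noise parameters to extracted-feature effects has no
closed form, so the ASD-like group's parameters are found numerically:
log-scale shifts of the five knobs (duration, jitter amplitude, jitter
correlation, tremor, profile flatness) are fitted by damped Gauss-Newton
least squares against the requested 12-dimensional effect vector, using
pilot simulations (48 virtual participants × 5 tasks × 3 trajectories per
evaluation) with common random numbers so paired contrasts are low-noise.
Requested contrasts get weight 2, null features weight 1.

With 5 knobs and 12 targets the match is necessarily approximate: across
seeds, the acceleration contrasts land near ±1.4–2.0 pooled SD, while
`sdSpeed` and `MaxSpeed` saturate around |0.6–1.1| — the jitter that
raises `sdSpeed` simultaneously raises its within-group variance, so the
standardized effect saturates. Signs are always correct, and collateral
effects appear on kinematically coupled null features (`MeanSpeed` falls
with `MaxSpeed`; tremor raises `DC`/`sdDC`). Quantitatively exact effect
sizes are available only on the feature path.

### What it does not emulate

No cognitive content (which card goes where): task correctness is an
i.i.d. Bernoulli flag (`incorrect_task_rate`). No touch pressure,
multi-touch, device physics, age/IQ covariates, or heavy-tailed /
non-stationary motor noise. Consequently, passing simulation tests shows
the *pipeline* recovers known structure at realistic sizes and noise
levels; it cannot certify performance on clinical data.

## 2. Feature extraction

Speeds are forward differences of position over the fixed 25 ms step — no
smoothing (configurable but off; smoothing would leak across the
segmentation boundary and blur the acceleration extremes the analysis
cares about). Acceleration is the signed derivative of scalar speed, so
deceleration is negative and `MinAcceleration` is informative; the
vector-acceleration magnitude would fold sign information away.

`MaxSpeed`/`MinSpeed`/`MaxAcceleration`/`MinAcceleration` are read as the
*mean of interior local extrema* of the series (strict sign changes of the
first difference), falling back to the global extremum for monotone
series; `peaks="global"` switches to plain global extrema. The ordering
MinSpeed ≤ MeanSpeed ≤ MaxSpeed is guaranteed only under the global
reading: with the local reading, noise-induced minima cluster near the
speed peak and the mean local minimum can exceed the mean speed.

Directional change (DC) is the absolute turning angle between successive
nonzero displacement vectors per unit time (rad/s), computed with
atan2(|cross|, dot) so collinear motion gives exactly zero; zero-length
displacements carry no direction and are skipped. STH is chord length /
path length ∈ [0, 1]. `MeanLength` is the mean Euclidean path length of
the task's trajectories; the trajectory *count* per task (the other
possible reading of "amount of trajectories") is recorded as metadata but
is not a model feature. Per-task rows are arithmetic means over the task's
trajectories; tasks flagged incorrect are dropped before extraction, and
degenerate trajectories (< 3 samples, zero path length, all-zero
displacements) are excluded with a logged warning rather than imputed.

## 3. Network and training

Architecture defaults: 12 → tanh(32) → {μ, log σ²} ∈ R^d; decoder mirrors
the encoder with a linear output (features are z-scored, so a linear
reconstruction head is the natural choice); predictor z → tanh(16) →
2-unit softmax. d = 10 for the dimension-selection run, d = 2 for the
final model. Optimizer: Adam, lr 1e-3, batch 64, 500 epochs (none of
these are dictated by the scientific design; all are config-exposed and
recorded in every artifact). Latent SD is parameterized through
log-variance with an exp transform, guaranteeing positivity without
constraints. Predicted probabilities are clamped to [1e-7, 1 − 1e-7]
inside the cross-entropy. A single-sigmoid predictor head is
config-selectable (`predictor_head="sigmoid"`); the two readings are
equivalent losses for two classes.

The whole network is plain numpy with hand-written backpropagation; the
test suite pins the gradients to central finite differences at 1e-4
relative error, and the KL closed form to 1-D quadrature at 1e-6. Training
is deterministic given (data, config, seed): weight init, batch order and
reparameterization draws all flow from one seeded generator. The logged
per-epoch `total` is computed as the sum of the three logged components,
so the decomposition is exact by construction, and a non-finite loss
raises a divergence error naming the epoch.

Prediction uses the encoder mean (no sampling noise) fed through the
predictor — sampling at prediction time would only add variance.

### Cross-validation

Stratified k-fold (k = 10) at the row level, matching a design where every
task row is an observation; each fold re-standardizes on its training rows
only. Row-level folds share participants between train and test, so the
reported accuracy includes participant-identity leakage; participant-
grouped folds (`by_participant=True`) are provided for the leakage-free
number. Neither is asserted as "the" protocol; the row-level default
mirrors the observation-as-input design.

## 4. Latent-space analysis

Latent positions are encoder means everywhere; a participant's position is
the arithmetic mean of their task positions. Dimension selection trains at
d = 10, runs PCA on the participant means, and keeps the smallest m with
cumulative explained variance ≥ 0.95 (floored at 2 so the downstream
bivariate analysis is defined).

Class Gaussians are diagonal, maximum-likelihood (divide-by-n variances)
with a 1e-6 variance floor, fitted by default to task-level points — the
distributions the KL regularization actually shapes. Assignment
posteriors are equal-prior density ratios computed in log space
(logsumexp), so extreme points underflow gracefully; posteriors always sum
to 1. The response curves report these normalized posteriors (the two
curves cross near 0.5); fitting- and plotting-level access to raw
log-densities remains available through `ClassGaussian.logpdf`.

Feature perturbation resamples the *raw* feature from
N(μ_f, σ_f) — empirical moments of the whole dataset by default
(per-group and per-participant scopes selectable) — then re-standardizes
with the model's training stats before encoding, keeping the sampling in
interpretable feature units. 100 draws per feature per participant;
displacement is the mean Euclidean distance from the participant's
unperturbed position. Density maps pool the perturbed *participant-mean*
positions into a normalized 2-D histogram.

Cross-seed consistency is measured by centered orthogonal Procrustes
(rotation/reflection, no scaling — the KL term pins the latent scale) on
matched participant configurations; the residual is reported relative to
the reference configuration's RMS radius.

## 5. Problem sizes used in the checks

The simulation-level tests run at the full default design (60 participants,
1,500 rows): 10-fold CV at d = 10, three seeds for the dimensionality
experiment, 100 perturbation draws per feature, 50-point response grids.
Unit tests use scaled-down cohorts (e.g. 20 + 20 participants × 5 tasks)
where the property under test does not depend on scale. The
trajectory-path calibration check uses 100 participants per group and
verifies signs and magnitude bands rather than exact values (§1).

## 6. Known limitations

* The generator's trajectory realism is unverifiable against clinical
  data; it is calibrated only to the qualitative feature-effect pattern.
* Standardized effects on the trajectory path are approximate (§1); exact
  effect-size control requires the feature path.
* Row-level CV overstates generalization to unseen children (participant
  leakage); use participant-grouped folds for that question.
* The latent-dimension selection protocol assumes the d = 10 model
  concentrates class-relevant variation in a few directions; with very
  weak group structure the PCA spectrum flattens and the floor of 2 binds.
* Local-extrema peak features are sensitive to sampling-rate and noise
  conventions; cross-study comparisons should fix the `peaks` convention
  explicitly.
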