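# kinvae

Supervised variational-autoencoder analysis of touchscreen drag kinematics
for digital phenotyping of motor patterns — distinguishing an ASD-like from
a typically-developing (TD-like) group of children from how they drag cards
across a tablet screen.

## Who this is for

Researchers in computational psychiatry / digital phenotyping who want a
reproducible, end-to-end implementation of the "kinematic features → latent
variable model → feature-level interpretation" workflow: from raw 40 Hz
finger trajectories to per-feature statements like *"higher acceleration
variability moves a child toward the ASD side of the latent space."*
Because clinical drag-trajectory datasets are rarely shareable, the package
ships a first-class synthetic cohort generator that emulates the study
design (30 + 30 participants, 25 tasks each, 5 drag trajectories per task)
with controllable between-group effect sizes.

## The model

Each task is summarized by 12 kinematic features
(`MeanSpeed, MaxSpeed, MinSpeed, sdSpeed, MeanAcceleration, MaxAcceleration,
MinAcceleration, sdAcceleration, STH, DC, sdDC, MeanLength`) extracted from
its drag trajectories. A variational autoencoder with a predictor head is
trained on the z-scored feature rows x ∈ R¹²:

* **Encoder** q(z|x): tanh hidden layer → latent mean μ and SD
  σ = exp(½ log σ²), with z = μ + σ ⊙ ε (reparameterization trick).
* **Decoder** p(x|z): mirror architecture, linear output x̂.
* **Predictor**: z → tanh(16) → 2-unit softmax giving p(ASD | z).

The loss is the equally weighted sum

    L = MSE(x, x̂) + KL(q(z|x) ‖ N(0, I)) + BCE(y, p)

with the diagonal-Gaussian KL in closed form
½ Σⱼ (μⱼ² + σⱼ² − 1 − log σⱼ²). Performance is assessed by stratified
10-fold cross-validation. Downstream, each class's latent points are fitted
with a diagonal Gaussian; the equal-prior density ratio gives an assignment
posterior (p_TD, p_ASD) for any latent point, and Monte-Carlo resampling of
one feature at a time (100 draws from that feature's empirical normal,
fᵢ ~ N(μ_fᵢ, σ_fᵢ), all other features held fixed) measures how much each
feature can move a participant across the latent space.

## Worked example

```python
from kinvae import CohortConfig, NetworkConfig, VAEClassifier, sample_feature_table

cohort = CohortConfig(seed=7)          # 30 + 30 participants, 25 tasks each
table = sample_feature_table(cohort)   # 1,500 x 12 feature rows
model = VAEClassifier(table, NetworkConfig(latent_dim=2))
results = model.fit(seed=0)
print(results.summary())
cv = model.cross_validate(k=10, seed=7)
print(cv.summary())
```

prints

```
Supervised VAE results
============================================
latent dim            2
encoder hidden        [32]
predictor hidden      16
epochs                500
batch size            64
learning rate         0.001
n rows                1500
final recon loss      0.91616
final KL loss         0.31193
final predictor loss  0.43721
final total loss      1.66529
training accuracy     0.9693
k-fold cross-validation
----------------------------------
fold  1: accuracy = 0.9667
...
fold 10: accuracy = 0.9733
----------------------------------
mean = 0.9600  sd = 0.0166  (k = 10)
```

The default cohort separates the groups by |1.5| pooled SD on five features
(higher `sdSpeed`, `MaxAcceleration`, `sdAcceleration`; lower `MaxSpeed`,
`MinAcceleration` in the ASD-like group), and the model recovers that
separation at 96% held-out accuracy. The final losses say the model spends
most of its budget reconstructing the 7 null features (recon 0.92 on
z-scored data) while the latent space stays close to the prior (KL 0.31)
and the predictor is confident (BCE 0.44 → mean p ≈ 0.9 for the true
class).

Latent analysis continues from the fitted results:

```python
from kinvae import (project_latent, fit_class_gaussians, feature_response_curve,
                    perturbation_displacements)

proj = project_latent(results, table)           # encoder means per task/participant
g_td, g_asd = fit_class_gaussians(proj)         # diagonal class Gaussians
curve = feature_response_curve(results, table, g_td, g_asd, "MaxAcceleration")
disp = perturbation_displacements(results, table, n=100, seed=0)
```

`curve.p_asd` rises monotonically with `MaxAcceleration` (the feature pushes
participants toward the ASD Gaussian) and `disp` ranks features by how far
their resampling moves participants in latent space.

A command-line interface mirrors the library
(`kinvae simulate | extract | train | cv | analyze | curves | run`); `kinvae
run --out results/ --seed 17` executes the whole pipeline, including
PCA-based latent-dimension selection (train at d = 10, keep the smallest
dimensionality explaining ≥ 95% of participant-mean variance, retrain) and
writes plots plus a JSON report.

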