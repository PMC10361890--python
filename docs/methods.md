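# Methods

This note records what the package models, the parameters that matter, and
the design choices made where more than one defensible option existed.

## Problem setting

Gastric adenocarcinoma is subtyped by the Laurén classification into
intestinal (gland-forming, cohesive) and diffuse (poorly cohesive,
scattered-cell) morphologies; diffuse type is conventionally associated
with worse prognosis, but the classification has high interobserver
variability.  The pipeline trains a slide-level binary classifier from
weak labels only (no tile annotations), exposes its per-tile evidence, and
asks whether the model's subtype stratifies survival — alone and combined
with the pathologist's call.

## Synthetic slides

Slides are rendered through a two-stain Beer–Lambert model: every pixel
carries hematoxylin/eosin concentrations (c_H, c_E), and
RGB = 255·10^(−M·c) with M the canonical H&E optical-density matrix.
Because the image formation is exactly the physics Macenko normalization
assumes, stain estimation can be tested against ground truth.

The slide area is divided into 256-µm blocks (matching the tessellation
grid, so each tile has an unambiguous ground-truth class).  Blocks are
grown as contiguous blobs of five kinds:

* **neutral stroma** — eosin-dominated texture with granular variation and
  sparse stromal nuclei; statistically identical in both classes;
* **signal** — the class texture: *intestinal-like* ring/gland primitives
  (annuli with cleared lumina) or *diffuse-like* scattered small nuclei;
  distinguishable by second-order and morphometric statistics;
* **background** — near-white; rejected by QC;
* **blur** — low-pass-filtered tissue emulating out-of-focus regions;
  rejected by QC;
* **mucin** — pale, nearly featureless pools; rejected by QC.

Per-slide stain intensity varies by ±15% per channel, which Macenko
normalization must undo.  Defaults: 1536×1536 µm slides (6×6 tiles) at
mpp = 256/224 ≈ 1.143 µm/px, signal fraction 0.3 of tissue, background
0.2, blur and mucin 0.05 each.  The slide size is a desk-scale miniature:
large enough for a meaningful bag (~25 QC-passed tiles), small enough that
a 200-case cohort renders in about a minute.

What the generator does **not** emulate: nuclei-level realism, intratumoral
heterogeneity gradients, pen marks and scanner artifacts, mixed-type
slides containing both class textures.  Passing tests therefore show the
pipeline's machinery is correct under its own assumptions, not that the
classifier would reach any particular performance on scanned tissue.

## Synthetic cohorts

Each case draws a latent subtype (diffuse prevalence 0.3, close to the
116:48 intestinal:diffuse ratio of the consensus-labelled training
cohort), a pathologist label (latent truth flipped with probability
`label_noise`, default 0.15, emulating interobserver discordance), and a
simulated model label (flipped with `model_label_noise`, default 0.3; see
the three-tier section).  Overall survival is exponential with hazard
`baseline_hazard × hazard_ratio^{diffuse}`; defaults 0.015/month (median
≈ 46 months for intestinal) and HR 1.46.  Censoring is independent
exponential, calibrated so a baseline-hazard subject is censored with
probability `censoring_rate` (default 0.3).  Cancer-specific survival
reclassifies a fixed 80% of deaths as cancer-caused (others become
censorings at the same time); disease-free survival multiplies event times
by U(0.5, 1).  Both are therefore bounded by OS, which is the only joint
structure assumed.

## Preprocessing

* **Tessellation**: non-overlapping 256-µm grid anchored at pixel (0,0),
  resampled to 224×224 px (effective 1.14 µm/px); partial edge tiles are
  dropped, not padded.
* **QC by edge quantity**: fraction of Canny edge pixels (σ = 1) on the
  grayscale tile; tiles below 0.02 are rejected.  Blank background, heavy
  blur and mucin pools all score ≈ 0; tissue scores ≈ 0.25.  The threshold
  is a config value, logged per run.
* **Macenko normalization**: OD = −log₁₀((I+10⁻⁶)/255); pixels with OD
  magnitude < β = 0.15 are transparent and discarded (the cut is on the OD
  norm — eosin absorbs almost no red light, so a per-channel floor would
  discard precisely the eosin-dominated pixels whose angle the method
  estimates); stain directions are the 1st/99th percentiles of the angle in
  the top-2 principal plane; concentrations are non-negative least squares
  (closed-form case analysis for two stains), rescaled at the 99th
  percentile to the target's maxima.  Hematoxylin is identified as the
  vector with the larger blue-channel OD.  Per slide, one reference is
  fitted on a pooled pixel sample and all tiles are mapped to the package
  default reference.
* **Augmentation** (training-time only): seeded rotation in [0°, 360°) and
  vertical flip with probability ½; right-angle rotations are exact.

## Stand-in feature extractor

A frozen pretrained network is out of scope; its *contract* — an n_tiles ×
d matrix, deterministic, no cross-tile state — is filled by a handcrafted
extractor: 66 per-tile statistics (channel moments on ImageNet-standardized
channels, gray/gradient/orientation histograms, GLCM contrast/homogeneity/
energy/correlation at 1 and 3 px, gradient energy, and hematoxylin-blob
morphometry — stained-area fraction, hole fraction after fill-holes, object
count, Euler number, object sizes, eccentricity).  The morphometric block
is what separates ring-shaped glands from scattered nuclei; intensity
statistics alone leave the two morphologies nearly collinear.  Statistics
are normalized by a median/IQR scaler calibrated once on the first batch
and frozen (the analogue of a network's frozen normalization constants),
clipped to ±4 so no single extreme tile dominates a bag, and pushed
through a fixed-seed Gaussian projection to d (2048 by default; the test
and acceptance configuration uses d = 64 for speed).

## attMIL model and training

Gated attention per the standard formulation: h_k = relu(W_e x_k),
a_k ∝ exp(wᵀ(tanh(V h_k) ⊙ σ(U h_k))), z = Σ a_k h_k, linear classifier on
z.  Hidden sizes h = 256, a = 128.  Ties at P(diffuse) = 0.5 classify as
diffuse (fixed, documented convention).

Training: AdamW (lr 10⁻³, weight decay 10⁻⁴), batches of 16 bags, ≤ 32
epochs, inverse-frequency class weighting, seeded subsampling of bags above
512 tiles, early stopping (patience 5) on a 15% stratified validation
split with best-parameter restore.  Two additions address a failure mode
specific to attention training:

* **Attention-weighted instance loss.**  The bag cross-entropy saturates
  long before the attention head organizes, leaving attention frozen along
  an arbitrary, initialization-dependent direction while the classifier
  reads the residual bag composition.  Adding
  λ·Σ_k a_k·CE(inst(h_k), bag label) with a separate linear instance head
  (λ = 0.5) keeps a sustained gradient on the attention: stroma tiles occur
  identically in both classes, so their instance loss cannot fall below
  ≈ log 2, and attention migrates to tiles that genuinely support the slide
  label — for both classes.  This is a differentiable analogue of the
  instance-clustering losses used in clustering-constrained attention MIL.
  The instance head also provides the per-tile class scores used by the
  heatmaps and top-tile reports.
* **Seeded restarts.**  A minority of initializations still converge to a
  non-localizing basin; that basin is identifiable by its higher total
  training loss.  Training runs 4 restarts and keeps the lowest-loss model.
  All restart seeds derive from the run seed; training is bit-reproducible.

Evaluation is patient-level stratified five-fold cross-validation (every
case predicted exactly once, out of fold); AUROC is computed in the
Mann–Whitney form (ties count ½).  The quality gate for proceeding to a
final model is mean fold AUROC ≥ 0.85 **and** mean − SD ≥ 0.80; the
"lower bound" is read as mean minus one SD (the worst-fold reading is also
computed and logged, but the gate uses mean − SD).  The deployed model is
a refit on all cases; a fold-model ensemble is available behind a flag.

## Survival analysis

Endpoints are truncated at 60 months (events after the horizon become
censorings at 60).  Kaplan–Meier uses the product-limit estimator with the
usual tie convention (censorings just after events).  Group comparisons
are pairwise log-rank tests at α = 0.05 with no multiplicity correction.
Cox proportional-hazards models use Efron tie handling by default
(Breslow available), Wald 95% CIs; constant covariates are rejected and
non-convergence is flagged, not hidden.  KM/log-rank estimation is
delegated to lifelines and Cox fitting to statsmodels; both are
cross-checked in the tests against hand product-limit computations, a hand
hypergeometric log-rank sum, and a brute-force grid maximizer of the Efron
partial likelihood.

## Three-tier stratification and its simulation

The agreement workflow: pathologist-intestinal cases go to the *best*
prognosis group without consulting the model; pathologist-diffuse cases
split into *worst* (model agrees) and *intermediate* (model disagrees).
Mixed-type cases are excluded from stratification with a logged count.

For the cohort-level ordering experiment the model label is simulated (the
generator's `model_label_noise`), since the quantity under test is the
survival ordering, not the image classifier.  With hazard tied to the
latent class, each stratum's survival is determined by its diffuse
fraction; with prevalence p = 0.3 and pathologist noise ε_p = 0.3 the
fractions are 0.155 (best), ε_m (intermediate) and 1−ε_m (worst), so the
expected ordering best ≥ intermediate ≥ worst requires
ε_m ∈ (0.155, 0.5).  The default ε_m = 0.3 mirrors the pathologist's noise
level from inside that interval.  The replicate size (n = 5000) is chosen
so the 60-month KM sampling error (≈ 0.01–0.02) resolves the smallest
planted gap (≈ 0.036 in survival probability); at realistic cohort sizes
(~300) the best/intermediate gap is within KM noise and the ordering is
only a tendency.

## Problem sizes

The test suite trains on a 40-case cohort of 4×4-tile slides; the
acceptance computation uses 200 cases of 6×6-tile slides with d = 64
features (about 25 retained tiles per bag), five folds, 4 restarts.  Null
calibration uses 200 replicate log-rank cohorts (n = 200) and three label
permutations of the 200-case CV; the stratification experiment uses 50
replicates of n = 5000.

## Known limitations

* The texture generator makes the two classes nearly separable; AUROC on
  it says nothing about performance on scanned tissue.
* The stand-in extractor is calibrated on its first batch; two extractors
  calibrated on different cohorts produce different (internally
  consistent) feature spaces.
* Attention localization depends on the instance-loss pressure; with
  λ = 0 the attention head is decorative on easy bags and settles along an
  arbitrary direction.
* Survival generation is proportional-hazards by construction, so Cox
  recovery tests validate the fitting machinery, not the assumption.
* Mixed-type morphology (both textures on one slide) is not simulated,
  matching the analysis that excludes mixed-type cases from training.
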