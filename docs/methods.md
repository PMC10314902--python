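# Methods

## The model

`icufusion` predicts in-hospital mortality for ICU patients from two
modalities: a bedside chest radiograph and the clinical parameters charted
during the first 48 hours of the stay.  Both modalities are reduced to
sequences of latent tokens of a shared width *D* and fused by a single
transformer encoder:

- **Image branch.** The grayscale radiograph is resized, replicated to three
  channels and normalised with ImageNet channel statistics, split into
  *P* × *P* patches, linearly embedded and passed through a pre-norm
  transformer encoder with learned positional embeddings.  This yields
  *N* = (H/P)(W/P) image tokens (576 at the full 384 × 384 / patch-16
  geometry; 16 in the CPU-scale 64 × 64 study configuration).  The backbone
  has no internal class token — classification is owned by the fusion stage.
- **Clinical branch.** The per-stay event stream is gridded onto hourly bins
  over *T* = 48 hours (last observation per bin wins), forward-filled, and
  missing-from-the-start cells take the schema's pre-specified impute
  default.  Categorical items (the three Glasgow Coma Scale sub-scores) are
  one-hot expanded and continuous items standardised, giving an *F* × *T*
  feature matrix (*F* = 27 for the packaged 15-item schema).  A learnable
  linear map projects each hourly feature vector to one token, so *M* = *T*
  = 48 clinical tokens.
- **Fusion.** Image tokens then clinical tokens are concatenated, *N* + *M*
  learnable position tokens are added element-wise, a learnable CLS token is
  prepended, and the sequence runs through a multi-head self-attention
  encoder.  A one-hidden-layer GELU MLP with a sigmoid reads the CLS output
  and returns the predicted probability of in-hospital death (labels code
  1 = died, 0 = discharged alive; the output is a death risk so that the
  binary cross-entropy pairs the positive term with y = 1).

Unimodal regimes reuse the identical network: the clinical-only regime feeds
the canonical zero image, the radiograph-only regime zeroes the clinical
feature matrix before projection.  Zeroing happens **in normalised space**,
so "image absent" is one fixed input regardless of normalisation constants,
and the clinical-only forward pass is bit-equivalent to the combined pass on
a zeroed image (a property the test suite asserts).

## Clinical parameter schema

The packaged schema lists 17 routinely charted parameters with type, unit,
population mean/SD, fraction of stays with no recorded value, and the
impute default (e.g. FiO₂ 0.21, GCS eye/motor/verbal 4/6/5, heart rate 86,
pH 7.4, temperature 36.6 °C).  Two items — capillary refill rate and the
GCS total — are recorded for no stay at all and are dropped before
modelling, leaving 15.  Dropping is driven by the recorded
`missing_fraction == 1`, so the same rule applies to any user schema.

## Training protocol

Binary cross-entropy is minimised with AdamW (decoupled weight decay 0.01,
applied to matrix-shaped parameters only) under per-epoch cosine annealing.
The full-scale defaults mirror the reference recipe (200 epochs,
5 × 10⁻⁶ → 1 × 10⁻⁷); the CPU-scale synthetic study uses its own scale
(below).  Three regimes are trained:

1. clinical-parameters-only (images always zeroed),
2. radiographs-only (clinical features zeroed),
3. combined, which **resumes from the clinical-only checkpoint with the
   highest validation AUROC** and trains with *vision dropout*: each
   sample's image is independently replaced by the zero image with
   probability p_VDO = 0.30 during training, preventing the fusion encoder
   from relying exclusively on the vision backbone.

Vision dropout is interpreted as per-sample whole-image zeroing: the stated
purpose (robustness to a missing modality) is only exercised by removing the
modality outright.  An i.i.d. per-entry variant remains available via
`FusionConfig(vdo_mode="pixel")`.

Two engine-level choices stabilise this protocol at small scale:

- **Unused-branch freezing.** During a unimodal phase the zeroed branch is
  frozen: its input is identically zero, so any parameter update there is
  noise fitted through the shared encoder, and (at random initialisation,
  with no pretrained weights) that drift measurably degrades the combined
  phase that later resumes from the clinical-only checkpoint.  The combined
  phase itself trains every parameter.
- **EMA checkpoints.** The per-epoch checkpoint is a per-step exponential
  moving average of the weights (decay 0.995), and validation AUROC is
  computed on that state.  Raw weights at this scale overfit within a few
  epochs and the small validation split makes best-epoch selection noisy;
  the EMA state gives smooth validation curves so checkpoint selection is
  well conditioned.  Setting ``TrainConfig(ema_decay=0)`` restores raw
  checkpoints.

Checkpoints are indexed by validation AUROC each epoch; ties resolve to the
earliest epoch.  Cohorts are split 72% / 8% / 20% at the patient level
(every radiograph of a patient lands in one split), with outcome-stratified
randomisation; an external `patient_id,set` CSV can override the random
split.

## Evaluation

- **AUROC** is the Mann–Whitney probability (ties count ½), checked in the
  tests against exhaustive pair counting and scikit-learn.
- **AUPRC** is average precision (no trapezoidal interpolation, which is
  optimistic on sparse positives).
- The **operating point** maximises Youden's criterion
  (sensitivity + specificity) over observed scores, predicting positive at
  score ≥ threshold; criterion ties resolve to the lower threshold (higher
  sensitivity).  Sensitivity, specificity and PPV are reported there.
- **Uncertainty** is a percentile bootstrap over sample-level redraws
  (10,000 by default; single-class resamples are redrawn).  The Youden
  threshold is refit inside each resample by default; a fixed-threshold
  mode exists.
- **Model comparisons** use a paired bootstrap: the same redraw indices are
  applied to both score vectors and the two-sided p-value is
  2·min(frac(Δ\* ≤ 0), frac(Δ\* ≥ 0)), floored at 1/n_boot.  DeLong's
  analytic test is provided as a cross-check, not the primary.
- The **robustness experiment** rescoring: for each k in {2,4,…,14} and each
  repetition, a k-subset of the 15 items is drawn uniformly without
  replacement, every encoded feature row derived from those items is zeroed
  across the whole test set (no re-imputation — the model sees "missing as
  zero", exactly what a deployed model would receive), and AUROC plus PPV at
  that run's Youden threshold are recorded.  Images are always provided.

Evaluation is per paired (radiograph, clinical) sample; per-patient
aggregation can be layered on top by the caller if needed.

## Synthetic cohort generator

The generator is the package's study bed, not a fixture: each patient
carries independent latent severities u_img, u_cp ~ N(0,1) and a label
drawn Bernoulli(σ(β₀ + β_img·u_img + β_cp·u_cp)).

- **Images**: a smooth background (mediastinal band + coarse smoothed
  noise) plus a central Gaussian opacity whose amplitude is strictly
  increasing in u_img (0.10 + 0.30·Φ(u_img)), with pixel noise of SD 0.03.
- **Clinical series**: per-item AR(1) processes (lag coefficient 0.8)
  around patient-level baselines drawn from the schema's population
  mean/SD; heart rate and respiratory rate shift up and oxygen saturation
  down by 0.9 SD per unit u_cp, and the GCS sub-scores degrade ordinally
  with u_cp.  Hourly values are dropped independently at `missing_rate`
  (default 0.30), and two items are never observed, exercising the
  17 → 15 exclusion downstream.
- **Defaults**: n = 2,000 patients, 64 × 64 images, β_img = β_cp = 1.4,
  β₀ = logit(0.16) (the real cohort's death prevalence; with nonzero
  effects the marginal prevalence rises to ≈ 25%), one radiograph per
  patient.  With these effect sizes the latent oracles land around 0.75
  (either single modality) versus 0.87 (joint), leaving a wide margin
  for the fused model to demonstrate superiority.
- `oracle_auc` scores the true latents against the drawn labels — the
  ceiling a model restricted to a modality can approach.  Everything is a
  pure function of the config seed.

What the generator does **not** emulate: radiograph anatomy, inter-item
physiological correlation beyond the shared latent, informative
missingness, multi-modal time alignment, or MIMIC's marginal
distributions beyond the schema's mean/SD columns.  Passing tests
demonstrate that the architecture and protocol recover planted cross-modal
signal under controlled conditions — not clinical performance.

## Study scale and numerical choices

The acceptance-level study trains at CPU scale: width D = 64, depth 2 in
both encoders, 4 heads, encoder MLP ratio 2, 64 × 64 images (N = 16).  The
unimodal regimes converge within about three epochs at this scale, so they
get 3 epochs each at AdamW 1 × 10⁻³ → 1 × 10⁻⁴ cosine and the combined
phase 12 epochs at 1.5 × 10⁻³ → 1 × 10⁻⁴, batch 16 throughout.  The engine computes in float32 (float64 switchable for
gradient checking; all gradients are verified against central finite
differences in float64).  Other numerics:

- BCE guards logs with ε = 10⁻¹²; probabilities are produced by a
  numerically stable tanh-form sigmoid, so outputs are strictly inside
  (0, 1).
- Feature standardisation clamps near-zero scales (constant features
  encode to zero rather than exploding).
- Softmax subtracts the row max; LayerNorm uses ε = 10⁻⁵.
- Binning uses 0-based half-open hour bins [t, t+1); events at or after
  T hours are discarded; within a bin the event latest in time wins, with
  input order breaking exact ties.
- Unobserved cells are NaN behind an explicit boolean mask and constructing
  a grid with an in-band "observed" number under a False mask is an error.

## Known limitations

- The vision backbone is randomly initialised; ImageNet-pretrained weights
  can be injected by loading a state dict with matching geometry, but no
  download is performed.
- The robustness experiment masks encoded features to zero; re-imputing
  masked items to their defaults is a different (also defensible) protocol
  and would need a one-line change where masking is applied.
- Bootstrap CIs treat samples as exchangeable; with several radiographs per
  patient a cluster bootstrap would be more conservative.
- Training at full scale (384 × 384, 200 epochs) is out of reach of the
  NumPy engine; the package's claims are about the method's behaviour at
  the synthetic study scale.
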