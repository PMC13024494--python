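# Methods

`eistrat` is a simulation-backed re-implementation of a data-centric study
design: does the *consistency* of training data — agreement between a
participant's subjective affect label and the affect actually expressed in
their facial frames — drive differences in binary valence/arousal
recognition, when training cohorts are stratified by emotional intelligence
(EI)? Because the original facial dataset is private, every input table is
generated synthetically with the statistical structure the analysis assumes,
and the package's claims are about the *machinery*: exact protocol counts,
oracle-verified statistics, calibrated error rates, and qualitative pattern
reproduction at desk scale.

## The generative model (`synthgen`)

**Cohort.** `n_participants` (default 44) receive EI scores drawn from
Normal(825, 150) clipped to [0, 1200], matching the scale of the 10-points-
per-response scoring scheme and a cohort centred near the High/Low boundary.
Each participant views one 6-minute stimulus video per circumplex quadrant
(HAHV/HALV/LAHV/LALV; 4 videos by default).

**Consistency.** The core latent quantity is a per-participant congruence
probability p(EI) — the chance that a frame's estimated affect sign agrees
with the participant's binary label. It is a logistic function of EI rising
from 0.55 to 0.95 around a midpoint of 700 (scale 150): nondecreasing by
construction, so High-EI participants supply cleaner training frames. These
four numbers are free parameters of the generator; they were chosen once to
give a Low-EI group with clearly noisier (but still usable) data and are
reported in every run manifest.

**Ratings.** Per video and dimension, a 7-point rating is neutral (4) with
probability 0.15, otherwise drawn from a discretized normal (SD 1.2 rating
points) centred on the quadrant's pole (6 for high, 2 for low). This
reproduces quadrant-consistent mean ratings with occasional opposite-pole
responses; the neutral mass is EI-independent.

**Frames.** Each video yields `frames_per_video` frames (default 300 — a
desk-scale stand-in for 6 min × 30 fps after validity filtering; large
enough that the top-100-per-dimension selection never starves). Per
dimension, a frame is congruent with probability p(EI); its |estimate| is
Beta(4, 2) when congruent and Beta(2, 4) when incongruent, so congruent
frames are stochastically larger in magnitude and low-magnitude frames are
intrinsically ambiguous. Estimates live in [−1, 1] by construction.

**Features.** Each frame gets a 14-dimensional vector: 3 coordinates loading
on the arousal estimate, 3 on the valence estimate (fixed sign-alternating
loadings, Gaussian noise SD 0.25), plus 8 pure-noise coordinates. Class
separability therefore scales with |estimate|; frames whose expressed sign
contradicts their label are *systematically* mislabeled for the classifier,
which is exactly the failure mode the selection procedure targets.

**HRV.** One row per participant × emotion condition; each variable follows
a two-way cell-means model with a group × emotion interaction of
configurable size keyed to a *true* EI cutoff (default 830) that the cutoff
scanner never sees — enabling recovery experiments. Replicate noise is
Gaussian (SD 1.0). No signal-level ECG simulation is attempted.

Every generator is a pure function of (config, seed), using independent
numbered RNG streams per table and a per-participant sub-seed for sessions.

## EI scoring and group cutoff (`ei`)

Scores are 10 points per correct response over 3 evaluation indices × 4
emotion categories × 10 stimulus instances (range 0–1200, 400 per index).
Candidate cutoffs — every 10 points between the 10th and 90th EI percentile
by default — are scored by the number of HRV variables whose group × emotion
interaction is significant at α = 0.05 in a two-way Type III ANOVA with
sum-to-zero contrasts (statsmodels OLS + `anova_lm(typ=3)`). The selected
cutoff maximizes that count subject to group imbalance ≤ 20% of the cohort;
ties break toward smaller imbalance, then the lower cutoff. Scores strictly
above the cutoff are High, at or below are Low. Per-participant HRV
replicates across conditions enter the ANOVA as independent observations (a
deliberate simplification: the two-way fixed-effects model has no
repeated-measures term).

The recovery experiment in the acceptance suite uses 60 participants with EI
~ Normal(700, 100), a true cutoff of 700, 12 HRV variables all carrying an
interaction of 0.8, and a 50-point candidate grid. The concentrated EI
distribution makes each grid step reclassify a meaningful fraction of the
cohort, which is what gives the significance-count curve a localized peak;
with a wide EI spread the curve plateaus and the balance tie-break, not the
physiology, decides.

## Labeling (`labeling`)

Ratings 1–3 → label 0, 5–7 → label 1 (provenance *response*); the neutral 4
takes the quadrant's pole on that dimension (provenance *weak*). No video is
dropped; each contributes one arousal and one valence label, propagated to
all of its frames as frame-level training labels.

## Selection and partitioning (`selection`)

Training data curation is two-stage per video: congruence filter (sign of
estimate matches label direction; exact zeros excluded as signless), then
the union of the top-100 frames by |arousal| among arousal-congruent and
top-100 by |valence| among valence-congruent. When the two top lists
overlap, next-ranked frames are appended alternately from each list until
200 per video is reached or supply is exhausted — guaranteeing the closed
forms 200/video and 800/participant whenever supply allows. Magnitude ties
break toward the lower frame index.

The fixed test set holds 2 High-EI + 2 Low-EI participants (seeded draw,
reused across all training configurations); the rest split 8:2 into
train/validation within strata keyed by participant-majority labels, never
splitting a participant. From the *unfiltered* test-participant pool, per
dimension and per (participant, video) cell: the unambiguous subset samples
6 frames uniformly from {congruent and |estimate| ≥ upper tertile}, the
ambiguous subset 6 from {incongruent or |estimate| < lower tertile} —
disjoint by construction, 96 frames per subset at the 4-participant shape.
Tertile cuts are computed within each cell; cells with fewer than 6
qualifying frames contribute all they have and are flagged. Uniform (rather
than top-6) sampling keeps the ambiguous stratum representative of its pool.

## Classifier (`classifier`)

A deliberately small stand-in for a pretrained vision backbone with parallel
heads: two tanh hidden layers (32, 16) shared by a one-logit classification
head and a linear regression head predicting the frame's continuous
estimate. The objective is L = L_BCE + λ·L_MSE with λ = 0.4;
inverse-frequency class weights (normalized to mean 1) address label
imbalance. Training is two-staged — heads only for 4 epochs at 3·10⁻⁴, then
everything for 6 epochs at 1·10⁻⁴ — with AdamW (weight decay 10⁻²), global
gradient-norm clipping at 1.0, and per-stage linear warm-up (3 epochs,
capped at stage length − 1) followed by cosine decay. The decision threshold
maximizes macro F1 on the validation set over a 0.2–0.8 grid in steps of
0.01 (61 candidates); ties break toward 0.5, then lower; a single-class
validation set falls back to 0.5 with a warning. Image augmentations have no
feature-vector analogue; an optional Gaussian feature jitter exists and is
off by default. The model family is High/Low/Total trained fresh, plus
(optionally) High→Total and Low→Total transfer models that reuse a group
model's weights as initialization on the Total data.

Scaled-down schedules in the test suite use larger step sizes (10⁻²-scale)
because a few dozen optimizer steps at the production learning rate cannot
move a freshly initialized network; the production schedule runs thousands
of steps per model.

## Evaluation and statistics (`evaluation`, `stats`)

Each training group is retrained R = 5 times (repetition r seeds as master
seed + r) and every model is scored on identical baseline / unambiguous /
ambiguous item sets. Metrics: macro precision/recall/F1, accuracy,
ROC-AUC (Mann–Whitney with half credit for ties), PR-AUC (step-wise average
precision, positive class = high pole).

Inference on the repetition-level table:

* per repetition, paired DeLong tests of High vs Low and High vs Total on
  the shared items (structural-components covariance; SE = 0 with ΔAUC = 0
  defines p = 1); sign convention ΔAUC = High − comparator;
* Fisher's method (−2Σln p ~ χ²₂ₖ, p floored at 10⁻³⁰⁰) combines the five
  p-values; a fixed-effect inverse-variance pool (weights 1/SE², zero-SE
  repetitions excluded with a warning) gives the overall ΔAUC and Wald CI;
* one binomial GEE per condition × task on the item-level correctness bit:
  logit link, group (High reference) + repetition as fixed effects,
  exchangeable working correlation clustered on test items (estimated
  correlation capped below 1), robust sandwich CIs, convergence tolerance
  10⁻⁸ within 200 iterations; complete separation is flagged unstable, and
  a constant outcome (everything correct at ceiling) yields a unit OR
  flagged unstable rather than a failed fit;
* Benjamini–Hochberg FDR within each family, a family being condition ×
  task × statistic type spanning the two contrasts;
* two-sided tests and 1.96-multiplier normal CIs throughout.

When every repetition pits two exact perfect scorers against each other
(unambiguous ceiling at desk scale), the pooled ΔAUC is reported as exactly
0 with a degenerate (0, 0) interval instead of erroring.

## Calibration (`calibration`)

Type-I error and power of the full comparison stack are measured on
evaluation tables simulated directly at the score level: raw score =
b_g·y* + u_i + ε with balanced labels y* = ±1, shared item effects u_i ~
N(0, 1) (inducing the within-item correlation the GEE absorbs) and
independent noise ε ~ N(0, 1). Under the null all groups share b = 1, so the
family-wise rejection rate estimates type-I error; the effect scenario
lowers one group's b by 0.6 — a moderate, clearly consequential degradation
of signal strength, which is the score-level consequence of training on less
label-congruent data — and the rate at which that group's GEE odds ratio is
flagged below 1 estimates power. Defaults: 100 items, 5 repetitions, 200
replicates for the null and 50 for the effect scenario.

## What passing tests do and do not show

The generator's feature model is linear in the frame estimates with
independent Gaussian noise; real facial features are high-dimensional,
correlated, and person-specific, and real label noise is not a simple
Bernoulli flip of the expressed sign. Consequently the desk-scale pattern —
ceiling AUC on the unambiguous stratum, ≈0.96 baseline, ≈0.6 on the
ambiguous stratum — reproduces the *ordering* and attenuation structure of
the original study but not its absolute levels (the ambiguous stratum here
contains truly contradictory items, bounding any classifier well below the
original's ≈0.95). Likewise, because training frames are congruence-filtered
for every group, High/Low/Total training sets differ only subtly, and the
group contrasts at baseline are tiny-in-magnitude — which is precisely the
regime the repetition-level machinery (significant combined q alongside
near-zero pooled ΔAUC) was built for. Passing tests certify the protocol
counts, the correctness and calibration of the statistics, and the
qualitative data-consistency mechanism — not any claim about real
participants.

## Known limitations

* HRV is simulated at the feature level only, and its ANOVA treats within-
  participant replicates as independent.
* The cutoff scan's balance tie-break can dominate when the interaction
  signal plateaus across neighbouring cutoffs; the recovery experiment
  documents the design regime where the scan is informative.
* The GEE assumes a common exchangeable correlation across all items; no
  alternative working structures or random-effects meta-analysis are
  offered.
* Transfer-initialized models are trained and summarized but excluded from
  the default comparison report, which contrasts the three fresh models.
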