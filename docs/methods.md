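# Methods

## Measurement model

A session is one placement of the five-electrode device: the
impedance magnitude spectra of all 10 electrode pairs on the 20–500
kHz grid (20 kHz steps, 25 points). Impedance is modeled as a real
magnitude per frequency, matching an RMS-detecting acquisition chain;
no phase is simulated. Channels compose additively in path impedance:
`Z(e0,ei) = Z_limb + Z_fi` and `Z(ei,ej) = Z_fi + Z_fj`. This
additivity is the load-bearing assumption of the whole package: it is
what makes the limb spectrum exactly recoverable by
`[Z(0,i) + Z(0,j) − Z(i,j)] / 2` and what makes that recovery
invariant to anything that perturbs a single finger. It idealizes the
physical contact: real electrode interfaces add residual
non-cancelling terms even under four-point sensing, so exactness here
is a property of the model, not of tissue.

## Synthetic-study generator

Latent per-subject spectra use a single-dispersion Cole model
`Z(f) = |r_inf + (r0 − r_inf) / (1 + (i f / fc)^alpha)|` — the
standard empirical description of tissue dispersion — with population
parameters drawn uniformly per subject:

| parameter | limb | finger | units |
|---|---|---|---|
| r0 | 120–260 | 300–900 | Ω |
| r_inf / r0 | 0.4–0.7 | 0.4–0.7 | — |
| fc | 30–200 | 30–200 | kHz |
| alpha | 0.6–0.9 | 0.6–0.9 | — |

These ranges are free parameters of the generator chosen to give
plausible dispersion shapes and clear between-subject separation;
they are not claims about tissue.

Condition effects are multiplicative on the latent spectra:

* **Day drift** — lognormal per subject-day; `sigma_day_limb = 0.005`,
  `sigma_day_finger = 0.05` (a 10× contrast, reflecting the
  qualitative observation that peripheral impedance is far less
  reproducible than the limb). Finger drift is split into a shared
  "whole hand" component and an independent per-finger component
  (`day_shared_frac = 0.7` of the log-variance is shared). The split
  matters: fully common drift would cancel exactly in ratio features
  and fully independent drift would not cancel at all, whereas real
  finger physiology plausibly co-varies. It places ratiometric
  reproducibility between raw finger and limb, which is the regime the
  method is designed for.
* **Temperature** — fingers scale by `1 + κ (T_ref − T_hand)` with
  `κ = 0.01 /°C` and `T_ref = 33 °C`; the limb is unaffected
  (homeostasis of the core). The linear form is the simplest shape
  consistent with an inverse, roughly linear impedance–temperature
  relation, and is chosen for testability.
* **Placement** — a multiplicative factor on one finger's impedance.
  The sweep scenario applies {0.90, 1.00, 1.12} (labelled P1–P3) to a
  designated finger; the nominal scenario can instead jitter all four
  fingers uniformly in a configured range per session.
* **Device noise** — multiplicative `Normal(1, noise_rel)` per channel
  and frequency, `noise_rel = 2e-5` by default (instrument-grade
  repeatability; overridable).

Randomness: one `SeedSequence` per study, with spawned substreams per
subject-day, so datasets are bit-reproducible for a given
(config, seed) and per-day draws are order-independent.

What the generator does **not** emulate: electrode–skin contact
chemistry, motion artifacts within a session, phase information,
inter-channel crosstalk, or any anatomical correlation between a
subject's limb and finger parameters. Passing tests therefore show
that the analysis recovers the structure this model injects — exact
limb cancellation, drift hierarchies, temperature signatures — not
that a physical device will achieve the same accuracies.

## Feature families

Canonical orderings are fixed (finger pairs (1,2),(1,3),(1,4),(2,3),
(2,4),(3,4); the six wrist triples in the same listing order; the six
ratio combinations chosen so each pair appears once per side) so
feature vectors are reproducible across runs. Ratios are taken at
matched frequencies only. Extracted limb values that fall ≤ 0 under
heavy noise are kept with a warning rather than clipped — clipping
would bias CV statistics. Flat vectors concatenate (family, combo,
frequency); the channels layout stacks combos for the convnet.

## Reproducibility statistics

The coefficient of variation uses the sample (n−1) standard deviation
over the mean. Day-to-day CV is computed per subject, combo and
frequency from daily means of the repeats, averaged over the six
combos into a family value per subject, then summarized across
subjects (mean and sd) per frequency; subjects with a single day are
excluded with a warning. PCA is applied to centered, unscaled
spectra (features within a family share units); component signs are
fixed by making each component's largest-magnitude loading positive.
Temperature response is the per-subject OLS slope and Pearson
correlation of band-averaged (mean over the 25 grid points and six
combos) impedance against hand temperature.

## Classifiers and evaluation

* Random forest: 150 trees, Gini criterion, at most 151 leaves per
  tree (≤ 150 splits), minimum leaf size 1.
* LDA: least-squares solver with a fixed shrinkage of 1e-3 — at desk
  scale features (150–300) exceed training samples, so the empirical
  covariance needs a ridge.
* k-NN: k = 1, Euclidean, distance weighting (moot at k = 1; kept so
  k remains configurable).
* SVM: degree-2 polynomial kernel, C = 1, one-vs-one multiclass.
  Margins are mapped per sample to [0, 1] by min–max and normalized to
  sum 1 as the posterior-like score convention for the open-set sweep.
* CNN: a numpy 1-D convnet — conv(24, field 5, same padding) → BN →
  ReLU → maxpool 2 → conv(48) → BN → ReLU → maxpool 2 → conv(48) → BN
  → ReLU → dense 128 → ReLU → dropout 0.5 → dense n_classes →
  softmax; Adam at 1e-4, batch 128. The hidden dense width (128) is a
  package default. Default 200 epochs suits desk-scale problems;
  larger studies warrant more. Training is fully deterministic given
  `random_state` (pure numpy: init, batch order and dropout all come
  from one seeded generator).

Cross-validation is one fold per measurement day; accuracy is pooled
(micro) over all test predictions rather than averaged per fold.
Every fold iteration asserts that train and test share no day label.
A class present in a test day but absent from training is scored
against the enrolled classes and counted as an error.

Open-set scoring pools genuine scores (posterior of the true class)
and impostor scores (posteriors of all other classes) over all
samples and folds. A score is accepted at threshold t iff score ≥ t;
FAR(t) is the accepted impostor fraction and FRR(t) the rejected
genuine fraction. The EER is linearly interpolated between the
adjacent thresholds where FAR crosses FRR; the AUC integrates
(FAR, 1−FRR) by the trapezoidal rule, with ties in FAR ordered by TAR
so the polyline stays monotone. Both are verified in tests against an
O(n²) exhaustive threshold-enumeration oracle.

The scalability curve draws seeded random subject subsets per cohort
size (the full cohort once, deterministically) and fits
`a(n) = a_inf + b·exp(−c·ln n) = a_inf + b·n^(−c)` by least squares,
constrained to a decay toward an asymptote in [0, 100] % — the
unconstrained fit is ill-posed on flat or near-saturated curves. The
functional form is a modeling convention validated for
self-consistency (the fitter recovers parameters of data generated
exactly from the model); a_inf from slowly decaying curves with few
cohort sizes should be read with caution.

## Problem sizes

Desk-scale defaults used by the test suite and the reproduction
script: nominal reproducibility runs use 10 subjects × 3 days × 10
repeats; the ablation and day-accumulation analyses use 15 subjects ×
4 days × 8 repeats under strong finger drift (`sigma_day_finger =
0.12`) with per-session placement jitter uniform in [0.90, 1.12]
(the P1–P3 envelope), aggregated over five paired seeds; the
scalability analysis uses 25 subjects with cohort sizes 5–25 in steps
of 5 and 3 subset draws per size. These sizes give stable qualitative
orderings with comfortably fast runs; all counts are configurable.

## Known limitations

* Exact limb cancellation is a property of the additive path model;
  real contact interfaces will leave residuals.
* Day-drift magnitudes and their correlation structure are generator
  conventions, not measured quantities; absolute CV values and
  accuracies on synthetic data do not transfer to hardware.
* The open-set protocol evaluates rejection of enrolled-class
  impostor scores; it does not simulate a disjoint population of
  never-enrolled users.
* LDA shrinkage, the SVM score mapping, CV aggregation across combos,
  and across-subject CV error bars are documented conventions where
  several reasonable choices exist.
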