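# limbid — upper-limb bioimpedance biometrics

`limbid` is an analysis pipeline for identity recognition from wearable
multi-electrode bioimpedance spectra. A wrist-worn device with five
electrodes — `e0` on the left wrist and `e1..e4` under the right
index..little fingers — measures the impedance magnitude |Z(f)| of all
C(5,2) = 10 electrode pairs over 20–500 kHz (20 kHz steps, 25
frequencies). Finger impedance is a rich biometric signal, but it
drifts day to day with peripheral physiology, rises as the hand cools,
and shifts with finger-on-electrode placement. The package implements
and evaluates the two feature constructions that defeat these
artifacts, for researchers prototyping impedance-based biometric
systems.

## The measurement model and features

Each wrist–finger channel reads limb and finger impedance in series,
and each finger–finger channel the sum of two fingers:

    Z(e0, ei) = Z_limb + Z_fi          Z(ei, ej) = Z_fi + Z_fj

**Pure upper-limb feature.** For each of the six triples
(e0, ei, ej), i < j:

    Z_limb = [ Z(e0, ei) + Z(e0, ej) − Z(ei, ej) ] / 2

The finger terms enter the wrist channels and the finger channel
identically and cancel *exactly*, so the recovered limb spectrum is
algebraically invariant to any per-finger perturbation — placement,
temperature, finger-specific drift.

**Ratiometric feature.** Six ratios of finger-pair channels at matched
frequencies, chosen so every pair appears once as numerator and once
as denominator: (e1,e2)/(e3,e4), (e1,e3)/(e1,e2), (e1,e4)/(e1,e3),
(e2,e3)/(e1,e4), (e2,e4)/(e2,e3), (e3,e4)/(e2,e4). Ratios cancel any
drift common to all fingers but remain exposed to single-finger
artifacts.

Each family yields six 25-point spectra, concatenated into a (150,)
vector (300 when fused) or stacked as (25 × 1 × C) channels for the
1-D convnet. Identification is evaluated with five classifiers
(random forest, LDA, k-NN, polynomial SVM, and an in-package numpy 1-D
CNN) under **day-stratified cross-validation** — one fold per
measurement day, so train and test never share a day and day-specific
physiological state cannot leak. Open-set operation thresholds the
winning posterior; sweeping the threshold over pooled genuine/impostor
scores traces the ROC, from which the equal error rate (EER, where
FAR = FRR) and AUC are read off.

Because real device datasets of this kind are not generally available,
the package ships a seeded synthetic-study generator (Cole-dispersion
latent spectra; lognormal day drift much stronger in fingers than
limb; inverse finger-impedance–temperature response; per-finger
placement factors; multiplicative device noise) plus readers for
long-format CSV from real hardware.

## Worked example

```python
import limbid

data, truths = limbid.simulate_study(n_subjects=10, n_days=4,
                                     repeats_per_day=8, seed=3)
print("sessions:", data.n_sessions, " channels:", data.channels.shape)

cv_limb = limbid.daily_cv_profile(data, "upper_limb")
cv_raw = limbid.daily_cv_profile(data, "raw_finger")
print(f"band-mean CV  raw finger: {cv_raw.cv_mean.mean():.4f}   "
      f"upper limb: {cv_limb.cv_mean.mean():.4f}")

report = limbid.evaluate(data, selection="ratio+limb", kind="rf", seed=3)
print(f"RF day-fold accuracy: {report.accuracy:.2f}%   "
      f"EER: {report.eer:.2f}%   AUC: {report.auc:.4f}")
```

prints

```
sessions: 320  channels: (320, 10, 25)
band-mean CV  raw finger: 0.0464   upper limb: 0.0051
RF day-fold accuracy: 100.00%   EER: 0.00%   AUC: 1.0000
```

The day-to-day coefficient of variation of the extracted limb spectra
is ~9× smaller than that of the raw finger channels — the drift the
generator injects into the fingers cancels in the limb feature — and
with the fused ratio + limb features the random forest identifies all
10 subjects across held-out days. Under harsher conditions (strong
finger drift plus placement jitter) raw-finger accuracy collapses
while the limb features stay near-perfect; see the reproduction
script below.

The same pipeline runs from the shell:

```
limbid simulate --config run.yaml --out study.csv
limbid extract  --data study.csv --features limb --out features.csv
limbid evaluate --data study.csv --features ratio+limb --model rf \
                --seed 1 --out-dir results/
limbid report   --report results/report.json
```

where `run.yaml` holds the study shape, scenario
(`nominal` | `temperature_sweep` | `placement_sweep`), generator
parameters and the mandatory `seed`.

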