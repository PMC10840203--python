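# cardiomotion

Quantitative analysis of heartbeat-induced motion of the heart and its
substructures under different breath-hold states, from 4D (cine,
ECG-gated) segmentation masks.

## The problem

In thoracic radiotherapy the dose received by the heart is usually
estimated from a single static planning CT, ignoring that the heart
beats and that its position, volume, and shape depend on the breathing
state. Quantifying that motion requires, per subject and per
breath-hold state — end-inspiration (EIBH), end-expiration (EEBH), and
deep-inspiration (DIBH) — a 20-phase cardiac cycle (0–95% in 5% steps)
of 3D segmentation masks for the heart and up to nine substructures
(pericardium, LV, LVM, RV, RVM, ventricular and atrial septum, pmLAD
and pLCX coronary branches).

`cardiomotion` reduces each per-structure phase series to the standard
motion-management summaries and compares breath-hold states across a
cohort:

- **displacement** — peak-to-peak excursion of the centroid per patient
  axis (left–right LR, anterior–posterior AP, cranio-caudal CC), in mm;
- **volume** — per-phase volume (mL) with max/min/mean and the
  variation `(V_max − V_min) / V_min`, as a percentage;
- **shape** — Dice similarity coefficient against the 0% reference
  phase, `DSC = 2|A∩B| / (|A| + |B|)`, with max/min/mean and the same
  (max−min)/min variation;
- **surface mismatch** — the symmetric Hausdorff distance
  `H(A,B) = max( max_a min_b ‖a−b‖, max_b min_a ‖b−a‖ )` in mm against
  the reference phase (max and mean over phases), computed between
  surface-voxel centers via exact Euclidean distance transforms and
  verified against an exhaustive reference implementation;
- **statistics** — cohort mean ± SD per (structure, state), within-state
  paired comparison of each subject's per-cycle maximum vs minimum, and
  paired between-state comparisons with percent changes. Tests are
  normality-gated: Shapiro–Wilk on the paired differences, then a
  paired t test, else a Mann–Whitney U test (Wilcoxon signed-rank
  available as an option).

Because no public dataset of such segmentations exists, the package
includes a fully synthetic 4D beating-heart **label phantom**: ten
analytic structures (ellipsoids, myocardial shells, coronary capsules)
with raised-cosine contraction and translation over the cycle,
breath-hold volume/position effects, per-subject variability, and
closed-form ground truth for every generated quantity. Every pipeline
stage is tested against that ground truth.

## Worked example

```sh
python examples/phantom_motion.py
```

```
LV over 20 cardiac phases (subject 0, EIBH)
  displacement LR/AP/CC : 2.85 / 6.08 / 3.42 mm
  programmed amplitudes : 2.88 / 6.12 / 3.61 mm
  volume max/min/mean   : 99.0 / 44.0 / 69.9 mL
  volume variation      : 124.7 % (closed-form truth 124.0 %)
  DSC vs 0% min/mean    : 0.612 / 0.800
  HD  vs 0% max/mean    : 14.9 / 8.7 mm
```

The left ventricle of one phantom subject moves a few millimetres per
axis (recovered to sub-voxel accuracy against the programmed
amplitudes), its volume swings by ~125% over the cycle (matching the
analytic ellipsoid truth to ~1 percentage point at the 2×2×5 mm grid),
and the worst surface mismatch against the reference phase is ~15 mm.
`examples/overlap_metrics.py` shows the pair metrics in isolation and
`examples/cohort_pipeline.py` runs the full cohort pipeline (CSV report
bundle, within-state p-values, DIBH-vs-EIBH volume compression).

The same pipeline runs from the shell:

```sh
cardiomotion phantom --out data/ --subjects 5 --seed 42   # synthetic cohort
cardiomotion validate --data data/                        # input diagnostics
cardiomotion run --config run.yaml                        # full report bundle
cardiomotion metrics a.msk b.msk                          # one pair, debugging
```

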