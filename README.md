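# patype

Physical-activity-type detection from multi-position accelerometry and
GPS.

Wearable studies in free-living conditions need to know *what* a person is
doing — walking, walking up or down a slope, running, cycling, sitting,
standing, lying — before they can say anything about dose, duration or
health impact. A single 3-D accelerometer separates postures and vigorous
locomotion well, but level and non-level walking produce nearly identical
acceleration profiles across subjects even though their energy costs
differ. `patype` implements a pipeline for this problem aimed at
researchers in physical-activity epidemiology and human activity
recognition: five body-worn 50 Hz accelerometers (chest, hips, pocket,
knee) are synchronized via jump markers, annotated, stop-filtered and cut
into overlapping windows; 85 time- and frequency-domain features are
extracted per sensor per window; a 1 Hz GPS track is cleaned, gap-filled,
map-matched to a road network and fused with a digital elevation model
(DEM) to yield two extra features per window — mean speed v̄ and elevation
difference Δh — and random-forest models are evaluated under
leave-one-subject-out (L1SO) and k-fold cross-validation in two training
scenarios.

Because the kind of human-subject dataset this method targets is not
publicly available, the package ships a first-class synthetic-data
generator (`patype.synthetic`) that emulates the study design —
subject-specific gait harmonics and postural gravity vectors, sync-jump
markers, clock offsets, road-following GPS with gaps and noise, sloped
terrain — so that every stage of the pipeline is tested end to end by
parameter recovery.

## The core quantities

Per window and class c (one-vs-rest, confusion matrix **C** with rows =
predicted, columns = true):

    precision_c = C_cc / Σ_j C_cj          (row sum)
    recall_c    = C_cc / Σ_i C_ic          (column sum)
    F1_c        = 2 · precision_c · recall_c / (β² precision_c + recall_c),  β = 1
    accuracy    = tr(C) / Σ C

The 85-feature vector per sensor: 61 time-domain + 24 frequency-domain
over the signals {x, y, z, ‖a‖}:

    time:  mean, sd, range (4 signals × 3) ............ 12
           axis correlations (xy, xz, yz) ............. 3
           kurtosis, skewness (3 axes × 2) ............ 6
           avg. absolute difference (4 signals) ....... 4
           10 fixed bins × 3 axes ..................... 30
           inter-peak interval, peak count (3 axes) ... 6    → 61
    freq:  PSD summary, energy, mean of 3 dominant
           frequencies, 3 dominant amplitudes
           (6 per signal × 4 signals) ................. 24   → 85

A general model concatenates all five positions (425 columns); the GPS
pair (v̄, Δh) is appended once (87 individual / 427 general). Δh is the
smoothed DEM elevation at the last fix of the window minus the first —
uphill positive — computed after point-to-curve map matching.

## Worked example

```python
from patype.experiments import run_study

res = run_study(seed=1)            # 10 synthetic subjects, 10 s windows
acc  = res["loso_acc"]             # general model, accelerometer only
gps  = res["loso_acc_gps"]        # + mean speed and elevation difference
kf   = res["kfold_acc"]           # segment-level 10-fold (leaky on purpose)
print(f"L1SO ACC      {acc.accuracy:.1f}%  "
      f"non-level-walking F1 {acc.per_class.loc['non_level_walking','f1']:.1f}")
print(f"L1SO ACC+GPS  {gps.accuracy:.1f}%  "
      f"non-level-walking F1 {gps.per_class.loc['non_level_walking','f1']:.1f}")
print(f"10-fold ACC   {kf.accuracy:.1f}%")
```

prints (seed 1):

```
L1SO ACC      87.9%  non-level-walking F1 71.5
L1SO ACC+GPS  90.3%  non-level-walking F1 77.9
10-fold ACC   100.0%
```

Read: with accelerometers alone, a cross-subject model confuses level and
non-level walking (F1 71.5) because the incline lean that distinguishes
them within a subject is masked by between-subject postural variation.
Adding the two GPS features lifts that class by ~6 F1 points and overall
accuracy by ~2 points. Segment-level 10-fold cross-validation scores
100 % on the same data — the within-subject leakage that makes it an
untrustworthy protocol for activity recognition.

The command-line interface mirrors this flow:

```
patype simulate --subjects 10 --seed 1 --out data/
patype features --in data/ --window 10 --out features.csv
patype evaluate --features features.csv --method loso --feature-set acc_gps --out report.json
patype sensitivity --seed 1 --out sensitivity.csv
```

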