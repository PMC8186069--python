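# hoofbeat

Behaviour classification from collar-mounted tri-axial accelerometer and
magnetometer data on caprids (Alpine ibex, *Capra ibex*, and pygmy goats,
*Capra aegagrus hircus*), built for movement ecologists who calibrate
biologging tags on captive or domestic surrogates before deploying them on
wild animals.

The package implements the full calibration workflow as a tested, reusable
pipeline:

* **Feature derivation** from raw 40 Hz sensor streams: static/dynamic
  acceleration decomposition (static `s` = centred running mean, dynamic
  `d = a − s`), posture angles (pitch = asin(s_x/‖s‖), roll = asin(s_y/‖s‖)),
  VeDBA = ‖d‖₂ and its smoothed variant, per-axis windowed statistics and
  dominant oscillation amplitudes (PSD1X/Y/Z), and five magnetometry
  variables — a 39-variable candidate registry over non-overlapping 2 s
  windows.
* **Model refinement**: sampling-frequency subsampling (40/20/10/5/1 Hz),
  correlation pruning (|Pearson r| ≥ 0.70, lower Gini importance loses),
  recursive feature elimination with cross-validated subset scoring, random
  down-sampling of majority classes to the pooled median class duration
  (560.4 s for the reference ethogram), and behaviour-set reduction.
* **Classification**: 500-tree random forests (Gini splitting, bootstrap per
  tree, √p feature subsampling) with mean-decrease-in-Gini importances and
  out-of-bag error traces.
* **Validation**: confusion matrices; per-class precision = TP/(TP+FP),
  recall = TP/(TP+FN), F1 = 2/(1/P + 1/R); overall accuracy; random 60/40
  row splits vs individual-level 60/40 splits enumerated over all admissible
  individual subsets (k-fold); cross-species transfer on shared behaviours,
  a sex-specific transfer variant, and a random-label null model; terrain
  slope (flat/uphill/downhill at ±2.5°) as extra locomotion classes.
* **A synthetic biologging simulator** that generates labelled streams with
  the structure the classifier relies on — posture set by behaviour and
  terrain slope, gait sinusoids with one harmonic, bounded heading random
  walks seen through a magnetometer, individual and species (morphology)
  variation, and bout durations weighted by a published zoo ethogram — so
  every stage of the pipeline is testable end to end without access to the
  original observations.

## Worked example

```python
import hoofbeat as hb

cfg = hb.SimulationConfig(seed=7)            # 6 ibex-like + 9 goat-like, 30 min each
cohort = hb.generate_cohort(cfg)
table = hb.cohort_feature_table(cohort, target_hz=10).reset_index(drop=True)

for species in cohort.species:
    t = table[table["species"] == species].reset_index(drop=True)
    plan = hb.split_random(t, seed=7)
    rep = hb.evaluate_split(t, plan, n_trees=500, seed=7)
    _, agg = hb.evaluate_individual_folds(t, n_trees=200, seed=7, max_folds=5)
    print(f"{species}: random split {rep.accuracy_pct:.1f} % "
          f"(mean F1 {rep.f1_mean:.2f}), "
          f"individual split {agg.loc['accuracy_pct', 'mean']:.1f} "
          f"± {agg.loc['accuracy_pct', 'sd']:.1f} %")
```

prints

```
goat: random split 99.8 % (mean F1 0.99), individual split 95.6 ± 2.3 %
ibex: random split 99.7 % (mean F1 0.99), individual split 97.5 ± 1.7 %
```

Random row splits place every individual on both sides (and consecutive 2 s
windows are autocorrelated), so they overestimate how well the model will
classify an animal it has never seen; the individual-level splits quantify
that optimism — here a 2–4 point drop, growing with the amount of
between-individual variation in the simulator.

The same pipeline is scriptable from a shell:

```sh
hoofbeat simulate --seed 7 --out cohort/
hoofbeat features --data cohort/ --freq 10 --out features.csv
hoofbeat run --seed 7 --out run/ && hoofbeat report --run run/
hoofbeat transfer --data cohort/ --train-species goat --test-species ibex \
    --sex female --out transfer.csv
```

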