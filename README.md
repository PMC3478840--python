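# fallkit

Fall detection from a waist-mounted tri-axial accelerometer (200 Hz,
12-bit, ±2 g), built around four per-sample action parameters and an
RBF-kernel soft-margin SVM, with a boxplot-threshold classifier as the
comparison baseline and a seeded activity simulator standing in for
volunteer recordings.

## What it does

1. **signals** — trace/manifest data model and delimited-text I/O.
2. **features** — per-sample parameters from a trace:
   `sv_total` (total magnitude), `cv_fast` (root-sum-square of per-axis
   max−min over a causal 0.1 s window), `va` (signed vertical
   acceleration from the law of cosines on the total and high-pass
   magnitudes), `phi_z` (posture angle between the low-pass gravity
   estimate and upright, degrees).
3. **training** — frame labeling (+1 where `cv_fast` reaches 0.87 × the
   fall trial's peak, −1 elsewhere), seeded trial selection
   (5 per subject × ADL by default), two-fold splits by trial or subject.
4. **svm** — C-SVC with RBF kernel (γ = 5.3, C = 4.7 defaults), reduced
   to a portable text model (support vectors, multipliers, bias); the
   decision function is evaluated from those parts directly.
5. **baseline** — per-parameter upper/lower falling thresholds from the
   boxplot whiskers of fall-trial peaks; trial-level rule classification.
6. **simulator** — seeded generator for all 21 activity classes
   (10 falling including soft bed/wheelchair falls, 11 non-falling) and
   continuous sessions with optional embedded, annotated falls.
7. **evaluate** — frame-to-event aggregation, greedy event matching,
   sensitivity/specificity/accuracy, FP per hour, per-class error tables.
8. **cli** — `fallkit` command tying the stages together.

## CLI

```bash
# simulate a 10-subject protocol (writes traces + manifest.csv)
fallkit simulate protocol --subjects 10 --trials 10 --seed 1 --out-dir simout

# feature extraction for one trace
fallkit extract --input simout/S01_A03_T01.csv --out feats.csv

# labeled frame matrix, SVM training, event-level evaluation
fallkit build-trainset --manifest simout/manifest.csv --out ts.csv --seed 1
fallkit train --trainset ts.csv --gamma 5.3 --cost 4.7 --out model.txt
fallkit classify --model model.txt --features feats.csv --out events.csv
fallkit evaluate --pred events.csv --truth truth.csv --tol 2.0

# threshold baseline
fallkit baseline-fit --manifest simout/manifest.csv --out thr.csv
fallkit baseline-classify --model thr.csv --manifest simout/manifest.csv --out pred.csv

# whole pipeline (simulate -> trainset -> train -> evaluate), reproducible per seed
fallkit run --seed 1 --out-dir runout --set subjects=3 --set trials_per_adl=4 \
    --set frame_stride=10
```

Config values can also come from a YAML file (`--config cfg.yaml`), with
`--set key=value` overrides; all stage randomness derives from the one
seed.

## File formats

All artifacts are plain delimited text: traces (`t,ax,ay,az`, `#`
comments for metadata), manifests (`path,subject,adl_id,trial,is_fall`),
features (`t,sv_total,cv_fast,va,phi_z`), annotations
(`start_s,end_s,adl_id,is_fall`), and a line-oriented SVM model file.
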