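# equispine

Equine thoracolumbar kinematics from optical motion capture: stride
segmentation, body-lean-corrected spinal and pelvic angles, per-stride
summaries, and mixed-model comparison of straight-line versus left/right
circle trot.

## The problem

Horses are routinely trained and clinically examined on circles (lungeing at
~5 m radius), where the body leans inward and, according to equestrian
theory, the spine bends laterally toward the inside. Quantifying this from
skin markers is delicate: a leaning trunk makes lab-fixed "side view" and
"top view" angles mix flexion–extension (FE) with lateral bending (LB).
`equispine` implements the full measurement chain for this problem, for
researchers in animal biomechanics and veterinary gait analysis:

1. **Stride segmentation.** Trot shows two vertical croup oscillations per
   stride; events are local maxima of the tubera sacrale height after a
   zero-lag Butterworth high-pass at 0.7 × stride frequency, with left/right
   hind-stance labels from the sign of the pelvis-roll oscillation.
2. **Lean-corrected angles.** Body lean is approximated by the windowed mean
   pelvis roll (window = one stride); the angle reference frame is tilted by
   that amount. For each of seven marker triplets along the back
   (withers–T15–tubera sacrale for the whole back, plus six segments), the
   signed projected three-point angle is computed per frame in the sagittal
   (FE) and horizontal (LB) body planes, alongside pelvis roll/pitch/yaw,
   head swivel, body tracking and speed.
3. **Per-stride summaries.** Stride mean and range of motion (ROM = max −
   min) per variable, with QC (measurements with < 5 strides or
   unrecoverable marker gaps are discarded).
4. **Mixed models.** On stride-by-stride data: `value ~ path * speed` with
   random intercepts for horse and measurement-within-horse (REML);
   least-squares means per path at the speed grand mean; pairwise path
   differences with Benjamini–Hochberg FDR adjustment. Per-path association
   models relate whole-back FE/LB to pelvic rotations, head swivel, body
   tracking and speed.

A first-class synthetic-data generator forward-simulates the whole study
design (12 horses × 2 days × 5 trials × 3 paths at 100 Hz) with known
kinematics, realistic variance structure, the physics body lean
arctan(v²/gr), and Gaussian marker noise at the 3.2 mm capture-residual
scale — so the entire chain is testable without any data download. The
generator inverts the measurement definitions exactly: on noise-free data
the pipeline recovers every configured stride mean to better than 0.05°.
See `docs/methods.md` for the model details.

## Worked example

```python
from equispine import SyntheticStudyConfig, run_synthetic_study, fit_path_model

cfg = SyntheticStudyConfig(n_horses=6, days=1, trials_per_day=3, seed=42)
table = run_synthetic_study(cfg)
print(f"{table['measurement'].nunique()} measurements, "
      f"{table.groupby('measurement')['stride'].nunique().sum()} strides")

result = fit_path_model(table, "lb_whole_back", statistic="mean")
print(result.ls_means.round(2).to_string(index=False))
print(result.differences[["contrast", "est", "se", "p_fdr"]].round(3).to_string(index=False))
```

prints

```
54 measurements, 1611 strides
    path   est   se
straight  0.54 0.93
    left -3.35 0.93
   right  4.15 0.93
      contrast    est    se  p_fdr
 straight-left  3.892 0.150    0.0
straight-right -3.614 0.150    0.0
    left-right -7.506 0.147    0.0
```

The LS means say this simulated cohort holds its back near straight on the
straight line and bends ~3–4° toward the inside of each circle (negative =
left bending, by the bent-right-positive convention); the `straight-left`
row estimates that difference at 3.89° ± 0.15° with an FDR-adjusted p-value
below printing precision. The large LS-mean SEs (0.93) reflect
between-horse variation, which cancels in the within-horse path contrasts.

A command-line interface mirrors the library:

```bash
equispine simulate --config study.yaml --out capture/      # one TSV per measurement
equispine segment  --in capture/horse01-d1-t1-left.tsv --out strides.csv
equispine angles   --in capture/horse01-d1-t1-left.tsv --out angles.csv
equispine summarize --in capture/ --out measurements.csv
equispine compare  --in measurements.csv --out comparison.csv
equispine all      --out analysis/ --seed 1                # end to end
```

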