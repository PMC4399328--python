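# soundmvpa

Multivariate decoding of 3D sound-source location from sparse-sampling
auditory fMRI, as a tested, reusable pipeline. Because no raw data from the
original experiment is deposited, the package ships a first-class synthetic
data generator that emulates the acquisition protocol (8 runs × 76 trials,
TR = 5.5 s with a 2 s acquisition burst, 64 stimulus trials — 4 per each of
16 speaker locations — plus 12 silent trials, 550 ms stimuli jittered in
the 2.5 s after acquisition) with planted, condition-specific multivoxel
patterns, so every downstream stage can be validated against ground truth.

## Pipeline stages

| module        | what it does |
|---------------|--------------|
| `geometry`    | the 16-speaker spherical array (80 cm radius), coordinate conversions, and the class labelings for left/right, up/down and front/back discrimination |
| `synth`       | run designs and synthetic 4D datasets: HRF-convolved responses, AR(1) noise, linear drift, one volume per trial |
| `glm`         | per-run beta-series GLM (16 location regressors + trend + intercept → 16 response maps per run, 128 per subject; never smoothed) and the univariate stimulus-vs-silent contrast with Benjamini–Hochberg FDR on smoothed data |
| `selection`   | permutation-test voxel selection: 2000 label permutations → per-voxel Gaussian null of the linear-SVM weight → two-sided tail p-values → p < 0.05 threshold, computed from training runs only |
| `decoding`    | leave-one-run-out SVM cross-validation per subject and condition; one-sided group t-test against the 50 % chance level |
| `aggregation` | effective voxels (selected in ≥ 5 of 8 folds), significant effective voxels (EV in ≥ 3 subjects), exact binomial tail bound |
| `pipeline`/`cli` | end-to-end orchestration with JSON config and per-stage persistence (NIfTI / TSV / JSON) |

## CLI

```sh
# one-shot run
soundmvpa all --config config.json --seed 7 --out out/

# or stage by stage (bit-identical to the one-shot run)
soundmvpa simulate --config config.json --seed 7 --out out/
soundmvpa glm      --config config.json --seed 7 --out out/
soundmvpa decode   --config config.json --seed 7 --out out/
soundmvpa aggregate --config config.json --seed 7 --out out/
soundmvpa report   --config config.json --seed 7 --out out/
```

A minimal desk-scale config:

```json
{
  "n_subjects": 3,
  "n_perm": 200,
  "synth": {
    "grid_shape": [24, 24, 12],
    "amplitudes": {"left_vs_right": 1.0, "up_vs_down": 1.0, "front_vs_back": 1.0},
    "n_informative": 10,
    "noise_sd": 1.0
  }
}
```

Defaults mirror the experimental protocol (8 subjects, 8 runs, 76 trials,
TR 5.5 s, 2000 permutations, α = 0.05, EV ≥ 5 folds, SEV ≥ 3 subjects).
The final `report.json` contains per-subject fold accuracies, group tests
per condition, EV/SEV summaries, and ground-truth recovery scores.

## Notes

- ROI size matters for the selection step: the permutation-null SVM-weight
  statistic is well calibrated and sensitive when the ROI has many more
  voxels than there are training samples (as in real data); with tiny ROIs
  the null distribution widens and selection loses power.
- Raw accuracy is reported against the 50 % chance convention; balanced
  accuracy is reported alongside because two of the three conditions have
  unequal class sizes (5 v 3 and 5 v 4 locations).
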