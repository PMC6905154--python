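# audpath

Auditory-pathway analysis pipeline: lifetime noise-exposure scoring,
adaptive audiometry, click-evoked ABR wave I/V extraction, and block-design
auditory fMRI analysis — exercised end-to-end on seeded synthetic data.

## Modules

| Module | Purpose |
| --- | --- |
| `audpath.nesi` | Lifetime noise-exposure units from structured-interview activity records; low/high group allocation at the 15-unit cut-off; age stratification |
| `audpath.audiometry` | Two-down one-up adaptive staircase (2-dB step, 12 reversals), simulated 2I-2AFC listener, threshold estimation, normal-hearing eligibility rules |
| `audpath.abr` | ABR pipeline: Cz−mastoid derivation, epoching with acoustic-delay correction, RMS artifact rejection, averaging, zero-phase 50–1500 Hz filtering, automated wave I/V peak picking |
| `audpath.fmri_design` | Block paradigm (64 s rest + 8 × [24 s on / 42 s off] per run, 4 runs, TR 2 s), HRF-convolved onset/offset/sustained regressors, DCT high-pass basis, regressor orthogonality |
| `audpath.physio` | RETROICOR-style cardiac/respiratory phase computation and sin/cos nuisance regressors |
| `audpath.fmri_glm` | Voxel-wise GLM with pooled AR(1) prewhitening, contrasts, Gaussian smoothing, composite (OR) ROI masks, ROI betas, cycle-averaged percent-change time-courses, max-statistic permutation group maps |
| `audpath.group_stats` | Split-plot mixed ANCOVA (within: region × hemisphere; between: exposure group; de-meaned age covariate), skew/kurtosis screening, Mood's median, chi-square, Mann-Whitney, Pearson r, paired-t percent difference |
| `audpath.synthetic_data` | Seeded generators for cohorts, ABR recordings, physiological traces and 4D BOLD datasets with known ground truth |
| `audpath.io` / `audpath.cli` / `audpath.pipeline` | File formats (CSV/TSV/NIfTI/raw+JSON), the `audpath` CLI, and end-to-end orchestration |

## CLI

```bash
audpath nesi score --activities activities.csv --out cohort.csv
audpath audiometry simulate --seed 3 --n-tracks 20
audpath abr run --raw rec.dat --events ev.tsv --out features.csv
audpath design build --out design.tsv --events events.tsv
audpath physio regressors --physio-csv physio.csv --out retroicor.tsv
audpath glm fit --bold bold.nii --design design.tsv --out fitdir/
audpath glm rois --maps onset_t.nii --maps offset_t.nii --maps sustained_t.nii --seeds seeds.json --out mask.nii
audpath stats ancova --cohort cohort.csv --response onset
audpath simulate all --seed 7 --out data/
audpath run --seed 0 --out results/
```

## Conventions

- Events TSV follows the BIDS layout (`onset`, `duration`, `trial_type`);
  volumes and masks are NIfTI-1 with a JSON label sidecar for ROI masks;
  electrophysiology is raw float32 binary plus a JSON header.
- ABR latencies are in ms relative to eardrum arrival (click onset +
  0.91 ms acoustic delay); voxel indices are 0-based with world coordinates
  from the NIfTI affine.
- Every stochastic routine takes an explicit seed; identical seeds give
  byte-identical outputs.
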