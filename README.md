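# vsasl

Kinetic analysis for velocity-selective arterial spin labelling (VSASL)
perfusion MRI: a closed-form forward signal model, multi-start voxelwise
fitting of perfusion (CBF), bolus duration and macrovascular parameters,
grey-matter masking and region aggregation, cerebrovascular reactivity (CVR)
computation, an a-priori power analysis, and a synthetic multi-subject
phantom generator so the whole pipeline runs without acquired data.

## Model

The difference signal at label-to-readout time `t` is the sum of

- a tissue compartment: a single-compartment kinetic model with
  instantaneous bolus arrival.  The effective bolus duration is
  `min(bolus duration, LCT)`, where the LCT (label-to-crusher time) is the
  delay between the velocity-selective label and the vascular crushing
  module; and
- a macrovascular compartment: residual intravascular signal decaying with
  blood T1 that vanishes abruptly once the macrovascular bolus has cleared.

Voxelwise fitting is unconstrained quasi-Newton least squares from multiple
starting values of the two durations, with post-hoc zeroing of unphysical
estimates.  Because the macrovascular bolus duration enters only through
which readout samples it covers, it is explored over every distinct
step-edge basin and is interval-censored at the readout-time resolution.

## Command line

```sh
# synthetic two-condition CVR study (small grid for speed)
vsasl simulate --preset experiment2 --grid 16,16,4 --seed 7 --out study/

# voxelwise parameter maps for every subject and condition
vsasl fit --study study/ --out fits/

# per-region group summary (median across voxels, mean +/- SD across subjects)
vsasl regions --study study/ --fits fits/ --condition normocapnia --out regions.csv

# CVR in %/mmHg from fitted CBF + per-LCT signal-change table
vsasl cvr --study study/ --fits fits/ --out cvr.csv

# refit with the LCT axis truncated
vsasl truncate --study study/ --max-lct 2.0 --out truncation.csv

# required sample size for a two-sided paired t-test
vsasl power --dz 0.7 --alpha 0.05 --power 0.8   # -> 19
```

`simulate` also accepts `--config config.yaml` with `physio:`, `timing:`,
`mask:` and `phantom:` blocks (schema-validated; unknown keys rejected).
Images are NIfTI-1; summaries are CSV with JSON provenance sidecars.

## Layout

- `src/vsasl/model.py` — forward model and timing/physiological constants
- `src/vsasl/fitting.py` — voxel fits, masks, region summaries
- `src/vsasl/synthetic.py` — phantom generator and experiment presets
- `src/vsasl/cvr.py` — percent signal change, CVR, truncation analysis
- `src/vsasl/power.py` — noncentral-t power / sample size
- `src/vsasl/io.py`, `src/vsasl/cli.py` — NIfTI/YAML/CSV plumbing and CLI
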