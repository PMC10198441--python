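# gliadyn

Analysis of two-channel (microglia / Purkinje cell) in-vivo two-photon
time-lapse z-stacks, together with a synthetic stack simulator so the whole
chain is testable without any imaging data.

The pipeline mirrors a cerebellar microglia imaging workflow:

| module | what it does |
|---|---|
| `gliadyn.simulate` | synthetic 4D two-channel stacks with known ground truth: Purkinje soma monolayer + dendrite fans, microglia with dynamic process turnover, red→green bleed-through, Poisson/Gaussian noise, lateral drift |
| `gliadyn.io_blind` | TIFF stack I/O (`(t, z, y, x, channel)` convention), dataset blinding with a separately stored key |
| `gliadyn.preprocess` | background subtraction, brightness-compensated bleed-through correction (Theil–Sen β), PCA denoising, molecular-layer / Purkinje-cell-layer separation |
| `gliadyn.segment` | deterministic component masks: microglia soma/process split, Purkinje dendrite, branch points (per-slice skeleton junctions), somas; thresholding + size exclusion |
| `gliadyn.dynamics` | drift correction, max projections, motility index (extended+retracted)/stable, surveillance index |
| `gliadyn.sholl` | ring-intersection profiles (2 µm rings to 80 µm) and a hierarchical Bayesian piecewise-Poisson change-point model (α₁, α₂, e^τ, γ) fit by MCMC |
| `gliadyn.interactions` | 3D voxel-overlap quantification per microglia×Purkinje component pair, normalization, time-averaging, interaction coverage index |
| `gliadyn.stats` | unpaired/paired t-tests, treatment×sex two-way ANOVA with Bonferroni post-hocs, GG-corrected repeated-measures ANOVA |

## Test

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (oracle
equivalence of the motility/surveillance counts, simulator calibration,
Sholl analytics and posterior recovery, partition identities, bleed-through
recovery, layer separation accuracy, end-to-end type-I calibration on 500
null cohorts, and byte-level determinism). The full suite takes roughly
10–15 minutes on one CPU; the non-acceptance portion runs in under a
minute.

## CLI

```bash
gliadyn simulate --out data/ --config cfg.yaml --seed 1      # one animal
gliadyn simulate --out data/ --cohort 6 --seed 1             # 6 per treatment x sex
gliadyn blind --out blinded/ --seed 2 data/*.tif
gliadyn dynamics --stack data/animal.tif --out mi.csv --pcl-start 55
gliadyn interactions --stack data/animal.tif --out ia.csv
gliadyn sholl --stack data/animal.tif --out prof.csv --center-y 120 --center-x 200
gliadyn sholl-fit --profiles prof.csv --out fit.csv --seed 3 --plot effects.png
gliadyn stats --table joined.csv --dv motility_index --out stats.csv
```

`cfg.yaml` may override any `SimConfig` field, e.g.:

```yaml
frame_shape: [600, 800]
n_z: 101
n_t: 12
layer_boundary_z: 55
process_turnover: 0.2
interaction_bias: 0.2
bleed_coeff: 0.15
drift_per_t_um: 1.0
```

Every stage is deterministic for a fixed config and seed (byte-identical
outputs on rerun).

## Conventions

- Arrays are indexed `(t, z, y, x, channel)`; channel 0 = green
  (microglia), 1 = red (Purkinje). z increases with depth (surface at z=0).
- All indices are 0-based; physical calibration (µm/px, µm/slice,
  min/frame) travels with the stack.
- Interaction outputs quantify voxel co-occupancy ("putative" contacts);
  light microscopy cannot resolve membrane apposition.
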