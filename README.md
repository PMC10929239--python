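# gliaquant

Quantification of microglial dynamics from fluorescence imaging: surveillance
motility, injury-directed chemotaxis, cell density and skeleton morphometry,
Aβ-deposit engulfment, receptor-staining intensity partitioning, and ΔΔCt
qPCR — plus a synthetic time-lapse generator that provides exact ground truth
for every stage.

Microglia, the resident immune cells of the CNS, continuously survey brain
tissue with ramified processes and extend them toward injury signals such as
ATP or amyloid-β. Ex-vivo slice studies quantify these behaviors with a small
set of image-analysis procedures that are usually assembled ad hoc from ImageJ
plugins. `gliaquant` packages those procedures as a tested, scriptable Python
library for imaging labs that want reproducible numbers from the same
measurements.

## The measurements

- **Motility index** — consecutive binarized frames are compared pixel-wise
  into extending (green), retracting (red) and stable (yellow) pixels;
  each frame pair scores `MI = (green + red) / yellow`, averaged over the
  time-lapse. Static cells score 0; higher means more surveillance.
- **Process velocity** — tracked tip coordinates give total path length over
  elapsed time (µm/min), truncated at arrival within a capture radius of the
  pipette; per-cell velocity averages 3–5 processes.
- **Density & morphology** — soma counts per calibrated field (cells/mm³) and
  per-cell skeleton metrics: endpoints (process tips) and total branch length
  (1 px orthogonal / √2 diagonal steps, scaled to µm).
- **Aβ coverage** — per time point, `100 · |microglia ∩ Aβ| / |Aβ|`, the
  fraction of the deposit overlapped by microglial pixels.
- **Intensity partition** — percent of staining intensity in processes after
  cropping out soma masks: `100 · process / (process + soma)`.
- **ΔΔCt** — Livak relative quantification: `fold = 2^(−ΔΔCt)` with the
  reference group defined as 1.0.
- **Statistics** — two-tailed t-tests, one-/two-way ANOVA with Sidak or Tukey
  contrasts, mean ± SEM summaries.

Every stage has a matching simulator (`gliaquant.synthetic`) that renders a
calibrated TIFF-compatible stack and records the programmed truth — change
counts, tip tracks, coverage schedule, planted cells, intensity split — so the
entire pipeline is validated by round-trip recovery. See `docs/methods.md`
for the models, defaults, and limitations.

## Worked example

Simulate a 20-s-interval surveillance lapse with 10% pixel turnover per frame
pair and recover the motility index:

```python
from gliaquant.synthetic import SimConfig, simulate_baseline_timelapse
from gliaquant.motility import timelapse_motility, motility_index

cfg = SimConfig(image_shape=(256, 256), n_frames=16, seed=1)
stack, truth = simulate_baseline_timelapse(cfg, turnover_rate=0.10)
res = timelapse_motility(stack)
print(f"mean motility index = {res.mean_index:.4f} over {res.n_pairs} pairs")
truth_mean = sum(motility_index(c) for c in truth.per_pair_change_counts) / 15
print(f"programmed truth    = {truth_mean:.4f}")
```

prints

```
mean motility index = 0.1044 over 15 pairs
programmed truth    = 0.1044
```

The recovered index equals the truth because at zero noise the rendered
frames binarize back to the underlying masks exactly; the value ≈ 0.10 is what
a 10% turnover rate implies (the flipped pixels are split between extension
and retraction, and the denominator is the stable area).

The same works from the shell:

```sh
gliaquant simulate --mode baseline --seed 1 --out scratch/base.tif \
    --shape 256,256 --n-frames 16 --turnover-rate 0.1
gliaquant motility --in scratch/base.tif
# mean motility index = 0.1044 over 15 pairs
```

Other subcommands: `velocity` (track CSVs), `morphology`, `coverage`,
`intensity`, `qpcr`, and `run` (a YAML-configured multi-condition pipeline
with per-stage CSVs, group summaries and comparisons).

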