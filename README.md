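# pitscan

Quantitative analysis of osteoclast resorption pits from stylus
surface-profilometry traces.

Osteoclasts cultured on bone discs leave resorption pits whose sub-surface
geometry reports how the cells resorbed: single isolated dents
(*unidented* pits) mark intermittent resorption interrupted by migration,
while compound excavations of two or more dents (*bidented*,
*multidented*) mark continuous resorption. In acute Charcot
osteoarthropathy — rapid inflammatory bone destruction of the neuropathic
foot — osteoclasts driven by M-CSF + RANKL erode abnormally deep, wide and
predominantly multidented pits, and neutralising TNF-α normalises the
profile. Quantifying that shift requires turning raw 1-D profilometer
traces into per-pit morphology and cohort statistics; `pitscan` implements
that pipeline end to end, together with a ground-truthed synthetic-surface
generator for validating every stage.

For each trace (position μm, height μm) the package:

1. estimates the unresorbed-surface baseline with a robust upper-mass fit
   (erosion contaminates the height distribution only from below);
2. segments sub-surface excursions into pits bounded by the baseline, and
   counts internal dents separated by ridges rising back to within
   `max(2σ_noise, 0.1·depth)` of the surface;
3. measures each pit: width at the surface *w*, maximum depth *d*, full
   width at half maximum (FWHM, the width at *d*/2), and eroded
   cross-sectional area ∫(baseline − surface) dx in μm²;
4. aggregates per subject × culture condition (medians per shape class,
   shape percentages, median pit area, planar resorbed-area %), and
5. runs the cohort's nonparametric design: Kruskal-Wallis across the three
   groups, Mann-Whitney U (exact for small samples) between groups and
   between conditions, chi-square for categorical tables, at α = 0.05.

## Worked example

Simulate one Charcot M-CSF+RANKL scan (1000 μm, 0.056 μm sampling) and
analyze it:

```python
import numpy as np
from pitscan import analyze_trace, RunConfig
from pitscan.synthetic import default_presets, generate_trace, ScanMetadata

preset = default_presets()[("charcot", "rankl")]
rng = np.random.default_rng(42)
trace, truth = generate_trace(preset, ScanMetadata(), rng, source_id="demo")
pits = analyze_trace(trace, RunConfig())
print(f"{len(pits)} pits detected ({len(truth.pits)} generated)")
for p in pits:
    print(f"  {p.shape_class:<11} width {p.width:6.1f} um  depth {p.depth:5.2f} um  "
          f"fwhm {p.fwhm:6.2f} um  area {p.area:7.1f} um^2")
```

```
10 pits detected (10 generated)
  unidented   width   16.7 um  depth  5.61 um  fwhm   8.90 um  area    50.0 um^2
  multidented width   55.9 um  depth  4.58 um  fwhm  48.84 um  area   136.8 um^2
  multidented width   60.3 um  depth  6.11 um  fwhm  52.75 um  area   177.1 um^2
  multidented width   51.7 um  depth  7.49 um  fwhm  45.16 um  area   165.6 um^2
  unidented   width   17.7 um  depth  6.36 um  fwhm   9.34 um  area    58.8 um^2
  unidented   width   16.2 um  depth  3.71 um  fwhm   8.51 um  area    31.4 um^2
  multidented width   62.4 um  depth  6.09 um  fwhm  54.68 um  area   197.5 um^2
  unidented   width   13.4 um  depth  7.73 um  fwhm   7.16 um  area    54.9 um^2
  multidented width   49.5 um  depth  6.66 um  fwhm  43.27 um  area   170.9 um^2
  bidented    width   23.2 um  depth  7.50 um  fwhm  17.16 um  area    87.9 um^2
```

All ten generated pits are recovered; the multidented pits are wider and
carry several-fold more eroded area than the unidented ones, which is the
morphological signature the cohort statistics operate on.

The same pipeline runs from the shell. `pitscan simulate` writes traces, a
cohort manifest, ground truth and planar masks; `analyze` produces per-trace
pit tables and `subject_summaries.csv`; `stats` writes the comparison table:

```sh
pitscan simulate --out run/sim --seed 1
pitscan analyze  --manifest run/sim/manifest.csv --out run/analysis
pitscan stats    --summaries run/analysis/subject_summaries.csv --out run/stats
# or all three: pitscan run-all --out run --seed 1
```

Cohort layout, per-cell generative presets and detection parameters are all
configurable from YAML (see `CohortSpec.from_file` and
`RunConfig.from_file`); every run echoes its resolved configuration.

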