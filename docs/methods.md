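# Methods

## The measurement problem

Osteoclasts cultured on bone discs excavate resorption pits. A stylus
profilometer dragged across a resorbed disc produces a 1-D height profile
(position μm, height μm) in which pits appear as excursions below the level
of the unresorbed surface. The morphology of these excursions carries
biological signal: a pit consisting of a single dent (*unidented*) records
one resorption event, while *bidented* and *multidented* pits — dents joined
below one excavation, separated by ridges rising back to the surface level —
record continuous resorption uninterrupted by migration. `pitscan` turns raw
traces into per-pit metrics (width at the surface, maximum depth, full width
at half maximum, sub-surface cross-sectional area in μm²), per-subject
summaries, and the cohort's nonparametric comparisons.

All quantities are measured relative to the estimated unresorbed-surface
baseline, not to the instrument zero. Emulated scan geometry matches the
instrument settings of the source study: 1000 μm scan length, 0.056 μm
sampling interval (17 858 samples), ±65.5 μm vertical range.

## Baseline estimation

The unresorbed surface level is not observed directly and a scan may be 30 %
or more eroded. Symmetric robust estimators (median/MAD) fail here in a
specific way: erosion contaminates the height distribution *only from
below*, so pit flanks inside any symmetric band drag the level down and
inflate the scale estimate. We therefore fit the **upper residual mass**:

1. Initial level = median of all heights; initial scale from the upper-sided
   MAD (1.4826 × median of the non-negative centred residuals).
2. Iterate (×3): samples at or above the current level form, to noise
   crossings, a half-normal sample of the surface roughness. Its 25th and
   75th percentiles identify both a level correction
   (`q25 − 0.3186·σ`) and the noise scale (`σ = (q75 − q25)/0.8317`).
3. A linear trend replaces the constant level when its slope t-statistic
   exceeds 4 on the unresorbed band (`baseline_trend="auto"`; `"constant"`
   and `"linear"` force either choice). The trend is only fit from the
   second iteration on: on a first-pass band that still spans eroded
   terraces, a tilted line is spuriously significant and would swallow the
   erosion signal.

The fixed point of step 2 is the true surface for arbitrary amounts of
one-sided contamination, with sampling error well inside the
`3·σ/√n` contract. If fewer than `min_unresorbed_fraction` (default 25 %)
of samples end within ±3σ of the final level the scan is rejected as fully
eroded (`BaselineError`); the analysis pipeline skips such scans with a
logged reason. Note the guard is conservative: a scan eroded at many
distinct depths can still defeat any baseline estimator without tripping it.

## Segmentation and dent counting

Topology decisions use a centred moving average (window 1.0 μm ≈ 18
samples, configurable); geometry is always measured on the raw trace so
smoothing cannot bias the metrics.

* **Seeds**: runs where the smoothed deficit (level − smoothed height)
  exceeds `depth_gate = max(3·noise_sigma, min_depth/2)`.
* **Separators**: a pit ends where the *raw* deficit returns to within the
  noise gate (`2·noise_sigma`) for at least `min_width` (default 1.0 μm)
  contiguously. Requiring a sustained return means isolated noise crossings
  at an intra-pit ridge cannot split a compound pit, while genuinely
  distinct pits separated by surface are split; boundary positions are
  linearly interpolated at the noise-gate crossing on the raw trace, so a
  noiseless pit boundary is located to within one sample.
* **Filters**: extents with maximum raw drop < `min_depth` (default 0.5 μm)
  or width < `min_width` are discarded.
* **Dents**: a separating ridge is a local maximum of the smoothed profile
  strictly inside the extent with topographic prominence ≥ `depth_gate`
  (stylus noise cannot fake one) whose apex rises to within
  `ridge_tolerance = max(2·noise_sigma, ridge_fraction·depth)` of the
  baseline (`ridge_fraction` default 0.10). The apex height is evaluated as
  the raw-trace median over 5 samples at the peak: the moving average
  flattens a sharp cusp downward by ~0.1 μm, enough to misread shallow
  bidented pits as unidented if the smoothed value were used. Dent count =
  1 + number of qualifying ridges; 1 → unidented, 2 → bidented, ≥3 →
  multidented.

Per-pit metrics: width = distance between interpolated boundaries; depth =
maximum raw deficit (leftmost sample on ties); FWHM = distance between the
outermost interpolated crossings of the half-depth contour (one value per
pit, also for compound pits); area = trapezoidal integral of the raw
deficit over the extent. Planar resorption (% of disc surface) is the pixel
fraction of a binary mask.

## Cohort statistics

Pits are pooled per subject × culture condition across discs and scans
(per-disc pooling available via `per_disc`). Per-subject summaries hold the
median width/depth/FWHM per shape class (missing, not zero, for empty
classes), shape percentages (always summing to 100 when any pit exists),
the median individual pit area (`area_mode="per_scan_total"` instead
medians each scan's total eroded area), and optionally the planar percent.

The comparison design mirrors the study: Kruskal-Wallis (tie-corrected,
chi-square approximation) across the three groups per condition; pairwise
and between-condition Mann-Whitney U tests (exact by enumeration when
n₁+n₂ ≤ 12 without ties, otherwise normal approximation with tie and
continuity correction; U reported as min(U₁, U₂)); Pearson chi-square
without continuity correction for pooled categorical shape counts
(optional, `shape_test="chi_square"`; the default tests each class's
subject-level percentages with Mann-Whitney). Significance is reported per
row at α = 0.05 with no multiplicity correction, matching the source
design. Quartiles use inclusive linear interpolation. Cells with fewer
than two subjects are flagged `insufficient n` and not tested.

## Synthetic cohorts

The generator emulates resorbed-disc scans, calibrated so the published
outcomes are its recovery targets:

* **Pits** follow a Poisson process, 7.5 pits/mm by default (≈75 pits per
  subject-condition over ten 1000 μm scans), placed uniformly with full
  support inside the scan and ≥5 μm between pits (rejection sampling, up to
  100 redraws then drop; >50 % drops raise an error).
* **Shape**: dent count from the cell's mixture (≥3 resolved uniformly on
  {3, 4}); each dent is a raised-cosine bump (compact support; exact area
  d·w/2 and half-depth width w/2; Gaussian optional) with log-normal depth
  and per-dent width. Consecutive dents are spaced so the internal ridge
  rises to `ridge_relief` (default 0.05) × the deeper neighbour's depth
  below baseline, floored at 3× the noise level (so roughness cannot sever
  a ridge) and capped at half the shallower dent (so both lobes stay
  distinct).
* **Noise**: additive Gaussian roughness, σ = 0.05 μm.
* **Presets** (group × condition): Charcot/RANKL uses mixture
  0.36/0.24/0.40 (unidented/bidented/multidented), depth median 5.0 μm,
  dent width median 15 μm, planar median 20 %; Charcot/anti-TNF-α uses
  0.53/0.22/0.25, 3.5 μm, 10 μm, 14 % (the 30 % planar reduction); diabetic
  and control cells share the normalised mixture/geometry in both
  conditions with planar median 8 %. Depth/width scales are free defaults
  chosen to make Charcot/RANKL pits visibly deeper and wider; the source
  reports those medians only in a prior publication.
* **Between-subject variability**: multiplicative log-normal jitter
  (sd 0.15) on density, depth, width and planar medians and on the mixture
  (renormalised), drawn once per subject and shared across conditions.
* **Planar masks**: Boolean model of random ellipses; total drawn area
  −ln(1−p)·A so the expected union fraction equals the target p. 512×512
  grid, text PGM output.
* **Reproducibility**: every stream derives from
  `SeedSequence([master_seed, stream, subject_index, substream])`; no state
  is shared across subjects, so identical (spec, seed) runs are
  byte-identical and any subject can be regenerated alone.

What the generator does *not* emulate: spatially correlated bone roughness
(lamellae, canals), stylus-tip convolution (2.5 μm radius), pit asymmetry
and trench-like elongation, scan-to-scan registration on a real disc, and
any coupling between planar masks and sub-surface traces. Passing recovery
tests therefore demonstrates that the analysis chain is unbiased for
pit-shaped signals in uncorrelated noise, not that it is robust to every
artefact of real Dektak data.

## Problem sizes and numerical conventions

The validation suite simulates the full study geometry: 10/8/9 subjects ×
2 conditions × 10 scans of 17 858 samples (540 traces per cohort). Shape
recovery and pit yield use the 10-subject Charcot cohort; the significance
pattern is checked over 20 master seeds of the full cohort; the planar
contrast over 20 seeds of mask generation. Crossing positions are linearly
interpolated between samples; depth ties resolve to the leftmost position;
positions are uniform in the generator but the analysis integrates on the
native grid without resampling. Trace files round-trip to 1e-9 μm.

## Known limitations

* FWHM is reported once per pit (outermost half-depth crossings); per-dent
  FWHM of compound pits is not computed.
* Compound pits whose maximum depth is ≲2.5 μm at σ = 0.05 μm sit in an
  intrinsically ambiguous regime: a ridge deep enough to survive the noise
  gate can exceed the 10 %-of-depth ridge tolerance. Dent counts for such
  pits are uncertain in either direction.
* The baseline rejects fully eroded scans but cannot flag a scan eroded
  uniformly to a single lower plateau (indistinguishable from surface).
* Scan-level clustering within subjects is ignored by the rank tests, as in
  the source design; no confidence intervals are attached to medians.
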