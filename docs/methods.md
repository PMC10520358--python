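# Methods

## Assay model

A screen is modelled as a grid chip (`ChipLayout`): 532 spots on a
14 × 38 row-major grid at 1.5 mm pitch, 0.75 mm pillar spots (1.2 mm for
the well chip) — the only factorization of 532 consistent with a
75 × 25 mm slide at that pitch. A `RegionMap` assigns spots to 72 drug
regions of 6 technical replicates in consecutive row-major blocks,
regions numbered 1–72 to match compound numbering; the final 100 spots
are unused. The physical plate map of the original device is not public,
so the block assignment is a deterministic convention, not a claim about
the hardware; every statistic downstream is invariant to which spots a
region occupies. Spot indices are 0-based, region ids 1-based, vehicle
controls default to regions 1 and 37.

## Statistics

**Relative viability.** For each region, the live fluorescent area is
averaged over valid replicates (arithmetic mean, no trimming) and divided
by the mean area of the designated DMSO control region, ×100. Only
region 1 normalizes; region 37 is carried through like a drug, serving as
a plate-consistency QC readout (it reads 90.87% / 110.86% in the packaged
panel, which is only consistent with single-region normalization).
Values above 100% are kept — under resistant 3D conditions most drugs
exceed the control.

**Panel Z-scores.** `z = (RV − mean) / SD` with mean/SD over one culture
condition's panel. Two conventions are left open by the formula: whether
controls enter the statistics, and population vs sample SD.
`calibrate_zscore_convention` fits all four variants against the packaged
panel's printed Z columns; *controls included + population SD* wins with
max |Δz| ≤ 0.0051 across both panels (next best: 0.018), and is the
package default. Because rounded inputs cannot prove the original choice
beyond doubt, the calibration table ships with every reproduction report
rather than being asserted silently.

**Linear distance.** `ld = (−z_3D + z_2D) / √2`, the signed perpendicular
distance from the identity line of the (z_2D, z_3D) plane; positive
means relatively stronger kill under 3D. The sign convention follows the
printed formula (no absolute value); the function is antisymmetric.

**Hit rule.** `z_3D ≤ −1` (inclusive) and `ld > 1` (strict), vehicle
controls excluded, hits ranked by descending ld. On the packaged panel
this yields exactly {regorafenib, everolimus, LGK-974, XL147}. The
alternative reading `z_3D < 1` that appears in one caption admits a
much larger set (10 compounds) and is kept only as a regression guard.

**Resistance shift.** Over non-control compounds: the count with
RV_3D > RV_2D (70/70 in the packaged panel) and the through-origin
least-squares slope of RV_3D on RV_2D (1.89). Both the dominance count
and the slope are reported because "distributed with slope ≥ 1" can be
read either way.

**Subculture QC.** Proliferation rate = 100 × recovered/seeded per 4-day
passage; stability is summarized by mean, sample SD (n−1) and
CV = 100 × SD/mean over six passages, with CV < 5% the stability
criterion. Internal values keep full precision; reports round half-up
(2 dp for screen tables, 1 dp for QC).

## Reproduction tolerances and known discrepancies

Comparisons to printed values always use tolerances, never rounding
equality. Printed Z columns: |Δ| ≤ 0.03 (achieved: ≤ 0.0051). Linear
distances: ±0.02 from printed Z, ±0.03 via the full viability chain; the
LGK-974 distance recomputes to 1.5768 (→ 1.58) against a printed 1.57,
consistent with truncation or unrounded inputs upstream, and is treated
as tolerance.

The published QC summary row for alginate (463.7 / 10.9 / 2.4) matches
the computed 463.767 / 10.969 / 2.365 only if the first two were
truncated at 1 dp while the CV was rounded; comparisons therefore accept
one unit of the last printed digit. The published Matrigel STDEV 5.4 and
CV 0.8 are **not** reproducible from the printed rates under any SD
convention (sample SD 7.73, population 7.06); the mean absolute
deviation (5.47) matches the printed value, suggesting a different
dispersion statistic was used for that row. `compare_to_published` flags
these entries as irreproducible instead of force-matching them.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes,
not the biology or optics of the instrument:

- **True effects** (`EffectSpec`): 2D viability uniform on [0, 100]%,
  3D = 2D + 75 points (the observed panel-mean gap between monolayer and
  dome screens, 27% vs 103%) + Gaussian scatter (SD 10 points),
  truncated at 0. Controls are pinned at 100%.
- **Spot areas**: area = base_area × viability/100 × lognormal noise
  with unit mean and CV `noise_cv` (σ² = ln(1 + cv²)), i.e. positive
  multiplicative replicate noise; spots then drop out with probability
  `dropout_p`. Replicate variability of the real instrument is
  unpublished, so the default CV of 5% is illustrative, not fitted.
- **Images**: 16-bit grayscale at 20 px/mm, background 500, foreground
  20 000, optional Gaussian blur. Each valid spot is drawn as a disk of
  exactly `round(area)` pixels, filled in order of distance from the
  spot center with ties broken row-major — deterministic and area-exact,
  which is what makes pixel-level oracles possible. The default base
  area of 80 px for a fully viable spot leaves headroom inside the
  0.75 mm disk (capacity ≈ 172 px at 20 px/mm) for resistant spots near
  twice the control area.

What the generator does **not** emulate: dose–response (the assay is
single-concentration, 20 µM), spatial plate effects (row/column or edge
gradients), intensity variation within spots, optical vignetting, debris
and segmentation artefacts, or cell-growth kinetics. Passing synthetic
tests therefore validates the arithmetic chain and its conventions, not
robustness to real scanner pathologies.

## Quantification

Grid registration projects mean intensity onto each axis and
peak-detects (prominence 5% of the profile range). Pitch is fit from
peak spacings allowing integer multiples, so whole dark rows/columns —
e.g. the 100 unused spots, or fully lethal regions — are tolerated as
long as two peaks remain per axis; a blank image raises an error
carrying the observed peak counts. The origin is the first peak, or is
phase-locked to an approximate origin when provided. Rotation and skew
are assumed negligible (slide scanner).

Per-spot areas are counts of pixels strictly above threshold inside
half-open one-pitch windows centered on grid nodes; the windows
partition the image, so no pixel is counted twice. The default
threshold is Otsu's method per image (the instrument's rule is
unpublished), overridable by a fixed level; on clean bimodal synthetic
images both agree exactly. Areas are integer pixel counts — no subpixel
estimation.

At zero noise/blur/dropout the full chain (effects → areas → image →
registration → quantification → viability) is exact by construction
when planted areas are integers, and the test suite asserts this
pixel-for-pixel.

## Problem sizes and determinism

Everything is seeded (`numpy.random.default_rng`); generators called
twice with identical arguments are bit-identical, and pipeline reruns
produce byte-identical CSVs. The test suite uses the full 532-spot chip
for geometry/imaging checks, Monte-Carlo sizes of 10 000 draws for
distribution calibration, and 100 seeded paired screens (22 regions × 6
replicates each) for hit-recovery power, keeping the default run around
five seconds while leaving the statistical assertions well-resolved.

## Limitations

- The region-to-spot map is a convention; analyses of *spatial* failure
  modes (edge effects, gradients) would need the real plate map and are
  out of scope, as are B-scores and plate-effect corrections, which the
  assay's single-chip design does not define.
- Hit calling is threshold-based as specified; no multiple-testing
  control or dose–response potency estimation is attempted.
- The dish used for 3D subculture is modelled as metadata only
  (`DishLayout`); proliferation-rate QC takes counted cells as input.
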