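# Methods

## The measurement

The package quantifies *spatial heterogeneity of local intensity asymmetry*
in a tumour region of interest (ROI) on T2-weighted MRI, and uses it as a
univariate imaging biomarker for response to neoadjuvant chemoradiotherapy
in locally advanced rectal cancer.  The underlying idea: an evolving tumour
alters its tissue sub-regions at different rates, so the *local* intensity
distribution departs from symmetry differently from place to place; a tumour
whose local skewness varies strongly across the ROI behaves differently
under therapy than one whose local skewness is uniform.  The statistic that
operationalises this is s_e, the Shannon entropy of the pooled local-skewness
map (`skewness_entropy`).

## Local parametric maps

Each slice is processed independently in 2D; slices are matched with binary
ROI masks, and arrays use row-major, 0-based, pixel-centre conventions.
In-plane pixel spacing must be isotropic (a *square* tissue unit is
otherwise ill-defined) and is a required input, never read from headers.

A square window of physical side `tissue_unit_mm` (default 5.0 mm) is
converted to an odd pixel count w: the odd integer nearest to
`tissue_unit_mm / pixel_spacing_mm`, ties broken toward the smaller odd
integer, with a hard floor of 3 px (coarser grids raise an error rather
than degrade into 1-pixel "windows").  At 0.5 mm spacing the default unit
is 9 px.

At every window position whose centre lies in the ROI, whose window lies
fully inside the image, and whose in-ROI pixel fraction is at least
`min_inmask_fraction` (default 1.0 — windows fully inside the tumour, so
intestinal lumen and background never contaminate the statistics), seven
first-order statistics of the w×w intensity multiset are recorded:

| statistic | definition |
|---|---|
| entropy | base-2 Shannon entropy of a histogram with `local_entropy_bins` (32) equal-width bins over the window's own [min, max] |
| mean / median | arithmetic mean; interpolated middle value |
| skewness | Fisher–Pearson m₃/m₂^{3/2}, population (biased) moments |
| kurtosis | excess kurtosis m₄/m₂² − 3, population moments |
| iqr | Q3 − Q1, linear-interpolation quantiles |
| cv | population sd / mean |

Zero-variance windows take the sentinel 0 for entropy, skewness, kurtosis,
iqr and cv, keeping every map finite where defined; cv additionally falls
back to 0 (with a logged warning) when |mean| < 1e-12, which can only occur
in degenerate synthetic input since T2w magnitudes are non-negative.
Binning the entropy over each window's own range makes the entropy, like
skewness, kurtosis and cv, invariant under intensity shift and positive
scaling; mean, median and iqr transform covariantly.  These invariances are
enforced by tests.

Maps are computed densely (stride 1) by default; `window_stride_px = w`
reproduces non-overlapping tiling.  The dense path is vectorised but
mirrors the scalar definitions exactly — a brute-force per-window
recomputation is the test oracle.

## Global features

Map values at valid centres are pooled across *all* slices of a patient
into one sample per map (one histogram per patient; the per-slice
alternative — descriptors averaged over slices — was considered and
rejected in favour of the single pooled histogram).  Twelve descriptors per
pooled sample: maximum; sample SD (n−1); median absolute deviation
(unscaled, no 1.4826 factor); mean and median of the *last decile* (values
at or above the 90th linear-interpolation percentile); and the same seven
statistics as the local maps, with `global_entropy_bins` (64) bins — pooled
samples are far larger than 81-pixel windows, so they support a finer
histogram.  7 maps × 12 descriptors = 84 features with canonical names
`<map>_<descriptor>` in a fixed order; `skewness_entropy` is s_e.

T2w intensities are used raw.  No normalisation is applied before
extraction; intensity-carrying features (mean/median maps and their
descriptors) are therefore scanner-dependent, a documented caveat.
Shift/scale-invariant features, s_e included, are unaffected.

## Selection and evaluation

Responders (TRG 0–1) are the positive class.  Selection runs in three
steps: (1) a one-tailed Wilcoxon rank-sum test per feature at α = 0.05
discards non-discriminative features; (2) survivors are ranked by
Bonferroni-corrected p with multiplicity m = number of survivors
(configurable to m = 84); (3) the minimum is selected.  The reported
family-wise threshold is α/m.  Because the 84 features are unsigned, the
one-tailed direction is set per feature from the sign of the observed
group-median difference — a post-hoc choice that inflates the type-I
error; the package logs a warning to that effect whenever selection runs.
Ties in corrected p are broken by raw p, then by canonical feature order
(deterministic and documented; see Limitations for when this matters).
An empty survivor set yields an explicit "no discriminative feature"
result, not an exception.

The Wilcoxon p-value is exact (full enumeration) when the combined sample
is ≤ 16 without ties, otherwise the tie- and continuity-corrected normal
approximation.  AUC uses the Mann–Whitney pair-concordance formula (ties
count ½); its 95% CI is a stratified percentile bootstrap (resampling
within each class, `bootstrap_reps` = 2000, seeded).  The Youden-optimal
cut-off is scanned over midpoints between consecutive distinct scores plus
±∞; ties in the Youden index favour higher sensitivity (clinically: never
exclude a responder unnecessarily), then the lower cut-off.  Score
orientation is auto-detected (scores negated when AUC < 0.5, and the flip
recorded).  Confusion identities (SE, SP, PPV, NPV, YI vs TP/FP/TN/FN) are
re-verified internally before any report is written.  Group summaries use
the same linear-interpolation quantile convention as everything else.

The ratio r = N/l (smallest class size over number of selected features)
is the overfitting guard; the pipeline hard-wires l = 1 and flags any
configuration with r < 10.

## Synthetic phantoms

Cohorts of this kind are private, so the generator builds what the analysis
assumes about them, not their anatomy.  Each phantom slice is a circular
ROI (radius 32 px ≈ 1.6 cm at 0.5 mm spacing, default 3 slices of 96×96)
partitioned into 8 Voronoi cells around RNG-placed seed pixels — random
placement avoids aliasing between a regular cell grid and the sliding
window.  Every cell draws standardized skew-normal deviates (population
mean 0, sd 1 exactly) mapped to `base_intensity + noise_sd·z` (400 ± 20,
arbitrary T2w units), with the shape parameter drawn once per cell from
Uniform(−spread, +spread): responder-like phantoms use spread 6 (cell
skewness up to ≈ ±0.9), non-responder-like phantoms spread 0 (pure
Gaussian, uniform skewness ≈ 0).  Standardizing the cells pins every cell's
mean and sd so the groups differ in the *heterogeneity of asymmetry*, not
in first-order intensity statistics — the mechanism under test.  Background
outside the ROI sits at half the base intensity with Gaussian noise, so the
in-mask window criterion is genuinely exercised.  Cohorts derive per-patient
seeds from the cohort seed through an integer `SeedSequence`, making every
stack bit-reproducible across platforms.  Default cohort: 15 responder-like
vs 25 non-responder-like phantoms.

What the phantoms do *not* emulate: MRI physics (Rician noise, bias
fields), anatomy-shaped lesions, inter-patient biological variability, or
partial-volume effects.  Passing tests therefore show that the pipeline
detects spatial heterogeneity of local asymmetry when present — not that
s_e is a validated clinical biomarker.

## What the phantom experiments show — and a known limitation

Paired phantoms differing only in spread (6 vs 0, same seed) recover the
core mechanism: the heterogeneous twin has the higher s_e in ~95% of seed
pairs (the s_e gap is modest because binning entropy over the pooled
sample's own [min, max] lets the heterogeneous map's wider tails stretch
the range and partially offset its flatter histogram).

End-to-end cohort selection behaves differently, and deliberately so is
reported as a limitation rather than patched: with fixed per-group phantom
templates the only within-group variability is sampling noise, so the
15-vs-25 groups separate *completely* on dozens of features — shape
heterogeneity necessarily leaks into every shape-sensitive local statistic
(skewness dispersion descriptors, median-map SD, intensity-entropy means),
not only into s_e.  All completely-separating features share U = 0 and
hence the identical one-tailed p floor (≈ 8.7×10⁻⁸ at 15 vs 25); Bonferroni
preserves the tie, and the winner is then decided by the deterministic
tie-break, not by the data.  s_e, whose phantom-cohort AUC is ≈ 0.95–1.0
but rarely exactly 1, is therefore almost never the unique p-minimum on
phantom cohorts, even though it carries the designed signal.  On clinical
cohorts — with real inter-patient variability keeping effect sizes well
below complete separation — this degeneracy does not arise.  Rescuing the
phantom experiment would require weakening the generator's effect size or
adding inter-patient template variability; both would change the stated
study conditions, so the behaviour is documented instead of hidden.

## Problem sizes

The test suite brute-forces windows on images up to 64×64, enumerates
rank-sum permutations up to combined n = 12, and runs the mechanism checks
at full phantom scale (20 seed pairs; 25 cohorts of 40 phantoms, 96×96×3).
The acceptance script uses the same sizes.  A full 40-patient cohort
extracts in a few seconds on one core.

## Known limitations

- One-tailed directions chosen post hoc from the data (logged; see above).
- Raw intensities; no inter-scanner harmonisation.
- 2D windows only; through-plane texture is ignored by design.
- Entropy bin counts (32 local / 64 global) are defensible defaults, not
  derived quantities; both are configurable and results depend on them.
- The Bonferroni multiplicity uses step-1 survivors by default; using all
  84 tests is stricter and available via configuration.
- Phantom cohort selection is tie-break-dominated at the default effect
  size (previous section).
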