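# Methods

## Synthetic section model

Each generated section emulates a bright-field scan of a DAB-Ni
immunostained brain section at 1.6 µm/px:

- **Cells.** Centers follow a homogeneous Poisson process with intensity
  `cell_density` (default 350 cells/mm², chosen to give a ~3% baseline
  stained-area fraction, a typical sparse activation level). Each cell is
  a stained cytoplasmic annulus between a nucleus radius and an outer soma
  radius (defaults 3 and 6 µm; per-cell radii vary with 10% relative
  spread, the nucleus scaling proportionally). Overlapping annuli merge by
  mask union. The nucleus disc stays at background, matching the
  cytoplasm-confined localization of the stain.
- **Stain polarity.** Stained pixels are *darker*: the annulus is
  depressed by `stain_level` (default 0.35) below the local background
  (default 0.85). All quantification operates on inverted intensity.
- **Unspecific background.** A zero-mean low-frequency field (coarse
  Gaussian grid at 32 px spacing, cubic-spline upsampled, rescaled to
  `background_stain_sd`, default 0.02) is added to the background. It
  mimics the faint blotchy ABC-kit background staining that makes even
  cell-free areas identifiable; it challenges thresholding but never
  enters the ground-truth mask.
- **Noise.** I.i.d. Gaussian (`noise_sd`, default 0.02), then clipping to
  [0, 1].

The ground truth of a section is exactly the set of annulus pixels; the
per-ROI true fraction is the mask count inside the ROI over the ROI pixel
count, so recovery statements are exact, not approximate.

**What the generator does not emulate:** realistic neuron morphology
(dendrites, processes), section artefacts (folds, tears, debris the real
scorer was instructed to exclude), intensity gradients from uneven
staining chemistry, slide-level layout, registration error, or spatial
correlation of activation within a region. Passing tests therefore show
that the measurement and statistics layers are correct and calibrated
*given* the stated image model; they do not certify performance on real
histology, where threshold choice and artefact exclusion dominate.

## Cohort layout

Defaults encode the study conditions: 19 named brain regions, four groups
(control, avoidance, trained, novelty) of 10 animals, and 4 ROIs per
animal × region — the smallest count consistent with "more than 3000
individual areas" over 19 regions × 40 animals (3040). Sides and sections
are emulated only as independent ROIs (alternating L/R labels, section
index), since quantification consumes ROIs, not anatomy; each ROI gets its
own image frame. Group effects enter as positive multipliers on the cell
density per (group, region); the control group is pinned to 1.0. Expected
true fraction is monotone in density and multiplier (up to annulus
overlap, which saturates very slowly at these densities).

## Measurement

- **Normalization.** Images are rescaled to [0, 1] by declared bit depth
  (8- or 16-bit TIFF) before inversion.
- **Rasterization.** Polygons use 0-based pixel coordinates; a pixel
  belongs to the ROI iff its center lies strictly inside the polygon.
  Boundary-center pixels are excluded, making masks bit-reproducible.
  ROIs extending beyond the raster are a hard error, never clipped.
- **Threshold rule.** Background per ROI is the median inverted
  intensity, spread the scaled MAD (×1.4826, so `k` reads in σ-like
  units); a pixel is stained iff inverted intensity exceeds
  `median + k·MAD` with k = 5 by default. The rule assumes stain covers a
  minority of the ROI — the regime the generator (and sparse pS6
  activation generally) lives in. For near-saturated ROIs the local
  median sits on the stain itself and the rule under-detects; callers can
  pass a reference `BackgroundEstimate` measured on a stain-free area
  instead. At k = 5 with the default noise, false-positive pixels are
  rare (≲1% of a cell-free ROI) and true annulus pixels sit ~12 MADs
  above threshold, which is why measured fractions track truth to ~10⁻³.
- **Pooling.** Animal × region values are area-weighted:
  Σ stained / Σ total over the animal's ROIs — the pooled form of "area
  stained divided by total area segmented", not a mean of ratios.
- **Blinding.** Presentation frames expose only position, blinded ID and
  image path; the sealed key is written separately. The blind order is a
  seeded uniform permutation.

## Statistics

- **U test.** Pair-count convention with half-credit for ties. For
  n₁+n₂ ≤ 20 and tie-free data the two-sided p is exact: the fraction of
  all C(n₁+n₂, n₁) labelings whose U is at least as far from n₁n₂/2 as
  observed, computed from the null distribution built by a subset-sum
  dynamic program over ranks (equivalent to full enumeration, and tested
  against explicit enumeration). Ties or larger samples use the normal
  approximation with tie-corrected variance and 0.5 continuity
  correction. Two-sided p was chosen because effects in both directions
  are reported; at the study's n = 10 vs 10 the exact test's true size at
  α = 0.05 is ≈ 0.043 due to discreteness.
- **Log ratio.** log₁₀(mean_group / mean_control) on per-animal pooled
  fractions (animal-level averaging, so each animal counts once
  regardless of its ROI count). Base 10 by default, configurable.
  Non-positive means raise rather than being patched with a pseudo-count;
  degenerate zero-staining configurations should be avoided by using
  fields large enough to contain cells.
- **Multiplicity.** Uncorrected per-region p < 0.05 flags by default (one
  star per region, as in the source analysis style); Benjamini–Hochberg
  is available via `correction="bh"`.
- **Calibration harness.** `error_calibration` runs the *full* chain
  (generate → measure → pool → test) per replicate on a reduced field:
  96 × 96 px, single region, 2 ROIs per animal — sizes chosen as the
  package's simulation defaults so that a 1000-replicate null calibration
  completes in minutes while still exercising every pipeline stage.
  Because measured fractions are ratios of integer pixel counts over a
  common denominator, occasional ties occur and those replicates use the
  tie-corrected approximation; the mixture stays within the binomial band
  around α.

## Behavioral scheduling

Rotational schemes are drawn uniformly from the valid set (5 L/5 R,
no run of three) by rejection sampling from balanced permutations —
uniform because the schemes were "randomly determined" with no stated
distribution; the valid set has exactly 84 elements (enumerated, and
cross-checked by an independent recursion in the tests). Four schemes
cycle over every four sessions, two sessions per day. The learning
criterion (≥7/10 correct in three consecutive sessions) is evaluated
online and returns the first qualifying session. The habituation schedule
(4 trials/session, 3 sessions/day, final day one session; 30 s
stimulus-to-food, stimulus off 2 min after food, 5 min inter-trial;
single 30 s novel-stimulus presentation) is carried as metadata — choice
behavior itself is not modelled beyond the Bernoulli test learner.

## Pipeline and reproducibility

The master seed expands into per-stage seeds through
`SeedSequence.spawn` in fixed order (cohort, blinding), keeping every
stage independently replayable; all derived seeds stay below 2³¹. All
artifacts use open formats (16-bit TIFF, JSON polygons, CSV tables), with
image paths stored relative to the cohort directory so re-runs are
byte-identical wherever they land. The manifest records config, config
hash, seeds, package and numpy versions, and SHA-256 of every table. A
non-empty output directory is refused without an explicit overwrite flag.

## Known limitations

- The per-ROI robust threshold is the package's documented substitute for
  the (unavailable) original automated workflow's detection operator; k
  is a free parameter with a fixed default, not fitted.
- Saturated ROIs (majority stained) under-detect without a reference
  background (see above).
- ROI-level correlation within animals is handled by pooling, not by a
  hierarchical model.
- Quantization to 16-bit on disk perturbs fractions at the 10⁻⁴ level
  relative to in-memory measurement.
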