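# Methods

## Problem and pipeline

`afspectra` analyses spectral autofluorescence image cubes of retinal
cross-sections excited at 488 nm: 21 emission channels at 6 nm spacing,
496–616 nm, one 12-bit image per channel. The analysis chain is

1. **Cube assembly** (`cube_io`) — per-channel TIFFs are stacked into a
   `SpectralCube`; a pseudo-RGB rendering (thirds of the emission range
   averaged into blue/green/red) supports visual ROI selection.
2. **Peak estimation** (`spectral_fit`) — an ordinary least-squares
   second-order polynomial `I(λ) ≈ aλ² + bλ + c` is fitted over all 21
   channels and the emission peak is taken analytically at the vertex
   `−b/(2a)`. A fit is *valid* only if concave (`a < 0`) with its vertex
   inside the axis span; invalid fits are excluded from every average and
   their fraction reported. Two modes exist because both are natural units
   of averaging: per-pixel fits averaged over a region (default for
   granule-sized ROIs) and a single fit to the region's mean spectrum
   (used by the macroscopic pipeline).
3. **Wavelength calibration** (`spectral_fit`) — reference microsphere
   fields imaged at the start and end of each session are fitted the same
   way; the additive offset `546 − mean(start, end)` (vendor bead reference,
   configurable) is added to every tissue peak of the session. The offset is
   applied to final peak wavelengths, which under shift equivariance of the
   quadratic vertex is equivalent to relabelling the axis.
4. **Macroscopic segmentation** (`segmentation`) — structural pixels are
   selected by thresholding total (channel-summed) intensity; the default
   threshold is Otsu's method on the log-total, which is parameter-free and
   invariant to global gain, with an absolute-value override. The combined
   mask is split by the band rule: `score = mean(526–538 nm channels) −
   mean(598–610 nm channels)`; positive scores are Bruch's membrane (BrM),
   negative are RPE, zero stays unassigned. Relative area is the BrM/RPE
   pixel-count ratio; relative intensity is the ratio of mean channel-summed
   intensity. Bands include every channel whose centre lies in the closed
   interval and are averaged, not summed, so unequal band sizes on
   non-default axes remain comparable.
5. **Cohort statistics** (`cohort_stats`) — the sampling unit is the donor
   eye: per-image metrics are averaged unweighted within eye and region
   (macula, periphery, and a pooled "combined"), and groups are compared on
   per-eye values with a two-tailed pooled-variance t-test
   (df = n₁ + n₂ − 2). Group spread is the SEM of per-eye means. No
   multiple-testing correction is applied by default.

## Synthetic scenes

No donor-eye images are distributed with this package, so every stage is
validated by parameter recovery on scenes from `synthetic_scene`:

- **Geometry** — a full-width horizontal BrM band (default 10 px thick)
  with an RPE stratum above it containing disk-shaped lipofuscin granules
  (1 µm ≈ 8 px diameter at the default 0.125 µm pixels) and annular
  melanolipofuscin granules (fluorescent ring, dark melanin core rendered at
  background level), plus optional drusen disks in the gap. Granules are
  placed by uniform rejection sampling; they may touch but never overlap.
  The total granule pixel count is chosen (final granule trimmed
  centre-outward) so the realised BrM/RPE area ratio matches the configured
  target to within a pixel.
- **Spectra** — each component emits a Gaussian in wavelength,
  `amplitude · exp(−(λ − peak)²/(2·width²))`. Defaults: BrM 549 nm
  (amplitude 1000), lipofuscin 575 nm, melanolipofuscin ring 578 nm
  (amplitude 2000), drusen 560 nm, microspheres 546 nm (amplitude 3000),
  plus a weak flat background (amplitude 50, width 200 nm). The BrM/granule
  amplitude ratio puts the relative BrM/RPE intensity near 0.5, in the range
  seen in tissue.
- **Spectral width** — the default standard deviation is 70 nm
  (FWHM ≈ 165 nm) for all components. Two reasons: lipofuscin-type
  autofluorescence emission is genuinely very broad (FWHM well above
  100 nm), and the quadratic-vertex estimator is only trustworthy when the
  spectrum is parabola-like across the 120 nm collection window. The
  vertex of a full-axis quadratic fitted to a *narrow* Gaussian is pulled
  toward the window centre — the bias is ≈ 2–4 nm at widths of 20–30 nm and
  falls below 1 nm at 70 nm for peaks in 546–576 nm. A generator default in
  the narrow regime would make the estimator systematically wrong by more
  than the effects under study (a ~4 nm group difference), so the wide
  regime is the study condition. Peaks outside ~540–580 nm retain larger
  edge-truncation bias; this is a known limitation of full-window quadratic
  peak interpolation.
- **Noise** — Poisson shot noise with mean equal to the expected intensity,
  additive Gaussian read noise (default sd 10 counts), then rounding and
  clipping to [0, 4095]. A fixed seed makes a render bit-identical.
- **Drift** — spectrometer instability is a single additive wavelength
  offset per session applied to every component; ground truth records both
  the undrifted peaks and the drift, so calibration recovery can be tested
  end to end.
- **Cohorts** — an "eye" draws a true combined RPE+BrM peak from
  Normal(group mean, between-eye sd), with between-eye sd = SEM·√4 when
  emulating a published 4-eye group summary. Each of the eye's images is a
  section whose structural components all share that peak, making the
  thresholded combined-mask spectrum's true peak exactly the drawn value.
  In these scenes the BrM/RPE band split carries no signal (both sides have
  the same spectrum), so only the combined-mask metrics are meaningful.

### What the generator does not emulate

No point-spread function or confocal sectioning, no spectral bleed-through
beyond additive background, no intra-component spectral heterogeneity, no
spatially varying background, and hard-edged (unblurred) structures.
Passing recovery tests therefore demonstrates correctness of the analysis
chain under its own model assumptions, not performance on tissue: real
images have mixed-spectra boundary pixels and structured background that
make thresholds and the band split less clean than here.

## Problem sizes and numerics

Default synthetic sections are 256×256 px (tests use 128–192 px variants);
these are deliberate package defaults that keep full recovery experiments
fast on a single CPU while leaving hundreds of granules per scene. The
quadratic is solved by `lstsq` on a wavelength-centred design matrix for
conditioning, with coefficients reported on the raw wavelength scale;
per-pixel fitting solves all masked pixels in one least-squares call. A
flat or all-zero spectrum yields `a = 0` and an invalid fit, never an
exception; empty-mask means are NaN, never zero. Cohort recovery estimates
average the pipeline group mean over replicate cohorts (24 in the
acceptance script) because a single 4-eye group mean carries irreducible
sampling noise of (between-eye sd)/2 ≈ 0.6–1.1 nm, which would otherwise
dominate the comparison with the generating value.

## Open design choices made here

- Melanolipofuscin ROIs include the full annulus as drawn; the dark core is
  background-level and unlabelled.
- Microsphere pixels are selected with the same (Otsu) threshold as tissue.
- The bead reference wavelength is a configurable `reference_nm`
  defaulting to 546 nm.
- Drusen are a supported ROI class and scene component but excluded from
  granule/BrM summary statistics; with default spectra they score on the
  BrM side of the band rule, one more reason they are kept out of the
  component statistics.
- Zero-score pixels in the band split stay unassigned rather than being
  forced into a component.
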