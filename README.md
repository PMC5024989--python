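# afspectra

Analysis of spectral autofluorescence (AF) image cubes of the retinal
pigment epithelium (RPE) and Bruch's membrane (BrM), for researchers
studying age-related macular degeneration (AMD) with confocal emission
spectroscopy at 488 nm excitation.

A cross-section is imaged as a spectral data cube — 21 emission channels at
6 nm spacing, 496–616 nm, one 12-bit image per channel. Because the
detector samples coarsely, the emission peak of a spectrum *I(λ)* is
interpolated by ordinary least squares of a second-order polynomial,

    I(λ) ≈ aλ² + bλ + c,   λ̂peak = −b / (2a),   valid iff a < 0,

with per-session wavelength calibration from reference microspheres
(additive offset against the 546 nm vendor peak). The combined RPE/BrM
signal is segmented unsupervised: an intensity threshold on the
channel-summed image, then a band-difference split — BrM is relatively
brighter in the green band (526–538 nm), RPE in the orange band
(598–610 nm), so `mean(green) − mean(orange) > 0` marks BrM. Per-eye means
are compared between groups with a pooled-variance two-tailed t-test, the
scientific question being whether AMD eyes show a blue-shifted (shorter
wavelength) emission peak.

Since no donor-eye images are available, the package ships a synthetic
scene generator (`afspectra.synthetic_scene`) with full ground truth —
lipofuscin disks, melanolipofuscin rings, a BrM band, drusen, shot/read
noise, 12-bit quantisation, and injectable spectrometer drift — so every
stage is validated by parameter recovery. See `docs/methods.md` for the
model and its limits.

## Worked example

```python
from afspectra import analyze_section
from afspectra.synthetic_scene import SceneConfig, render_section

cube, truth = render_section(SceneConfig(seed=30))   # BrM 549 nm, RPE 575 nm
res = analyze_section(cube)
print(f"BrM {res.brm_peak_nm:.2f} nm, RPE {res.rpe_peak_nm:.2f} nm, "
      f"combined {res.combined_peak_nm:.2f} nm, area ratio {res.relative_area:.3f}")
```

prints

```
BrM 549.39 nm, RPE 575.62 nm, combined 569.96 nm, area ratio 0.500
```

i.e. the automated pipeline recovers the generated component peaks to well
under 1 nm, reproduces the ~26 nm blue shift of BrM relative to RPE
granules, and returns the geometric BrM/RPE area ratio the scene was built
with.

The numbered drivers under `analysis/` run the full study sequence and
write tables under `results/`:

- `01_simulate_scenes.py` — reference section and bead field, pseudo-RGB previews
- `02_calibration.py` — drift injection and microsphere-corrected recovery
- `03_component_peaks.py` — manual ROI class means vs automated segmentation
- `04_area_ratio.py` — BrM/RPE relative-area recovery across ratios
- `05_cohort_comparison.py` — two 4-eye cohorts, eye-level t-test summary, e.g.
  `AMD 567.0 ± 1.1 nm vs control 572.3 ± 2.1 nm (t = -2.17, p = 0.073)`

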