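"""Manual-ROI workflow: labelled regions over a cube, per-class peak statistics.

ROIs mirror the manual granule-level analysis: each is a small pixel set the
size of a single RPE granule (~1 um) or a stretch of Bruch's membrane,
tagged with a component class.  Peaks are fitted per pixel and averaged
within the ROI (the default ROI mode), calibrated with the session's
microsphere offset, and summarised per class.  Drusen ROIs are accepted as a
class but excluded from the granule/BrM summary statistics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cube_io import SpectralCube
from .errors import ROIError
from .spectral_fit import CalibrationRecord, NO_CALIBRATION, apply_calibration, fit_pixels

LABEL_VOCABULARY = ("lipofuscin", "melanolipofuscin", "brm", "drusen")

#: classes included in the summary statistics (drusen excluded)
STATS_LABELS = ("lipofuscin", "melanolipofuscin", "brm")


@dataclass
class ROI:
    """A labelled pixel set on one cube."""

    label: str
    pixels: np.ndarray          # (N, 2) int array of (row, col)
    source_image: str = ""

    def mask(self, shape: tuple) -> np.ndarray:
        m = np.zeros(shape[:2], bool)
        m[self.pixels[:, 0], self.pixels[:, 1]] = True
        return m


def _disk_pixels(center: tuple, radius: float) -> np.ndarray:
    r = int(np.ceil(radius))
    dr, dc = np.mgrid[-r : r + 1, -r : r + 1]
    inside = dr**2 + dc**2 <= radius**2
    return np.column_stack([dr[inside] + center[0], dc[inside] + center[1]])


def load_rois(path, cube: SpectralCube) -> list[ROI]:
    """Read ROI definitions from JSON and validate them against the cube.

    Each entry carries a ``label`` and either an explicit ``pixels`` list of
    ``[row, col]`` pairs or a ``disk`` shorthand ``{"center": [r, c],
    "radius": x}``.  Unknown labels, empty ROIs and out-of-bounds pixels are
    errors naming the offending ROI.
    """
    entries = json.loads(Path(path).read_text())
    if isinstance(entries, dict):
        entries = entries.get("rois", [])
    h, w, _ = cube.shape
    rois = []
    for i, e in enumerate(entries):
        label = e.get("label")
        if label not in LABEL_VOCABULARY:
            raise ROIError(f"ROI {i}: unknown label {label!r}; expected one of {LABEL_VOCABULARY}")
        if "disk" in e:
            px = _disk_pixels(tuple(e["disk"]["center"]), e["disk"]["radius"])
        else:
            px = np.asarray(e.get("pixels", []), dtype=int).reshape(-1, 2)
        if len(px) == 0:
            raise ROIError(f"ROI {i} ({label}): empty pixel set")
        if px.min() < 0 or px[:, 0].max() >= h or px[:, 1].max() >= w:
            raise ROIError(f"ROI {i} ({label}): pixels out of bounds for {h}x{w} cube")
        rois.append(ROI(label, px, e.get("source_image", "")))
    return rois


@dataclass
class ROIAnalysis:
    """Per-ROI results, per-class means, and normalised mean spectra."""

    table: pd.DataFrame         # one row per ROI
    class_means: dict           # label -> mean corrected peak over usable ROIs
    spectra: pd.DataFrame       # normalised mean spectrum per ROI (rows), channels as columns


def analyze_rois(
    cube: SpectralCube,
    rois: list,
    calibration: CalibrationRecord = NO_CALIBRATION,
) -> ROIAnalysis:
    """Per-ROI peak (per-pixel fits averaged), calibration, class summaries.

    ROIs whose pixels all yield invalid fits are flagged and excluded from
    the class means.  Each exported spectrum is the ROI's mean spectrum
    divided by its own mean over channels, so it averages to 1.
    """
    rows = []
    spectra = []
    for i, roi in enumerate(rois):
        mask = roi.mask(cube.shape)
        fit = fit_pixels(cube, mask)
        raw = fit.mean_peak_nm
        usable = np.isfinite(raw)
        rows.append(
            {
                "roi": i,
                "image": roi.source_image,
                "label": roi.label,
                "n_pixels": len(roi.pixels),
                "peak_nm_raw": raw,
                "peak_nm_corrected": apply_calibration(raw, calibration) if usable else np.nan,
                "valid_fraction": 1.0 - fit.invalid_fraction,
                "usable": usable,
            }
        )
        mean_spec = cube.mean_spectrum(mask)
        spectra.append(mean_spec / mean_spec.mean())
    table = pd.DataFrame(rows)
    class_means = {}
    if len(table):
        ok = table[table["usable"]]
        class_means = ok.groupby("label")["peak_nm_corrected"].mean().to_dict()
    spec_df = pd.DataFrame(
        spectra, columns=[f"{lam:g}nm" for lam in cube.axis.wavelengths]
    )
    if len(table):
        spec_df.insert(0, "label", table["label"].to_numpy())
    return ROIAnalysis(table=table, class_means=class_means, spectra=spec_df)
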