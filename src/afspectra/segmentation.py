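"""Unsupervised RPE/BrM segmentation by threshold and green-orange band rule.

A cross-section is first reduced to its structural pixels with an intensity
threshold on the channel-summed image (removing background and weak choroid
or sclera signal), then split by the spectral band difference: BrM emission
is relatively stronger in the green band (526-538 nm) and RPE emission in
the orange band (598-610 nm), so

    score = mean(green-band channels) - mean(orange-band channels)

is positive for BrM pixels and negative for RPE pixels.  Zero-score pixels
stay unassigned.  Relative area is |BrM| / |RPE| pixel counts; relative
intensity is the ratio of mean channel-summed intensity over each mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu

from .cube_io import SpectralCube

GREEN_BAND = (526.0, 538.0)
ORANGE_BAND = (598.0, 610.0)


@dataclass
class ThresholdResult:
    mask: np.ndarray          # (H, W) bool
    threshold_value: float    # on the channel-summed intensity scale
    empty: bool               # warning flag: threshold excluded every pixel


@dataclass
class SegmentationResult:
    threshold_value: float
    combined_mask: np.ndarray
    brm_mask: np.ndarray
    rpe_mask: np.ndarray
    relative_area: float        # |BrM| / |RPE|, nan when |RPE| == 0
    relative_intensity: float   # mean BrM / mean RPE total intensity
    empty: bool = False


def threshold_cube(cube: SpectralCube, threshold: float | None = None) -> ThresholdResult:
    """Select structural pixels by total (channel-summed) intensity.

    Default is Otsu's method on the log of the summed image, which is
    parameter-free and invariant to a global intensity rescaling; pass an
    absolute ``threshold`` (summed-intensity counts) to override.  Pixels
    with total intensity >= the threshold form the combined mask; an
    all-excluded result is flagged, not raised.
    """
    total = cube.summed_intensity()
    if threshold is None:
        if total.max() == total.min():
            # degenerate flat image: nothing separable from background
            return ThresholdResult(np.zeros(total.shape, bool), float(total.max()), True)
        thr = float(np.expm1(threshold_otsu(np.log1p(total))))
    else:
        thr = float(threshold)
    mask = total >= thr
    return ThresholdResult(mask, thr, not mask.any())


def split_rpe_brm(
    cube: SpectralCube,
    combined_mask: np.ndarray,
    green_band: tuple = GREEN_BAND,
    orange_band: tuple = ORANGE_BAND,
) -> tuple[np.ndarray, np.ndarray]:
    """Split the combined mask into (brm_mask, rpe_mask) by band difference.

    A band includes every channel whose centre lies within its closed
    interval; band intensities are averaged (not summed) so unequal band
    sizes on non-default axes stay comparable.  Raises
    :class:`~afspectra.errors.BandConfigError` when a band misses the axis.
    """
    g_idx = cube.axis.band_channels(*green_band)
    o_idx = cube.axis.band_channels(*orange_band)
    data = cube.intensities.astype(np.float64)
    score = data[:, :, g_idx].mean(axis=2) - data[:, :, o_idx].mean(axis=2)
    combined = np.asarray(combined_mask, bool)
    brm = combined & (score > 0)
    rpe = combined & (score < 0)
    return brm, rpe


def component_metrics(
    cube: SpectralCube, brm_mask: np.ndarray, rpe_mask: np.ndarray
) -> tuple[float, float]:
    """(relative_area, relative_intensity) of BrM vs RPE.

    An empty RPE mask yields NaNs (missing values, not a division error);
    an empty BrM mask with RPE present yields zeros.
    """
    brm_mask = np.asarray(brm_mask, bool)
    rpe_mask = np.asarray(rpe_mask, bool)
    if (brm_mask & rpe_mask).any():
        raise ValueError("brm_mask and rpe_mask must be disjoint")
    n_brm, n_rpe = int(brm_mask.sum()), int(rpe_mask.sum())
    if n_rpe == 0:
        return float("nan"), float("nan")
    if n_brm == 0:
        return 0.0, 0.0
    total = cube.summed_intensity()
    return n_brm / n_rpe, float(total[brm_mask].mean() / total[rpe_mask].mean())


def segment_cube(
    cube: SpectralCube,
    threshold: float | None = None,
    green_band: tuple = GREEN_BAND,
    orange_band: tuple = ORANGE_BAND,
) -> SegmentationResult:
    """Full macroscopic segmentation: threshold, band split, metrics."""
    thr = threshold_cube(cube, threshold=threshold)
    brm, rpe = split_rpe_brm(cube, thr.mask, green_band, orange_band)
    rel_area, rel_int = component_metrics(cube, brm, rpe)
    return SegmentationResult(
        threshold_value=thr.threshold_value,
        combined_mask=thr.mask,
        brm_mask=brm,
        rpe_mask=rpe,
        relative_area=rel_area,
        relative_intensity=rel_int,
        empty=thr.empty,
    )


def masks_to_image(result: SegmentationResult) -> np.ndarray:
    """Label image export: 0 = background, 1 = RPE, 2 = BrM."""
    img = np.zeros(result.combined_mask.shape, dtype=np.uint8)
    img[result.rpe_mask] = 1
    img[result.brm_mask] = 2
    return img
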