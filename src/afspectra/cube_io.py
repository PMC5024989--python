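"""Spectral data cubes: wavelength axis, container, file I/O, pseudo-colour.

A spectral cube is a ``height x width x n_channels`` stack of emission-channel
images with an attached wavelength axis.  The reference acquisition is a
1024 x 1024 frame with 21 channels at 6 nm spacing covering 496-616 nm,
stored as one 12-bit grayscale image per channel (16-bit TIFF container,
values <= 4095) plus a JSON metadata sidecar.

Conventions used everywhere in this package: row-major arrays, 0-based pixel
indices, channel index 0 is the shortest wavelength.
"""

from __future__ import annotations

import json
import os
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import tifffile

from .errors import AxisMismatchError, BandConfigError, CubeFormatError, IntensityRangeError

MAX_INTENSITY = 4095  # 12-bit full scale

_SIDECAR_NAME = "cube_meta.json"


@dataclass(frozen=True)
class WavelengthAxis:
    """Evenly spaced emission-channel centre wavelengths.

    The default axis (496 nm start, 6 nm step, 21 channels, last channel
    616 nm) matches the spectral detector configuration the analysis was
    designed for.
    """

    start_nm: float = 496.0
    step_nm: float = 6.0
    n_channels: int = 21

    def __post_init__(self) -> None:
        if self.step_nm <= 0:
            raise AxisMismatchError(f"step_nm must be positive, got {self.step_nm}")
        if self.n_channels < 3:
            raise AxisMismatchError(
                f"need at least 3 channels to fit a parabola, got {self.n_channels}"
            )

    @property
    def end_nm(self) -> float:
        return self.start_nm + (self.n_channels - 1) * self.step_nm

    @property
    def wavelengths(self) -> np.ndarray:
        """Channel centre wavelengths in nm, ascending."""
        return self.start_nm + self.step_nm * np.arange(self.n_channels)

    def band_channels(self, lo_nm: float, hi_nm: float) -> np.ndarray:
        """Indices of channels whose centres lie in the closed band [lo, hi].

        Raises :class:`BandConfigError` if the band captures no channel.
        """
        lam = self.wavelengths
        idx = np.flatnonzero((lam >= lo_nm) & (lam <= hi_nm))
        if idx.size == 0:
            raise BandConfigError(
                f"band [{lo_nm}, {hi_nm}] nm contains no channel centre on axis "
                f"{self.start_nm}-{self.end_nm} nm"
            )
        return idx


DEFAULT_AXIS = WavelengthAxis()


@dataclass
class SpectralCube:
    """Emission-stack image cube with its wavelength axis and metadata.

    ``intensities`` has shape (height, width, n_channels), integer dtype,
    values within the 12-bit range.
    """

    intensities: np.ndarray
    axis: WavelengthAxis = DEFAULT_AXIS
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities)
        if arr.ndim != 3:
            raise CubeFormatError(f"cube must be 3-D, got shape {arr.shape}")
        if arr.shape[0] < 1 or arr.shape[1] < 1:
            raise CubeFormatError(f"cube spatial dimensions must be >= 1, got {arr.shape}")
        if arr.shape[2] != self.axis.n_channels:
            raise AxisMismatchError(
                f"cube has {arr.shape[2]} channels but axis declares {self.axis.n_channels}"
            )
        if not np.issubdtype(arr.dtype, np.integer):
            raise CubeFormatError(f"cube intensities must be integer, got dtype {arr.dtype}")
        if arr.min() < 0 or arr.max() > MAX_INTENSITY:
            raise IntensityRangeError(
                f"intensities outside [0, {MAX_INTENSITY}]: min={arr.min()}, max={arr.max()}"
            )
        self.intensities = arr

    @property
    def shape(self) -> tuple:
        return self.intensities.shape

    def summed_intensity(self) -> np.ndarray:
        """Per-pixel total intensity (sum over channels), float64."""
        return self.intensities.sum(axis=2, dtype=np.float64)

    def mean_spectrum(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Mean spectrum over masked pixels (all pixels when mask is None)."""
        if mask is None:
            return self.intensities.reshape(-1, self.axis.n_channels).mean(axis=0)
        return self.intensities[np.asarray(mask, bool)].mean(axis=0)


def _channel_filename(k: int, wavelength_nm: float) -> str:
    return f"ch{k:02d}_{wavelength_nm:g}nm.tif"


def load_cube(
    channel_files: Sequence[str | os.PathLike],
    axis: WavelengthAxis = DEFAULT_AXIS,
    metadata: Mapping | None = None,
) -> SpectralCube:
    """Stack per-channel image files (ordered by ascending wavelength) into a cube.

    Every file must exist, share identical dimensions, and hold 12-bit data.
    Channel ``k`` of the returned cube equals file ``k`` pixel for pixel.
    """
    paths = [Path(p) for p in channel_files]
    if len(paths) != axis.n_channels:
        raise AxisMismatchError(
            f"got {len(paths)} channel files but axis declares {axis.n_channels} channels"
        )
    planes = []
    ref_shape = None
    for p in paths:
        if not p.exists():
            raise CubeFormatError(f"channel file does not exist: {p}")
        plane = tifffile.imread(p)
        if plane.ndim != 2:
            raise CubeFormatError(f"channel file is not a single grayscale image: {p}")
        if ref_shape is None:
            ref_shape = plane.shape
        elif plane.shape != ref_shape:
            raise CubeFormatError(
                f"channel file {p} has shape {plane.shape}, expected {ref_shape}"
            )
        if plane.max(initial=0) > MAX_INTENSITY:
            raise IntensityRangeError(
                f"channel file {p} holds values > {MAX_INTENSITY} (not 12-bit data)"
            )
        planes.append(plane.astype(np.uint16))
    cube = np.stack(planes, axis=2)
    return SpectralCube(cube, axis, dict(metadata or {}))


def save_cube(cube: SpectralCube, out_dir: str | os.PathLike) -> list[Path]:
    """Write one 16-bit TIFF per channel plus a JSON metadata sidecar.

    Filenames follow ``ch{kk}_{wavelength}nm.tif`` with a zero-padded 0-based
    channel index.  ``load_cube(save_cube(c))`` reproduces ``c`` bit-exactly.
    Returns the written channel paths (sidecar excluded).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for k, lam in enumerate(cube.axis.wavelengths):
        p = out / _channel_filename(k, lam)
        tifffile.imwrite(p, cube.intensities[:, :, k].astype(np.uint16))
        written.append(p)
    sidecar = {
        "axis": {
            "start_nm": cube.axis.start_nm,
            "step_nm": cube.axis.step_nm,
            "n_channels": cube.axis.n_channels,
        },
        "metadata": cube.metadata,
    }
    (out / _SIDECAR_NAME).write_text(json.dumps(sidecar, indent=2))
    return written


def read_cube_dir(cube_dir: str | os.PathLike) -> SpectralCube:
    """Load a cube previously written by :func:`save_cube`.

    Channel files are ordered by the wavelength encoded in the filename, so a
    shuffled directory listing still yields the same cube.
    """
    d = Path(cube_dir)
    sidecar = json.loads((d / _SIDECAR_NAME).read_text())
    axis = WavelengthAxis(**sidecar["axis"])
    pat = re.compile(r"ch(\d+)_([0-9.]+)nm\.tif$")
    files = []
    for p in d.iterdir():
        m = pat.match(p.name)
        if m:
            files.append((float(m.group(2)), p))
    files.sort(key=lambda t: t[0])
    return load_cube([p for _, p in files], axis, sidecar["metadata"])


def pseudo_rgb(cube: SpectralCube) -> np.ndarray:
    """False-colour rendering: thirds of the emission range -> blue/green/red.

    The shortest-wavelength third of the channels is averaged into the blue
    plane, the middle third into green, the longest into red.  All three
    planes share one rescaling factor so the global maximum is 1; an all-zero
    cube maps to an all-zero image.  Returns (H, W, 3) float in [0, 1] with
    the last axis ordered R, G, B.
    """
    n = cube.axis.n_channels
    # rounding thirds keeps the split total for channel counts not divisible by 3
    edges = [int(round(i * n / 3)) for i in range(4)]
    data = cube.intensities.astype(np.float64)
    b = data[:, :, edges[0]:edges[1]].mean(axis=2)
    g = data[:, :, edges[1]:edges[2]].mean(axis=2)
    r = data[:, :, edges[2]:edges[3]].mean(axis=2)
    img = np.stack([r, g, b], axis=2)
    peak = img.max()
    if peak > 0:
        img /= peak
    return img


def save_pseudo_rgb(cube: SpectralCube, path: str | os.PathLike) -> Path:
    """Export the pseudo-RGB rendering as an 8-bit PNG."""
    from PIL import Image

    img = (pseudo_rgb(cube) * 255).round().astype(np.uint8)
    p = Path(path)
    Image.fromarray(img, mode="RGB").save(p)
    return p
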