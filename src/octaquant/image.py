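"""Calibrated en-face angiography rasters.

The pipeline's input is a 2-D grayscale en-face projection of the superficial
capillary plexus (SCP) flow signal over a 6x6 mm macular field.  Images carry
the acquisition metadata needed downstream: the physical pixel pitch (µm), the
device signal-strength index (SSI, 0-10) used for quality control, and
eye / visit / grader labels.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np


class InvalidImageError(ValueError):
    """Raised when a raster violates the en-face image contract."""


@dataclasses.dataclass
class EnFaceImage:
    """A square grayscale en-face raster with acquisition metadata.

    Parameters
    ----------
    pixels : ndarray
        2-D float array; intensities are held normalized to [0, 1].
    pixel_pitch_um : float
        Physical size of one pixel in micrometres.  The default 12 µm/px
        corresponds to a 500 px raster spanning a 6 mm field.
    ssi : float
        Device signal-strength index in [0, 10]; scans below 8 are
        conventionally discarded.
    eye_id, visit, grader : str
        Free-form labels used when metric records are tabulated.
    """

    pixels: np.ndarray
    pixel_pitch_um: float = 12.0
    ssi: float = 10.0
    eye_id: str = ""
    visit: str = "baseline"
    grader: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise InvalidImageError("en-face raster must be 2-D")
        if self.pixels.shape[0] != self.pixels.shape[1]:
            raise InvalidImageError(
                f"en-face raster must be square, got {self.pixels.shape}"
            )
        if not self.pixel_pitch_um > 0:
            raise InvalidImageError("pixel_pitch_um must be positive")
        if not 0.0 <= self.ssi <= 10.0:
            raise InvalidImageError("ssi must lie in [0, 10]")

    @property
    def grid_px(self) -> int:
        return self.pixels.shape[0]

    @property
    def field_size_mm(self) -> float:
        """Physical side length of the imaged field in millimetres."""
        return self.grid_px * self.pixel_pitch_um / 1000.0

    def with_pixels(self, pixels: np.ndarray) -> "EnFaceImage":
        """Copy of this image with a new raster and the same metadata."""
        return dataclasses.replace(self, pixels=pixels)


def _normalize_raster(arr: np.ndarray) -> np.ndarray:
    arr = np.asarray(arr)
    if arr.ndim == 3:  # collapse RGB(A) grayscale-coded files
        arr = arr[..., 0]
    if np.issubdtype(arr.dtype, np.integer):
        info = np.iinfo(arr.dtype)
        return arr.astype(float) / float(info.max)
    arr = arr.astype(float)
    top = arr.max()
    return arr / top if top > 1.0 else arr


def read_image(path: str | Path, **metadata) -> EnFaceImage:
    """Read an 8/16-bit grayscale TIFF or PNG as an :class:`EnFaceImage`."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        arr = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        arr = iio.imread(path)
    return EnFaceImage(_normalize_raster(arr), **metadata)


def write_image(path: str | Path, image: EnFaceImage | np.ndarray) -> None:
    """Write a raster (intensities or boolean mask) as 8-bit grayscale."""
    arr = image.pixels if isinstance(image, EnFaceImage) else np.asarray(image)
    if arr.dtype == bool:
        out = (arr * 255).astype(np.uint8)
    else:
        out = (np.clip(arr, 0.0, 1.0) * 255).round().astype(np.uint8)
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        tifffile.imwrite(path, out)
    else:
        import imageio.v3 as iio

        iio.imwrite(path, out)
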