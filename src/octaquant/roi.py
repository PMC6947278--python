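"""Macular region-of-interest geometry.

The quantitative analysis is restricted to a macular annulus of 5.5 mm
diameter centred on the fovea, excluding the foveal avascular zone (FAZ),
and split into a parafoveal region (disc of 2.5 mm diameter minus FAZ) and a
perifoveal annulus (2.5-5.5 mm).  Masks are built in physical units on the
pixel grid: membership is decided by the centre-of-pixel distance from the
foveal centre, with half-open rings [inner, outer) so the two regions tile
the macular annulus without overlap.

Coordinates are 0-based (row, col) with pixel centres at integer positions.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from .image import EnFaceImage


class GeometryError(ValueError):
    """Raised when the requested annuli do not fit the imaged field."""


@dataclasses.dataclass
class RegionMask:
    """Boolean analysis mask for one macular region."""

    mask: np.ndarray
    region: str  # parafoveal | perifoveal | macular | full
    center_px: tuple[float, float]
    inner_diameter_mm: float
    outer_diameter_mm: float

    @property
    def pixel_count(self) -> int:
        return int(self.mask.sum())

    @classmethod
    def full(cls, grid_px: int) -> "RegionMask":
        """Whole-raster mask (used for phantom ground-truth comparisons)."""
        c = (grid_px - 1) / 2.0
        return cls(np.ones((grid_px, grid_px), bool), "full", (c, c), 0.0, np.inf)


def _radius_map_mm(grid_px: int, pixel_pitch_um: float,
                   center_px: tuple[float, float]) -> np.ndarray:
    rows, cols = np.mgrid[0:grid_px, 0:grid_px]
    d_px = np.hypot(rows - center_px[0], cols - center_px[1])
    return d_px * pixel_pitch_um / 1000.0


def make_region_masks(
    grid_px: int,
    pixel_pitch_um: float = 12.0,
    center_px: tuple[float, float] | None = None,
    faz_diameter_mm: float = 0.6,
    parafoveal_diameter_mm: float = 2.5,
    perifoveal_diameter_mm: float = 5.5,
    faz_mask: np.ndarray | None = None,
) -> tuple[RegionMask, RegionMask]:
    """Build the parafoveal and perifoveal masks on the image grid.

    The parafoveal region is the ring [faz_diameter/2, 1.25 mm) and the
    perifoveal region the ring [1.25 mm, 2.75 mm), both half-open so the
    regions are disjoint and together tile the FAZ-excluded macular annulus.

    Parameters
    ----------
    faz_mask : ndarray of bool, optional
        Explicit FAZ pixels to exclude instead of the fixed-diameter disc
        (e.g. loaded from a hand-drawn mask file).
    """
    if not faz_diameter_mm < parafoveal_diameter_mm:
        raise GeometryError("FAZ diameter must be smaller than the parafoveal disc")
    field_mm = grid_px * pixel_pitch_um / 1000.0
    if perifoveal_diameter_mm > field_mm + 1e-9:
        raise GeometryError(
            f"{perifoveal_diameter_mm} mm annulus exceeds the {field_mm:g} mm field"
        )
    if center_px is None:
        c = (grid_px - 1) / 2.0
        center_px = (c, c)
    r = _radius_map_mm(grid_px, pixel_pitch_um, center_px)

    para = (r >= faz_diameter_mm / 2.0) & (r < parafoveal_diameter_mm / 2.0)
    peri = (r >= parafoveal_diameter_mm / 2.0) & (r < perifoveal_diameter_mm / 2.0)
    if faz_mask is not None:
        faz_mask = np.asarray(faz_mask, bool)
        if faz_mask.shape != para.shape:
            raise GeometryError("FAZ mask shape does not match the grid")
        para &= ~faz_mask
        peri &= ~faz_mask

    para_rm = RegionMask(para, "parafoveal", center_px,
                         faz_diameter_mm, parafoveal_diameter_mm)
    peri_rm = RegionMask(peri, "perifoveal", center_px,
                         parafoveal_diameter_mm, perifoveal_diameter_mm)
    return para_rm, peri_rm


def find_fovea_center(image: EnFaceImage,
                      search_window_mm: float = 1.5,
                      smooth_sigma_px: float = 1.5,
                      vessel_level: float = 0.25) -> tuple[float, float]:
    """Locate the foveal centre as the middle of the largest avascular disc.

    A light smoothing suppresses speckle, pixels above ``vessel_level`` of
    the image's (robust) dynamic range are treated as vessels, and the
    centre of the largest vessel-free inscribed disc within the central
    search window — the foveal avascular zone bounded by its terminal
    capillary ring — is returned as the centroid of the near-maximal
    distance-transform plateau.  A flat image (no vascular structure) falls
    back to the geometric raster centre.  Deterministic.
    """
    g = image.grid_px
    geom_center = ((g - 1) / 2.0, (g - 1) / 2.0)
    half_win = search_window_mm * 1000.0 / image.pixel_pitch_um / 2.0
    r0 = max(int(np.floor(geom_center[0] - half_win)), 0)
    r1 = min(int(np.ceil(geom_center[0] + half_win)) + 1, g)

    smoothed = ndimage.gaussian_filter(image.pixels, smooth_sigma_px)
    lo, hi = np.quantile(smoothed, [0.005, 0.995])
    if hi - lo < 1e-12:
        return geom_center
    vessels = smoothed > lo + vessel_level * (hi - lo)
    if not vessels.any() or vessels.all():
        return geom_center

    dist = ndimage.distance_transform_edt(~vessels)
    window = dist[r0:r1, r0:r1]
    peak = np.unravel_index(np.argmax(window), window.shape)
    plateau = window >= 0.85 * window[peak]
    labels, _ = ndimage.label(plateau)
    comp = labels == labels[peak]
    rows, cols = np.nonzero(comp)
    return (float(rows.mean()) + r0, float(cols.mean()) + r0)
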