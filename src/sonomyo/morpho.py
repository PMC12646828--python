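"""Geometric ROI measurements: muscle thickness and area, height-normalised
area index, subcutaneous fat thickness and pennation angle.

Definitions
-----------
* RFMT (cm): maximal anteroposterior diameter of the ROI — the maximum
  over columns of the contiguous vertical extent of the mask, scaled by
  the depth calibration.  Depends on the mask only.
* RFMA (cm^2): ROI pixel count times the pixel area.  Mask only.
* RFMAI (cm^2/m^2): RFMA / height^2, by analogy with other
  height-normalised indices (BMI, ASMI).
* SFT (cm): distance between the skin line and the superior aponeurosis
  on a longitudinal frame, the two shallowest bright-band maxima of the
  column-averaged intensity profile.
* Pennation angle (deg): angle between the dominant fascicle orientation
  inside the ROI and the lower aponeurosis, both estimated as the peak of
  a shear-projection orientation-response profile; reported >= 0.

Incomplete captures (mask touching the frame border) are measured on the
visible area; ``roi_truncated`` flags them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .errors import (DetectionFailureError, EmptyRoiError,
                     InvalidParameterError)
from .simimg import RoiMask, UltrasoundFrame, _max_column_run


@dataclass(frozen=True)
class MorphometryResult:
    """Per-image geometric measurements; longitudinal fields optional."""

    rfmt_cm: float | None = None
    rfma_cm2: float | None = None
    rfmai_cm2_m2: float | None = None
    sft_cm: float | None = None
    pennation_deg: float | None = None
    truncated: bool = False

    def __post_init__(self):
        for name in ("rfmt_cm", "rfma_cm2", "rfmai_cm2_m2", "sft_cm"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise InvalidParameterError(f"{name} must be positive, got {v}")
        if self.pennation_deg is not None and self.pennation_deg < 0:
            raise InvalidParameterError("pennation angle must be >= 0")


def muscle_area(roi: RoiMask, row_calib: float, col_calib: float) -> float:
    """Cross-sectional ROI area in cm^2 (pixel count x pixel area)."""
    if not (row_calib > 0 and col_calib > 0):
        raise InvalidParameterError("calibrations must be positive")
    n = roi.n_pixels
    if n == 0:
        raise EmptyRoiError("empty ROI")
    return n * row_calib * col_calib


def muscle_thickness(roi: RoiMask, row_calib: float) -> float:
    """Maximal anteroposterior (depth-axis) ROI diameter in cm."""
    if not row_calib > 0:
        raise InvalidParameterError("row calibration must be positive")
    if roi.n_pixels == 0:
        raise EmptyRoiError("empty ROI")
    return _max_column_run(roi.mask) * row_calib


def area_index(rfma_cm2: float, height_m: float) -> float:
    """Height-normalised muscle area index, RFMA / height^2 (cm^2/m^2)."""
    if not height_m > 0:
        raise InvalidParameterError("height must be positive")
    if not rfma_cm2 > 0:
        raise InvalidParameterError("area must be positive")
    return rfma_cm2 / (height_m * height_m)


def roi_truncated(roi: RoiMask) -> bool:
    """True when the mask touches the frame border (incomplete capture)."""
    m = roi.mask
    return bool(m[0, :].any() or m[-1, :].any() or m[:, 0].any() or m[:, -1].any())


# ---------------------------------------------------------------------------
# Longitudinal landmarks
# ---------------------------------------------------------------------------

def fat_thickness(frame: UltrasoundFrame, skin_row: int | None = None,
                  aponeurosis_row: int | None = None) -> float:
    """Subcutaneous fat thickness (cm) on a longitudinal frame.

    When the two landmark rows are not supplied they are detected as the
    two shallowest bright-band maxima of the column-averaged intensity
    profile (central third of columns, lightly smoothed).
    """
    if skin_row is None or aponeurosis_row is None:
        skin_row, aponeurosis_row = _detect_bright_bands(frame)
    if aponeurosis_row <= skin_row:
        raise InvalidParameterError(
            "superior aponeurosis must lie deeper than the skin line")
    return (aponeurosis_row - skin_row) * frame.row_calib


def _detect_bright_bands(frame: UltrasoundFrame):
    """Centres of the two shallowest bright bands of the depth profile.

    Bands are contiguous runs of the column-averaged intensity profile
    above half the floor-to-maximum range; each band centre is the
    intensity-weighted centroid of its run, so plateau-shaped bands
    (e.g. the skin line flush with row 0) are located at their middle.
    """
    rows, cols = frame.shape
    lo, hi = cols // 3, 2 * cols // 3
    profile = frame.pixels[:, lo:hi].mean(axis=1)
    smooth = gaussian_filter1d(profile, sigma=1.0)
    floor = np.median(smooth)
    height = floor + 0.5 * (smooth.max() - floor)
    above = smooth > height
    if not above.any():
        raise DetectionFailureError("no bright bands in the depth profile")
    edges = np.diff(above.astype(np.int8))
    starts = list(np.nonzero(edges == 1)[0] + 1)
    stops = list(np.nonzero(edges == -1)[0] + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        stops.append(rows)
    centres = []
    for a, b in zip(starts, stops):
        w = smooth[a:b] - height
        centres.append(float(np.average(np.arange(a, b), weights=w)))
    if len(centres) < 2:
        raise DetectionFailureError(
            "fewer than two bright bands detected in the depth profile")
    c = sorted(centres)[:2]
    return c[0], c[1]


# ---------------------------------------------------------------------------
# Pennation angle via shear-projection orientation response
# ---------------------------------------------------------------------------

def _shear_profile_variance(img: np.ndarray, weight: np.ndarray,
                            slopes_px: np.ndarray) -> np.ndarray:
    """Orientation response: variance of the row profile after shearing.

    For each candidate slope (px of depth per px of width), every column
    is shifted so that lines of that slope become horizontal; the
    variance of the weighted row-mean profile peaks when the shear
    matches the dominant line orientation.
    """
    rows, cols = img.shape
    col_idx = np.arange(cols)
    row_idx = np.arange(rows)[:, None]
    wimg = img * weight
    responses = np.empty(len(slopes_px))
    for i, s in enumerate(slopes_px):
        shift = s * col_idx  # fractional row shift per column
        src = row_idx + shift[None, :]
        f = np.floor(src).astype(np.int64)
        frac = src - f
        f0 = np.clip(f, 0, rows - 1)
        f1 = np.clip(f + 1, 0, rows - 1)
        sheared = wimg[f0, col_idx] * (1 - frac) + wimg[f1, col_idx] * frac
        wsh = weight[f0, col_idx] * (1 - frac) + weight[f1, col_idx] * frac
        wsum = wsh.sum(axis=1)
        valid = wsum > 0.5 * cols  # rows mostly inside the ROI after shear
        if valid.sum() < 3:
            responses[i] = 0.0
            continue
        prof = sheared[valid].sum(axis=1) / wsum[valid]
        responses[i] = prof.var()
    return responses


def _dominant_orientation_deg(img: np.ndarray, weight: np.ndarray,
                              row_calib: float, col_calib: float,
                              search_deg: float = 31.0) -> float:
    """Physical angle (deg, signed) of the dominant line structure."""
    coarse = np.arange(-search_deg, search_deg + 0.25, 0.25)
    slopes = np.tan(np.radians(coarse)) * (col_calib / row_calib)
    resp = _shear_profile_variance(img, weight, slopes)
    if resp.max() <= 1e-12 or resp.max() < 1.05 * np.median(resp):
        raise DetectionFailureError("no dominant orientation in the ROI")
    centre = coarse[int(np.argmax(resp))]
    fine = np.arange(centre - 0.3, centre + 0.3001, 0.02)
    fine = fine[(fine >= -search_deg) & (fine <= search_deg)]
    slopes = np.tan(np.radians(fine)) * (col_calib / row_calib)
    resp = _shear_profile_variance(img, weight, slopes)
    return float(fine[int(np.argmax(resp))])


def pennation_angle(frame: UltrasoundFrame, roi: RoiMask) -> float:
    """Pennation angle (deg) between fascicles and the lower aponeurosis.

    The fascicle orientation is the peak of the shear-projection response
    computed inside the ROI; the lower aponeurosis orientation is
    estimated from the bright band just below the ROI (assumed horizontal
    when no band is found within the search window).
    """
    if frame.shape != roi.shape:
        raise InvalidParameterError("frame and mask shapes differ")
    if roi.n_pixels == 0:
        raise EmptyRoiError("empty ROI")

    rr, cc = np.nonzero(roi.mask)
    r0, r1 = rr.min(), rr.max() + 1
    c0, c1 = cc.min(), cc.max() + 1
    img = frame.pixels[r0:r1, c0:c1].astype(np.float64)
    weight = roi.mask[r0:r1, c0:c1].astype(np.float64)
    img = img - img[weight > 0].mean()

    fascicle_deg = _dominant_orientation_deg(
        img * weight, weight, frame.row_calib, frame.col_calib)

    apo_deg = _lower_aponeurosis_orientation(frame, roi, r1, c0, c1)
    return abs(fascicle_deg - apo_deg)


def _lower_aponeurosis_orientation(frame: UltrasoundFrame, roi: RoiMask,
                                   roi_bottom: int, c0: int, c1: int) -> float:
    """Orientation (deg) of the bright band just below the ROI.

    Fits a line to the per-column brightest row within a thin window
    below the ROI; returns 0 when no band stands out there.
    """
    rows = frame.shape[0]
    window = frame.pixels[roi_bottom:min(rows, roi_bottom + 6), c0:c1].astype(float)
    if window.size == 0:
        return 0.0
    col_max = window.max(axis=0)
    bright = col_max > np.median(frame.pixels) + 0.5 * (
        frame.pixels.max() - np.median(frame.pixels))
    if bright.sum() < max(10, (c1 - c0) // 4):
        return 0.0
    peak_rows = window.argmax(axis=0).astype(float)
    cols = np.arange(c1 - c0, dtype=float)
    slope_px = np.polyfit(cols[bright], peak_rows[bright], 1)[0]
    slope_phys = slope_px * frame.row_calib / frame.col_calib
    return float(np.degrees(np.arctan(slope_phys)))
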