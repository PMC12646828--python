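"""Synthetic B-mode-like muscle ultrasound frames with full ground truth.

Generates 8-bit grayscale frames that emulate the anatomy a transverse or
longitudinal scan of the quadriceps rectus femoris shows: a bright skin
line, a darker subcutaneous fat layer, and either an elliptical muscle
belly containing three echogenicity tissue classes (transverse) or two
bright aponeuroses enclosing pennate fascicles (longitudinal).  Every
frame comes with the exact segmentation mask and the planted quantities
(tissue-class fractions, muscle thickness and area, fat thickness,
pennation angle), so downstream measurement code can be tested against
known truth.

Conventions
-----------
Row 0 is the skin surface and depth increases with the row index.
Vertical distances use ``row_calib`` (cm/pixel) and horizontal distances
``col_calib``.  The default isotropic 0.01 cm/px on a 450-row frame gives
a 4.5 cm imaging depth, matching typical musculoskeletal preset depths of
4.5-4.7 cm.

Speckle is modelled as multiplicative unit-mean Rayleigh noise (scale
sigma = sqrt(2/pi)), the standard fully-developed-speckle envelope; the
``speckle_scale`` parameter linearly interpolates between noise-free
(0.0) and full Rayleigh speckle (1.0).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

from .errors import InvalidParameterError, ValidationError

VIEW_TRANSVERSE = "transverse"
VIEW_LONGITUDINAL = "longitudinal"

# Background/tissue base intensities (8-bit grey levels) used by the
# renderer.  ROI class means are parameters; these are scene furniture.
_BACKGROUND = 30
_FAT = 45
_SKIN = 240
_APONEUROSIS = 245
_MUSCLE_BASE = 60
_FASCICLE = 170

_RAYLEIGH_UNIT_MEAN_SCALE = float(np.sqrt(2.0 / np.pi))

_CONNECT4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


# ---------------------------------------------------------------------------
# Core containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UltrasoundFrame:
    """A 2-D 8-bit intensity grid with physical pixel calibration.

    Parameters
    ----------
    pixels : ndarray of uint8, shape (rows, cols)
        Grey levels in [0, 255]; rows and cols must both be >= 64.
    row_calib, col_calib : float
        Physical size of one pixel in cm along depth / width.
    view : {"transverse", "longitudinal"}
    """

    pixels: np.ndarray
    row_calib: float
    col_calib: float
    view: str

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.shape[0] < 64 or px.shape[1] < 64:
            raise InvalidParameterError(
                f"frame must be 2-D with at least 64x64 pixels, got {px.shape}")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise InvalidParameterError("intensities must lie in [0, 255]")
            px = px.astype(np.uint8)
        object.__setattr__(self, "pixels", px)
        if not (self.row_calib > 0 and self.col_calib > 0):
            raise InvalidParameterError("calibrations must be positive")
        if self.view not in (VIEW_TRANSVERSE, VIEW_LONGITUDINAL):
            raise InvalidParameterError(f"unknown view {self.view!r}")

    @property
    def shape(self):
        return self.pixels.shape


@dataclass(frozen=True)
class RoiMask:
    """Binary mask of the muscle region of interest.

    Must be non-empty and a single 4-connected component, mirroring the
    single muscle-belly segmentations the analysis assumes.
    """

    mask: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.mask, dtype=bool)
        object.__setattr__(self, "mask", m)
        if m.ndim != 2:
            raise InvalidParameterError("mask must be 2-D")
        if not m.any():
            raise InvalidParameterError("mask must contain at least one pixel")
        _, n_comp = ndimage.label(m, structure=_CONNECT4)
        if n_comp != 1:
            raise InvalidParameterError(
                f"mask must be a single 4-connected component, found {n_comp}")

    @property
    def shape(self):
        return self.mask.shape

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class GroundTruth:
    """Planted/realized quantities accompanying a synthetic frame."""

    roi: RoiMask
    class_fractions_pct: tuple | None  # realized (low, medium, high) % of ROI
    rfmt_cm: float
    rfma_cm2: float
    sft_cm: float
    pennation_deg: float | None = None
    seed: int | None = None

    def __post_init__(self):
        if self.class_fractions_pct is not None:
            s = float(sum(self.class_fractions_pct))
            if abs(s - 100.0) > 1e-6:
                raise InvalidParameterError(
                    f"realized class fractions must sum to 100, got {s}")
        if not (self.rfmt_cm > 0 and self.rfma_cm2 > 0):
            raise InvalidParameterError("RFMT and RFMA must be positive")


# ---------------------------------------------------------------------------
# Scene parameterisations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TransverseSceneParams:
    """Geometry, tissue composition and noise of a transverse scene.

    Defaults put a muscle belly of thickness 0.98 cm and area ~3.1 cm^2
    (cohort-typical values) under a 0.77 cm fat layer, with tissue-class
    fractions (46.55, 39.29, 14.16)% and class mean intensities 60/130/220
    chosen to be separable by a 3-class histogram threshold under default
    speckle.
    """

    shape: tuple = (450, 512)
    row_calib: float = 0.01
    col_calib: float = 0.01
    sft_cm: float = 0.77
    semi_axis_depth_cm: float = 0.49
    semi_axis_width_cm: float = 2.01
    class_fractions: tuple = (0.4655, 0.3929, 0.1416)
    class_means: tuple = (60.0, 130.0, 220.0)
    speckle_scale: float = 1.0
    speckle_grain_px: float = 1.5
    corr_length_px: float = 4.0
    skin_cm: float = 0.06
    seed: int = 0

    def __post_init__(self):
        f = np.asarray(self.class_fractions, dtype=float)
        if f.size != 3 or (f < 0).any() or abs(f.sum() - 1.0) > 1e-9:
            raise InvalidParameterError(
                "class_fractions must be 3 non-negative values summing to 1")
        m = np.asarray(self.class_means, dtype=float)
        if m.size != 3 or not (np.diff(m) > 0).all():
            raise InvalidParameterError("class means must be strictly increasing")
        if self.speckle_scale < 0 or self.corr_length_px <= 0:
            raise InvalidParameterError("speckle/correlation parameters invalid")
        if not (self.row_calib > 0 and self.col_calib > 0):
            raise InvalidParameterError("calibrations must be positive")
        if self.sft_cm < 0 or self.semi_axis_depth_cm <= 0 or self.semi_axis_width_cm <= 0:
            raise InvalidParameterError("scene distances must be positive")
        rows, cols = self.shape
        skin_px = max(1, round(self.skin_cm / self.row_calib))
        sft_px = round(self.sft_cm / self.row_calib)
        b_px = self.semi_axis_depth_cm / self.row_calib
        a_px = self.semi_axis_width_cm / self.col_calib
        if skin_px + sft_px + 2 * b_px + 2 > rows:
            raise InvalidParameterError(
                "muscle ellipse does not fit below the fat layer in the frame")
        if 2 * a_px + 2 > cols:
            raise InvalidParameterError("muscle ellipse wider than the frame")


@dataclass(frozen=True)
class LongitudinalSceneParams:
    """Geometry and noise of a longitudinal (pennation) scene."""

    shape: tuple = (450, 512)
    row_calib: float = 0.01
    col_calib: float = 0.01
    sft_cm: float = 0.77
    thickness_cm: float = 0.98
    pennation_deg: float = 5.32
    fascicle_spacing_px: float = 12.0
    speckle_scale: float = 1.0
    speckle_grain_px: float = 1.5
    skin_cm: float = 0.06
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.pennation_deg <= 30.0):
            raise InvalidParameterError(
                f"pennation angle must lie in [0, 30] degrees, got {self.pennation_deg}")
        if self.thickness_cm <= 0 or self.sft_cm < 0:
            raise InvalidParameterError("scene distances must be positive")
        if not (self.row_calib > 0 and self.col_calib > 0):
            raise InvalidParameterError("calibrations must be positive")
        if self.fascicle_spacing_px < 2:
            raise InvalidParameterError("fascicle spacing must be >= 2 px")
        rows, _ = self.shape
        skin_px = max(1, round(self.skin_cm / self.row_calib))
        sft_px = round(self.sft_cm / self.row_calib)
        thick_px = round(self.thickness_cm / self.row_calib)
        if skin_px + sft_px + thick_px + 6 > rows:
            raise InvalidParameterError("muscle compartment does not fit in the frame")


# ---------------------------------------------------------------------------
# Rendering helpers
# ---------------------------------------------------------------------------

def _apply_speckle(base: np.ndarray, speckle_scale: float, grain_px: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Multiplicative unit-mean Rayleigh speckle, blended by speckle_scale.

    The envelope is smoothed at the resolution-cell scale (``grain_px``),
    giving speckle its characteristic granularity; smoothing preserves
    the unit mean.
    """
    out = base.astype(np.float64)
    if speckle_scale > 0:
        envelope = rng.rayleigh(scale=_RAYLEIGH_UNIT_MEAN_SCALE, size=base.shape)
        if grain_px > 0:
            envelope = ndimage.gaussian_filter(envelope, sigma=grain_px)
        out = out * (1.0 + speckle_scale * (envelope - 1.0))
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def _max_column_run(mask: np.ndarray) -> int:
    """Longest contiguous vertical run of True in any column."""
    best = np.zeros(mask.shape[1], dtype=np.int64)
    cur = np.zeros(mask.shape[1], dtype=np.int64)
    for row in mask:
        cur = np.where(row, cur + 1, 0)
        np.maximum(best, cur, out=best)
    return int(best.max())


# ---------------------------------------------------------------------------
# Frame generators
# ---------------------------------------------------------------------------

def generate_transverse_frame(params: TransverseSceneParams):
    """Render a transverse scene; return ``(UltrasoundFrame, GroundTruth)``.

    The three ROI tissue classes are planted by rank-thresholding a
    spatially correlated Gaussian random field at the requested fractions,
    so the realized per-class pixel counts match the planted fractions to
    within one pixel of rounding.  Ground-truth RFMT/RFMA are measured on
    the discretised elliptical mask itself, not the continuous ellipse.
    """
    rng = np.random.default_rng(params.seed)
    rows, cols = params.shape

    skin_px = max(1, round(params.skin_cm / params.row_calib))
    sft_px = round(params.sft_cm / params.row_calib)
    b_px = params.semi_axis_depth_cm / params.row_calib
    a_px = params.semi_axis_width_cm / params.col_calib
    centre_row = skin_px + sft_px + b_px
    centre_col = cols / 2.0

    rr, cc = np.mgrid[0:rows, 0:cols]
    mask = ((rr - centre_row) / b_px) ** 2 + ((cc - centre_col) / a_px) ** 2 <= 1.0
    roi = RoiMask(mask)

    base = np.full((rows, cols), _BACKGROUND, dtype=np.float64)
    base[:skin_px, :] = _SKIN
    base[skin_px:skin_px + sft_px, :] = _FAT

    # Correlated field -> rank-based class assignment at planted fractions.
    n_roi = roi.n_pixels
    field = ndimage.gaussian_filter(
        rng.standard_normal((rows, cols)), sigma=params.corr_length_px)
    order = np.argsort(field[mask], kind="stable")
    n_low = int(round(params.class_fractions[0] * n_roi))
    n_med = int(round(params.class_fractions[1] * n_roi))
    n_med = min(n_med, n_roi - n_low)
    labels = np.full(n_roi, 2, dtype=np.int8)
    labels[order[:n_low]] = 0
    labels[order[n_low:n_low + n_med]] = 1
    base[mask] = np.asarray(params.class_means, dtype=float)[labels]

    pixels = _apply_speckle(base, params.speckle_scale,
                            params.speckle_grain_px, rng)
    frame = UltrasoundFrame(pixels, params.row_calib, params.col_calib,
                            VIEW_TRANSVERSE)

    counts = np.bincount(labels, minlength=3).astype(float)
    fractions = tuple(100.0 * counts / n_roi)
    truth = GroundTruth(
        roi=roi,
        class_fractions_pct=fractions,
        rfmt_cm=_max_column_run(mask) * params.row_calib,
        rfma_cm2=n_roi * params.row_calib * params.col_calib,
        sft_cm=params.sft_cm,
        pennation_deg=None,
        seed=params.seed,
    )
    return frame, truth


def generate_longitudinal_frame(params: LongitudinalSceneParams):
    """Render a longitudinal scene; return ``(UltrasoundFrame, GroundTruth)``.

    The skin line and the two aponeuroses are near-horizontal bright
    bands; band centres are placed so that centre-to-centre distances
    equal the planted SFT and muscle thickness.  Fascicles are parallel
    bright lines inclined at the planted pennation angle to the (exactly
    horizontal) lower aponeurosis, with the physical angle honoured under
    anisotropic calibration.
    """
    rng = np.random.default_rng(params.seed)
    rows, cols = params.shape

    skin_px = max(1, round(params.skin_cm / params.row_calib))
    skin_centre = (skin_px - 1) / 2.0
    sft_px = round(params.sft_cm / params.row_calib)
    thick_px = round(params.thickness_cm / params.row_calib)
    sup_centre = int(round(skin_centre + sft_px))
    inf_centre = sup_centre + thick_px
    band_half = 1  # aponeurosis band half-width in px

    if sup_centre - band_half <= skin_px - 1:
        raise InvalidParameterError(
            "fat layer too thin: superior aponeurosis merges with the skin line")

    base = np.full((rows, cols), _BACKGROUND, dtype=np.float64)
    base[:skin_px, :] = _SKIN
    base[skin_px:sup_centre - band_half, :] = _FAT
    base[sup_centre - band_half:sup_centre + band_half + 1, :] = _APONEUROSIS
    base[inf_centre - band_half:inf_centre + band_half + 1, :] = _APONEUROSIS

    # Muscle compartment between the bands.
    top = sup_centre + band_half + 1
    bottom = inf_centre - band_half  # exclusive
    mask = np.zeros((rows, cols), dtype=bool)
    mask[top:bottom, :] = True
    base[mask] = _MUSCLE_BASE

    # Fascicles: lines row + slope*col = const, slope chosen so the
    # physical angle to the horizontal equals pennation_deg.
    slope_px = np.tan(np.radians(params.pennation_deg)) * (
        params.col_calib / params.row_calib)
    rr, cc = np.mgrid[0:rows, 0:cols]
    phase = np.mod(rr + slope_px * cc, params.fascicle_spacing_px)
    fascicle = (phase < 1.5) & mask
    base[fascicle] = _FASCICLE

    pixels = _apply_speckle(base, params.speckle_scale,
                            params.speckle_grain_px, rng)
    frame = UltrasoundFrame(pixels, params.row_calib, params.col_calib,
                            VIEW_LONGITUDINAL)

    roi = RoiMask(mask)
    truth = GroundTruth(
        roi=roi,
        class_fractions_pct=None,
        rfmt_cm=(bottom - top) * params.row_calib,
        rfma_cm2=roi.n_pixels * params.row_calib * params.col_calib,
        sft_cm=sft_px * params.row_calib,
        pennation_deg=params.pennation_deg,
        seed=params.seed,
    )
    return frame, truth


# ---------------------------------------------------------------------------
# PNG / JSON sidecar I/O
# ---------------------------------------------------------------------------

def write_frame(path, frame: UltrasoundFrame) -> None:
    Image.fromarray(frame.pixels, mode="L").save(path, format="PNG")


def read_frame(path, row_calib: float, col_calib: float, view: str) -> UltrasoundFrame:
    try:
        img = Image.open(path).convert("L")
    except Exception as exc:  # unreadable / not an image
        raise ValidationError(f"cannot read frame {path}: {exc}") from exc
    return UltrasoundFrame(np.asarray(img), row_calib, col_calib, view)


def write_mask(path, roi: RoiMask) -> None:
    Image.fromarray(np.where(roi.mask, 255, 0).astype(np.uint8), mode="L").save(
        path, format="PNG")


def read_mask(path) -> RoiMask:
    try:
        img = Image.open(path).convert("L")
    except Exception as exc:
        raise ValidationError(f"cannot read mask {path}: {exc}") from exc
    return RoiMask(np.asarray(img) > 127)


def write_ground_truth(path, truth: GroundTruth, row_calib: float,
                       col_calib: float) -> None:
    payload = {
        "row_calib_cm": row_calib,
        "col_calib_cm": col_calib,
        "class_fractions_pct": (list(truth.class_fractions_pct)
                                if truth.class_fractions_pct is not None else None),
        "rfmt_cm": truth.rfmt_cm,
        "rfma_cm2": truth.rfma_cm2,
        "sft_cm": truth.sft_cm,
        "pennation_deg": truth.pennation_deg,
        "seed": truth.seed,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
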