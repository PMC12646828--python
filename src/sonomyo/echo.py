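"""Multilevel Otsu thresholding of the ROI grey-level histogram and the
three echogenicity biomarkers.

The muscle-quality biomarkers are the percentages of ROI pixels falling
into the low / medium / high echogenicity classes of a per-image 3-class
Otsu partition of the 8-bit grey-level histogram:

* ``MiT``     - low echogenicity, a surrogate of muscle tissue;
* ``FATiT``   - medium echogenicity, a surrogate of adipose tissue;
* ``NMNFiT``  - high echogenicity, neither-muscle-nor-fat / artefact.

The threshold search maximises the between-class variance

    sigma_B^2 = sum_k  w_k (mu_k - mu_T)^2

over all strictly increasing threshold tuples, where class k comprises
grey levels in the half-open interval [t_k, t_{k+1}) with t_0 = 0 and
t_K = 256 (a pixel whose value equals a threshold belongs to the upper
class).  Ties are broken by the lexicographically smallest tuple.
Thresholds are always computed per image, never pooled across a cohort.

The implementation is exact: a backward dynamic programme over the
equivalent objective sum_k S_k^2 / W_k (S_k, W_k the class intensity sum
and mass) followed by a greedy reconstruction that realises the
lexicographic tie-break.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateHistogramError, EmptyRoiError, InvalidParameterError
from .simimg import RoiMask, UltrasoundFrame

_N_LEVELS = 256


@dataclass(frozen=True)
class GreyHistogram:
    """256-bin grey-level histogram of a region of interest."""

    counts: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.counts, dtype=np.int64)
        if c.shape != (_N_LEVELS,) or (c < 0).any():
            raise InvalidParameterError("counts must be 256 non-negative integers")
        if c.sum() < 1:
            raise EmptyRoiError("histogram is empty")
        object.__setattr__(self, "counts", c)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def n_distinct_levels(self) -> int:
        return int((self.counts > 0).sum())


@dataclass(frozen=True)
class ThresholdSet:
    """Strictly increasing grey-level thresholds; K classes need K-1."""

    thresholds: tuple

    def __post_init__(self):
        t = tuple(int(v) for v in self.thresholds)
        if len(t) < 1 or any(not (1 <= v <= 255) for v in t):
            raise InvalidParameterError("thresholds must lie in 1..255")
        if any(b <= a for a, b in zip(t, t[1:])):
            raise InvalidParameterError("thresholds must be strictly increasing")
        object.__setattr__(self, "thresholds", t)

    @property
    def n_classes(self) -> int:
        return len(self.thresholds) + 1


@dataclass(frozen=True)
class EchogenicityPartition:
    """Percentages of ROI pixels per echogenicity class; sums to 100."""

    mit_pct: float
    fatit_pct: float
    nmnfit_pct: float
    thresholds: ThresholdSet

    def __post_init__(self):
        for v in (self.mit_pct, self.fatit_pct, self.nmnfit_pct):
            if not (0.0 <= v <= 100.0):
                raise InvalidParameterError("percentages must lie in [0, 100]")
        if abs(self.mit_pct + self.fatit_pct + self.nmnfit_pct - 100.0) > 1e-9:
            raise InvalidParameterError("class percentages must sum to 100")


def roi_histogram(frame: UltrasoundFrame, roi: RoiMask) -> GreyHistogram:
    """Histogram of frame intensities restricted to the ROI."""
    if frame.shape != roi.shape:
        raise InvalidParameterError(
            f"frame shape {frame.shape} != mask shape {roi.shape}")
    values = frame.pixels[roi.mask]
    if values.size == 0:
        raise EmptyRoiError("ROI mask selects no pixels")
    return GreyHistogram(np.bincount(values, minlength=_N_LEVELS))


def _class_scores(counts: np.ndarray):
    """Prefix sums and the S^2/W class-score table builder.

    Returns a function score(a, b) giving S([a,b))^2 / W([a,b)) with the
    empty-class convention score = 0.  Vectorised variants are provided
    through the returned cumulative arrays.
    """
    c = counts.astype(np.float64)
    levels = np.arange(_N_LEVELS, dtype=np.float64)
    W = np.concatenate(([0.0], np.cumsum(c)))            # W[i] = mass below i
    S = np.concatenate(([0.0], np.cumsum(c * levels)))   # S[i] = intensity sum
    return W, S


def multi_otsu(hist: GreyHistogram, n_classes: int = 3) -> ThresholdSet:
    """Exact multilevel Otsu thresholds of ``hist``.

    Maximises between-class variance over all valid threshold tuples;
    among maximisers returns the lexicographically smallest tuple.

    Raises
    ------
    DegenerateHistogramError
        If fewer distinct populated grey levels than classes.
    """
    if n_classes < 2:
        raise InvalidParameterError("n_classes must be >= 2")
    if hist.n_distinct_levels < n_classes:
        raise DegenerateHistogramError(
            f"histogram has {hist.n_distinct_levels} distinct levels, "
            f"need >= {n_classes}")

    W, S = _class_scores(hist.counts)

    def seg_score(a: np.ndarray, b) -> np.ndarray:
        w = W[b] - W[a]
        s = S[b] - S[a]
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(w > 0, s * s / np.where(w > 0, w, 1.0), 0.0)
        return out

    # g[m][a] = best objective over m classes covering levels [a, 256).
    # Threshold positions range over 1..255; boundaries a over 0..255.
    a_idx = np.arange(_N_LEVELS + 1)
    g = {1: seg_score(a_idx, _N_LEVELS)}  # g[1][a] = score(a, 256)
    for m in range(2, n_classes + 1):
        prev = g[m - 1]
        best = np.full(_N_LEVELS + 1, -np.inf)
        # candidate first-threshold t for a segment starting at a: a < t <= 255
        for a in range(0, _N_LEVELS):
            t = np.arange(a + 1, _N_LEVELS)
            if t.size == 0:
                continue
            vals = seg_score(np.full(t.shape, a), t) + prev[t]
            best[a] = vals.max()
        g[m] = best

    # Greedy lexicographic reconstruction of the argmax tuple.
    thresholds = []
    a = 0
    for m in range(n_classes, 1, -1):
        target = g[m][a]
        t = np.arange(a + 1, _N_LEVELS)
        vals = seg_score(np.full(t.shape, a), t) + g[m - 1][t]
        choice = int(t[np.nonzero(vals == target)[0][0]])
        thresholds.append(choice)
        a = choice
    return ThresholdSet(tuple(thresholds))


def partition_roi(frame: UltrasoundFrame, roi: RoiMask,
                  thresholds: ThresholdSet) -> EchogenicityPartition:
    """Echogenicity class percentages of the ROI under ``thresholds``.

    Half-open class convention: a pixel with grey level g belongs to the
    low class if g < t1, medium if t1 <= g < t2, high if g >= t2.
    """
    if thresholds.n_classes != 3:
        raise InvalidParameterError("echogenicity partition requires 3 classes")
    if frame.shape != roi.shape:
        raise InvalidParameterError(
            f"frame shape {frame.shape} != mask shape {roi.shape}")
    values = frame.pixels[roi.mask]
    if values.size == 0:
        raise EmptyRoiError("ROI mask selects no pixels")
    t1, t2 = thresholds.thresholds
    total = values.size
    n_low = int((values < t1).sum())
    n_high = int((values >= t2).sum())
    n_med = total - n_low - n_high
    return EchogenicityPartition(
        mit_pct=100.0 * n_low / total,
        fatit_pct=100.0 * n_med / total,
        nmnfit_pct=100.0 * n_high / total,
        thresholds=thresholds,
    )


def between_class_variance(hist: GreyHistogram, thresholds: ThresholdSet) -> float:
    """sigma_B^2 of the partition induced by ``thresholds`` on ``hist``."""
    W, S = _class_scores(hist.counts)
    bounds = [0, *thresholds.thresholds, _N_LEVELS]
    total_w = W[-1]
    mu_t = S[-1] / total_w
    var = 0.0
    for a, b in zip(bounds, bounds[1:]):
        w = W[b] - W[a]
        if w > 0:
            mu = (S[b] - S[a]) / w
            var += (w / total_w) * (mu - mu_t) ** 2
    return float(var)
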