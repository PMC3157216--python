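"""Lesion ROI definition and negative-contrast SNR detectability scoring.

A demyelinated lesion appears as a signal *deficit* inside hot white matter,
so the usual SNR = mu_signal / sigma_background is replaced by the
negative-contrast statistic

    SNR = (mu_BGR - mu_LES) / sigma_BGR,

where mu_BGR and sigma_BGR are the mean and standard deviation of the
lesion-free image over the lesion ROI, and mu_LES is the mean of the
lesion-bearing image over the same pixels.  The ROI itself is found on a
lesion-only image (activity modelled solely in the lesion) by thresholding
at 25% of the peak height above the whole-image mean:

    cutoff = baseline + (max - baseline) / 4.

The baseline-anchored reading of the cutoff is used (the two readings
coincide when the lesion-only baseline is zero, which it nearly is).

Feasibility classes: SNR < 1 not imageable, 1 <= SNR < 2 maybe imageable,
SNR >= 2 imageable; the alternate lower threshold 1.3 is supported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

FEASIBILITY_CLASSES = ("not_feasible", "maybe", "feasible")


class ConstantImageError(ValueError):
    """Raised when a lesion-only image is constant and no ROI is definable."""


@dataclass
class ROIMask:
    """A lesion region of interest on one slice."""

    mask: np.ndarray            # boolean 2D
    lesion_id: int | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("ROI mask must be 2D")
        if not self.mask.any():
            raise ValueError("ROI mask is empty")

    @property
    def area(self) -> int:
        return int(self.mask.sum())

    @property
    def centroid(self) -> tuple[float, float]:
        rows, cols = np.nonzero(self.mask)
        return float(rows.mean()), float(cols.mean())


@dataclass
class SNRResult:
    """Negative-contrast SNR of one lesion under one condition."""

    mu_bgr: float
    mu_les: float
    sigma_bgr: float
    snr: float
    feasibility: str
    roi: ROIMask | None = None


def lesion_cutoff(lesion_only_image: np.ndarray) -> float:
    """Intensity threshold at 25% of the lesion peak height above baseline.

    baseline = mean over the entire image, max = image maximum;
    cutoff = baseline + (max - baseline)/4.  A constant image (max equals
    baseline) admits no ROI and raises :class:`ConstantImageError`.
    """
    img = np.asarray(lesion_only_image, dtype=float)
    baseline = img.mean()
    peak = img.max()
    if peak <= baseline:
        raise ConstantImageError("lesion-only image has no peak above its mean")
    return baseline + (peak - baseline) / 4.0


def define_roi(lesion_only_image: np.ndarray, cutoff: float,
               lesion_centers=None) -> list[ROIMask]:
    """Strictly-above threshold, connected components as lesion ROIs.

    Components are labelled with 8-connectivity; if ``lesion_centers``
    ((row, col) pairs) are given, each component is assigned the id of the
    nearest center, otherwise ids follow component order.  An empty
    threshold mask is an error.
    """
    img = np.asarray(lesion_only_image, dtype=float)
    above = img > cutoff
    if not above.any():
        raise ValueError("cutoff is above the image maximum; no ROI pixels")
    labels, n = ndimage.label(above, structure=np.ones((3, 3), dtype=int))
    rois = []
    for k in range(1, n + 1):
        roi = ROIMask(labels == k, lesion_id=k - 1)
        if lesion_centers is not None:
            cy, cx = roi.centroid
            dists = [(cy - c[0]) ** 2 + (cx - c[1]) ** 2 for c in lesion_centers]
            roi.lesion_id = int(np.argmin(dists))
        rois.append(roi)
    return rois


def snr_negative(lesion_image: np.ndarray, lesion_free_image: np.ndarray,
                 roi: ROIMask, thresholds=(1.0, 2.0)) -> SNRResult:
    """Negative-contrast SNR over the ROI pixels of a paired simulation.

    mu_bgr and sigma_bgr come from the lesion-free image over the ROI
    (sample standard deviation, ddof=1); mu_les from the lesion-bearing
    image over the same pixels.  The statistic may be negative if the
    "lesion" is hotter than the background.
    """
    les = np.asarray(lesion_image, dtype=float)
    free = np.asarray(lesion_free_image, dtype=float)
    if les.shape != free.shape or les.shape != roi.mask.shape:
        raise ValueError("images and ROI must be congruent")
    bgr_vals = free[roi.mask]
    mu_bgr = float(bgr_vals.mean())
    sigma_bgr = float(bgr_vals.std(ddof=1))
    if sigma_bgr == 0.0:
        raise ZeroDivisionError("sigma_bgr is zero; SNR undefined")
    mu_les = float(les[roi.mask].mean())
    snr = (mu_bgr - mu_les) / sigma_bgr
    return SNRResult(mu_bgr, mu_les, sigma_bgr, snr,
                     classify_feasibility(snr, thresholds), roi)


def classify_feasibility(snr: float, thresholds=(1.0, 2.0)) -> str:
    """Map an SNR value to a feasibility class.

    ``thresholds = (low, high)`` must be increasing; SNR < low is
    "not_feasible", low <= SNR < high "maybe", SNR >= high "feasible"
    (the high boundary is inclusive).
    """
    low, high = thresholds
    if not low < high:
        raise ValueError("thresholds must be increasing")
    if snr < low:
        return "not_feasible"
    if snr < high:
        return "maybe"
    return "feasible"


def inflate_roi(roi: ROIMask, area_factor: float = 1.5) -> ROIMask:
    """Grow the ROI to ``area_factor`` times its area with adjacent pixels.

    Morphological dilation by whole 8-connected rings until the area reaches
    the target, then the farthest-from-centroid surplus pixels of the last
    ring are trimmed so the target area is hit exactly.  Ties are broken
    deterministically in scan order.
    """
    if area_factor < 1.0:
        raise ValueError("area_factor must be >= 1")
    target = int(round(area_factor * roi.area))
    if target == roi.area:
        return ROIMask(roi.mask.copy(), roi.lesion_id)
    cy, cx = roi.centroid
    mask = roi.mask.copy()
    struct = np.ones((3, 3), dtype=bool)
    while mask.sum() < target:
        grown = ndimage.binary_dilation(mask, structure=struct)
        if grown.sum() == mask.sum():
            raise ValueError("ROI inflation exceeded image bounds")
        ring = grown & ~mask
        need = target - int(mask.sum())
        ring_px = np.argwhere(ring)
        if len(ring_px) > need:
            d2 = (ring_px[:, 0] - cy) ** 2 + (ring_px[:, 1] - cx) ** 2
            # keep the nearest pixels; stable lexicographic tie-break
            order = np.lexsort((ring_px[:, 1], ring_px[:, 0], d2))
            ring_px = ring_px[order[:need]]
        mask[ring_px[:, 0], ring_px[:, 1]] = True
    return ROIMask(mask, roi.lesion_id)


def score_lesion(paired, lesion_center_rc=None, thresholds=(1.0, 2.0),
                 area_factor: float | None = None) -> SNRResult:
    """Full per-lesion scoring from a :class:`~myelinpet.petsim.PairedScan`.

    Defines the ROI on the lesion-only image, optionally inflates it, and
    evaluates the negative-contrast SNR on the paired images.  With several
    connected components the one nearest ``lesion_center_rc`` (or the
    largest) is scored.
    """
    cutoff = lesion_cutoff(paired.lesion_only)
    centers = [lesion_center_rc] if lesion_center_rc is not None else None
    rois = define_roi(paired.lesion_only, cutoff, centers)
    if lesion_center_rc is not None:
        cy, cx = lesion_center_rc
        roi = min(rois, key=lambda r: (r.centroid[0] - cy) ** 2 + (r.centroid[1] - cx) ** 2)
    else:
        roi = max(rois, key=lambda r: r.area)
    if area_factor is not None:
        roi = inflate_roi(roi, area_factor)
    return snr_negative(paired.lesion_bearing, paired.lesion_free, roi, thresholds)
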