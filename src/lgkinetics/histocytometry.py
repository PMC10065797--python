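"""Histo-cytometry: flow-cytometry-style quantification of tissue images.

Per-cell reporter intensities are extracted from two-channel lymph-gland
images and presented as quadrant-gated scatter data:

1. slice selection — the optical sections at 25%, 50% and 75% of the stack
   thickness are analysed, so slice choice is unbiased across samples;
2. nucleus detection — scale-normalized Laplacian-of-Gaussian blob detection
   on the channel sum (so dim-green/bright-red cells are not missed), with
   radius-based non-maximum suppression;
3. seeded random subsampling to a fixed number of cells per group;
4. quadrant gating on green (progenitor fate) and red (differentiated state)
   into GhighRlow / GhighRhigh / GlowRhigh / GlowRlow.

The detector's quality score is unit-normalized: an ideal isotropic Gaussian
blob of matched scale and unit peak intensity scores exactly 1, which makes
the quality threshold portable across images (the tracking software's raw
"quality" units are not).  High/low gate thresholds default to per-channel
Otsu thresholds on log10 intensity pooled across the compared conditions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_laplace
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu

from .errors import ParameterError, ValidationError

__all__ = [
    "CellRecord",
    "select_slices",
    "detect_nuclei",
    "subsample_cells",
    "classify_quadrants",
    "otsu_log_thresholds",
    "total_detected_cells",
]

QUADRANTS = ("GhighRlow", "GhighRhigh", "GlowRhigh", "GlowRlow")


@dataclass
class CellRecord:
    """One detected nucleus with its per-channel mean intensities."""

    cell_id: str
    slice_index: int
    centroid_px: tuple[float, float]     # (row, col)
    green: float
    red: float
    quality: float                       # unit-normalized LoG response
    quadrant: str | None = None


def select_slices(n_slices: int) -> tuple[int, int, int]:
    """0-based indices of the sections at 25%, 50% and 75% of the stack.

    Indices are ``round(q * (n_slices - 1))`` with half-up rounding and must
    be strictly increasing (n_slices = 4 collides at (1, 2, 2), so the
    smallest accepted stack is 5 slices).
    """
    if n_slices < 4:
        raise ParameterError(f"need >= 4 slices, got {n_slices}")
    idx = tuple(int(math.floor(q * (n_slices - 1) + 0.5))
                for q in (0.25, 0.5, 0.75))
    if not (idx[0] < idx[1] < idx[2]):
        raise ParameterError(
            f"quantile slices collide for {n_slices} slices: {idx}")
    return idx


def detect_nuclei(image: np.ndarray, diameter_px: float = 13.0,
                  quality_threshold: float = 0.2,
                  slice_index: int = 0) -> list[CellRecord]:
    """Detect nuclei in one two-channel slice by scale-normalized LoG.

    Parameters
    ----------
    image : (2, H, W) array
        Channel 0 = green, channel 1 = red.
    diameter_px : float
        Expected blob diameter; the LoG scale is sigma = diameter / (2*sqrt(2)).
    quality_threshold : float
        Minimum unit-normalized response (matched unit-peak blob = 1).

    Detection runs on the channel sum; per-cell green/red are then the means
    within a disc of radius diameter/2 at each detected centroid.  Local
    maxima closer than diameter/2 are suppressed (brightest wins).
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 3 or image.shape[0] != 2:
        raise ParameterError("image must be (2, H, W)")
    if diameter_px < 3:
        raise ParameterError("blob diameter must be >= 3 px")
    h, w = image.shape[1:]
    if diameter_px > min(h, w):
        raise ParameterError("blob diameter exceeds image side")
    if image.size == 0 or not np.any(image):
        return []
    sigma = diameter_px / (2.0 * math.sqrt(2.0))
    combined = image.sum(axis=0)
    # matched unit-peak Gaussian blob gives -sigma^2 * LoG = 1/2 at its
    # centre, hence the factor 2 for a unit-normalized quality
    response = -2.0 * sigma ** 2 * gaussian_laplace(combined, sigma)
    min_sep = max(1, int(round(diameter_px / 2.0)))
    peaks = peak_local_max(response, min_distance=min_sep,
                           threshold_abs=quality_threshold, exclude_border=False)
    radius = diameter_px / 2.0
    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]
    records = []
    for k, (r, c) in enumerate(peaks):
        disc = (rows - r) ** 2 + (cols - c) ** 2 <= radius ** 2
        records.append(CellRecord(
            cell_id=f"s{slice_index}_c{k}", slice_index=slice_index,
            centroid_px=(float(r), float(c)),
            green=float(image[0][disc].mean()),
            red=float(image[1][disc].mean()),
            quality=float(response[r, c])))
    return records


def subsample_cells(records, n: int, seed: int) -> list[CellRecord]:
    """Uniform random subset of n records without replacement.

    Implemented as a seeded shuffle of the full list followed by taking the
    first n, so the output order is itself randomized; deterministic per seed.
    """
    records = list(records)
    if n > len(records):
        raise ValidationError(
            f"requested {n} cells but only {len(records)} available")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(records))
    return [records[i] for i in order[:n]]


def otsu_log_thresholds(records) -> tuple[float, float]:
    """Per-channel Otsu thresholds on log10 intensity, returned on the
    original intensity scale.  Pool records across the conditions being
    compared before calling, so both groups are gated identically."""
    records = list(records)
    if len(records) < 2:
        raise ValidationError("need >= 2 records for Otsu thresholds")
    out = []
    for attr in ("green", "red"):
        vals = np.array([getattr(r, attr) for r in records], dtype=float)
        logs = np.log10(np.maximum(vals, 1e-12))
        out.append(float(10 ** threshold_otsu(logs)))
    return tuple(out)


def total_detected_cells(per_lobe_counts) -> int:
    """Group total of per-lobe detected-cell counts (bookkeeping check:
    the summed counts must match the totals reported for the group)."""
    counts = list(per_lobe_counts)
    if not counts or any(int(c) < 0 or int(c) != c for c in counts):
        raise ValidationError("per-lobe counts must be non-negative integers")
    return int(sum(int(c) for c in counts))


def classify_quadrants(records, g_threshold: float, r_threshold: float):
    """Gate records into the four green/red quadrants.

    Returns ``(records, counts)`` with each record's ``quadrant`` set and a
    dict of per-quadrant counts that always sum to ``len(records)``.
    """
    if g_threshold <= 0 or r_threshold <= 0:
        raise ValidationError("quadrant thresholds must be > 0")
    records = list(records)
    counts = {q: 0 for q in QUADRANTS}
    for rec in records:
        g_high = rec.green >= g_threshold
        r_high = rec.red >= r_threshold
        rec.quadrant = (
            "GhighRhigh" if g_high and r_high else
            "GhighRlow" if g_high else
            "GlowRhigh" if r_high else
            "GlowRlow")
        counts[rec.quadrant] += 1
    return records, counts
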