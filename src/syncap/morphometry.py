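"""Per-embryo morphometric metrics from label maps and point annotations.

Covers the quantities compared between genotypes: cap-area statistics and
the fraction of small caps (<80 μm² by default, strict inequality),
nuclear density (nuclei per μm², the readout of nuclear fallout), the
missing-furrow ratio, centrosome separation and vertex angle (180° =
centrosomes fully migrated to opposite sides of the nucleus), spindle
length, and the apical/basal furrow actin intensity ratio after min–max
normalization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu

from .cap_segmentation import LabelMap
from .image import Image2D

__all__ = [
    "CapStatistics",
    "SpindleGeometry",
    "CentrosomeMetrics",
    "cap_statistics",
    "nuclear_density",
    "count_bright_regions",
    "missing_furrow_ratio",
    "centrosome_metrics",
    "furrow_intensity_ratio",
    "normalize_minmax",
]

SMALL_CAP_THRESHOLD_UM2 = 80.0


@dataclass
class CapStatistics:
    """Summary of one embryo's cap-area distribution."""

    mean_area_um2: float
    n_caps: int
    small_cap_fraction: float
    small_threshold_um2: float
    hist_counts: np.ndarray
    hist_edges: np.ndarray


def cap_statistics(
    table: pd.DataFrame,
    small_threshold_um2: float = SMALL_CAP_THRESHOLD_UM2,
    bin_width_um2: float = 10.0,
) -> CapStatistics:
    """Mean cap area, area histogram and small-cap fraction for one field.

    ``small_cap_fraction`` counts caps with area strictly below the
    threshold. The histogram spans 0 to the next bin edge past the
    largest cap, with fixed bin width.
    """
    if len(table) == 0:
        raise ValueError("empty cap table")
    areas = np.asarray(table["area_um2"], dtype=float)
    if np.any(areas <= 0):
        raise ValueError("cap areas must be positive")
    upper = bin_width_um2 * math.ceil(areas.max() / bin_width_um2)
    edges = np.arange(0.0, upper + bin_width_um2 / 2, bin_width_um2)
    counts, edges = np.histogram(areas, bins=edges)
    return CapStatistics(
        mean_area_um2=float(areas.mean()),
        n_caps=len(areas),
        small_cap_fraction=float((areas < small_threshold_um2).mean()),
        small_threshold_um2=small_threshold_um2,
        hist_counts=counts,
        hist_edges=edges,
    )


def nuclear_density(n_nuclei: int, field_area_um2: float) -> float:
    """Nuclei per μm² — the nuclear-fallout readout."""
    if n_nuclei < 0:
        raise ValueError("n_nuclei must be nonnegative")
    if not field_area_um2 > 0:
        raise ValueError("field_area_um2 must be positive")
    return n_nuclei / field_area_um2


def count_bright_regions(img: Image2D, label_map: LabelMap) -> int:
    """Count segmented regions that are bright in the source channel.

    Watershed tessellates the whole field, so basins seeded in dark
    background (e.g. fallout gaps) must be excluded before counting
    nuclei/caps. Per-region mean source intensities are split into a
    bright and a dark class by an Otsu threshold; when the means span
    less than a factor of two there is no background class (a fully
    occupied field) and every region is counted.
    """
    labels = label_map.labels
    if labels.max() == 0:
        return 0
    pixels = img.pixels
    if np.all(pixels == pixels.flat[0]):
        raise ValueError("constant image: cannot separate structures from background")
    from scipy import ndimage as _ndi

    ids = np.unique(labels[labels > 0])
    means = np.asarray(_ndi.mean(pixels, labels=labels, index=ids))
    if means.max() <= 2 * means.min():
        return len(means)
    thr = threshold_otsu(means)
    return int((means > thr).sum())


def missing_furrow_ratio(n_missing: int, n_caps: int) -> float:
    """Missing pseudo-cleavage furrows normalized by the number of caps."""
    if n_caps < 1:
        raise ValueError("n_caps must be >= 1")
    if n_missing < 0:
        raise ValueError("n_missing must be nonnegative")
    return n_missing / n_caps


@dataclass
class SpindleGeometry:
    """Point annotation for one nucleus: centrosomes and optional poles."""

    nucleus_center_um: tuple[float, float]
    centrosome_a_um: tuple[float, float]
    centrosome_b_um: tuple[float, float]
    spindle_pole_a_um: tuple[float, float] | None = None
    spindle_pole_b_um: tuple[float, float] | None = None


@dataclass
class CentrosomeMetrics:
    distance_um: float
    angle_deg: float
    spindle_length_um: float | None


def centrosome_metrics(g: SpindleGeometry) -> CentrosomeMetrics:
    """Centrosome separation, vertex angle at the nucleus, spindle length.

    The angle is subtended at the nuclear center by the two centrosomes
    (180° when they flank the nucleus on opposite sides); undefined, and
    an error, when a centrosome coincides with the nuclear center.
    """
    n = np.asarray(g.nucleus_center_um, dtype=float)
    a = np.asarray(g.centrosome_a_um, dtype=float)
    b = np.asarray(g.centrosome_b_um, dtype=float)
    if not np.all(np.isfinite([*n, *a, *b])):
        raise ValueError("non-finite coordinates")
    va, vb = a - n, b - n
    la, lb = np.linalg.norm(va), np.linalg.norm(vb)
    if la == 0 or lb == 0:
        raise ValueError("centrosome coincides with nucleus center: angle undefined")
    cos = float(np.clip(np.dot(va, vb) / (la * lb), -1.0, 1.0))
    angle = math.degrees(math.acos(cos))
    distance = float(np.linalg.norm(a - b))
    spindle = None
    if g.spindle_pole_a_um is not None and g.spindle_pole_b_um is not None:
        spindle = float(
            np.linalg.norm(
                np.asarray(g.spindle_pole_a_um, float) - np.asarray(g.spindle_pole_b_um, float)
            )
        )
    return CentrosomeMetrics(distance, angle, spindle)


def normalize_minmax(values) -> np.ndarray:
    """Rescale to [0, 1] via (I − I_min)/(I_max − I_min); order preserved."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least two values")
    lo, hi = float(v.min()), float(v.max())
    if hi == lo:
        raise ValueError("zero dynamic range: all values equal")
    return (v - lo) / (hi - lo)


def furrow_intensity_ratio(
    positions_um,
    intensities,
    apical_window_um: float = 2.0,
    basal_window_um: float = 2.0,
) -> float:
    """Apical/basal furrow actin ratio over the outermost 2 μm windows.

    Intensities along the furrow axis (apical end first) are min–max
    normalized, then averaged over the first ``apical_window_um`` and the
    last ``basal_window_um`` of the profile; the ratio of the two means
    is returned.
    """
    pos = np.asarray(positions_um, dtype=float)
    norm = normalize_minmax(intensities)
    length = pos[-1] - pos[0]
    if length < apical_window_um + basal_window_um:
        raise ValueError("profile shorter than the apical+basal windows")
    apical = norm[pos <= pos[0] + apical_window_um]
    basal = norm[pos >= pos[-1] - basal_window_um]
    basal_mean = float(basal.mean())
    if basal_mean == 0:
        raise ValueError("basal window mean is zero: ratio undefined")
    return float(apical.mean()) / basal_mean
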