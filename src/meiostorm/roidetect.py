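"""Semi-automatic detection of recombination-focus regions of interest.

Implements the 11-step selection used to place 750-nm circular ROIs on
RAD51/DMC1 accumulations that lie on or near the synaptonemal-complex
axes:

1-3.  axis channel rendered, Gaussian-blurred (sigma 10 nm), Huang
      thresholded (dark background), components filtered to area
      >= 50,000 nm^2 and circularity <= 0.89 (beads excluded), dilated
      by 125 nm;
4-6.  per-recombinase Huang masks with minimum component areas of
      12,500 nm^2 (RAD51) and 7,500 nm^2 (DMC1), dilated by 15 nm;
      a double-positive mask (regions containing both) and the merged
      union mask;
7-8.  final axis mask = axis mask UNION double-positive mask; merged
      recombinase density restricted to it;
9-10. local maxima of the restricted density become ROI centers; one
      single-linkage merging round replaces center clusters within
      400 nm by their unweighted centroid;
11.   declarative manual edits (removals/additions/recenterings).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.ndimage import distance_transform_edt, gaussian_filter
from skimage import measure
from skimage.feature import peak_local_max

from .locio import LocalizationTable
from .render import BinaryMask, DensityImage, render_density

__all__ = [
    "ROI",
    "RoiEditList",
    "EditError",
    "huang_threshold",
    "build_axis_mask",
    "build_recombinase_masks",
    "detect_rois",
    "apply_manual_edits",
]

logger = logging.getLogger(__name__)

AXIS_BLUR_SIGMA_NM = 10.0
AXIS_MIN_AREA_NM2 = 50_000.0
AXIS_MAX_CIRCULARITY = 0.89
AXIS_DILATION_NM = 125.0
RAD51_MIN_AREA_NM2 = 12_500.0
DMC1_MIN_AREA_NM2 = 7_500.0
RECOMBINASE_DILATION_NM = 15.0
ROI_DIAMETER_NM = 750.0
MERGE_RADIUS_NM = 400.0
DEFAULT_NOISE_TOLERANCE = 0.15  # loc/nm^2, matches the recombinase KDE threshold


@dataclass
class ROI:
    """A 750-nm circular region of interest around one putative DSB site."""

    id: str
    nucleus_id: str
    center: tuple[float, float]
    diameter: float = ROI_DIAMETER_NM
    provenance: str = "automatic"
    chromosome_label: str | None = None

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("ROI diameter must be positive")

    @property
    def radius(self) -> float:
        return self.diameter / 2.0


@dataclass
class RoiEditList:
    """Declarative manual-curation record (step 11)."""

    removals: list[str] = field(default_factory=list)
    additions: list[tuple[float, float]] = field(default_factory=list)
    recenterings: dict[str, tuple[float, float]] = field(default_factory=dict)


class EditError(ValueError):
    """Manual edit references an unknown ROI id."""


# ---------------------------------------------------------------------------
# Huang threshold (fuzzy-entropy minimization, Fiji "Huang dark" in spirit)


def huang_threshold(values: np.ndarray, nbins: int = 256) -> float:
    """Huang-Wang minimum-fuzziness threshold of an intensity image.

    The image is binned into ``nbins`` levels; for each candidate level the
    fuzzy membership of a pixel to its side's class mean is scored with
    Shannon's entropy function and the level minimizing total fuzziness is
    returned (as a value on the original intensity scale, objects above).
    """
    v = np.asarray(values, float).ravel()
    lo, hi = float(v.min()), float(v.max())
    if hi <= lo:
        return hi
    hist, edges = np.histogram(v, bins=nbins, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    nz = np.flatnonzero(hist)
    first, last = nz[0], nz[-1]
    term = 1.0 / max(last - first, 1)
    w = hist.astype(float)
    cum_w = np.cumsum(w)
    cum_wx = np.cumsum(w * np.arange(nbins))
    total_w, total_wx = cum_w[-1], cum_wx[-1]

    best_t, best_ent = first, np.inf
    for t in range(first, last):
        w0 = cum_w[t]
        w1 = total_w - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = cum_wx[t] / w0
        mu1 = (total_wx - cum_wx[t]) / w1
        idx = np.arange(nbins)
        mem = np.where(
            idx <= t,
            1.0 / (1.0 + term * np.abs(idx - mu0)),
            1.0 / (1.0 + term * np.abs(idx - mu1)),
        )
        mem = np.clip(mem, 1e-12, 1 - 1e-12)
        ent = float(np.sum(w * (-mem * np.log(mem) - (1 - mem) * np.log(1 - mem))))
        if ent < best_ent:
            best_ent, best_t = ent, t
    return float(centers[best_t])


# ---------------------------------------------------------------------------
# mask construction helpers


def _disk_radius_px(radius_nm: float, pixel_size: float) -> int:
    return max(1, int(round(radius_nm / pixel_size)))


def _dilate_disc(mask: np.ndarray, radius_px: int) -> np.ndarray:
    """Euclidean-disc morphological dilation via the distance transform."""
    if radius_px <= 0 or not mask.any():
        return mask
    return distance_transform_edt(~mask) <= radius_px


def _filter_components(
    mask: np.ndarray,
    pixel_area: float,
    min_area_nm2: float,
    max_circularity: float | None = None,
) -> np.ndarray:
    """Drop 8-connected components below an area floor (and, optionally,
    rounder than the circularity ceiling - the bead exclusion)."""
    labels = measure.label(mask, connectivity=2)
    keep = np.zeros(labels.max() + 1, bool)
    for rp in measure.regionprops(labels):
        area_nm2 = rp.area * pixel_area
        if area_nm2 < min_area_nm2:
            continue
        if max_circularity is not None:
            perim = rp.perimeter
            circ = 4 * np.pi * rp.area / perim**2 if perim > 0 else 1.0
            if circ > max_circularity:
                continue
        keep[rp.label] = True
    return keep[labels]


def build_axis_mask(
    axis_table: LocalizationTable,
    axis_channel: str | None = None,
    pixel_size: float = 5.0,
    blur_sigma: float = AXIS_BLUR_SIGMA_NM,
    min_area: float = AXIS_MIN_AREA_NM2,
    max_circularity: float = AXIS_MAX_CIRCULARITY,
    dilation: float = AXIS_DILATION_NM,
    *,
    extent: tuple[float, float, float, float] | None = None,
    density: DensityImage | None = None,
) -> BinaryMask:
    """Steps 1-3: blurred axis density, Huang threshold, particle filter,
    125-nm dilation. ``density`` may be supplied to reuse a rendered image."""
    if density is None:
        density = render_density(axis_table, axis_channel, pixel_size, extent=extent)
    if not np.any(density.values > 0):
        warnings.warn("axis channel is empty; returning empty mask")
        return BinaryMask(np.zeros(density.shape, bool), density.pixel_size, density.origin)
    blurred = gaussian_filter(density.values, blur_sigma / density.pixel_size)
    thr = huang_threshold(blurred)
    mask = blurred > thr
    mask = _filter_components(mask, density.pixel_area, min_area, max_circularity)
    mask = _dilate_disc(mask, _disk_radius_px(dilation, density.pixel_size))
    return BinaryMask(mask, density.pixel_size, density.origin)


def _recombinase_mask(
    density: DensityImage, min_area_nm2: float, dilation_nm: float
) -> np.ndarray:
    if not np.any(density.values > 0):
        warnings.warn("empty recombinase channel")
        return np.zeros(density.shape, bool)
    thr = huang_threshold(density.values)
    mask = density.values > thr
    mask = _filter_components(mask, density.pixel_area, min_area_nm2)
    return _dilate_disc(mask, _disk_radius_px(dilation_nm, density.pixel_size))


def build_recombinase_masks(
    rad51_density: DensityImage,
    dmc1_density: DensityImage,
    rad51_min_area: float = RAD51_MIN_AREA_NM2,
    dmc1_min_area: float = DMC1_MIN_AREA_NM2,
    dilation: float = RECOMBINASE_DILATION_NM,
) -> tuple[BinaryMask, BinaryMask, BinaryMask, BinaryMask]:
    """Steps 4-6: per-channel masks, the double-positive mask (connected
    regions of the union that contain pixels of both channels), and the
    merged union mask. The two densities must share grid geometry."""
    if rad51_density.shape != dmc1_density.shape:
        raise ValueError("RAD51 and DMC1 densities must share grid geometry")
    geo = (rad51_density.pixel_size, rad51_density.origin)
    rad = _recombinase_mask(rad51_density, rad51_min_area, dilation)
    dmc = _recombinase_mask(dmc1_density, dmc1_min_area, dilation)
    union = rad | dmc
    labels = measure.label(union, connectivity=2)
    in_rad = np.unique(labels[rad])
    in_dmc = np.unique(labels[dmc])
    both = np.intersect1d(in_rad, in_dmc)
    keep = np.zeros(labels.max() + 1, bool)
    keep[both[both > 0]] = True
    double = keep[labels]
    return (
        BinaryMask(rad, *geo),
        BinaryMask(dmc, *geo),
        BinaryMask(double, *geo),
        BinaryMask(union, *geo),
    )


# ---------------------------------------------------------------------------
# ROI placement


def _merge_centers(centers: np.ndarray, merge_radius: float) -> np.ndarray:
    """One single-linkage round: transitive chains of centers within
    ``merge_radius`` collapse to their unweighted centroid."""
    if len(centers) <= 1:
        return centers
    Z = linkage(centers, method="single")
    groups = fcluster(Z, t=merge_radius, criterion="distance")
    return np.array([centers[groups == g].mean(axis=0) for g in np.unique(groups)])


def detect_rois(
    axis_mask: BinaryMask,
    recombinase_masks: tuple[BinaryMask, BinaryMask, BinaryMask, BinaryMask],
    merged_density: DensityImage,
    roi_diameter: float = ROI_DIAMETER_NM,
    merge_radius: float = MERGE_RADIUS_NM,
    noise_tolerance: float = DEFAULT_NOISE_TOLERANCE,
    nucleus_id: str = "",
) -> list[ROI]:
    """Steps 7-10: union with the double-positive mask, restrict the merged
    recombinase density, find local maxima, merge nearby centers."""
    _, _, double_positive, _ = recombinase_masks
    if axis_mask.shape != merged_density.shape:
        raise ValueError("axis mask and merged density must share grid geometry")
    final_axis = axis_mask.values | double_positive.values
    restricted = np.where(final_axis, merged_density.values, 0.0)
    # Fiji-style "Find Maxima": regional maxima above the noise tolerance;
    # a small minimum separation suppresses plateau duplicates, the 400-nm
    # merging round below handles the rest.
    min_dist_px = max(1, int(round(50.0 / merged_density.pixel_size)))
    peaks = peak_local_max(
        restricted, min_distance=min_dist_px, threshold_abs=noise_tolerance,
        exclude_border=False,
    )
    if len(peaks) == 0:
        warnings.warn("no ROI maxima found")
        return []
    centers_px = peaks[:, ::-1].astype(float)  # (col, row)
    centers = merged_density.pixel_to_world(centers_px)
    centers = _merge_centers(centers, merge_radius)
    logger.info("detect_rois: %d maxima -> %d ROIs after merging", len(peaks), len(centers))
    return [
        ROI(f"roi_{i}", nucleus_id, (float(x), float(y)), roi_diameter)
        for i, (x, y) in enumerate(centers)
    ]


def apply_manual_edits(rois: list[ROI], edits: RoiEditList) -> list[ROI]:
    """Step 11: removals, additions (provenance ``manual_added``) and
    recenterings; the touched fraction is logged for QC."""
    known = {r.id for r in rois}
    unknown = [i for i in list(edits.removals) + list(edits.recenterings) if i not in known]
    if unknown:
        raise EditError(f"edit references unknown ROI id(s): {unknown}")
    out: list[ROI] = []
    for roi in rois:
        if roi.id in edits.removals:
            continue
        if roi.id in edits.recenterings:
            roi = replace(
                roi, center=tuple(edits.recenterings[roi.id]), provenance="manual_recentered"
            )
        out.append(roi)
    diameter = rois[0].diameter if rois else ROI_DIAMETER_NM
    nucleus = rois[0].nucleus_id if rois else ""
    for k, (x, y) in enumerate(edits.additions):
        out.append(
            ROI(f"roi_manual_{k}", nucleus, (float(x), float(y)), diameter, "manual_added")
        )
    n_edits = len(edits.removals) + len(edits.additions) + len(edits.recenterings)
    if rois:
        logger.info("manual edits touched %.1f%% of ROIs", 100 * n_edits / len(rois))
    return out
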