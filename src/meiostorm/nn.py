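"""Nearest-neighbor distance analyses of nanofocus centers.

Each nanofocus contributes the Euclidean distance to its nearest
same-channel neighbor within the nucleus (directed: mutual pairs count
twice). Per-nucleus relative-frequency histograms use 100-nm bins up to
3.5 um with an explicit "rest" bin beyond, and nuclei are averaged with
equal weight. Two wild-type subsetting controls mimic the reduced
focus numbers of the knockout: ROI-based (keep a random 38.5% of ROIs
with all their nanofoci, preserving intra-ROI structure) and
nanofocus-based (keep a random 40% of nanofoci regardless of ROI,
destroying it). An axis-projected variant measures along-axis
arc-length distances between projected nanofocus coordinates within
each axis fragment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "NNHistogram",
    "nearest_neighbor_distances",
    "bin_distances",
    "subset_nuclei",
    "axis_projected_nn",
    "band_mass",
]

BIN_WIDTH_NM = 100.0
REST_THRESHOLD_NM = 3_500.0
ROI_SUBSET_FRACTION = 0.385
NANOFOCUS_SUBSET_FRACTION = 0.40


def nearest_neighbor_distances(points: np.ndarray) -> np.ndarray:
    """Directed nearest-neighbor distance for every point of one channel
    within one nucleus; fewer than two points yield an empty result."""
    pts = np.asarray(points, float).reshape(-1, 2)
    if len(pts) < 2:
        return np.zeros(0)
    tree = cKDTree(pts)
    dist, _ = tree.query(pts, k=2)
    return dist[:, 1]


@dataclass
class NNHistogram:
    """Across-nuclei average of per-nucleus relative-frequency histograms."""

    bin_edges: np.ndarray  # 0..3500 step 100
    mean_frequency: np.ndarray  # per bin
    sd_frequency: np.ndarray
    rest_fraction: float  # mean frequency of distances > 3500 nm
    n_nuclei: int

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def bin_distances(
    per_nucleus_distances: Sequence[np.ndarray],
    bin_width: float = BIN_WIDTH_NM,
    rest_threshold: float = REST_THRESHOLD_NM,
) -> NNHistogram:
    """Bin each nucleus's distances into half-open 100-nm bins (rest beyond
    3.5 um), normalize per nucleus, then average nuclei unweighted."""
    edges = np.arange(0.0, rest_threshold + bin_width / 2, bin_width)
    freqs, rests = [], []
    for d in per_nucleus_distances:
        d = np.asarray(d, float)
        if len(d) == 0:
            continue
        counts, _ = np.histogram(d, bins=edges)
        rest = np.sum(d >= rest_threshold)
        total = len(d)
        freqs.append(counts / total)
        rests.append(rest / total)
    if not freqs:
        raise ValueError("no nucleus contributed any distance")
    F = np.vstack(freqs)
    return NNHistogram(
        bin_edges=edges,
        mean_frequency=F.mean(axis=0),
        sd_frequency=F.std(axis=0, ddof=1) if len(F) > 1 else np.zeros(F.shape[1]),
        rest_fraction=float(np.mean(rests)),
        n_nuclei=len(freqs),
    )


def band_mass(hist: NNHistogram, lo: float, hi: float) -> float:
    """Summed mean frequency of the bins whose full extent lies in [lo, hi]."""
    sel = (hist.bin_edges[:-1] >= lo) & (hist.bin_edges[1:] <= hi)
    return float(hist.mean_frequency[sel].sum())


def subset_nuclei(
    roi_ids: np.ndarray,
    mode: str,
    fraction: float,
    seed: int | None = None,
) -> np.ndarray:
    """Boolean keep-mask for one nucleus's nanofoci.

    ``roi_ids`` assigns each nanofocus to its ROI. ``roi_based`` keeps a
    uniform random floor(fraction * n_rois) ROIs (minimum 1) with all
    their nanofoci; ``nanofocus_based`` keeps floor(fraction * n) nanofoci
    (minimum 1) regardless of ROI membership. Sampling is without
    replacement and reproducible by seed.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    roi_ids = np.asarray(roi_ids)
    rng = np.random.default_rng(seed)
    if mode == "roi_based":
        rois = np.unique(roi_ids)
        k = max(1, int(np.floor(fraction * len(rois)))) if len(rois) else 0
        keep_rois = rng.choice(rois, size=k, replace=False) if k else rois
        return np.isin(roi_ids, keep_rois)
    if mode == "nanofocus_based":
        n = len(roi_ids)
        k = max(1, int(np.floor(fraction * n))) if n else 0
        keep = np.zeros(n, bool)
        keep[rng.choice(n, size=k, replace=False)] = True
        return keep
    raise ValueError(f"unknown subset mode {mode!r}")


def axis_projected_nn(
    projections: Sequence[tuple[str, float]],
    roi_membership: Sequence[str],
) -> np.ndarray:
    """Along-axis nearest-neighbor distances of projected coordinates.

    ``projections`` are (fragment_id, arc_nm) per nanofocus and
    ``roi_membership`` the owning ROI id. Fragments whose nanofoci all
    come from a single ROI are excluded (they would only contribute
    intra-ROI distances). Distances are |arc_i - arc_j| within a
    fragment, each point contributing its nearest neighbor.
    """
    frags = np.array([f for f, _ in projections])
    arcs = np.array([a for _, a in projections], float)
    rois = np.asarray(roi_membership)
    out: list[float] = []
    for frag in np.unique(frags):
        sel = frags == frag
        if len(np.unique(rois[sel])) < 2:
            continue
        a = np.sort(arcs[sel])
        if len(a) < 2:
            continue
        gaps = np.diff(a)
        for i in range(len(a)):
            if i == 0:
                out.append(gaps[0])
            elif i == len(a) - 1:
                out.append(gaps[-1])
            else:
                out.append(min(gaps[i - 1], gaps[i]))
    return np.asarray(out)
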