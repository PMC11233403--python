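"""Granule contour extraction and diameter (Feret length) morphometry.

Granules appear in binary masks as filled, roughly circular silhouettes.
Each 8-connected component yields one outer contour (holes are ignored —
granules are solid); its *length* is the Feret diameter, the longest
distance between two contour points, scaled by the pixel pitch.  Silhouettes
of overlapping granules merge into one component and produce spuriously long
lengths, so the diameter distribution is read from lengths below a cutoff
(50 nm by default) where the measurement reflects single, well-separated
granules; for those, length is close to the width in both x and y.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from skimage import measure

from .io_core import SegMask

DEFAULT_CUTOFF_NM = 50.0
DEFAULT_BIN_NM = 2.5  # resolves the 15-40 nm granule range


@dataclass
class GranuleContour:
    """Outer contour of one connected granule silhouette.

    ``points`` are ordered (row, col) pixel-center coordinates of the
    component's boundary pixels, in tracing order.
    """

    component_id: int
    points: np.ndarray
    length_nm: float
    width_x_nm: float
    width_y_nm: float


@dataclass
class DiameterHistogram:
    bin_edges_nm: np.ndarray
    counts: np.ndarray
    n_total: int
    n_kept: int
    cutoff_nm: float


def feret_length_bruteforce(points: np.ndarray, pixel_nm: float) -> float:
    """Exhaustive max pairwise distance — the test oracle, O(n^2)."""
    pts = np.asarray(points, dtype=float)
    if len(pts) == 0:
        raise ValueError("empty contour")
    if len(pts) == 1:
        return 0.0
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
    return float(np.sqrt(d2.max())) * pixel_nm


def feret_length(points: np.ndarray, pixel_nm: float) -> float:
    """Feret length: max pairwise distance over contour points, in nm.

    Computed on the convex hull of the points (the diameter of a point set is
    attained between hull vertices), which keeps the pairwise search small.
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) == 0:
        raise ValueError("empty contour")
    if len(pts) <= 3:
        return feret_length_bruteforce(pts, pixel_nm)
    try:
        hull = ConvexHull(pts)
        pts = pts[hull.vertices]
    except QhullError:
        pass  # degenerate (collinear) point sets: brute force directly
    return feret_length_bruteforce(pts, pixel_nm)


def _snap_to_boundary_pixels(trace: np.ndarray, img: np.ndarray) -> np.ndarray:
    """Snap a marching-squares trace to the boundary *pixel centers* inside.

    Each trace vertex sits halfway between an inside and an outside pixel;
    the inside one is the boundary pixel.  Consecutive duplicates are
    dropped, preserving the tracing order.
    """
    lo = np.floor(trace).astype(int)
    hi = np.ceil(trace).astype(int)
    snapped = np.empty_like(lo)
    for k, (p, a, b) in enumerate(zip(trace, lo, hi)):
        candidates = {(a[0], a[1]), (a[0], b[1]), (b[0], a[1]), (b[0], b[1])}
        inside = [c for c in candidates if img[c[0], c[1]]]
        snapped[k] = min(inside, key=lambda c: (c[0] - p[0]) ** 2 + (c[1] - p[1]) ** 2)
    keep = np.ones(len(snapped), dtype=bool)
    keep[1:] = (np.diff(snapped, axis=0) != 0).any(axis=1)
    out = snapped[keep]
    if len(out) > 1 and (out[0] == out[-1]).all():
        out = out[:-1]
    return out.astype(float)


def extract_contours(mask: SegMask) -> list[GranuleContour]:
    """One outer contour per 8-connected component of a binary granules mask."""
    if mask.scheme != "granules":
        raise ValueError("extract_contours expects a granules mask")
    arr = mask.labels
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("mask must be binary")
    labeled, n_comp = measure.label(arr, connectivity=2, return_num=True)
    contours: list[GranuleContour] = []
    for region in measure.regionprops(labeled):
        r0, c0, r1, c1 = region.bbox
        # pad by 1 so marching squares closes contours at the image border
        sub = np.zeros((r1 - r0 + 2, c1 - c0 + 2), dtype=np.uint8)
        sub[1:-1, 1:-1] = region.image
        found = measure.find_contours(sub.astype(float), 0.5)
        if not found:  # pragma: no cover - a nonempty component always has one
            continue
        trace = max(found, key=len)  # outer contour is the longest; holes ignored
        pts = _snap_to_boundary_pixels(trace, sub) + np.array([r0 - 1, c0 - 1])
        length = feret_length(pts, mask.pixel_nm)
        width_y = float(pts[:, 0].max() - pts[:, 0].min()) * mask.pixel_nm
        width_x = float(pts[:, 1].max() - pts[:, 1].min()) * mask.pixel_nm
        contours.append(
            GranuleContour(
                component_id=region.label,
                points=pts,
                length_nm=length,
                width_x_nm=width_x,
                width_y_nm=width_y,
            )
        )
    return contours


def diameter_histogram(
    lengths_nm,
    cutoff_nm: float = DEFAULT_CUTOFF_NM,
    bin_nm: float = DEFAULT_BIN_NM,
) -> DiameterHistogram:
    """Histogram of well-measured diameters: lengths below ``cutoff_nm``.

    Lengths at or above the cutoff (merged silhouettes) are excluded from the
    counts but reported in ``n_total``.
    """
    if bin_nm <= 0:
        raise ValueError("bin width must be positive")
    lengths = np.asarray(lengths_nm, dtype=float)
    if (lengths < 0).any():
        raise ValueError("lengths must be non-negative")
    kept = lengths[lengths < cutoff_nm]
    edges = np.arange(0.0, cutoff_nm + bin_nm, bin_nm)
    counts, edges = np.histogram(kept, bins=edges)
    return DiameterHistogram(
        bin_edges_nm=edges,
        counts=counts,
        n_total=int(lengths.size),
        n_kept=int(kept.size),
        cutoff_nm=cutoff_nm,
    )
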