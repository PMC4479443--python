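"""Separation of overlapped blood cells by concave-point cutting.

An overlapped aggregate shows a waist: the boundary dips inside its convex
hull on both sides.  The contour is cut at a pair of concave points (the
deepest convexity-defect apexes across the waist) and each open fragment is
re-closed by expressing its boundary as r(theta) about the fragment centroid
and linearly interpolating the radius across the angular gap — tracing a
conic-like closing arc back in cartesian space that restores the occluded
part of the cell border while keeping the visible boundary untouched.  A
final 3x3 morphological closing joins small discontinuities.  Fragments too
small to be cells are discarded.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull
from skimage import draw as _skdraw

from .features import _ordered_boundary

logger = logging.getLogger(__name__)

__all__ = ["Contour", "detect_concave_points", "split_overlapped"]


class Contour:
    """Closed boundary of a region with a polar representation.

    Wraps the ordered (row, col) boundary pixel chain; the polar form is
    taken about the contour centroid.
    """

    def __init__(self, points: np.ndarray):
        points = np.asarray(points, dtype=np.float64)
        if len(points) < 3:
            raise ValueError("a contour needs at least 3 points")
        self.points = points
        self.centroid = points.mean(axis=0)

    @classmethod
    def from_mask(cls, mask: np.ndarray) -> "Contour":
        return cls(_ordered_boundary(mask))

    def __len__(self) -> int:
        return len(self.points)

    def polar(self) -> tuple[np.ndarray, np.ndarray]:
        """(theta, r) of every boundary point about the centroid, theta in [0, 2pi)."""
        d = self.points - self.centroid
        theta = np.mod(np.arctan2(d[:, 0], d[:, 1]), 2.0 * np.pi)
        r = np.hypot(d[:, 0], d[:, 1])
        return theta, r


def _hull_depths(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-point depth below the convex hull and the hull-arc id of each point.

    The hull is computed on the contour points; between two consecutive hull
    vertices (in contour order) every point's depth is its perpendicular
    distance to the hull chord.  Points on the hull have depth 0.
    """
    n = len(points)
    hull = ConvexHull(points)
    hull_idx = np.sort(np.unique(hull.vertices))
    depths = np.zeros(n)
    arc_id = np.full(n, -1, dtype=np.int64)
    for a_num, (i0, i1) in enumerate(zip(hull_idx, np.roll(hull_idx, -1))):
        seg = np.arange(i0, i1 if i1 > i0 else i1 + n) % n
        if len(seg) <= 1:
            continue
        p0, p1 = points[i0], points[i1 % n]
        chord = p1 - p0
        norm = np.linalg.norm(chord)
        if norm == 0:
            continue
        interior = seg[1:]
        rel = points[interior] - p0
        d = np.abs(chord[0] * rel[:, 1] - chord[1] * rel[:, 0]) / norm
        depths[interior] = d
        arc_id[interior] = a_num
    return depths, arc_id


def detect_concave_points(contour: Contour, depth_min: float = 3.0) -> list[int]:
    """Indices of convexity-defect apexes at least ``depth_min`` deep.

    Within each hull arc the depth profile is scanned for local maxima (with
    a prominence of ``depth_min``/2), so two waists whose crest dips just
    below the hull still yield separate apexes.  A waist between two
    overlapped cells yields one apex on each side; a convex contour returns
    an empty list.
    """
    from scipy.signal import find_peaks

    if len(contour) < 20:
        raise ValueError("contour too short for concavity analysis (need >= 20 points)")
    depths, arc_id = _hull_depths(contour.points)
    apexes: list[int] = []
    for arc in np.unique(arc_id[arc_id >= 0]):
        members = np.nonzero(arc_id == arc)[0]
        # members are consecutive along the contour (modulo wrap)
        order = np.argsort((members - members[0]) % len(contour))
        members = members[order]
        profile = np.concatenate([[0.0], depths[members], [0.0]])  # hull-vertex endpoints
        peaks, _ = find_peaks(profile, height=depth_min, prominence=depth_min / 2.0)
        apexes.extend(int(members[p - 1]) for p in peaks)
    return sorted(apexes)


def _closed_fragment_polygon(frag: np.ndarray, step_deg: float = 1.0) -> np.ndarray:
    """Close an open boundary fragment with a polar-interpolated arc.

    The fragment is expressed as r(theta) about its own centroid; the angular
    gap from the last point back to the first is filled by linear
    interpolation of r over theta (sampled at ``step_deg``), so the closing
    curve is a conic-like arc in cartesian space.
    """
    centroid = frag.mean(axis=0)
    d = frag - centroid
    theta = np.arctan2(d[:, 0], d[:, 1])
    r = np.hypot(d[:, 0], d[:, 1])
    theta_u = np.unwrap(theta)
    span = theta_u[-1] - theta_u[0]
    # the closing arc completes the winding to +-2pi
    gap = (2.0 * np.pi if span >= 0 else -2.0 * np.pi) - span
    n_steps = max(2, int(abs(gap) / np.deg2rad(step_deg)))
    gthetas = theta_u[-1] + gap * np.linspace(0.0, 1.0, n_steps + 1)[1:-1]
    gr = r[-1] + (r[0] - r[-1]) * np.linspace(0.0, 1.0, n_steps + 1)[1:-1]
    arc = centroid + np.column_stack([gr * np.sin(gthetas), gr * np.cos(gthetas)])
    return np.vstack([frag, arc])


def _rasterize(polygon: np.ndarray, frag: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    rr, cc = _skdraw.polygon(polygon[:, 0], polygon[:, 1], shape=shape)
    mask[rr, cc] = True
    # stamp the original boundary pixels so the visible border is kept exactly
    fr = np.clip(np.round(frag[:, 0]).astype(int), 0, shape[0] - 1)
    fc = np.clip(np.round(frag[:, 1]).astype(int), 0, shape[1] - 1)
    mask[fr, fc] = True
    return mask


def _chord_inside(mask: np.ndarray, p: np.ndarray, q: np.ndarray, n_samples: int = 25) -> bool:
    """Whether the straight segment p-q stays inside the (slightly dilated) region."""
    fat = ndimage.binary_dilation(mask, iterations=1)
    t = np.linspace(0.0, 1.0, n_samples)
    pts = p[None, :] * (1 - t[:, None]) + q[None, :] * t[:, None]
    rr = np.clip(np.round(pts[:, 0]).astype(int), 0, mask.shape[0] - 1)
    cc = np.clip(np.round(pts[:, 1]).astype(int), 0, mask.shape[1] - 1)
    return bool(fat[rr, cc].all())


def _best_cut_pair(points: np.ndarray, apexes: list[int], mask: np.ndarray) -> tuple[int, int] | None:
    """Pick the cut pair: the mutually closest apexes whose chord crosses the waist.

    The chord between the two sides of a waist is the shortest apex-apex
    segment that stays inside the region.
    """
    n = len(points)
    best: tuple[float, int, int] | None = None
    for ai in range(len(apexes)):
        for aj in range(ai + 1, len(apexes)):
            i, j = apexes[ai], apexes[aj]
            # apexes adjacent along the contour bound the same indentation
            if min((j - i) % n, (i - j) % n) < 5:
                continue
            if not _chord_inside(mask, points[i], points[j]):
                continue
            dist = float(np.linalg.norm(points[i] - points[j]))
            if best is None or dist < best[0]:
                best = (dist, i, j)
    if best is None:
        return None
    return best[1], best[2]


def split_overlapped(
    mask: np.ndarray,
    depth_min: float = 3.0,
    min_area: int = 50,
    step_deg: float = 1.0,
    _depth: int = 0,
) -> list[np.ndarray]:
    """Split an overlapped region into child cell masks.

    Cuts the contour at the mutually closest pair of concave points from
    opposite sides of a waist, closes each fragment with the polar
    interpolation arc, assigns contested pixels to the nearest fragment
    centroid, applies a 3x3 morphological closing, and recurses on each
    child (a three-cell clump needs two cuts).  Children smaller than
    ``min_area`` are discarded (logged).  A convex region is returned
    unchanged as its own single child.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return []
    if _depth >= 4:
        return [mask]
    contour = Contour.from_mask(mask)
    if len(contour) < 20:
        return [mask]
    apexes = detect_concave_points(contour, depth_min=depth_min)
    if len(apexes) < 2:
        return [mask]
    pair = _best_cut_pair(contour.points, apexes, mask)
    if pair is None:
        return [mask]
    i, j = sorted(pair)
    pts = contour.points
    n = len(pts)
    frag_a = pts[i : j + 1]
    frag_b = pts[np.concatenate([np.arange(j, n), np.arange(0, i + 1)])]

    children: list[np.ndarray] = []
    centroids: list[np.ndarray] = []
    for frag in (frag_a, frag_b):
        if len(frag) < 5:
            continue
        poly = _closed_fragment_polygon(frag, step_deg=step_deg)
        child = _rasterize(poly, frag, mask.shape) & mask
        children.append(child)
        centroids.append(frag.mean(axis=0))
    if len(children) < 2:
        return [mask]

    # contested pixels go to the nearest fragment centroid
    both = children[0] & children[1]
    if both.any():
        rr, cc = np.nonzero(both)
        d0 = (rr - centroids[0][0]) ** 2 + (cc - centroids[0][1]) ** 2
        d1 = (rr - centroids[1][0]) ** 2 + (cc - centroids[1][1]) ** 2
        keep0 = d0 <= d1
        children[0][rr[~keep0], cc[~keep0]] = False
        children[1][rr[keep0], cc[keep0]] = False

    out: list[np.ndarray] = []
    selem = np.ones((3, 3), dtype=bool)
    for k, child in enumerate(children):
        closed = ndimage.binary_closing(child, structure=selem) & mask
        closed &= ~np.logical_or.reduce([c for t, c in enumerate(children) if t != k])
        closed = _largest_component(closed)
        if closed.sum() < min_area:
            logger.info("discarding separation fragment of %d px (< %d)", closed.sum(), min_area)
            continue
        out.extend(split_overlapped(closed, depth_min=depth_min, min_area=min_area, step_deg=step_deg, _depth=_depth + 1))
    return out if out else [mask]


def _largest_component(mask: np.ndarray) -> np.ndarray:
    lab, n = ndimage.label(mask, structure=np.ones((3, 3)))
    if n <= 1:
        return mask
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    return lab == (int(np.argmax(sizes)) + 1)
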