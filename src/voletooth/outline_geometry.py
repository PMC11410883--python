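"""Outline extraction, anatomical feature detection and landmark resampling.

The processing chain turns a calibrated, canonically oriented molar image
into 200 ordered landmarks along the anterior semiperimeter:

1. ``extract_outline`` traces the closed inner-enamel outline.  Photographs
   are segmented and the boundary of the filled mask is traced; drawings are
   cleaned of cement blobs, thinned to a one-pixel skeleton and the largest
   closed skeleton cycle (the stroke midline) is returned.
2. ``detect_feature_points`` finds the anterior apex, the buccal/lingual
   re-entrant angles (BRA/LRA, numbered from the posterior end), the
   triangle salients between them, and the endpoints of Van der Meulen's
   segment 'a' (the deepest points of BRA3 and LRA4).
3. ``anterior_semiperimeter`` keeps the sub-chain between the two 'a'
   endpoints that passes through the apex (triangles T4..T7 plus the
   anterior cap); the posterior part carries no discriminant information
   and is discarded.
4. ``resample_landmarks`` decimates the semiperimeter to n=200 points at
   uniform arc-length spacing and converts to a y-up mm frame.

Pixel coordinates are y-down, 0-based, (x, y) = (column, row); landmark
coordinates are y-up mm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.ndimage import binary_fill_holes, uniform_filter1d
from scipy.spatial import ConvexHull
from shapely.geometry import LinearRing, Point

from .errors import (
    ClippedSpecimenError,
    InsufficientReentrantsError,
    OutlineNotClosedError,
    SemiperimeterTooShortError,
    ValidationError,
)
from .image_ingest import OcclusalImage

__all__ = [
    "OutlineTrace",
    "FeatureAnnotation",
    "LandmarkSet",
    "extract_outline",
    "detect_feature_points",
    "anterior_semiperimeter",
    "resample_landmarks",
]

#: moving-average window (samples at 1 px spacing) used before curvature/hull analysis
SMOOTHING_WINDOW = 7
#: re-entrant depth threshold as a fraction of the convex-hull perimeter.
#: The hull perimeter is used as the size reference because, unlike the
#: outline length, it does not itself grow with fold depth.  2% of a typical
#: 7-8 mm hull is ~0.15 mm: well above smoothing/noise-induced pocket depths
#: (a few hundredths of a mm) and below any true arvicoline re-entrant.
REENTRANT_DEPTH_FRACTION = 0.02


@dataclass(frozen=True)
class OutlineTrace:
    """Ordered closed outline of the occlusal surface, pixel coordinates.

    ``points`` run counter-clockwise in a y-up frame (clockwise on screen),
    with ~1 px spacing; the first point is not repeated at the end.
    """

    points: np.ndarray  # (N, 2) float, (x_px, y_px)
    scale: float  # mm per pixel

    def __len__(self) -> int:
        return len(self.points)

    @property
    def perimeter_px(self) -> float:
        closed = np.vstack([self.points, self.points[:1]])
        return float(np.linalg.norm(np.diff(closed, axis=0), axis=1).sum())

    def enclosed_area_px(self) -> float:
        x, y = self.points[:, 0], self.points[:, 1]
        return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0)

    def to_mm(self) -> np.ndarray:
        """Convert to the y-up mm frame used by landmarks and measurements."""
        out = self.points * self.scale
        out[:, 1] *= -1.0
        return out


@dataclass(frozen=True)
class FeatureAnnotation:
    """Indices into an OutlineTrace of the detected anatomical features."""

    apex: int
    buccal_reentrants: list[int] = field(default_factory=list)  # BRA1.. from posterior
    lingual_reentrants: list[int] = field(default_factory=list)  # LRA1.. from posterior
    buccal_salients: list[int] = field(default_factory=list)  # between consecutive BRA
    lingual_salients: list[int] = field(default_factory=list)
    a_endpoint_buccal: int | None = None  # deepest point of BRA3
    a_endpoint_lingual: int | None = None  # deepest point of LRA4


@dataclass(frozen=True)
class LandmarkSet:
    """200 ordered semiperimeter landmarks in mm (y-up).

    Ordered from the buccal 'a' endpoint, through the anterior apex, to the
    lingual 'a' endpoint.
    """

    coords: np.ndarray  # (n, 2) mm
    specimen_id: str = ""
    species: str = ""
    source_kind: str = "photo"

    def __post_init__(self):
        c = np.asarray(self.coords, dtype=float)
        if c.ndim != 2 or c.shape[1] != 2:
            raise ValidationError("landmark coords must be (n, 2)")
        object.__setattr__(self, "coords", c)

    def __len__(self) -> int:
        return len(self.coords)

    def centred(self) -> np.ndarray:
        return self.coords - self.coords.mean(axis=0)


# ---------------------------------------------------------------------------
# outline extraction
# ---------------------------------------------------------------------------

def _canonical_direction(points: np.ndarray) -> np.ndarray:
    """Orient a closed pixel-frame polyline counter-clockwise in y-up."""
    x, y = points[:, 0], points[:, 1]
    area2 = np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))
    # pixel frame is y-down: a y-up-CCW loop has negative shoelace area there
    return points[::-1].copy() if area2 > 0 else points


def _largest_component(mask: np.ndarray) -> np.ndarray:
    from skimage.measure import label as cc_label

    lab = cc_label(mask, connectivity=2)
    if lab.max() == 0:
        raise OutlineNotClosedError("empty foreground")
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    return lab == sizes.argmax()


def _extract_photo(img: OcclusalImage) -> np.ndarray:
    from skimage.measure import find_contours

    mask = binary_fill_holes(_largest_component(img.foreground))
    contours = find_contours(mask.astype(float), 0.5)
    if not contours:
        raise OutlineNotClosedError("no boundary contour found")
    contour = max(contours, key=len)
    if not (np.allclose(contour[0], contour[-1])):
        raise OutlineNotClosedError("boundary contour is not closed")
    # find_contours yields (row, col); convert to (x, y) and drop the repeat
    return contour[:-1, ::-1].copy()


def _skeleton_cycle(skel: np.ndarray) -> np.ndarray:
    """Order the largest closed cycle of a skeleton into an (x, y) chain."""
    g = nx.Graph()
    rows, cols = np.nonzero(skel)
    pixels = set(zip(rows.tolist(), cols.tolist()))
    for r, c in pixels:
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if (dr or dc) and (r + dr, c + dc) in pixels:
                    g.add_edge((r, c), (r + dr, c + dc))
    # prune spur branches until only cycle pixels remain
    while True:
        leaves = [n for n in g.nodes if g.degree(n) <= 1]
        if not leaves:
            break
        g.remove_nodes_from(leaves)
    if g.number_of_nodes() == 0:
        raise OutlineNotClosedError("outline not closed: drawing stroke has no cycle")
    comp = max(nx.connected_components(g), key=len)
    sub = g.subgraph(comp)
    # walk the cycle, preferring the straightest continuation at junctions
    start = next(iter(sub.nodes))
    chain = [start]
    prev = None
    current = start
    for _ in range(sub.number_of_nodes() + 1):
        nbrs = [n for n in sub.neighbors(current) if n != prev]
        if not nbrs:
            break
        if prev is None:
            nxt = nbrs[0]
        else:
            d = (current[0] - prev[0], current[1] - prev[1])
            nxt = max(
                nbrs,
                key=lambda n: (n[0] - current[0]) * d[0] + (n[1] - current[1]) * d[1],
            )
        if nxt == start:
            break
        chain.append(nxt)
        prev, current = current, nxt
    if len(chain) < 0.8 * sub.number_of_nodes():
        warnings.warn("skeleton cycle walk skipped part of the cycle", stacklevel=2)
    return np.array([(c, r) for r, c in chain], dtype=float)


def _extract_drawing(img: OcclusalImage) -> np.ndarray:
    from scipy.ndimage import binary_opening, distance_transform_edt
    from skimage.morphology import disk, skeletonize

    fg = _largest_component(img.foreground)
    # stroke half-width from the distance transform of the stroke interior
    dist = distance_transform_edt(fg)
    half_w = float(np.median(dist[dist > 0])) if np.any(dist > 0) else 1.0
    # cement areas: blobs thicker than the stroke; subtracting them leaves
    # only the drawn enamel line (they touch the stroke but do not cross it)
    blobs = binary_opening(fg, structure=disk(int(np.ceil(2 * half_w)) + 1))
    stroke = fg & ~blobs
    skel = skeletonize(stroke)
    return _skeleton_cycle(skel)


def extract_outline(img: OcclusalImage) -> OutlineTrace:
    """Trace the closed inner-enamel outline of an oriented molar image.

    Photographs: the boundary chain of the filled foreground mask.
    Drawings: cement blobs removed, the stroke thinned to one pixel, and the
    largest closed skeleton cycle (the stroke midline) returned.

    Raises
    ------
    ClippedSpecimenError
        if the foreground touches the image border.
    OutlineNotClosedError
        if a drawing's stroke contains no closed cycle.
    """
    fg = img.foreground
    if fg[0, :].any() or fg[-1, :].any() or fg[:, 0].any() or fg[:, -1].any():
        raise ClippedSpecimenError("clipped specimen: foreground touches the image border")
    pts = _extract_photo(img) if img.source_kind == "photo" else _extract_drawing(img)
    if len(pts) < 8:
        raise OutlineNotClosedError("outline degenerate (fewer than 8 points)")
    # light circular smoothing removes the half-pixel staircase of the raster
    # boundary (which otherwise inflates arc lengths by ~6%)
    pts = uniform_filter1d(pts, size=5, axis=0, mode="wrap")
    return OutlineTrace(points=_canonical_direction(pts), scale=img.scale)


# ---------------------------------------------------------------------------
# feature detection
# ---------------------------------------------------------------------------

def _resample_uniform(points: np.ndarray, spacing: float = 1.0):
    """Resample a closed polyline at ~uniform arc-length spacing.

    Returns (resampled points, original-index lookup) where the lookup maps
    each resampled point to the nearest original vertex index.
    """
    closed = np.vstack([points, points[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    n = max(int(round(total / spacing)), 16)
    t = np.linspace(0.0, total, n, endpoint=False)
    x = np.interp(t, s, closed[:, 0])
    y = np.interp(t, s, closed[:, 1])
    orig = np.searchsorted(s, t, side="right") - 1
    orig = np.minimum(orig, len(points) - 1)
    return np.column_stack([x, y]), orig


def _smooth_closed(points: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return points
    return uniform_filter1d(points, size=window, axis=0, mode="wrap")


def detect_feature_points(
    trace: OutlineTrace,
    smoothing_window: int = SMOOTHING_WINDOW,
    depth_fraction: float = REENTRANT_DEPTH_FRACTION,
) -> FeatureAnnotation:
    """Detect apex, re-entrants, salients and the segment-'a' endpoints.

    The trace is resampled to 1 px spacing and smoothed with a circular
    moving average.  Re-entrant angles are concave pockets of the convex
    hull whose depth (distance from the hull chord) exceeds
    ``depth_fraction`` of the hull perimeter; the deepest point of each
    pocket is its landmark.  Pockets are assigned to the buccal (bottom of
    screen) or lingual side by the position of their hull chord relative to
    the outline centroid, and numbered 1, 2, ... from the posterior (max-x)
    end.  Salients are the extremal points between consecutive same-side
    re-entrants.  The 'a' endpoints are the deepest points of BRA3 and LRA4.

    Raises
    ------
    InsufficientReentrantsError
        fewer than 3 buccal or 4 lingual re-entrants found (the 'a' line
        cannot be anchored; endpoints may then be supplied manually).
    """
    pts = trace.points
    rs, orig = _resample_uniform(pts, spacing=1.0)
    # start the loop at the posterior-most (max-x) point, a convex-hull
    # vertex, so no concave region spans the index wrap
    shift = int(np.argmax(rs[:, 0]))
    rs = np.roll(rs, -shift, axis=0)
    orig = np.roll(orig, -shift)
    sm = _smooth_closed(rs, smoothing_window)
    n = len(sm)

    hull = ConvexHull(sm)
    hull_ring = LinearRing(sm[hull.vertices])
    threshold = depth_fraction * hull_ring.length

    # signed turn angle at each vertex over a baseline of ~0.03 mm of arc
    # (scale-aware so detection is resolution-independent); the sign of the
    # total turning tells which sign means convex for this traversal
    k = max(2, int(round(0.03 / trace.scale))) if trace.scale > 0 else 3
    v1 = sm - np.roll(sm, k, axis=0)
    v2 = np.roll(sm, -k, axis=0) - sm
    cross = v1[:, 0] * v2[:, 1] - v1[:, 1] * v2[:, 0]
    dot = (v1 * v2).sum(axis=1)
    turn = np.arctan2(cross, dot)
    turn = uniform_filter1d(turn, size=smoothing_window, mode="wrap")
    concave_turn = -np.sign(turn.sum()) * turn  # > 0 (radians) where concave

    # a fold tip turns sharply; pocket walls are straight (|turn| ~ 0)
    strong = concave_turn > 0.2
    depth = np.zeros(n)
    for i in np.nonzero(strong)[0]:
        depth[i] = hull_ring.distance(Point(sm[i]))
    deep = strong & (depth > threshold)

    # candidate tips: deepest vertex of each contiguous run, after closing
    # sub-window gaps between runs; each tip is then re-localized on the
    # unsmoothed curve (smoothing drags asymmetric pocket tips sideways)
    raw_hull = LinearRing(rs[ConvexHull(rs).vertices])
    pockets = []  # (resampled tip idx, depth)
    if deep.any():
        from scipy.ndimage import binary_closing

        deep = binary_closing(deep, structure=np.ones(smoothing_window))
        deep &= depth > 0  # closing must not resurrect wall vertices
        lab = np.cumsum(np.diff(np.r_[False, deep].astype(int)) == 1) * deep
        for run in range(1, lab.max() + 1):
            idx = np.nonzero(lab == run)[0]
            tip = int(idx[np.argmax(depth[idx])])
            nbh = np.arange(tip - smoothing_window, tip + smoothing_window + 1) % n
            raw_depth = np.array([raw_hull.distance(Point(rs[j])) for j in nbh])
            # fold tips are locally flat: take the centre of the near-maximal
            # plateau rather than the argmax, which dithers with pixel noise
            plateau = np.nonzero(raw_depth >= raw_depth.max() - 0.75)[0]
            j = int(plateau[len(plateau) // 2])
            pockets.append((int(nbh[j]), float(raw_depth[j])))

    def is_buccal(i_rs: int) -> bool:
        from shapely.ops import nearest_points

        tip = Point(sm[i_rs])
        nearest = nearest_points(hull_ring, tip)[0]
        # buccal folds open toward the bottom of the screen (larger y)
        return nearest.y > tip.y

    buccal = [(i, d) for i, d in pockets if is_buccal(i)]
    lingual = [(i, d) for i, d in pockets if not is_buccal(i)]
    # number 1, 2, ... from the posterior (max-x) end
    buccal.sort(key=lambda pk: -sm[pk[0], 0])
    lingual.sort(key=lambda pk: -sm[pk[0], 0])

    def to_orig(i_rs: int) -> int:
        return int(orig[i_rs])

    bi = [to_orig(i) for i, _ in buccal]
    li = [to_orig(i) for i, _ in lingual]

    def salients_between(side_rs: list[int], lower: bool) -> list[int]:
        out = []
        for i, j in zip(side_rs[:-1], side_rs[1:]):
            lo, hi = sorted((i, j))
            between = np.arange(lo + 1, hi)
            if len(between) == 0:
                continue
            ys = sm[between, 1]
            k = int(np.argmax(ys) if lower else np.argmin(ys))
            out.append(to_orig(int(between[k])))
        return out

    b_sal = salients_between([pk[0] for pk in buccal], lower=True)
    l_sal = salients_between([pk[0] for pk in lingual], lower=False)

    apex = int(np.argmin(pts[:, 0]))
    ab = bi[2] if len(bi) >= 3 else None
    al = li[3] if len(li) >= 4 else None
    ann = FeatureAnnotation(
        apex=apex,
        buccal_reentrants=bi,
        lingual_reentrants=li,
        buccal_salients=b_sal,
        lingual_salients=l_sal,
        a_endpoint_buccal=ab,
        a_endpoint_lingual=al,
    )
    if ab is None or al is None:
        raise InsufficientReentrantsError(
            f"insufficient re-entrants; cannot anchor segment a "
            f"(found {len(bi)} buccal, {len(li)} lingual; need >=3 and >=4)"
        )
    return ann


# ---------------------------------------------------------------------------
# semiperimeter and landmarks
# ---------------------------------------------------------------------------

def anterior_semiperimeter(trace: OutlineTrace, ann: FeatureAnnotation) -> np.ndarray:
    """The open sub-chain from the buccal 'a' endpoint, through the apex,
    to the lingual 'a' endpoint (pixel coordinates).

    The returned polyline is canonicalized to start at the buccal endpoint.
    A warning is emitted if the semiperimeter is under 20% or over 80% of
    the full perimeter (a suspicious split).
    """
    if ann.a_endpoint_buccal is None or ann.a_endpoint_lingual is None:
        raise InsufficientReentrantsError("annotation lacks 'a' endpoints")
    pts = trace.points
    n = len(pts)
    i, j = ann.a_endpoint_buccal, ann.a_endpoint_lingual

    def arc(start: int, stop: int) -> np.ndarray:
        if start <= stop:
            return np.arange(start, stop + 1)
        return np.concatenate([np.arange(start, n), np.arange(0, stop + 1)])

    fwd = arc(i, j)
    bwd = arc(j, i)
    if ann.apex in fwd and ann.apex not in bwd:
        sel = fwd
    elif ann.apex in bwd and ann.apex not in fwd:
        sel = bwd[::-1]  # traverse buccal-first
    elif ann.apex in fwd:
        sel = fwd if len(fwd) <= len(bwd) else bwd[::-1]
    else:
        raise ValidationError("internal consistency error: apex not on either branch")

    poly = pts[sel]
    frac = np.linalg.norm(np.diff(poly, axis=0), axis=1).sum() / max(
        trace.perimeter_px, 1e-9
    )
    if not (0.2 <= frac <= 0.8):
        warnings.warn(
            f"suspicious split: semiperimeter is {100 * frac:.1f}% of the perimeter",
            stacklevel=2,
        )
    return poly.copy()


def resample_landmarks(
    poly: np.ndarray,
    n: int = 200,
    scale: float = 1.0,
    specimen_id: str = "",
    species: str = "",
    source_kind: str = "photo",
) -> LandmarkSet:
    """Uniformly decimate an open pixel polyline to n mm landmarks.

    Points are placed at equal arc-length spacing with both endpoints
    preserved exactly; pixel coordinates are converted to a y-up mm frame.
    """
    poly = np.asarray(poly, dtype=float)
    if n < 2:
        raise ValidationError("need at least 2 landmarks")
    if len(poly) < n:
        raise SemiperimeterTooShortError(
            f"semiperimeter too short: {len(poly)} points for {n} landmarks"
        )
    seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    t = np.linspace(0.0, s[-1], n)
    x = np.interp(t, s, poly[:, 0])
    y = np.interp(t, s, poly[:, 1])
    x[0], y[0] = poly[0]
    x[-1], y[-1] = poly[-1]
    coords = np.column_stack([x * scale, -y * scale])
    return LandmarkSet(
        coords=coords,
        specimen_id=specimen_id,
        species=species,
        source_kind=source_kind,
    )


def process_image(
    img: OcclusalImage,
    n_landmarks: int = 200,
    specimen_id: str = "",
    species: str = "",
) -> tuple[OutlineTrace, FeatureAnnotation, LandmarkSet]:
    """Full chain: outline -> features -> semiperimeter -> landmarks."""
    trace = extract_outline(img)
    ann = detect_feature_points(trace)
    semi = anterior_semiperimeter(trace, ann)
    lm = resample_landmarks(
        semi,
        n=n_landmarks,
        scale=trace.scale,
        specimen_id=specimen_id,
        species=species,
        source_kind=img.source_kind,
    )
    return trace, ann, lm
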