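"""Curved embryo contour and margin-distance assignment.

The distance of each nucleus from the margin is measured along a curved
contour built from the segmented nuclei themselves: centroids from the
selected z-slices are projected onto one plane; the convex hull of the
cloud defines the embryo outline and its two highest-curvature vertices
the left and right margins; a minimal-cost path hugging the ridge of a
distance transform traces the tissue between the margins; Savitzky-Golay
smoothing yields the final contour; and every nucleus is projected onto
it, its margin distance being the arc distance to the closer endpoint.

Two masks play a role.  The *embryo mask* is the filled convex hull of the
cloud (the full-embryo outline).  The *tissue band mask* is a morphological
dilation of the centroid raster: because the blastoderm is a thin curved
shell, the hull's interior medial path would cut through the (nucleus-free)
yolk region and systematically shorten margin distances, so the traced
valley is constrained to the band actually occupied by nuclei.  Both masks
feed the same ridge-path construction.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from scipy.signal import savgol_filter
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import ConvexHull, QhullError
from skimage.draw import polygon2mask

from .core import DegenerateHullError, DisconnectedMaskError, NucleusRecord

_NEIGHBORS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass
class CentroidCloud:
    """Projected 2D centroids (x, y in µm) with their originating z indices."""

    points: np.ndarray
    z_indices: np.ndarray

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        self.z_indices = np.asarray(self.z_indices, dtype=int).reshape(-1)


@dataclass
class EmbryoMask:
    """Binary raster with calibration; ``origin_um`` maps pixel (0, 0) to µm coordinates."""

    mask: np.ndarray
    pixel_size_um: float
    origin_um: tuple

    def to_px(self, xy_um) -> np.ndarray:
        xy = np.asarray(xy_um, dtype=float)
        return (xy - np.asarray(self.origin_um)) / self.pixel_size_um


@dataclass
class MarginEndpoints:
    """Left/right margin positions (µm) with their hull curvatures (rad/µm)."""

    left_um: np.ndarray
    right_um: np.ndarray
    left_curvature: float
    right_curvature: float


@dataclass
class Contour:
    """Arc-length parameterized polyline from left margin to right margin (µm)."""

    points_um: np.ndarray          # (n, 2) as (x, y)
    arc_length_um: np.ndarray      # cumulative s, 0 .. L

    @property
    def total_length_um(self) -> float:
        return float(self.arc_length_um[-1])


def select_central_slices(records: Sequence[NucleusRecord], n_slices: int = 10,
                          center: Optional[int] = None) -> list[int]:
    """Z indices of the ``n_slices`` slices around the center of the embryo axis.

    The center slice k defaults to the slice with the most segmented nuclei
    (ties broken toward the lower index) and can be pinned explicitly via
    ``center``.  The window is k - ceil(n/2) .. k + ceil(n/2) - 1,
    intersected with the available slices.  If fewer than ``n_slices``
    slices carry records, a warning is issued and all available slices are
    returned.
    """
    if not records:
        raise ValueError("no records to select slices from")
    zs = np.array([r.z_index for r in records])
    available = np.unique(zs)
    if len(available) < n_slices:
        warnings.warn(
            f"only {len(available)} slices available (< {n_slices}); using all",
            stacklevel=2)
        return [int(z) for z in available]
    if center is None:
        counts = np.bincount(zs)
        center = int(np.argmax(counts))  # argmax returns the lowest index on ties
    half = int(np.ceil(n_slices / 2))
    window = set(range(center - half, center + half))
    return [int(z) for z in available if z in window]


def project_centroids(records: Sequence[NucleusRecord],
                      z_indices: Sequence[int]) -> CentroidCloud:
    """Drop z: collect (x, y) of every record in the selected slices."""
    zset = set(int(z) for z in z_indices)
    if not zset:
        raise ValueError("empty slice selection")
    sel = [r for r in records if r.z_index in zset]
    if not sel:
        raise ValueError("no records fall in the selected slices")
    pts = np.array([[r.centroid_x_um, r.centroid_y_um] for r in sel])
    return CentroidCloud(points=pts, z_indices=np.array([r.z_index for r in sel]))


def _hull(points: np.ndarray) -> ConvexHull:
    if len(points) < 3:
        raise DegenerateHullError(f"need >= 3 points, got {len(points)}")
    try:
        return ConvexHull(points)
    except QhullError as exc:
        raise DegenerateHullError(
            f"degenerate (collinear?) centroid cloud: {exc}") from exc


def build_mask(cloud: CentroidCloud, pixel_size_um: float = 1.0,
               pad_px: int = 10) -> EmbryoMask:
    """Filled convex hull of the cloud, rasterized with a background pad.

    Every input point maps to a foreground pixel (hull vertices sit on the
    polygon boundary, so their pixels are set explicitly after the fill).
    """
    hull = _hull(cloud.points)
    pts = cloud.points
    x0 = pts[:, 0].min() - pad_px * pixel_size_um
    y0 = pts[:, 1].min() - pad_px * pixel_size_um
    width = int(np.ceil((pts[:, 0].max() - pts[:, 0].min()) / pixel_size_um)) + 2 * pad_px + 1
    height = int(np.ceil((pts[:, 1].max() - pts[:, 1].min()) / pixel_size_um)) + 2 * pad_px + 1
    verts_px = (pts[hull.vertices] - [x0, y0]) / pixel_size_um
    mask = polygon2mask((height, width), verts_px[:, ::-1])  # polygon2mask wants (row, col)
    pts_px = np.round((pts - [x0, y0]) / pixel_size_um).astype(int)
    mask[pts_px[:, 1], pts_px[:, 0]] = True
    return EmbryoMask(mask=mask, pixel_size_um=pixel_size_um, origin_um=(x0, y0))


def build_band_mask(cloud: CentroidCloud, pixel_size_um: float = 1.0,
                    radius_um: Optional[float] = None,
                    endpoints: Optional[MarginEndpoints] = None,
                    pad_px: Optional[int] = None,
                    _ladder=(30.0, 40.0, 50.0, 60.0, 80.0, 100.0)) -> EmbryoMask:
    """Tissue band: the centroid raster dilated by a disk.

    With ``radius_um=None`` the radius is auto-selected as the smallest
    ladder value for which the two margin endpoints land in one connected
    foreground component (sparser clouds need wider bridging).  The band is
    the region the traced valley is allowed to use, so it must both bridge
    inter-nucleus gaps and stay close to the tissue shell.
    """
    pts = cloud.points
    ladder = _ladder if radius_um is None else (float(radius_um),)

    last = None
    for rad in ladder:
        r_px = max(1, int(round(rad / pixel_size_um)))
        pad = pad_px if pad_px is not None else r_px + 2
        x0 = pts[:, 0].min() - pad * pixel_size_um
        y0 = pts[:, 1].min() - pad * pixel_size_um
        width = int(np.ceil((pts[:, 0].max() - pts[:, 0].min()) / pixel_size_um)) + 2 * pad + 1
        height = int(np.ceil((pts[:, 1].max() - pts[:, 1].min()) / pixel_size_um)) + 2 * pad + 1
        raster = np.zeros((height, width), dtype=bool)
        pts_px = np.round((pts - [x0, y0]) / pixel_size_um).astype(int)
        raster[pts_px[:, 1], pts_px[:, 0]] = True
        dy, dx = np.mgrid[-r_px:r_px + 1, -r_px:r_px + 1]
        disk = dy ** 2 + dx ** 2 <= r_px ** 2
        band = ndimage.binary_dilation(raster, structure=disk)
        last = EmbryoMask(mask=band, pixel_size_um=pixel_size_um, origin_um=(x0, y0))
        if endpoints is None:
            return last
        lbl, _ = ndimage.label(band, structure=np.ones((3, 3), dtype=int))
        e1 = np.round(last.to_px(endpoints.left_um)).astype(int)
        e2 = np.round(last.to_px(endpoints.right_um)).astype(int)
        try:
            l1 = lbl[e1[1], e1[0]]
            l2 = lbl[e2[1], e2[0]]
        except IndexError:
            continue
        if l1 > 0 and l1 == l2:
            return last
    if radius_um is not None:
        return last
    raise DisconnectedMaskError(
        "margin endpoints remain disconnected in the tissue band at all "
        f"dilation radii {list(ladder)} µm")


def _hull_turning(points: np.ndarray, hull: ConvexHull):
    """Per-vertex exterior turning angles, edge lengths and perimeter positions (CCW)."""
    V = points[hull.vertices]
    e_out = np.roll(V, -1, axis=0) - V
    elen = np.hypot(e_out[:, 0], e_out[:, 1])
    ang = np.arctan2(e_out[:, 1], e_out[:, 0])
    turn = np.diff(np.concatenate([[ang[-1]], ang]))
    turn = (turn + np.pi) % (2 * np.pi) - np.pi  # exterior angle in (-pi, pi]
    s = np.concatenate([[0.0], np.cumsum(elen)])[:-1]
    return V, np.abs(turn), elen, s, float(elen.sum())


def find_margin_endpoints(cloud: CentroidCloud, min_sep_fraction: float = 0.2,
                          curvature_window_um: float = 0.0,
                          refine_dominant_edge: bool = True) -> MarginEndpoints:
    """Two highest-curvature hull vertices, the left and right margins.

    With ``curvature_window_um = 0`` the discrete curvature at a vertex is
    its exterior turning angle divided by the mean length of its two
    adjacent edges.  A positive window instead accumulates the net turning
    of all hull vertices within half a window along the perimeter on each
    side and divides by the window length; on unevenly sampled hulls this
    suppresses short-edge jitter (alternating turns cancel) while a true
    corner keeps its full turn, making margin detection robust to sparse
    clouds.

    The pair must be separated along the hull perimeter by at least
    ``min_sep_fraction`` of its length.  Ties are broken by maximizing the
    Euclidean separation, then by lexicographic (x, y) order; left/right is
    assigned by x-coordinate.

    When the hull has a single dominant edge — the straight margin-to-margin
    closure that any crescent-shaped tissue cloud produces across the
    nucleus-free interior — the two endpoints of that edge *are* the margin
    corners, and they are used directly (``refine_dominant_edge``).  On
    sparse corner clusters pure curvature ranking can otherwise settle one
    or two vertices short of the true extreme.  The refinement only fires
    when the longest edge spans at least ``min_sep_fraction`` of the
    perimeter and is 1.5 times the runner-up, so compact clouds (squares,
    dense outlines) fall through to the curvature rule.
    """
    hull = _hull(cloud.points)
    V, turn, elen, s, perim = _hull_turning(cloud.points, hull)
    k = len(V)
    if curvature_window_um > 0:
        w = curvature_window_um
        kappa = np.empty(k)
        for i in range(k):
            acc = turn[i]
            for j in range(1, k):
                if (s[(i + j) % k] - s[i]) % perim <= w / 2:
                    acc += turn[(i + j) % k]
                else:
                    break
            for j in range(1, k):
                if (s[i] - s[(i - j) % k]) % perim <= w / 2:
                    acc += turn[(i - j) % k]
                else:
                    break
            kappa[i] = acc / w
    else:
        mean_edge = 0.5 * (elen + np.roll(elen, 1))
        with np.errstate(divide="ignore"):
            kappa = np.where(mean_edge > 0, turn / mean_edge, 0.0)

    if refine_dominant_edge and k >= 3:
        by_len = np.sort(elen)
        j = int(np.argmax(elen))
        if (elen[j] >= min_sep_fraction * perim
                and (len(by_len) < 2 or elen[j] >= 1.5 * by_len[-2])):
            a, b = V[j], V[(j + 1) % k]
            (left, kl), (right, kr) = sorted(
                [(a, kappa[j]), (b, kappa[(j + 1) % k])],
                key=lambda t: (t[0][0], t[0][1]))
            return MarginEndpoints(left_um=np.asarray(left, dtype=float),
                                   right_um=np.asarray(right, dtype=float),
                                   left_curvature=float(kl),
                                   right_curvature=float(kr))

    # deterministic ordering: curvature desc, then lexicographic (x, y)
    order = np.lexsort((V[:, 1], V[:, 0], -kappa))
    first = order[0]
    best = None
    for cand in order[1:]:
        sep = abs(s[cand] - s[first]) % perim
        sep = min(sep, perim - sep)
        if sep < min_sep_fraction * perim:
            continue
        key = (kappa[cand], np.hypot(*(V[cand] - V[first])),
               -V[cand, 0], -V[cand, 1])
        if best is None or key > best[0]:
            best = (key, cand)
    if best is None:
        raise DegenerateHullError(
            "no admissible margin pair: all high-curvature vertices are "
            f"closer than {min_sep_fraction:.0%} of the hull perimeter "
            "(endpoints may be supplied explicitly via configuration)")
    second = best[1]
    a, b = V[first], V[second]
    (left, kl), (right, kr) = sorted(
        [(a, kappa[first]), (b, kappa[second])], key=lambda t: (t[0][0], t[0][1]))
    return MarginEndpoints(left_um=np.asarray(left, dtype=float),
                           right_um=np.asarray(right, dtype=float),
                           left_curvature=float(kl), right_curvature=float(kr))


def valley_cost_graph(mask: np.ndarray):
    """Sparse 8-connected graph whose shortest paths hug the distance-transform ridge.

    Per-step cost is ``step_length * (D_max - mean(D_u, D_v) + eps)`` with
    ``D`` the Euclidean distance transform of the mask (distance to
    background), ``D_max`` its maximum and ``eps = 1e-6 * D_max``: the
    minimal-cost path between two points runs along the ridge of D — the
    valley of its negation.  Returns ``(graph, index_map, ys, xs, D)``
    where ``index_map`` maps pixel (row, col) to node id (-1 outside).
    """
    mask = np.asarray(mask, dtype=bool)
    D = ndimage.distance_transform_edt(mask)
    Dmax = float(D.max())
    eps = 1e-6 * Dmax if Dmax > 0 else 1e-12
    H, W = mask.shape
    idx = -np.ones(mask.shape, dtype=np.int64)
    ys, xs = np.nonzero(mask)
    idx[ys, xs] = np.arange(len(ys))
    n = len(ys)
    rows, cols, data = [], [], []
    for dy, dx in _NEIGHBORS:
        ny, nx = ys + dy, xs + dx
        ok = (ny >= 0) & (ny < H) & (nx >= 0) & (nx < W)
        ok[ok] &= mask[ny[ok], nx[ok]]
        step = float(np.hypot(dy, dx))
        u = idx[ys[ok], xs[ok]]
        v = idx[ny[ok], nx[ok]]
        w = step * (Dmax - 0.5 * (D[ys[ok], xs[ok]] + D[ny[ok], nx[ok]]) + eps)
        rows.append(u)
        cols.append(v)
        data.append(w)
    graph = coo_matrix((np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
                       shape=(n, n)).tocsr()
    return graph, idx, ys, xs, D


def path_cost(path_px: np.ndarray, D: np.ndarray) -> float:
    """Total ridge cost of a pixel path under the :func:`valley_cost_graph` convention."""
    Dmax = float(D.max())
    eps = 1e-6 * Dmax if Dmax > 0 else 1e-12
    p = np.asarray(path_px, dtype=int)
    dvals = D[p[:, 0], p[:, 1]]
    steps = np.hypot(*np.diff(p.astype(float), axis=0).T)
    return float(np.sum(steps * (Dmax - 0.5 * (dvals[:-1] + dvals[1:]) + eps)))


def _snap_to_foreground(idx: np.ndarray, ys, xs, pt_px, snap_px: int = 3) -> int:
    col, row = int(round(pt_px[0])), int(round(pt_px[1]))
    H, W = idx.shape
    if 0 <= row < H and 0 <= col < W and idx[row, col] >= 0:
        return int(idx[row, col])
    d2 = (ys - row) ** 2 + (xs - col) ** 2
    j = int(np.argmin(d2))
    if d2[j] > snap_px ** 2:
        raise ValueError(
            f"endpoint ({pt_px[0]:.1f}, {pt_px[1]:.1f}) px is more than "
            f"{snap_px} px from mask foreground")
    return j


def trace_valley(mask: EmbryoMask, endpoints: MarginEndpoints,
                 snap_px: int = 3) -> np.ndarray:
    """Minimal-cost ridge path between the margin endpoints, as (row, col) pixels.

    Endpoints are snapped to the nearest foreground pixel within
    ``snap_px``; disconnected endpoints raise
    :class:`~smadgrad.core.DisconnectedMaskError`.  Deterministic.
    """
    graph, idx, ys, xs, _D = valley_cost_graph(mask.mask)
    src = _snap_to_foreground(idx, ys, xs, mask.to_px(endpoints.left_um), snap_px)
    dst = _snap_to_foreground(idx, ys, xs, mask.to_px(endpoints.right_um), snap_px)
    dist, pred = dijkstra(graph, indices=src, return_predecessors=True)
    if not np.isfinite(dist[dst]):
        raise DisconnectedMaskError(
            "margin endpoints lie in disconnected foreground components")
    nodes = [dst]
    while nodes[-1] != src:
        nodes.append(int(pred[nodes[-1]]))
    nodes.reverse()
    nodes = np.asarray(nodes)
    return np.stack([ys[nodes], xs[nodes]], axis=1)


def smooth_contour(rough_path_px: np.ndarray, mask: EmbryoMask,
                   window_pts: Optional[int] = None, polyorder: int = 3) -> Contour:
    """Savitzky-Golay smoothing of the rough path into the final contour.

    The pixel path is resampled to uniform arc-length spacing (one pixel
    step), x(s) and y(s) are each filtered (default window: 51 points or a
    fifth of the path length rounded odd, whichever is smaller), endpoints
    are re-pinned to the pre-smoothing endpoints, and the cumulative arc
    length is recomputed in µm.  Too-short paths are passed through with a
    warning.
    """
    p = np.asarray(rough_path_px, dtype=float)
    if p.ndim != 2 or p.shape[1] != 2:
        raise ValueError("rough path must be (n, 2) pixel coordinates")
    px_sz = mask.pixel_size_um
    xy = np.stack([p[:, 1], p[:, 0]], axis=1) * px_sz + np.asarray(mask.origin_um)
    seg = np.hypot(*np.diff(xy, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] == 0:
        return Contour(points_um=xy[:1], arc_length_um=np.array([0.0]))
    su = np.arange(0.0, s[-1] + 0.5 * px_sz, px_sz)
    xu = np.interp(su, s, xy[:, 0])
    yu = np.interp(su, s, xy[:, 1])
    if window_pts is None:
        window_pts = min(51, (len(su) // 5) | 1)
    if window_pts % 2 == 0 or window_pts <= polyorder:
        window_pts = max(polyorder + 1, window_pts) | 1
    if len(su) < window_pts or window_pts <= polyorder:
        warnings.warn("path too short for Savitzky-Golay smoothing; returning raw path",
                      stacklevel=2)
        xs_, ys_ = xu, yu
    else:
        xs_ = savgol_filter(xu, window_pts, polyorder)
        ys_ = savgol_filter(yu, window_pts, polyorder)
        xs_[0], ys_[0] = xu[0], yu[0]
        xs_[-1], ys_[-1] = xu[-1], yu[-1]
    pts = np.stack([xs_, ys_], axis=1)
    seg = np.hypot(*np.diff(pts, axis=0).T)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    return Contour(points_um=pts, arc_length_um=arc)


def assign_distances(records: Sequence[NucleusRecord], contour: Contour) -> list[NucleusRecord]:
    """Project each record onto the contour; distance = arc length to the closer margin.

    The nearest point on the polyline is found by segment-wise orthogonal
    projection (ties resolved toward smaller arc position s*); the margin
    distance is ``min(s*, L - s*)``, so it always lies in [0, L/2].
    Returns new record objects; the inputs are not mutated.
    """
    P = contour.points_um
    s = contour.arc_length_um
    L = contour.total_length_um
    A = P[:-1]
    B = P[1:]
    AB = B - A
    ab2 = np.sum(AB ** 2, axis=1)
    ab2[ab2 == 0] = 1.0
    seglen = np.sqrt(np.sum((B - A) ** 2, axis=1))
    out = []
    for r in records:
        q = np.array([r.centroid_x_um, r.centroid_y_um])
        if len(P) == 1:
            sstar = 0.0
        else:
            t = np.clip(np.sum((q - A) * AB, axis=1) / ab2, 0.0, 1.0)
            proj = A + t[:, None] * AB
            d2 = np.sum((proj - q) ** 2, axis=1)
            k = int(np.argmin(d2))  # first minimum -> smaller s on ties
            sstar = s[k] + t[k] * seglen[k]
        dist = min(sstar, L - sstar)
        out.append(NucleusRecord(**{**r.__dict__, "margin_distance_um": float(dist)}))
    return out


@dataclass
class ContourResult:
    """Everything the contour stage produced, for downstream use and inspection."""

    contour: Contour
    endpoints: MarginEndpoints
    hull_mask: EmbryoMask
    band_mask: EmbryoMask
    cloud: CentroidCloud
    rough_path_px: np.ndarray


def contour_from_records(records: Sequence[NucleusRecord],
                         pixel_size_um: float = 1.0,
                         z_indices: Optional[Sequence[int]] = None,
                         min_sep_fraction: float = 0.2,
                         curvature_window_um: float = 40.0,
                         band_radius_um: Optional[float] = None,
                         sg_window_pts: Optional[int] = None,
                         sg_polyorder: int = 3) -> ContourResult:
    """Full contour stage: project -> hull & margins -> band -> valley -> smooth."""
    if z_indices is None:
        z_indices = sorted({r.z_index for r in records})
    cloud = project_centroids(records, z_indices)
    endpoints = find_margin_endpoints(cloud, min_sep_fraction=min_sep_fraction,
                                      curvature_window_um=curvature_window_um)
    hull_mask = build_mask(cloud, pixel_size_um=pixel_size_um)
    band_mask = build_band_mask(cloud, pixel_size_um=pixel_size_um,
                                radius_um=band_radius_um, endpoints=endpoints)
    rough = trace_valley(band_mask, endpoints)
    contour = smooth_contour(rough, band_mask, window_pts=sg_window_pts,
                             polyorder=sg_polyorder)
    return ContourResult(contour=contour, endpoints=endpoints, hull_mask=hull_mask,
                         band_mask=band_mask, cloud=cloud, rough_path_px=rough)
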