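"""Bifurcating vascular centerlines: containers, extraction and decomposition.

The anatomy handled here is the fetal great-vessel "double arch": the
ascending aorta + transverse arch (AAo segment), the arterial duct (AD)
and the descending aorta (DAo) meet at a single bifurcation origin where
the duct inserts into the aorta.  Centerlines are extracted from a
landmarked surface mesh in two passes (DAo -> duct, then DAo -> AAo on a
duct-clipped mesh), merged at an objectively defined bifurcation origin
and resampled to a fixed per-segment point count so that every case has
point-to-point correspondence.

Ordering convention (assumed by every downstream module):

* ``aao``: AAo free end -> bifurcation origin (25 points by default)
* ``ad``:  AD free end  -> bifurcation origin (25 points)
* ``dao``: bifurcation origin -> diaphragm     (51 points)

All coordinates are physical millimetres.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import cKDTree

from .errors import (
    DecompositionError,
    LandmarkError,
    ParameterError,
    SegmentError,
    TopologyError,
)

DEFAULT_COUNTS = (25, 25, 51)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class Centerline:
    """An ordered 3D polyline with a per-point maximal inscribed radius."""

    points: np.ndarray  # (n, 3) mm
    radius: np.ndarray  # (n,) mm

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        self.radius = np.asarray(self.radius, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ParameterError("points must be an (n, 3) array")
        if self.radius.shape != (self.points.shape[0],):
            raise ParameterError("radius must be an (n,) array matching points")

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    def validate(self) -> None:
        if self.n_points < 2:
            raise ParameterError("centerline needs at least 2 points")
        if not np.all(np.isfinite(self.points)) or not np.all(np.isfinite(self.radius)):
            raise ParameterError("centerline contains non-finite values")
        if np.any(self.radius <= 0):
            raise ParameterError("radius must be positive everywhere")
        steps = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if np.any(steps == 0):
            raise ParameterError("consecutive centerline points must be distinct")

    def arc_lengths(self) -> np.ndarray:
        """Cumulative arc length from the first point (starts at 0)."""
        steps = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(steps)])

    @property
    def length(self) -> float:
        return float(self.arc_lengths()[-1])

    def copy(self) -> "Centerline":
        return Centerline(self.points.copy(), self.radius.copy())


@dataclass
class ArchCenterline:
    """Three labeled segments sharing one bifurcation origin.

    Segment point counts after resampling default to 25 (AAo), 25 (AD)
    and 51 (DAo) for a total of N = 101 correspondence points.
    """

    aao: Centerline
    ad: Centerline
    dao: Centerline
    bifurcation_origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.bifurcation_origin = np.asarray(self.bifurcation_origin, dtype=float)

    @property
    def counts(self) -> tuple[int, int, int]:
        return (self.aao.n_points, self.ad.n_points, self.dao.n_points)

    @property
    def n_points(self) -> int:
        return sum(self.counts)

    def segments(self) -> dict[str, Centerline]:
        return {"aao": self.aao, "ad": self.ad, "dao": self.dao}

    def validate(self, counts: tuple[int, int, int] | None = None,
                 spacing_rtol: float | None = None) -> None:
        """Check counts, origin coincidence and (optionally) spacing.

        Resampling places points uniformly in source arc length by
        construction.  ``spacing_rtol`` additionally checks the chords of
        the resampled polyline, which on a curved or jittered source
        deviate at O(h^2 * curvature) + O(noise); leave it None unless
        the segment is noise-free.
        """
        for seg in self.segments().values():
            seg.validate()
        if counts is not None and self.counts != tuple(counts):
            raise SegmentError(
                f"expected per-segment counts {tuple(counts)}, got {self.counts}")
        ends = [self.aao.points[-1], self.ad.points[-1], self.dao.points[0]]
        for seg, end in zip(("aao", "ad", "dao"), ends):
            spacing = self.segments()[seg].length / (self.segments()[seg].n_points - 1)
            if np.linalg.norm(end - self.bifurcation_origin) > spacing:
                raise SegmentError(
                    f"{seg} does not meet the bifurcation origin within one "
                    "sample spacing")
        if spacing_rtol is not None:
            for name, seg in self.segments().items():
                steps = np.linalg.norm(np.diff(seg.points, axis=0), axis=1)
                mean = steps.mean()
                if mean > 0 and np.max(np.abs(steps - mean)) / mean > spacing_rtol:
                    raise SegmentError(f"{name} spacing is not uniform")

    def copy(self) -> "ArchCenterline":
        return ArchCenterline(self.aao.copy(), self.ad.copy(), self.dao.copy(),
                              self.bifurcation_origin.copy())


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------


def resample_centerline(line: Centerline, n: int) -> Centerline:
    """Resample to ``n`` points evenly spaced in arc length (linear interp)."""
    if n < 2:
        raise SegmentError("cannot resample to fewer than 2 points")
    if line.n_points < 2:
        raise SegmentError("cannot resample a segment shorter than 2 samples")
    s = line.arc_lengths()
    if s[-1] <= 0:
        raise SegmentError("segment has zero length")
    target = np.linspace(0.0, s[-1], n)
    pts = np.column_stack([np.interp(target, s, line.points[:, i]) for i in range(3)])
    rad = np.interp(target, s, line.radius)
    return Centerline(pts, rad)


def _resample_array(points: np.ndarray, radius: np.ndarray, n: int):
    line = resample_centerline(Centerline(points, radius), n)
    return line.points, line.radius


# ---------------------------------------------------------------------------
# mesh-based extraction (medial-approximation shortest path)
# ---------------------------------------------------------------------------


def _mesh_components(mesh):
    """Split a (possibly multi-body) mesh into wall components and obstacles.

    A component is an *obstacle* (forbidden region marker, e.g. the
    inverted sphere inserted by :func:`clip_ad`) when it is closed and
    its signed volume is negative, i.e. its normals point inward.
    """
    try:
        comps = mesh.split(only_watertight=False)
    except Exception:  # single body or split unsupported
        comps = []
    if len(comps) == 0:
        comps = [mesh]
    walls, obstacles = [], []
    for c in comps:
        if c.is_watertight and c.volume < 0:
            obstacles.append(c)
        else:
            walls.append(c)
    return walls, obstacles


class _SoupField:
    """Approximate inside/outside and clearance queries on a triangle soup.

    Face centroids carry face normals; the sign of the projection of
    (query - nearest centroid) on that normal classifies a point against
    each closed component.  The sign test is only meaningful near the
    wall, so a component may claim points no farther than its *reach* —
    0.6x its minimal oriented-bounding-box extent (= 1.2x the caliber of
    a tube), a bound that still covers the whole interior of a tubular
    body.  A point is inside the union when it is inside any wall
    component and inside no obstacle.
    """

    def __init__(self, mesh):
        self.walls, self.obstacles = _mesh_components(mesh)
        self._wall_trees = [self._component_query(c) for c in self.walls]
        self._obs_trees = [self._component_query(c) for c in self.obstacles]

    @staticmethod
    def _component_query(comp):
        centroids = comp.triangles_center
        try:
            reach = 0.6 * float(np.min(comp.bounding_box_oriented.extents))
        except Exception:  # degenerate hull; fall back to the AABB
            reach = 0.6 * float(np.min(comp.extents))
        return cKDTree(centroids), comp.face_normals, reach

    def classify(self, pts: np.ndarray):
        """Return (inside_union, clearance) for an (m, 3) array of points."""
        pts = np.atleast_2d(pts)
        m = pts.shape[0]
        inside = np.zeros(m, dtype=bool)
        clearance = np.full(m, np.inf)
        for tree, normals, reach in self._wall_trees:
            d, idx = tree.query(pts)
            signed = np.einsum("ij,ij->i", normals[idx], pts - tree.data[idx])
            comp_inside = (signed < 0) & (d <= reach)
            inside |= comp_inside
            clearance = np.where(comp_inside, np.minimum(clearance, d), clearance)
        for tree, normals, reach in self._obs_trees:
            d, idx = tree.query(pts)
            # obstacle normals point inward: positive projection = inside it
            signed = np.einsum("ij,ij->i", normals[idx], pts - tree.data[idx])
            forbidden = (signed > 0) & (d <= reach)
            inside &= ~forbidden
        clearance[~inside] = 0.0
        clearance = np.where(np.isfinite(clearance), clearance, 0.0)
        return inside, clearance


class _ClosestSurface:
    """Exact closest-point-on-mesh queries via centroid candidates.

    The nearest triangle is searched among the k nearest face centroids
    (exact point-triangle distance on the candidates); dense tube
    meshes satisfy this locality assumption comfortably.
    """

    def __init__(self, mesh, k: int = 24):
        self.triangles = np.asarray(mesh.triangles)
        self.tree = cKDTree(mesh.triangles_center)
        self.k = int(min(k, len(self.triangles)))

    def query(self, pts: np.ndarray):
        """Return (closest_points, distances) for an (m, 3) array."""
        from trimesh.triangles import closest_point as tri_closest

        pts = np.atleast_2d(pts)
        m = pts.shape[0]
        _, idx = self.tree.query(pts, k=self.k)
        idx = np.atleast_2d(idx)
        rep = np.repeat(pts, self.k, axis=0)
        cand = tri_closest(self.triangles[idx.ravel()], rep)
        dist = np.linalg.norm(cand - rep, axis=1).reshape(m, self.k)
        j = np.argmin(dist, axis=1)
        rows = np.arange(m)
        return cand.reshape(m, self.k, 3)[rows, j], dist[rows, j]


_VOXEL_OFFSETS = np.array(
    [(i, j, k)
     for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
     if (i, j, k) > (0, 0, 0)], dtype=int)  # 13 half-neighborhood offsets


def extract_centerline(mesh, seed_point, target_point, pitch: float = 0.7,
                       refine_iters: int = 3, landmark_tol: float = 2.5,
                       ) -> Centerline:
    """Extract a centerline between two interior landmarks of a mesh.

    The vessel interior is rasterized at ``pitch`` millimetres; a graph
    over interior voxels with edge weights inversely proportional to the
    local clearance (distance to the wall) is searched with Dijkstra, so
    the path maximizes distance to the surface.  The raw voxel path is
    then snapped toward the medial axis (midpoint of the maximal chord
    through each point, perpendicular to the running direction) and the
    per-point maximal inscribed radius is set to the exact distance to
    the surface.

    This is a self-contained medial approximation of Voronoi-based
    centerline extraction; it assumes locally tubular geometry.
    """
    import trimesh  # local import keeps non-mesh workflows light

    if len(mesh.faces) == 0:
        from .errors import EmptyMeshError
        raise EmptyMeshError("mesh has no triangles")
    seed_point = np.asarray(seed_point, dtype=float)
    target_point = np.asarray(target_point, dtype=float)

    field_ = _SoupField(mesh)

    lo, hi = mesh.bounds
    lo = lo - pitch
    hi = hi + pitch
    shape = np.maximum(np.ceil((hi - lo) / pitch).astype(int) + 1, 2)
    axes = [lo[i] + pitch * np.arange(shape[i]) for i in range(3)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)

    inside, clearance = field_.classify(grid)
    if not inside.any():
        raise TopologyError("mesh interior is empty at the chosen pitch")
    vox_pts = grid[inside]
    vox_r = np.maximum(clearance[inside], 0.25 * pitch)

    # map flat voxel ids to interior node ids
    node_id = -np.ones(grid.shape[0], dtype=int)
    node_id[np.flatnonzero(inside)] = np.arange(vox_pts.shape[0])
    inside3 = inside.reshape(shape)
    id3 = node_id.reshape(shape)

    rows, cols, wts = [], [], []
    for off in _VOXEL_OFFSETS:
        sl_a = tuple(slice(max(0, -o), shape[i] - max(0, o)) for i, o in enumerate(off))
        sl_b = tuple(slice(max(0, o), shape[i] + min(0, o)) for i, o in enumerate(off))
        both = inside3[sl_a] & inside3[sl_b]
        a = id3[sl_a][both]
        b = id3[sl_b][both]
        step = pitch * np.linalg.norm(off)
        w = step / (0.5 * (vox_r[a] + vox_r[b]))
        rows.append(a)
        cols.append(b)
        wts.append(w)
    n_vox = vox_pts.shape[0]

    # seed/target nodes appended after the voxels
    tree = cKDTree(vox_pts)

    def _attach(point, name):
        pin, _ = field_.classify(point[None])
        d, idx = tree.query(point, k=min(12, n_vox))
        d = np.atleast_1d(d)
        idx = np.atleast_1d(idx)
        if not pin[0] and d[0] > landmark_tol:
            raise LandmarkError(
                f"{name} landmark at {np.round(point, 2)} lies outside the mesh "
                f"(nearest interior point {d[0]:.1f} mm away)")
        w = d / np.maximum(vox_r[idx], 0.25 * pitch)
        return idx, w

    seed_idx, seed_w = _attach(seed_point, "seed")
    tgt_idx, tgt_w = _attach(target_point, "target")
    s_node, t_node = n_vox, n_vox + 1
    rows.append(np.full(len(seed_idx), s_node))
    cols.append(seed_idx)
    wts.append(seed_w)
    rows.append(np.full(len(tgt_idx), t_node))
    cols.append(tgt_idx)
    wts.append(tgt_w)

    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    wts = np.concatenate(wts)
    n_nodes = n_vox + 2
    graph = coo_matrix((wts, (rows, cols)), shape=(n_nodes, n_nodes)).tocsr()

    dist, pred = dijkstra(graph, directed=False, indices=s_node,
                          return_predecessors=True)
    if not np.isfinite(dist[t_node]):
        raise TopologyError("no interior path connects the two landmarks")
    path_ids = [t_node]
    while path_ids[-1] != s_node:
        path_ids.append(pred[path_ids[-1]])
    path_ids.reverse()
    all_pts = np.vstack([vox_pts, seed_point[None], target_point[None]])
    path = all_pts[path_ids]

    # drop duplicate consecutive points
    keep = np.ones(len(path), dtype=bool)
    keep[1:] = np.linalg.norm(np.diff(path, axis=0), axis=1) > 1e-9
    path = path[keep]

    wall_surfaces = [_ClosestSurface(c) for c in field_.walls]
    path = _medial_refine(field_, wall_surfaces, path, refine_iters)

    # final radii: depth within the deepest containing component, so the
    # other branch's wall crossing the junction does not shrink them
    radius = np.maximum(_union_depth(field_, wall_surfaces, path), 1e-6)
    line = Centerline(path, radius)
    n_out = max(int(round(line.length / (0.75 * pitch))) + 1, 8)
    return resample_centerline(line, n_out)


def _component_depths(field_: _SoupField, surfaces: list, pts: np.ndarray
                      ) -> np.ndarray:
    """(m, n_walls) matrix of exact wall depths; -inf where not inside."""
    pts = np.atleast_2d(pts)
    depths = np.full((pts.shape[0], len(surfaces)), -np.inf)
    for ci, ((tree, normals, reach), surf) in enumerate(
            zip(field_._wall_trees, surfaces)):
        d, idx = tree.query(pts)
        signed = np.einsum("ij,ij->i", normals[idx], pts - tree.data[idx])
        inside = (signed < 0) & (d <= reach)
        if inside.any():
            _, exact = surf.query(pts[inside])
            depths[inside, ci] = exact
    return depths


def _union_depth(field_: _SoupField, surfaces: list, pts: np.ndarray
                 ) -> np.ndarray:
    """Inscribed-radius estimate: depth in the deepest containing wall."""
    depths = _component_depths(field_, surfaces, pts)
    best = depths.max(axis=1)
    missing = ~np.isfinite(best)
    if missing.any():  # endpoint on a cap etc.: plain surface distance
        d = np.full(missing.sum(), np.inf)
        for surf in surfaces:
            _, dc = surf.query(pts[missing])
            d = np.minimum(d, dc)
        best[missing] = d
    return best


def _medial_step(surface: _ClosestSurface, pts: np.ndarray, tang: np.ndarray,
                 n_march: int = 8, n_bisect: int = 7) -> np.ndarray:
    """One medial-snapping step of a point set against one wall component.

    Moving away from the nearest wall along direction ``u``, the
    projection of (probe - its nearest wall point) onto ``u`` flips sign
    exactly when the probe crosses the locally equidistant (medial) set.
    The crossing is bracketed by marching in steps of 0.3x the local
    clearance, then bisected; the move is applied perpendicular to the
    running path direction only.
    """

    def _side(probe, u):
        cp, _ = surface.query(probe)
        return np.einsum("ij,ij->i", probe - cp, u)

    pts = pts.copy()
    cp, d = surface.query(pts)
    u = pts - cp
    norm = np.linalg.norm(u, axis=1)
    ok = norm > 1e-9
    u[ok] /= norm[ok, None]
    step = 0.3 * np.where(ok, d, 0.0)

    lo = np.zeros(len(pts))
    hi = np.zeros(len(pts))
    found = ~ok  # degenerate points stay put
    for j in range(1, n_march + 1):
        active = ~found
        if not active.any():
            break
        s = j * step
        side = np.ones(len(pts))
        side[active] = _side(pts[active] + s[active, None] * u[active],
                             u[active])
        flipped = active & (side < 0)
        hi[flipped] = s[flipped]
        lo[active & ~flipped] = s[active & ~flipped]
        found |= flipped
    move = found & ok
    if move.any():
        a, b = lo.copy(), hi.copy()
        for _ in range(n_bisect):
            mid = 0.5 * (a + b)
            side = _side(pts[move] + mid[move, None] * u[move], u[move])
            upper = np.zeros(len(pts), dtype=bool)
            upper[move] = side > 0
            a[upper] = mid[upper]
            b[move & ~upper] = mid[move & ~upper]
        s_star = 0.5 * (a + b)
        delta = s_star[:, None] * u
        delta -= np.einsum("ij,ij->i", delta, tang)[:, None] * tang
        pts[move] += delta[move]
    return pts


def _medial_refine(field_: _SoupField, surfaces: list, path: np.ndarray,
                   iters: int) -> np.ndarray:
    """Snap path points toward the medial axis of their own branch.

    Each point is refined against the wall component it lies deepest
    inside, so internal walls of the *other* branch crossing the
    bifurcation region do not distort the path.
    """
    path = path.copy()
    for _ in range(iters):
        tang = np.gradient(path, axis=0)
        tang /= np.maximum(np.linalg.norm(tang, axis=1, keepdims=True), 1e-12)
        depths = _component_depths(field_, surfaces, path)
        assign = depths.argmax(axis=1)
        # points inside no component: refine against the nearest wall
        orphan = ~np.isfinite(depths.max(axis=1))
        if orphan.any():
            dmin = np.full((orphan.sum(), len(surfaces)), np.inf)
            for ci, surf in enumerate(surfaces):
                _, dc = surf.query(path[orphan])
                dmin[:, ci] = dc
            assign[orphan] = dmin.argmin(axis=1)
        for ci, surf in enumerate(surfaces):
            sel = assign == ci
            if sel.any():
                path[sel] = _medial_step(surf, path[sel], tang[sel])
    # light smoothing to remove voxel zigzag (keep endpoints)
    for _ in range(2):
        path[1:-1] = 0.25 * path[:-2] + 0.5 * path[1:-1] + 0.25 * path[2:]
    return path


def clip_ad(mesh, ad_medial, clip_radius: float | None = None):
    """Block the mid-duct so the aortic extraction cannot shortcut the AD.

    Faces entirely within ``clip_radius`` of the mid-duct landmark are
    removed and an inward-facing sphere is inserted as an obstacle that
    the extraction treats as forbidden space.  The input mesh is left
    untouched.  ``clip_radius`` defaults to 1.5x the local duct radius.
    """
    import trimesh

    center = np.asarray(ad_medial, dtype=float)
    field_ = _SoupField(mesh)
    inside, clearance = field_.classify(center[None])
    if clip_radius is None:
        if not inside[0]:
            raise LandmarkError("mid-duct landmark lies outside the mesh; "
                                "cannot infer a clip radius")
        clip_radius = 1.5 * max(clearance[0], 1e-6)
    if clip_radius <= 0:
        return mesh.copy()
    if not inside[0]:
        _, d = _ClosestSurface(mesh).query(center[None])
        if d[0] > clip_radius:
            warnings.warn("clip center lies outside the mesh; returning the "
                          "mesh unchanged", stacklevel=2)
            return mesh.copy()

    out = mesh.copy()
    vin = np.linalg.norm(out.vertices - center, axis=1) < clip_radius
    drop = vin[out.faces].all(axis=1)
    if drop.any():
        out.update_faces(~drop)
    ball = trimesh.creation.icosphere(subdivisions=2, radius=clip_radius)
    ball.apply_translation(center)
    ball.invert()  # inward normals: marks the interior as forbidden
    return trimesh.util.concatenate([out, ball])


# ---------------------------------------------------------------------------
# bifurcation decomposition
# ---------------------------------------------------------------------------


def find_bifurcation_origin(line_dao_ad: Centerline, line_dao_aao: Centerline):
    """Merge two centerlines sharing a descending-aortic trunk.

    Both lines must start at the same DAo landmark.  Walking from that
    shared end, a point pair is *co-contained* when each point lies
    inside the other line's maximal inscribed sphere.  The bifurcation
    origin is the midpoint of the last co-contained pair; the returned
    split indices separate the shared trunk from each distal branch.
    """
    a, b = line_dao_ad, line_dao_aao
    a.validate()
    b.validate()
    start_gap = np.linalg.norm(a.points[0] - b.points[0])
    if start_gap > max(a.radius[0], b.radius[0], 1.0):
        raise DecompositionError(
            "centerlines do not start at a shared DAo landmark "
            f"(gap {start_gap:.1f} mm)")
    tree_b = cKDTree(b.points)
    d, j = tree_b.query(a.points)
    contained = d < np.minimum(a.radius, b.radius[j])
    if not contained.any():
        raise DecompositionError(
            "centerlines are never co-contained; check the landmarks")
    i_last = int(np.flatnonzero(contained)[-1])
    if i_last >= a.n_points - 1 and int(j[i_last]) >= b.n_points - 1:
        raise DecompositionError("centerlines never diverge (identical lines?)")
    j_last = int(j[i_last])
    origin = 0.5 * (a.points[i_last] + b.points[j_last])
    return origin, (i_last, j_last)


def decompose_and_resample(line_dao_ad: Centerline, line_dao_aao: Centerline,
                           counts: tuple[int, int, int] = DEFAULT_COUNTS,
                           trunk_blend_points: int = 64) -> ArchCenterline:
    """Split two DAo-anchored centerlines into AAo / AD / DAo segments.

    The shared descending trunk is taken as the pointwise average (by
    arc-length correspondence) of the two extracted trunks; each branch
    beyond the origin becomes the AD (duct line) or AAo (aortic line).
    Every segment is resampled to the requested count, evenly spaced in
    arc length, with the bifurcation origin as its shared endpoint.
    """
    n_aao, n_ad, n_dao = counts
    origin, (i_a, j_b) = find_bifurcation_origin(line_dao_ad, line_dao_aao)

    def _trunk(line, split):
        pts = np.vstack([line.points[:split + 1], origin[None]])
        rad = np.concatenate([line.radius[:split + 1], [line.radius[split]]])
        return pts, rad

    def _branch(line, split):
        pts = np.vstack([line.points[split + 1:][::-1], origin[None]])
        rad = np.concatenate([line.radius[split + 1:][::-1], [line.radius[split]]])
        return pts, rad

    ta_pts, ta_rad = _trunk(line_dao_ad, i_a)
    tb_pts, tb_rad = _trunk(line_dao_aao, j_b)
    if len(ta_pts) < 2 or len(tb_pts) < 2:
        raise SegmentError("shared DAo trunk is shorter than 2 samples")
    m = max(trunk_blend_points, len(ta_pts), len(tb_pts))
    ta_pts, ta_rad = _resample_array(ta_pts, ta_rad, m)
    tb_pts, tb_rad = _resample_array(tb_pts, tb_rad, m)
    trunk_pts = 0.5 * (ta_pts + tb_pts)
    trunk_rad = 0.5 * (ta_rad + tb_rad)
    # orient origin -> diaphragm and pin the origin endpoint exactly
    trunk_pts = trunk_pts[::-1].copy()
    trunk_rad = trunk_rad[::-1].copy()
    trunk_pts[0] = origin

    ad_pts, ad_rad = _branch(line_dao_ad, i_a)
    aao_pts, aao_rad = _branch(line_dao_aao, j_b)
    for name, pts in (("ad", ad_pts), ("aao", aao_pts)):
        if len(pts) < 2:
            raise SegmentError(f"{name} branch is shorter than 2 samples")

    aao_p, aao_r = _resample_array(aao_pts, aao_rad, n_aao)
    ad_p, ad_r = _resample_array(ad_pts, ad_rad, n_ad)
    dao_p, dao_r = _resample_array(trunk_pts, trunk_rad, n_dao)
    arch = ArchCenterline(Centerline(aao_p, aao_r), Centerline(ad_p, ad_r),
                          Centerline(dao_p, dao_r), origin)
    return arch
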