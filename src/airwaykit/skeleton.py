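"""Airway skeleton data model and processing.

A skeleton is a tree of branches; each branch is an ordered centreline
polyline with a tube radius at every sampling point.  All coordinates and
radii are in millimetres, in the (right-handed) frame of the source CT.

The skeleton is the driving structure for convolution-surface modelling:
generation grading, radius measurement from a surface mesh, junction radius
smoothing, centreline spline fitting, radius resampling and distal trimming
all live here.
"""

from __future__ import annotations

import csv
import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.interpolate import splev, splprep

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "skeleton-v1"

#: tolerance (mm) within which a child's first point must touch its parent
ATTACH_TOL = 0.5


class SkeletonError(ValueError):
    """Structural or value error in skeleton data."""


@dataclass(frozen=True)
class SkeletonPoint:
    """One centreline sampling point: position (mm), tube radius (mm),
    cumulative arc length from the branch start (mm)."""

    position: np.ndarray
    radius: float
    arclen: float = 0.0

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        object.__setattr__(self, "position", pos)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise SkeletonError(f"position must be a finite 3-vector, got {pos!r}")
        if not (self.radius > 0):
            raise SkeletonError(f"radius must be > 0, got {self.radius}")


@dataclass
class Branch:
    """An ordered polyline of :class:`SkeletonPoint` with tree metadata."""

    id: str
    parent_id: str | None
    points: list[SkeletonPoint]
    generation: int = 0

    def __post_init__(self):
        if len(self.points) < 2:
            raise SkeletonError(f"branch {self.id!r}: needs >= 2 points")
        self._recompute_arclens()

    def _recompute_arclens(self) -> None:
        pos = self.positions()
        seg = np.linalg.norm(np.diff(pos, axis=0), axis=1)
        arclens = np.concatenate([[0.0], np.cumsum(seg)])
        self.points = [
            replace(p, arclen=float(s)) for p, s in zip(self.points, arclens)
        ]

    def positions(self) -> np.ndarray:
        return np.array([p.position for p in self.points])

    def radii(self) -> np.ndarray:
        return np.array([p.radius for p in self.points])

    def arclens(self) -> np.ndarray:
        return np.array([p.arclen for p in self.points])

    @property
    def length(self) -> float:
        return self.points[-1].arclen

    def with_radii(self, radii: Sequence[float]) -> "Branch":
        if len(radii) != len(self.points):
            raise SkeletonError(
                f"branch {self.id!r}: {len(radii)} radii for {len(self.points)} points"
            )
        pts = [replace(p, radius=float(r)) for p, r in zip(self.points, radii)]
        return Branch(self.id, self.parent_id, pts, self.generation)


@dataclass
class Skeleton:
    """A tree of branches. Exactly one root (``parent_id is None``)."""

    branches: list[Branch]
    units: str = "mm"

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.units != "mm":
            raise SkeletonError(f"units must be 'mm', got {self.units!r}")
        ids = [b.id for b in self.branches]
        if len(set(ids)) != len(ids):
            raise SkeletonError("duplicate branch ids")
        by_id = {b.id: b for b in self.branches}
        roots = [b for b in self.branches if b.parent_id is None]
        if len(roots) != 1:
            raise SkeletonError(f"expected exactly one root, found {len(roots)}")
        # acyclicity / connectivity: walk each branch to the root
        for b in self.branches:
            seen = {b.id}
            cur = b
            while cur.parent_id is not None:
                if cur.parent_id not in by_id:
                    raise SkeletonError(
                        f"branch {cur.id!r}: unknown parent {cur.parent_id!r}"
                    )
                cur = by_id[cur.parent_id]
                if cur.id in seen:
                    raise SkeletonError(f"cycle through branch {cur.id!r}")
                seen.add(cur.id)
        # attachment: child's first point near some parent point
        for b in self.branches:
            if b.parent_id is None:
                continue
            parent = by_id[b.parent_id]
            d = np.linalg.norm(
                parent.positions() - b.points[0].position, axis=1
            ).min()
            if d > ATTACH_TOL:
                raise SkeletonError(
                    f"branch {b.id!r}: first point is {d:.3f} mm from parent "
                    f"{b.parent_id!r} (tolerance {ATTACH_TOL} mm)"
                )

    def branch(self, branch_id: str) -> Branch:
        for b in self.branches:
            if b.id == branch_id:
                return b
        raise SkeletonError(f"no branch {branch_id!r}")

    @property
    def root(self) -> Branch:
        return next(b for b in self.branches if b.parent_id is None)

    def children(self, branch_id: str) -> list[Branch]:
        return [b for b in self.branches if b.parent_id == branch_id]

    def terminal_branches(self) -> list[Branch]:
        parents = {b.parent_id for b in self.branches if b.parent_id is not None}
        return [b for b in self.branches if b.id not in parents]

    def total_length(self) -> float:
        return float(sum(b.length for b in self.branches))

    def copy(self) -> "Skeleton":
        return Skeleton(
            [Branch(b.id, b.parent_id, list(b.points), b.generation)
             for b in self.branches],
            self.units,
        )


# ---------------------------------------------------------------------------
# I/O — documented open schema "skeleton-v1"
# ---------------------------------------------------------------------------

def write_skeleton(skeleton: Skeleton, path: str | Path, format: str = "json") -> None:
    """Write a skeleton as JSON (nested) or CSV (one row per point).

    JSON schema: ``{"schema": "skeleton-v1", "units": "mm", "branches":
    [{"id", "parent_id", "generation", "points": [{"xyz": [..], "radius": r}]}]}``.
    CSV columns: ``branch_id,parent_id,generation,x,y,z,radius``.
    """
    skeleton.validate()
    path = Path(path)
    if format == "json":
        doc = {
            "schema": SCHEMA_VERSION,
            "units": skeleton.units,
            "branches": [
                {
                    "id": b.id,
                    "parent_id": b.parent_id,
                    "generation": b.generation,
                    "points": [
                        {"xyz": [float(v) for v in p.position],
                         "radius": float(p.radius)}
                        for p in b.points
                    ],
                }
                for b in skeleton.branches
            ],
        }
        path.write_text(json.dumps(doc, indent=1))
    elif format == "csv":
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["branch_id", "parent_id", "generation", "x", "y", "z", "radius"])
            for b in skeleton.branches:
                for p in b.points:
                    w.writerow(
                        [b.id, "" if b.parent_id is None else b.parent_id,
                         b.generation, repr(float(p.position[0])),
                         repr(float(p.position[1])), repr(float(p.position[2])),
                         repr(float(p.radius))]
                    )
    else:
        raise ValueError(f"unknown format {format!r}")


def read_skeleton(path: str | Path, format: str | None = None) -> Skeleton:
    """Read a skeleton written by :func:`write_skeleton`.

    The format is inferred from the file suffix when not given.  Invariant
    violations raise :class:`SkeletonError` naming the offending branch.
    """
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "json"
    if format == "json":
        try:
            doc = json.loads(path.read_text())
        except json.JSONDecodeError as e:
            raise SkeletonError(f"{path}: malformed JSON: {e}") from e
        if "branches" not in doc:
            raise SkeletonError(f"{path}: missing 'branches' field")
        branches = []
        for bd in doc["branches"]:
            try:
                pts = [SkeletonPoint(np.asarray(pd["xyz"], float), float(pd["radius"]))
                       for pd in bd["points"]]
                branches.append(
                    Branch(str(bd["id"]),
                           None if bd.get("parent_id") in (None, "") else str(bd["parent_id"]),
                           pts, int(bd.get("generation", 0)))
                )
            except (KeyError, TypeError) as e:
                raise SkeletonError(
                    f"{path}: branch {bd.get('id')!r}: missing field {e}") from e
        return Skeleton(branches, units=doc.get("units", "mm"))
    elif format == "csv":
        rows: dict[str, dict] = {}
        order: list[str] = []
        with open(path, newline="") as fh:
            r = csv.DictReader(fh)
            required = {"branch_id", "x", "y", "z", "radius"}
            if r.fieldnames is None or not required <= set(r.fieldnames):
                raise SkeletonError(f"{path}: CSV needs columns {sorted(required)}")
            for i, row in enumerate(r, start=2):
                try:
                    bid = row["branch_id"]
                    if bid not in rows:
                        rows[bid] = {
                            "parent": row.get("parent_id") or None,
                            "gen": int(row.get("generation") or 0),
                            "pts": [],
                        }
                        order.append(bid)
                    rows[bid]["pts"].append(
                        SkeletonPoint(
                            np.array([float(row["x"]), float(row["y"]), float(row["z"])]),
                            float(row["radius"]))
                    )
                except (TypeError, ValueError) as e:
                    raise SkeletonError(f"{path}: line {i}: {e}") from e
        branches = [Branch(bid, rows[bid]["parent"], rows[bid]["pts"], rows[bid]["gen"])
                    for bid in order]
        return Skeleton(branches)
    raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# Tree grading
# ---------------------------------------------------------------------------

def grade_generations(skeleton: Skeleton) -> Skeleton:
    """Assign generations by breadth-first walk: the trachea (root) is
    generation 0, its children 1, and so on.  Idempotent and independent of
    the branch order in the input."""
    out = skeleton.copy()
    by_parent: dict[str | None, list[Branch]] = {}
    for b in out.branches:
        by_parent.setdefault(b.parent_id, []).append(b)
    queue = [(out.root, 0)]
    while queue:
        b, g = queue.pop()
        b.generation = g
        for c in by_parent.get(b.id, []):
            queue.append((c, g + 1))
    return out


# ---------------------------------------------------------------------------
# Equivalent radius from a surface mesh
# ---------------------------------------------------------------------------

def _loop_area_and_centroid(loop: np.ndarray) -> tuple[float, np.ndarray]:
    """Area and centroid of a closed planar 3D polygon (Newell's method)."""
    v = loop - loop.mean(axis=0)
    cross = np.cross(v[:-1], v[1:])
    normal_sum = cross.sum(axis=0)
    area = 0.5 * np.linalg.norm(normal_sum)
    return float(area), loop.mean(axis=0)


def equivalent_radius(mesh, point, tangent) -> float:
    """Equivalent radius sqrt(S/pi) of the mesh cross-section through
    ``point`` with normal ``tangent`` (the centreline tangent).

    When the cutting plane intersects the mesh in several closed loops (as
    it will near bifurcations), the loop whose centroid is nearest to
    ``point`` is used.
    """
    import trimesh

    point = np.asarray(point, float)
    tangent = np.asarray(tangent, float)
    nrm = np.linalg.norm(tangent)
    if not np.isclose(nrm, 1.0, atol=1e-6):
        tangent = tangent / nrm
    section = mesh.section(plane_origin=point, plane_normal=tangent)
    if section is None:
        raise SkeletonError("cutting plane does not intersect the mesh")
    loops = [np.asarray(d) for d in section.discrete]
    if not loops:
        raise SkeletonError("cutting plane produced no closed loop")
    best_area, best_dist = None, np.inf
    for loop in loops:
        if not np.allclose(loop[0], loop[-1], atol=1e-8):
            warnings.warn("open cross-section loop encountered; skipping")
            continue
        area, centroid = _loop_area_and_centroid(loop)
        d = np.linalg.norm(centroid - point)
        if d < best_dist:
            best_dist, best_area = d, area
    if best_area is None or best_area <= 0:
        raise SkeletonError("no closed cross-section loop near the point")
    return float(np.sqrt(best_area / np.pi))


def area_to_radius(area: float) -> float:
    """sqrt(S/pi): radius of the circle with the same area."""
    if area <= 0:
        raise ValueError(f"area must be > 0, got {area}")
    return float(np.sqrt(area / np.pi))


# ---------------------------------------------------------------------------
# Junction radius smoothing — the 20 % node-transition rule
# ---------------------------------------------------------------------------

def smooth_node_radii(skeleton: Skeleton, threshold: float = 0.20,
                      window: int = 3) -> Skeleton:
    """Smooth abrupt radius steps at parent->child junctions.

    At every junction, if the relative radius difference (with respect to
    the larger of the two) exceeds ``threshold``, the ``window`` samples on
    each side are replaced by linear interpolation (in arc length across the
    junction) between the flanking untouched radii.  Junctions within the
    threshold are left untouched.
    """
    if not (0 <= threshold < 1):
        raise ValueError(f"threshold must be in [0, 1), got {threshold}")
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window}")
    out = skeleton.copy()
    by_id = {b.id: b for b in out.branches}
    new_radii = {b.id: b.radii().copy() for b in out.branches}
    for child in out.branches:
        if child.parent_id is None:
            continue
        parent = by_id[child.parent_id]
        rp = parent.points[-1].radius
        rc = child.points[0].radius
        rel = abs(rp - rc) / max(rp, rc)
        if rel <= threshold:
            continue
        wp = min(window, len(parent.points) - 1)
        wc = min(window, len(child.points) - 1)
        if wp < window or wc < window:
            logger.warning(
                "junction %s->%s: window clamped to %d/%d (short branch)",
                parent.id, child.id, wp, wc)
        # arc-length coordinate across the junction: parent tail negative,
        # child head positive, junction at 0
        pa = parent.arclens() - parent.length
        ca = child.arclens()
        s0, r0 = pa[-1 - wp], new_radii[parent.id][-1 - wp]
        s1, r1 = ca[wc], new_radii[child.id][wc]
        for k in range(len(parent.points) - wp, len(parent.points)):
            t = (pa[k] - s0) / (s1 - s0)
            new_radii[parent.id][k] = r0 + t * (r1 - r0)
        for k in range(wc):
            t = (ca[k] - s0) / (s1 - s0)
            new_radii[child.id][k] = r0 + t * (r1 - r0)
    out.branches = [b.with_radii(new_radii[b.id]) for b in out.branches]
    return out


# ---------------------------------------------------------------------------
# Centreline spline fitting and radius resampling
# ---------------------------------------------------------------------------

def fit_centerline(points, smoothing: float = 0.0, n_out: int | None = None):
    """Fit a cubic chord-length-parameterized spline to an ordered polyline.

    Returns ``(points_out, tangents_out)``: ``n_out`` samples on the curve
    (uniform in parameter) and the unit tangents there.  Endpoints are
    preserved exactly; with ``smoothing == 0`` the spline interpolates the
    input points.
    """
    pts = np.asarray(points, float)
    # deduplicate coincident consecutive points
    keep = np.concatenate([[True], np.linalg.norm(np.diff(pts, axis=0), axis=1) > 1e-12])
    if not keep.all():
        warnings.warn("coincident consecutive points removed before spline fit")
        pts = pts[keep]
    if len(pts) < 4:
        raise ValueError(f"need >= 4 distinct points, got {len(pts)}")
    if n_out is None:
        n_out = len(pts)
    if n_out < 2:
        raise ValueError("n_out must be >= 2")
    chord = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))])
    u = chord / chord[-1]
    tck, _ = splprep(pts.T, u=u, s=smoothing, k=3)
    uu = np.linspace(0, 1, n_out)
    out = np.array(splev(uu, tck)).T
    # pin endpoints exactly: a smoothing spline is free at the ends, so add
    # the linear correction field (1-u)*d0 + u*d1 which leaves smoothness
    # intact but makes the endpoints exact
    d0 = pts[0] - np.array(splev(0.0, tck))
    d1 = pts[-1] - np.array(splev(1.0, tck))
    out = out + np.outer(1 - uu, d0) + np.outer(uu, d1)
    der = np.array(splev(uu, tck, der=1)).T + (d1 - d0)[None, :]
    tangents = der / np.linalg.norm(der, axis=1, keepdims=True)
    return out, tangents


def _project_arclen(polyline: np.ndarray, q: np.ndarray) -> float:
    """Arc length along ``polyline`` of the closest point to ``q``."""
    best, best_d = 0.0, np.inf
    s = 0.0
    for i in range(len(polyline) - 1):
        p0, p1 = polyline[i], polyline[i + 1]
        d = p1 - p0
        L2 = d @ d
        t = 0.0 if L2 == 0 else float(np.clip((q - p0) @ d / L2, 0, 1))
        proj = p0 + t * d
        dist = np.linalg.norm(q - proj)
        if dist < best_d:
            best_d, best = dist, s + t * np.sqrt(L2)
        s += np.sqrt(L2)
    return best


def resample_radii(branch: Branch, new_points) -> Branch:
    """Build a branch on ``new_points`` with radii linearly interpolated (in
    arc length) from the original branch profile."""
    new_points = np.asarray(new_points, float)
    poly = branch.positions()
    s_new = np.array([_project_arclen(poly, q) for q in new_points])
    radii = np.interp(s_new, branch.arclens(), branch.radii())
    pts = [SkeletonPoint(p, float(r)) for p, r in zip(new_points, radii)]
    return Branch(branch.id, branch.parent_id, pts, branch.generation)


# ---------------------------------------------------------------------------
# Distal trimming
# ---------------------------------------------------------------------------

def trim_distal(skeleton: Skeleton, terminal_length: float) -> Skeleton:
    """Truncate every terminal branch at ``terminal_length`` mm of arc length
    beyond its proximal bifurcation, so all model outlets end at a common
    distal length.  Branches already shorter are left unchanged.  Idempotent.
    """
    if terminal_length <= 0:
        raise ValueError(f"terminal_length must be > 0, got {terminal_length}")
    out = skeleton.copy()
    terminal_ids = {b.id for b in out.terminal_branches()}
    new_branches = []
    for b in out.branches:
        if b.id not in terminal_ids or b.length <= terminal_length:
            if b.id in terminal_ids and b.length < terminal_length:
                logger.info("branch %s shorter than trim length; left unchanged", b.id)
            new_branches.append(b)
            continue
        arclens = b.arclens()
        keep = arclens < terminal_length
        pts = [b.points[i] for i in range(len(b.points)) if keep[i]]
        # interpolate an exact endpoint at the cut
        i = int(np.searchsorted(arclens, terminal_length))
        s0, s1 = arclens[i - 1], arclens[i]
        t = (terminal_length - s0) / (s1 - s0)
        p0, p1 = b.points[i - 1], b.points[i]
        cut = SkeletonPoint(p0.position + t * (p1.position - p0.position),
                            p0.radius + t * (p1.radius - p0.radius))
        pts.append(cut)
        new_branches.append(Branch(b.id, b.parent_id, pts, b.generation))
    out.branches = new_branches
    return out
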