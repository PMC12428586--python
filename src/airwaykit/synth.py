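"""Synthetic fixtures: bifurcating airway trees, stenoses, cylinder meshes
and patient tables.

Every generator is a pure function of its spec and seed, so tests and
examples need no external data.  The bifurcating tree follows a Weibel-like
homothety: each generation's radius is ``radius_ratio`` (default 2^(-1/3))
times its parent's, lengths shrink by ``length_ratio``, and the two
children leave the parent direction at ``half_angle``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dilation import StenosisAnnotation
from .fev1 import PatientRecord
from .skeleton import Branch, Skeleton, SkeletonPoint


@dataclass(frozen=True)
class TreeSpec:
    """Parameters of a symmetric bifurcating airway tree."""

    generations: int = 4
    root_radius: float = 8.0        # mm, adult trachea scale
    root_length: float = 60.0       # mm
    radius_ratio: float = 2.0 ** (-1.0 / 3.0)
    length_ratio: float = 0.8
    half_angle_deg: float = 35.0
    points_per_branch: int = 9
    jitter: float = 0.0             # mm, optional positional noise
    seed: int = 0

    def __post_init__(self):
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if not (0 < self.radius_ratio < 1 and 0 < self.length_ratio < 1):
            raise ValueError("ratios must be in (0, 1)")


def make_bifurcating_tree(spec: TreeSpec) -> Skeleton:
    """Symmetric bifurcating tree with ``2^generations - 1`` branches.

    Deterministic given the seed; ``jitter`` adds seeded Gaussian noise to
    interior sampling points (endpoints stay exact so children still attach).
    """
    rng = np.random.default_rng(spec.seed)
    branches: list[Branch] = []

    def grow(bid, parent_id, gen, origin, direction, normal, length, radius):
        npts = max(spec.points_per_branch, 2)
        ts = np.linspace(0.0, 1.0, npts)
        pos = origin[None, :] + np.outer(ts * length, direction)
        if spec.jitter > 0:
            noise = rng.normal(0.0, spec.jitter, size=(npts, 3))
            noise[0] = noise[-1] = 0.0
            pos = pos + noise
        pts = [SkeletonPoint(p, radius) for p in pos]
        branches.append(Branch(bid, parent_id, pts, gen))
        if gen + 1 >= spec.generations:
            return
        tip = pos[-1]
        half = np.deg2rad(spec.half_angle_deg)
        # children fan out in the plane spanned by direction and normal;
        # successive bifurcation planes rotate 90 degrees, as real airways do
        new_normal = np.cross(direction, normal)
        for k, sign in enumerate((+1.0, -1.0)):
            child_dir = np.cos(half) * direction + sign * np.sin(half) * normal
            child_dir = child_dir / np.linalg.norm(child_dir)
            grow(f"{bid}.{k}", bid, gen + 1, tip, child_dir, new_normal,
                 length * spec.length_ratio, radius * spec.radius_ratio)

    grow("b0", None, 0, np.zeros(3), np.array([0.0, 0.0, -1.0]),
         np.array([1.0, 0.0, 0.0]), spec.root_length, spec.root_radius)
    return Skeleton(branches)


def insert_stenosis(skeleton: Skeleton, branch_id: str, center_mm: float,
                    length_mm: float, severity: float
                    ) -> tuple[Skeleton, StenosisAnnotation]:
    """Narrow a branch over an arc-length interval with cosine shoulders.

    Radii inside the interval are scaled by ``1 - severity * w(t)`` where
    w rises smoothly from 0 at the edges to 1 at the centre, so the
    minimum radius is ``(1 - severity)`` times the original.  Returns the
    stenosed skeleton plus an annotation whose healthy profile R1 is the
    original radii — dilating back at alpha = 1 recovers them exactly.
    """
    if not (0.0 < severity < 1.0):
        raise ValueError(f"severity must be in (0, 1), got {severity}")
    out = skeleton.copy()
    branch = out.branch(branch_id)
    s = branch.arclens()
    start, end = center_mm - length_mm / 2.0, center_mm + length_mm / 2.0
    if start < 0 or end > branch.length:
        raise ValueError(
            f"interval [{start:.3g}, {end:.3g}] outside branch "
            f"[0, {branch.length:.3g}]")
    mask = (s >= start - 1e-12) & (s <= end + 1e-12)
    if mask.sum() < 2:
        raise ValueError("interval covers fewer than 2 branch samples; "
                         "lengthen it or resample the branch")
    radii = branch.radii().copy()
    u = (s[mask] - start) / (end - start)
    w = 0.5 * (1.0 - np.cos(2.0 * np.pi * u))
    r1 = radii[mask].copy()
    r2 = radii[mask] * (1.0 - severity * w)
    radii[mask] = r2
    out.branches = [b.with_radii(radii) if b.id == branch_id else b
                    for b in out.branches]
    # cosine shoulders already taper to zero change at the edges, so the
    # annotation needs no extra edge ramp — and alpha = 1 stays exact
    ann = StenosisAnnotation(branch_id, float(start), float(end),
                             healthy_radii=r1, stenotic_radii=r2,
                             ramp_margin=0.0)
    return out, ann


def make_cylinder_mesh(radius: float, length: float, n_circ: int = 64,
                       n_axial: int = 16, capped: bool = True):
    """Axis-aligned (z) cylinder mesh centred at the origin.

    Cross-section is a regular ``n_circ``-gon whose area approaches
    pi*r^2 as n_circ grows; used as the analytic oracle geometry for
    cross-section radius measurements.
    """
    import warnings

    from .convsurface import TriangleMesh

    if n_circ < 8:
        warnings.warn(f"n_circ={n_circ} is a degenerate cross-section")
    if n_circ < 3:
        raise ValueError("n_circ must be >= 3")
    theta = np.linspace(0.0, 2.0 * np.pi, n_circ, endpoint=False)
    zs = np.linspace(-length / 2.0, length / 2.0, n_axial + 1)
    ring = np.stack([radius * np.cos(theta), radius * np.sin(theta)], axis=1)
    verts = [np.column_stack([ring, np.full(n_circ, z)]) for z in zs]
    V = np.vstack(verts)
    faces = []
    for i in range(n_axial):
        base0, base1 = i * n_circ, (i + 1) * n_circ
        for j in range(n_circ):
            j1 = (j + 1) % n_circ
            faces.append([base0 + j, base0 + j1, base1 + j])
            faces.append([base0 + j1, base1 + j1, base1 + j])
    if capped:
        c_bot = len(V)
        c_top = len(V) + 1
        V = np.vstack([V, [[0, 0, zs[0]], [0, 0, zs[-1]]]])
        top0 = n_axial * n_circ
        for j in range(n_circ):
            j1 = (j + 1) % n_circ
            faces.append([c_bot, (j1) % n_circ, j])
            faces.append([c_top, top0 + j, top0 + j1])
    return TriangleMesh(vertices=np.asarray(V, float),
                        faces=np.asarray(faces, int))


def synth_patient_records(n: int, slope: float = 0.82,
                          intercept: float = -0.089,
                          noise_sd: float = 0.01,
                          c_range: tuple[float, float] = (1.4, 3.5),
                          seed: int = 0) -> list[PatientRecord]:
    """Synthetic (a, b, c) patient triples around a known line y = slope*x
    + intercept: x uniform in (0.3, 1.0), Gaussian noise on y, c uniform
    in ``c_range``; then a = x*c and b = y*c."""
    if n < 3:
        raise ValueError("need n >= 3")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    x = rng.uniform(0.3, 1.0, n)
    y = slope * x + intercept + rng.normal(0.0, noise_sd, n)
    c = rng.uniform(*c_range, n)
    return [PatientRecord(f"S{i:03d}", a=float(xi * ci), c=float(ci),
                          b=float(yi * ci))
            for i, (xi, yi, ci) in enumerate(zip(x, y, c))]
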