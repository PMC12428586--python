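"""Stenosis annotation and parametric dilation of airway skeletons.

A stenotic interval on a branch carries two radius profiles: the current
(stenotic) radii R2 and the healthy reference radii R1.  The dilation
radius ratio

    alpha = (R - R2) / (R1 - R2)

interpolates the tube radius between the patient's current state
(alpha = 0) and the healthy state (alpha = 1), giving a family of
transitional airway models for preoperative planning.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .skeleton import Skeleton

DEFAULT_ALPHAS = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)


@dataclass
class StenosisAnnotation:
    """A stenotic arc-length interval on one branch.

    ``healthy_radii`` (R1) and ``stenotic_radii`` (R2) are per-point
    profiles over the branch samples inside the interval, in branch order.
    ``ramp_margin`` is the arc length (mm) over which the radius change is
    blended back to the unmodified profile outside the interval.
    """

    branch_id: str
    start_mm: float
    end_mm: float
    healthy_radii: np.ndarray
    stenotic_radii: np.ndarray
    ramp_margin: float = 2.0

    def __post_init__(self):
        self.healthy_radii = np.asarray(self.healthy_radii, float)
        self.stenotic_radii = np.asarray(self.stenotic_radii, float)
        if self.end_mm <= self.start_mm:
            raise ValueError("empty stenosis interval")
        if self.healthy_radii.shape != self.stenotic_radii.shape:
            raise ValueError("R1 and R2 profiles differ in length")
        if np.any(self.stenotic_radii <= 0):
            raise ValueError("stenotic radii must be > 0")
        if np.any(self.healthy_radii < self.stenotic_radii - 1e-12):
            raise ValueError("healthy radii must be >= stenotic radii")

    def to_json(self, path: str | Path) -> None:
        doc = {
            "branch_id": self.branch_id,
            "start_mm": self.start_mm,
            "end_mm": self.end_mm,
            "R1": self.healthy_radii.tolist(),
            "R2": self.stenotic_radii.tolist(),
            "ramp_margin": self.ramp_margin,
        }
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "StenosisAnnotation":
        doc = json.loads(Path(path).read_text())
        return cls(doc["branch_id"], doc["start_mm"], doc["end_mm"],
                   np.asarray(doc["R1"], float), np.asarray(doc["R2"], float),
                   doc.get("ramp_margin", 2.0))


@dataclass(frozen=True)
class DilationSpec:
    """Dilation radius ratio alpha in [0, 1]."""

    alpha: float

    def __post_init__(self):
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")


def _interval_mask(branch, ann: StenosisAnnotation) -> np.ndarray:
    s = branch.arclens()
    return (s >= ann.start_mm - 1e-12) & (s <= ann.end_mm + 1e-12)


def apply_dilation(skeleton: Skeleton, ann: StenosisAnnotation,
                   alpha: float) -> Skeleton:
    """Set radii in the stenotic interval to R2 + alpha*(R1 - R2); radii
    outside the interval are never touched.

    With ``ramp_margin`` > 0, the radius change is damped linearly to zero
    over the first/last ``ramp_margin`` mm *inside* the interval, so a
    rectangle-shaped annotation does not produce a radius step at the
    interval boundary.  Annotations whose profiles already taper to
    R1 = R2 at the edges (e.g. cosine-shouldered synthetic stenoses) should
    use ramp_margin = 0 to keep alpha = 1 an exact inverse.
    """
    DilationSpec(alpha)  # validates range
    out = skeleton.copy()
    branch = out.branch(ann.branch_id)
    mask = _interval_mask(branch, ann)
    n_in = int(mask.sum())
    if n_in != len(ann.stenotic_radii):
        raise ValueError(
            f"annotation has {len(ann.stenotic_radii)} profile samples but the "
            f"interval covers {n_in} branch points — annotation/skeleton mismatch")
    radii = branch.radii().copy()
    if not np.allclose(radii[mask], ann.stenotic_radii, atol=1e-9):
        raise ValueError(
            "branch radii inside the interval do not match the annotation's R2")
    delta = alpha * (ann.healthy_radii - ann.stenotic_radii)
    if ann.ramp_margin > 0:
        s_in = branch.arclens()[mask]
        edge_dist = np.minimum(s_in - ann.start_mm, ann.end_mm - s_in)
        delta = delta * np.clip(edge_dist / ann.ramp_margin, 0.0, 1.0)
    new_radii = radii.copy()
    new_radii[mask] = ann.stenotic_radii + delta
    out.branches = [b.with_radii(new_radii) if b.id == ann.branch_id else b
                    for b in out.branches]
    return out


def generate_transition_series(skeleton: Skeleton, ann: StenosisAnnotation,
                               alphas=DEFAULT_ALPHAS):
    """One dilated skeleton per alpha (default 0 %..100 % in 20 % steps).

    The minimum radius inside the interval is non-decreasing in alpha."""
    alphas = list(alphas)
    if any(a2 < a1 for a1, a2 in zip(alphas, alphas[1:])):
        raise ValueError("alphas must be sorted ascending")
    return [(a, apply_dilation(skeleton, ann, a)) for a in alphas]


def build_healthy_reference(skeleton: Skeleton, branch_id: str,
                            start_mm: float, end_mm: float,
                            flank_window: int = 3) -> np.ndarray:
    """Infer a healthy radius profile R1 over a stenotic interval by
    linear interpolation between the mean radii of flanking windows
    (default 3 samples each side), in arc length.

    Errors out when the interval touches either branch end — there is then
    no healthy flank to interpolate from and R1 must be supplied manually.
    """
    branch = skeleton.branch(branch_id)
    s = branch.arclens()
    radii = branch.radii()
    mask = (s >= start_mm - 1e-12) & (s <= end_mm + 1e-12)
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        raise ValueError("interval covers no branch samples")
    lo = idx[0] - flank_window
    hi = idx[-1] + flank_window
    if lo < 0 or hi >= len(radii):
        raise ValueError(
            "stenotic interval touches the branch end; healthy reference "
            "cannot be inferred from flanks — supply R1 manually")
    r_left = float(radii[lo:idx[0]].mean())
    r_right = float(radii[idx[-1] + 1:hi + 1].mean())
    s_left = float(s[lo:idx[0]].mean())
    s_right = float(s[idx[-1] + 1:hi + 1].mean())
    return np.interp(s[mask], [s_left, s_right], [r_left, r_right])
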