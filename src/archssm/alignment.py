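"""Rigid pose normalization of arch centerlines.

Every case is translated so its bifurcation origin sits at the
coordinate origin and rotated about the vertical axis Z so that the
horizontal projection of the ductal direction v_AD (bifurcation origin
-> free end of the arterial duct) lands on the +X half-axis.  No scaling
is applied: absolute segment lengths and calibers are informative and
must survive alignment.  Tilt (rotations off the Z axis) is deliberately
left untouched — inputs are assumed to be in the fetal anatomical frame
(+X left->right, +Z inferior->superior).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .centerline import ArchCenterline, Centerline
from .errors import DegeneratePoseError

__all__ = ["AlignmentTransform", "compute_alignment", "apply_alignment",
           "align", "is_aligned"]

#: minimum horizontal component (mm) of v_AD before the pose is degenerate
HORIZONTAL_TOL = 1e-6


@dataclass
class AlignmentTransform:
    """Translate-then-rotate-about-Z rigid transform (never scales)."""

    translation: np.ndarray  # (3,) mm, applied first
    alpha: float             # rotation angle about +Z, radians
    v_ad: np.ndarray         # (3,) unit ductal direction before rotation

    def rotation_matrix(self) -> np.ndarray:
        c, s = np.cos(self.alpha), np.sin(self.alpha)
        return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])

    def apply_points(self, points: np.ndarray) -> np.ndarray:
        return (points + self.translation) @ self.rotation_matrix().T

    def to_dict(self) -> dict:
        return {"translation": self.translation.tolist(),
                "alpha": float(self.alpha),
                "v_ad": self.v_ad.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "AlignmentTransform":
        return cls(np.asarray(d["translation"], dtype=float), float(d["alpha"]),
                   np.asarray(d["v_ad"], dtype=float))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "AlignmentTransform":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def compute_alignment(arch: ArchCenterline) -> AlignmentTransform:
    """Derive the pose-normalizing transform for one arch.

    v_AD points from the bifurcation origin to the duct's free end
    (the pulmonary-bifurcation landmark end of the AD segment).
    """
    origin = arch.bifurcation_origin
    v = arch.ad.points[0] - origin
    norm = np.linalg.norm(v)
    if norm == 0:
        raise DegeneratePoseError("duct free end coincides with the origin")
    v_ad = v / norm
    if np.hypot(v[0], v[1]) <= HORIZONTAL_TOL:
        raise DegeneratePoseError(
            "v_AD is vertical; the Z-rotation is undefined")
    alpha = -np.arctan2(v_ad[1], v_ad[0])
    return AlignmentTransform(translation=-origin.astype(float), alpha=alpha,
                              v_ad=v_ad)


def apply_alignment(arch: ArchCenterline, t: AlignmentTransform) -> ArchCenterline:
    """Apply a transform; radii and all pairwise distances are unchanged."""
    segs = {}
    for name, seg in arch.segments().items():
        segs[name] = Centerline(t.apply_points(seg.points), seg.radius.copy())
    origin = t.apply_points(arch.bifurcation_origin[None])[0]
    return ArchCenterline(segs["aao"], segs["ad"], segs["dao"], origin)


def align(arch: ArchCenterline) -> ArchCenterline:
    """Convenience: compute and apply the canonical pose in one call."""
    return apply_alignment(arch, compute_alignment(arch))


def is_aligned(arch: ArchCenterline, origin_atol: float = 1.0,
               angle_atol: float = 0.05) -> bool:
    """Loose check that an arch is in the canonical pose.

    Tolerances default to 1 mm on the origin and 0.05 rad on the
    azimuth of v_AD so that noisy or reconstructed (model-space) shapes
    still pass, while unaligned raw geometry does not.
    """
    if np.linalg.norm(arch.bifurcation_origin) > origin_atol:
        return False
    v = arch.ad.points[0] - arch.bifurcation_origin
    if np.hypot(v[0], v[1]) <= HORIZONTAL_TOL:
        return False
    return bool(abs(np.arctan2(v[1], v[0])) <= angle_atol)
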