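"""Automated geometric descriptors of the aligned arch anatomy.

The simple single-number metrics the shape risk score is benchmarked
against: the projected vertical angle between duct and isthmus
(ang_vert), the distal ascending-aortic caliber (diam_daao), the
vertical arch displacement over the mid-duct (disp_vert), the offset of
the isthmus insertion from the descending-aortic axis (disp_dao, the
"posterior shelf" surrogate), the isthmus:duct caliber ratio, per-segment
arc lengths and duct tortuosity.  All are computed from the aligned,
resampled centerlines; the isthmus is taken as the distal 20% of the
AAo segment (the model carries no aortic branches to define it
anatomically).
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .alignment import is_aligned
from .centerline import ArchCenterline, Centerline
from .discriminant import auc as rank_auc
from .errors import AlignmentRequiredError, ParameterError

__all__ = ["DescriptorSet", "compute_descriptors", "descriptor_table",
           "descriptor_benchmark", "DESCRIPTOR_COLUMNS"]

DESCRIPTOR_COLUMNS = [
    "ang_vert_deg", "diam_daao_mm", "disp_vert_mm", "disp_dao_mm",
    "isthmus_duct_ratio", "len_aao_mm", "len_ad_mm", "len_dao_mm",
    "ad_tortuosity",
]


@dataclass
class DescriptorSet:
    """One case's geometric descriptors (angles deg, distances mm)."""

    ang_vert_deg: float
    diam_daao_mm: float
    disp_vert_mm: float
    disp_dao_mm: float
    isthmus_duct_ratio: float
    len_aao_mm: float
    len_ad_mm: float
    len_dao_mm: float
    ad_tortuosity: float

    def to_dict(self) -> dict:
        return asdict(self)


def _mean_tangent(points: np.ndarray) -> np.ndarray:
    """Mean of unit finite-difference tangents along the point ordering."""
    diffs = np.diff(points, axis=0)
    diffs /= np.maximum(np.linalg.norm(diffs, axis=1, keepdims=True), 1e-12)
    t = diffs.mean(axis=0)
    return t / np.linalg.norm(t)


def _interp_at_arc(line: Centerline, frac: float):
    """Point and radius at a fraction of total arc length."""
    s = line.arc_lengths()
    target = frac * s[-1]
    pt = np.array([np.interp(target, s, line.points[:, i]) for i in range(3)])
    return pt, float(np.interp(target, s, line.radius))


def compute_descriptors(arch: ArchCenterline, tangent_window: int = 5,
                        isthmus_fraction: float = 0.2,
                        dao_axis_points: int = 10) -> DescriptorSet:
    """Extract all descriptors from one aligned arch.

    ``ang_vert`` is the angle between the mean isthmus tangent (last
    ``tangent_window`` AAo points before the origin) and the mean duct
    tangent (the ``tangent_window`` AD points nearest the origin), both
    taken along the free-end -> origin ordering and projected onto the
    XZ plane — canonical after alignment, where v_AD lies along +X.
    """
    if not is_aligned(arch):
        raise AlignmentRequiredError(
            "descriptors require a pose-normalized arch (run alignment first)")
    if tangent_window < 2:
        raise ParameterError("tangent_window must be >= 2")

    aao, ad, dao = arch.aao, arch.ad, arch.dao

    t_isth = _mean_tangent(aao.points[-tangent_window:])
    t_ad = _mean_tangent(ad.points[-tangent_window:])
    xz = np.array([0, 2])
    u = t_isth[xz] / np.linalg.norm(t_isth[xz])
    v = t_ad[xz] / np.linalg.norm(t_ad[xz])
    ang_vert = float(np.degrees(np.arccos(np.clip(u @ v, -1.0, 1.0))))

    _, r80 = _interp_at_arc(aao, 1.0 - isthmus_fraction)
    diam_daao = 2.0 * r80

    ad_mid, r_ad_mid = _interp_at_arc(ad, 0.5)
    disp_vert = float(aao.points[:, 2].max() - ad_mid[2])

    # offset of the isthmus insertion from the proximal DAo axis (XY)
    pts = dao.points[:dao_axis_points, :2]
    centroid = pts.mean(axis=0)
    u_axis = np.linalg.svd(pts - centroid)[2][0]
    rel = aao.points[-1, :2] - centroid
    disp_dao = float(np.linalg.norm(rel - (rel @ u_axis) * u_axis))

    _, r_isth_mid = _interp_at_arc(aao, 1.0 - 0.5 * isthmus_fraction)
    ratio = r_isth_mid / r_ad_mid

    chord = float(np.linalg.norm(ad.points[0] - ad.points[-1]))
    tort = ad.length / chord if chord > 0 else np.inf

    return DescriptorSet(
        ang_vert_deg=ang_vert, diam_daao_mm=diam_daao, disp_vert_mm=disp_vert,
        disp_dao_mm=disp_dao, isthmus_duct_ratio=ratio,
        len_aao_mm=aao.length, len_ad_mm=ad.length, len_dao_mm=dao.length,
        ad_tortuosity=tort)


def descriptor_table(arches: list[ArchCenterline],
                     case_ids: list[str] | None = None,
                     **kwargs) -> pd.DataFrame:
    """Descriptor CSV table for a cohort of aligned arches."""
    if case_ids is None:
        case_ids = [f"case_{i:04d}" for i in range(len(arches))]
    rows = [compute_descriptors(a, **kwargs).to_dict() for a in arches]
    table = pd.DataFrame(rows)
    table.insert(0, "case_id", case_ids)
    return table


def descriptor_benchmark(table: pd.DataFrame, labels: np.ndarray,
                         risk_scores: np.ndarray) -> pd.DataFrame:
    """Per-descriptor discrimination (AUC) and agreement with the score (R^2).

    AUC orientation is chosen per descriptor (best-case single-metric
    performance), so values are >= 0.5.  R^2 is the ordinary
    least-squares coefficient of determination against the risk score.
    """
    labels = np.asarray(labels).astype(int)
    risk_scores = np.asarray(risk_scores, dtype=float)
    rows = []
    for col in DESCRIPTOR_COLUMNS:
        if col not in table.columns:
            continue
        x = table[col].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            warnings.warn(f"descriptor {col} is constant; AUC 0.5, R^2 0",
                          stacklevel=2)
            rows.append({"descriptor": col, "auc": 0.5, "r2": 0.0})
            continue
        a = rank_auc(x, labels)
        a = max(a, 1.0 - a)
        if np.ptp(risk_scores) == 0:
            r2 = 0.0
        else:
            r2 = float(np.corrcoef(x, risk_scores)[0, 1] ** 2)
        rows.append({"descriptor": col, "auc": a, "r2": r2})
    return pd.DataFrame(rows)
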