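"""PCA statistical shape model over aligned arch centerlines.

Each aligned case is encoded as a feature vector of length 4N — for
every one of the N correspondence points (default 25 AAo + 25 AD +
51 DAo = 101, hence 404 features) its x, y, z coordinates and maximal
inscribed radius, all in millimetres.  PCA on the centered feature
matrix yields ranked orthonormal modes of anatomical variation, per-mode
variances and per-case shape coefficients.  Coordinates and radii share
units, so the data are centered but not standardized, and variances use
the unbiased 1/(n-1) convention.

Also here: reconstruction from truncated mode sets, +/-SD extreme
shapes, per-region reconstruction RMSE (coordinates only) and the
per-mode two-sample t-test between outcome groups.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from dataclasses import dataclass, field
from scipy import stats

from .centerline import ArchCenterline, Centerline, DEFAULT_COUNTS
from .errors import CorrespondenceError, InsufficientDataError, ParameterError

__all__ = [
    "ShapeModel", "assemble_features", "disassemble_features", "fit_pca",
    "project", "reconstruct", "reconstruct_vector", "extreme_shape",
    "reconstruction_rmse", "mode_group_ttest", "region_point_indices",
    "feature_point_rmse", "save_model", "load_model", "REGIONS",
]

REGIONS = ("AAO", "AD", "DAO", "ALL", "NEAR_BIFURCATION")

#: minimum radius (mm) after reconstruction; smaller values are clamped
RADIUS_FLOOR = 1e-6


# ---------------------------------------------------------------------------
# feature assembly
# ---------------------------------------------------------------------------


def _arch_to_vector(arch: ArchCenterline) -> np.ndarray:
    blocks = []
    for seg in (arch.aao, arch.ad, arch.dao):
        blocks.append(np.column_stack([seg.points, seg.radius]).ravel())
    return np.concatenate(blocks)


def assemble_features(arches: list[ArchCenterline]) -> np.ndarray:
    """Stack aligned cases into an (n_cases, 4N) feature matrix.

    Point order is fixed (AAo free->origin, AD free->origin, DAo
    origin->diaphragm; x, y, z, radius per point) and the mapping is
    bijective: :func:`disassemble_features` inverts it exactly.
    """
    if len(arches) == 0:
        raise InsufficientDataError("no cases to assemble")
    counts = arches[0].counts
    for i, arch in enumerate(arches):
        if arch.counts != counts:
            raise CorrespondenceError(
                f"case {i} has counts {arch.counts}, expected {counts}")
    return np.vstack([_arch_to_vector(a) for a in arches])


def disassemble_features(vector: np.ndarray,
                         counts: tuple[int, int, int] = DEFAULT_COUNTS,
                         clamp_radius: bool = True) -> ArchCenterline:
    """Invert :func:`assemble_features` for one case.

    The bifurcation origin is recovered as the mean of the three
    bifurcation-adjacent segment endpoints.  Non-positive radii (possible
    after truncated reconstruction) are clamped to a small floor with a
    warning.
    """
    vector = np.asarray(vector, dtype=float).ravel()
    expected = 4 * sum(counts)
    if vector.shape[0] != expected:
        raise CorrespondenceError(
            f"feature vector has length {vector.shape[0]}, expected {expected}")
    segs = []
    offset = 0
    for n in counts:
        block = vector[offset:offset + 4 * n].reshape(n, 4)
        offset += 4 * n
        radius = block[:, 3].copy()
        if clamp_radius and np.any(radius < RADIUS_FLOOR):
            warnings.warn("reconstructed radii clamped to the positive floor",
                          stacklevel=2)
            radius = np.maximum(radius, RADIUS_FLOOR)
        segs.append(Centerline(block[:, :3].copy(), radius))
    aao, ad, dao = segs
    origin = (aao.points[-1] + ad.points[-1] + dao.points[0]) / 3.0
    return ArchCenterline(aao, ad, dao, origin)


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------


@dataclass
class ShapeModel:
    """Population mean + ranked PCA modes + per-case shape coefficients."""

    mean: np.ndarray          # (4N,)
    modes: np.ndarray         # (m, 4N), orthonormal rows, ranked
    variances: np.ndarray     # (m,), eigenvalues (mm^2), non-increasing
    coefficients: np.ndarray  # (n_cases, m) projections (mm)
    case_ids: list[str] = field(default_factory=list)
    counts: tuple[int, int, int] = DEFAULT_COUNTS

    @property
    def n_cases(self) -> int:
        return self.coefficients.shape[0]

    @property
    def n_modes(self) -> int:
        return self.modes.shape[0]

    def explained_variance_ratio(self) -> np.ndarray:
        total = self.variances.sum()
        return self.variances / total if total > 0 else np.zeros_like(self.variances)


def fit_pca(features: np.ndarray, case_ids: list[str] | None = None,
            counts: tuple[int, int, int] = DEFAULT_COUNTS) -> ShapeModel:
    """Fit the shape model by SVD of the centered feature matrix.

    Retains min(n-1, 4N) modes.  Mode signs are canonicalized so each
    mode's largest-magnitude loading is positive, for reproducible
    serialization.  Agrees with the eigendecomposition of the sample
    covariance (1/(n-1)) to numerical precision.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise InsufficientDataError("PCA needs at least 2 cases")
    n, p = X.shape
    mean = X.mean(axis=0)
    Xc = X - mean
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    m = min(n - 1, p)
    s, vt = s[:m], vt[:m]
    variances = s**2 / (n - 1)
    # sign canonicalization: largest |loading| positive per mode
    flip = vt[np.arange(m), np.argmax(np.abs(vt), axis=1)] < 0
    vt[flip] *= -1.0
    coefficients = Xc @ vt.T
    if case_ids is None:
        case_ids = [f"case_{i:04d}" for i in range(n)]
    return ShapeModel(mean=mean, modes=vt, variances=variances,
                      coefficients=coefficients, case_ids=list(case_ids),
                      counts=tuple(counts))


def project(model: ShapeModel, feature: np.ndarray, k: int | None = None) -> np.ndarray:
    """Shape coefficients b = modes^T (feature - mean), first k entries.

    Accepts a single vector or an (n, 4N) matrix.
    """
    k = model.n_modes if k is None else k
    if not 1 <= k <= model.n_modes:
        raise ParameterError(f"k must be in [1, {model.n_modes}]")
    feature = np.asarray(feature, dtype=float)
    return (feature - model.mean) @ model.modes[:k].T


def reconstruct_vector(model: ShapeModel, coefficients: np.ndarray,
                       k: int | None = None) -> np.ndarray:
    """mean + sum_{j<=k} b_j mode_j as a raw feature vector (k=0 -> mean)."""
    coefficients = np.atleast_1d(np.asarray(coefficients, dtype=float))
    if k is None:
        k = len(coefficients)
    if k < 0 or k > model.n_modes:
        raise ParameterError(f"k must be in [0, {model.n_modes}]")
    vec = model.mean.copy()
    if k > 0:
        vec = vec + coefficients[:k] @ model.modes[:k]
    return vec


def reconstruct(model: ShapeModel, coefficients: np.ndarray,
                k: int | None = None) -> ArchCenterline:
    """Truncated reconstruction, returned as an arch centerline."""
    return disassemble_features(reconstruct_vector(model, coefficients, k),
                                model.counts)


def extreme_shape(model: ShapeModel, mode_index: int,
                  sd_multiple: float = 3.0) -> ArchCenterline:
    """Shape at mean + sd_multiple * sqrt(variance_k) along one mode."""
    if not 0 <= mode_index < model.n_modes:
        raise ParameterError(f"mode_index must be in [0, {model.n_modes - 1}]")
    sd = np.sqrt(max(model.variances[mode_index], 0.0))
    vec = model.mean + sd_multiple * sd * model.modes[mode_index]
    return disassemble_features(vec, model.counts)


# ---------------------------------------------------------------------------
# reconstruction error
# ---------------------------------------------------------------------------


def region_point_indices(region: str,
                         counts: tuple[int, int, int] = DEFAULT_COUNTS) -> np.ndarray:
    """Point indices (0..N-1) belonging to a region.

    NEAR_BIFURCATION is the bifurcation-adjacent half of each segment,
    rounding up (13/13/26 points for 25/25/51): the last points of AAo
    and AD (ordered free end -> origin) and the first points of DAo.
    """
    n_aao, n_ad, n_dao = counts
    starts = np.cumsum([0, n_aao, n_ad])
    if region == "AAO":
        return np.arange(n_aao)
    if region == "AD":
        return starts[1] + np.arange(n_ad)
    if region == "DAO":
        return starts[2] + np.arange(n_dao)
    if region == "ALL":
        return np.arange(sum(counts))
    if region == "NEAR_BIFURCATION":
        h_aao = -(-n_aao // 2)
        h_ad = -(-n_ad // 2)
        h_dao = -(-n_dao // 2)
        return np.concatenate([
            np.arange(n_aao - h_aao, n_aao),
            starts[1] + np.arange(n_ad - h_ad, n_ad),
            starts[2] + np.arange(h_dao),
        ])
    raise ParameterError(f"unknown region {region!r}; choose from {REGIONS}")


def feature_point_rmse(vec_a: np.ndarray, vec_b: np.ndarray,
                       counts: tuple[int, int, int] = DEFAULT_COUNTS,
                       region: str = "ALL") -> float:
    """RMSE (mm) over per-point 3D distances between two feature vectors.

    The radius channel is excluded: this is a geometric error.
    """
    pa = np.asarray(vec_a, dtype=float).reshape(-1, 4)[:, :3]
    pb = np.asarray(vec_b, dtype=float).reshape(-1, 4)[:, :3]
    idx = region_point_indices(region, counts)
    d2 = np.sum((pa[idx] - pb[idx]) ** 2, axis=1)
    return float(np.sqrt(d2.mean()))


def reconstruction_rmse(model: ShapeModel, case_index: int, k: int,
                        region: str = "ALL") -> float:
    """RMSE between a training case and its k-mode reconstruction."""
    if not 0 <= case_index < model.n_cases:
        raise ParameterError("case_index out of range")
    truth = reconstruct_vector(model, model.coefficients[case_index],
                               model.n_modes)
    approx = reconstruct_vector(model, model.coefficients[case_index], k)
    return feature_point_rmse(truth, approx, model.counts, region)


# ---------------------------------------------------------------------------
# group comparison
# ---------------------------------------------------------------------------


def mode_group_ttest(model: ShapeModel, labels: np.ndarray,
                     alpha: float = 0.01) -> pd.DataFrame:
    """Two-tailed equal-variance two-sample t-test per mode (class 0 vs 1).

    No multiple-comparison correction is applied; modes are flagged
    significant at p < alpha (default 0.01).
    """
    labels = np.asarray(labels)
    if labels.shape[0] != model.n_cases:
        raise ParameterError("labels length must match the number of cases")
    g0 = model.coefficients[labels == 0]
    g1 = model.coefficients[labels == 1]
    if len(g0) < 2 or len(g1) < 2:
        raise InsufficientDataError("each class needs at least 2 members")
    t, p = stats.ttest_ind(g0, g1, axis=0, equal_var=True)
    t = np.atleast_1d(t)
    p = np.atleast_1d(p)
    # identical distributions yield 0/0 -> no evidence of a difference
    t = np.nan_to_num(t, nan=0.0)
    p = np.where(np.isnan(p), 1.0, p)
    return pd.DataFrame({"mode": np.arange(1, model.n_modes + 1),
                         "t": t, "p": p, "significant": p < alpha})


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def save_model(model: ShapeModel, path) -> None:
    """Write the model to a single .npz container (bit-stable round trip)."""
    np.savez(path, mean=model.mean, modes=model.modes,
             variances=model.variances, coefficients=model.coefficients,
             case_ids=np.asarray(model.case_ids, dtype="U"),
             counts=np.asarray(model.counts, dtype=int))


def load_model(path) -> ShapeModel:
    with np.load(path, allow_pickle=False) as data:
        return ShapeModel(mean=data["mean"], modes=data["modes"],
                          variances=data["variances"],
                          coefficients=data["coefficients"],
                          case_ids=[str(c) for c in data["case_ids"]],
                          counts=tuple(int(c) for c in data["counts"]))
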