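"""Sample-size robustness study and virtual-cohort sampling.

The robustness protocol refits the whole model (PCA + LDA) on stratified
random subsets of the cohort at fractions 50-90%, ten repeats each,
recording RS/LOOCV AUC and the +/-3SD discriminant phenotypes, and
measures how the subset phenotypes converge to the full-cohort ones as
the fraction grows.  Virtual cohorts are drawn from a fitted shape model
by sampling each mode coefficient independently from N(0, variance_k).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .centerline import ArchCenterline
from .discriminant import (DiscriminantAxis, auc, fit_lda, lda_extreme_shapes,
                           loocv_scores, risk_scores)
from .errors import InsufficientDataError, ParameterError
from .shape_model import (ShapeModel, disassemble_features, feature_point_rmse,
                          fit_pca)

__all__ = ["RobustnessResult", "stratified_subsets", "run_robustness",
           "VirtualCohort", "sample_virtual_cohort"]

DEFAULT_FRACTIONS = (0.5, 0.6, 0.7, 0.8, 0.9)


def stratified_subsets(labels: np.ndarray, fraction: float,
                       n_repeats: int = 10, seed: int = 0) -> list[np.ndarray]:
    """Index sets preserving the class proportion (without replacement).

    Per class, round(fraction * n_class) cases are drawn; rounding may
    return the full class at fractions near 1 (then repeats coincide).
    """
    labels = np.asarray(labels).astype(int)
    if not 0 < fraction <= 1:
        raise ParameterError("fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    idx0 = np.flatnonzero(labels == 0)
    idx1 = np.flatnonzero(labels == 1)
    m0 = int(round(fraction * len(idx0)))
    m1 = int(round(fraction * len(idx1)))
    if m0 == 0 or m1 == 0:
        raise InsufficientDataError(
            f"fraction {fraction} leaves a class empty after rounding")
    subsets = []
    for _ in range(n_repeats):
        pick = np.concatenate([rng.choice(idx0, m0, replace=False),
                               rng.choice(idx1, m1, replace=False)])
        subsets.append(np.sort(pick))
    return subsets


@dataclass
class RobustnessResult:
    """Per-fraction AUC statistics and mean +/-3SD phenotypes."""

    fractions: np.ndarray
    auc_rs: np.ndarray        # (n_fractions, n_repeats)
    auc_loocv: np.ndarray     # (n_fractions, n_repeats)
    phenotype_minus: np.ndarray   # (n_fractions, 4N) mean -3SD shape vectors
    phenotype_plus: np.ndarray    # (n_fractions, 4N)
    phenotype_distance: np.ndarray  # (n_fractions,) RMSE mm to full phenotypes
    full_auc_rs: float
    full_auc_loocv: float
    counts: tuple[int, int, int] = (25, 25, 51)
    n_repeats: int = 10
    k: int = 10

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, f in enumerate(self.fractions):
            for r in range(self.auc_rs.shape[1]):
                rows.append({"fraction": float(f), "repeat": r,
                             "auc_rs": self.auc_rs[i, r],
                             "auc_loocv": self.auc_loocv[i, r]})
        return pd.DataFrame(rows)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "fraction": self.fractions,
            "auc_rs_mean": self.auc_rs.mean(axis=1),
            "auc_rs_sd": self.auc_rs.std(axis=1, ddof=1),
            "auc_loocv_mean": self.auc_loocv.mean(axis=1),
            "auc_loocv_sd": self.auc_loocv.std(axis=1, ddof=1),
            "phenotype_distance_mm": self.phenotype_distance,
        })

    def mean_phenotypes(self, fraction_index: int):
        minus = disassemble_features(self.phenotype_minus[fraction_index],
                                     self.counts)
        plus = disassemble_features(self.phenotype_plus[fraction_index],
                                    self.counts)
        return minus, plus


def _fit_and_score(features: np.ndarray, labels: np.ndarray, k: int,
                   sd_multiple: float):
    model = fit_pca(features)
    kk = min(k, model.n_modes)
    coeffs = model.coefficients[:, :kk]
    axis = fit_lda(coeffs, labels)
    rs = auc(risk_scores(axis, coeffs), labels)
    lo = auc(loocv_scores(coeffs, labels), labels)
    minus, plus = lda_extreme_shapes(model, axis, sd_multiple)
    from .shape_model import assemble_features
    vec_minus = assemble_features([minus])[0]
    vec_plus = assemble_features([plus])[0]
    return rs, lo, vec_minus, vec_plus


def run_robustness(features: np.ndarray, labels: np.ndarray,
                   fractions=DEFAULT_FRACTIONS, n_repeats: int = 10,
                   k: int = 10, sd_multiple: float = 3.0, seed: int = 0,
                   counts: tuple[int, int, int] = (25, 25, 51)
                   ) -> RobustnessResult:
    """Stratified-subsampling study over a cohort feature matrix.

    Phenotype averaging over repeats is done pointwise in feature space
    (valid because all cases share correspondence); the reported
    phenotype distance is the geometric RMSE (coordinates only) between
    the per-fraction mean phenotypes and the full-cohort ones, averaged
    over the two extremes.
    """
    X = np.asarray(features, dtype=float)
    labels = np.asarray(labels).astype(int)
    fractions = np.asarray(fractions, dtype=float)

    full_rs, full_lo, full_minus, full_plus = _fit_and_score(
        X, labels, k, sd_multiple)

    n_f = len(fractions)
    auc_rs = np.empty((n_f, n_repeats))
    auc_lo = np.empty((n_f, n_repeats))
    phen_minus = np.empty((n_f, X.shape[1]))
    phen_plus = np.empty((n_f, X.shape[1]))
    dist = np.empty(n_f)
    rng = np.random.default_rng(seed)
    for i, f in enumerate(fractions):
        subs = stratified_subsets(labels, float(f), n_repeats,
                                  seed=int(rng.integers(0, 2**31 - 1)))
        vm = np.empty((n_repeats, X.shape[1]))
        vp = np.empty((n_repeats, X.shape[1]))
        for r, idx in enumerate(subs):
            rs, lo, m_vec, p_vec = _fit_and_score(X[idx], labels[idx], k,
                                                  sd_multiple)
            auc_rs[i, r] = rs
            auc_lo[i, r] = lo
            vm[r] = m_vec
            vp[r] = p_vec
        phen_minus[i] = vm.mean(axis=0)
        phen_plus[i] = vp.mean(axis=0)
        dist[i] = 0.5 * (feature_point_rmse(phen_minus[i], full_minus, counts)
                         + feature_point_rmse(phen_plus[i], full_plus, counts))
    return RobustnessResult(fractions=fractions, auc_rs=auc_rs,
                            auc_loocv=auc_lo, phenotype_minus=phen_minus,
                            phenotype_plus=phen_plus, phenotype_distance=dist,
                            full_auc_rs=full_rs, full_auc_loocv=full_lo,
                            counts=counts, n_repeats=n_repeats, k=k)


@dataclass
class VirtualCohort:
    """Synthetic cases sampled from a fitted shape model."""

    coefficients: np.ndarray  # (n, n_modes)
    features: np.ndarray      # (n, 4N)
    scores: np.ndarray | None
    counts: tuple[int, int, int]
    case_ids: list[str] = field(default_factory=list)

    @property
    def n_cases(self) -> int:
        return self.features.shape[0]

    def to_arches(self) -> list[ArchCenterline]:
        return [disassemble_features(v, self.counts) for v in self.features]


def sample_virtual_cohort(model: ShapeModel, n: int, seed: int = 0,
                          axis: DiscriminantAxis | None = None) -> VirtualCohort:
    """Draw n cases with independent Gaussian mode coefficients.

    Coefficients for mode k are sampled from N(0, variance_k); shapes are
    reconstructed from the full mode set, and risk scores are attached
    when a discriminant axis is supplied.
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    rng = np.random.default_rng(seed)
    sds = np.sqrt(np.maximum(model.variances, 0.0))
    coeffs = rng.normal(0.0, 1.0, size=(n, model.n_modes)) * sds
    features = model.mean[None, :] + coeffs @ model.modes
    scores = risk_scores(axis, coeffs) if axis is not None else None
    ids = [f"virtual_{i:05d}" for i in range(n)]
    return VirtualCohort(coefficients=coeffs, features=features, scores=scores,
                         counts=model.counts, case_ids=ids)
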