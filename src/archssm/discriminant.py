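"""Fisher discriminant shape scoring over PCA coefficients.

A Fisher linear discriminant over the first k shape coefficients yields
a single anatomical deformation axis separating the two outcome groups.
Projections onto it, standardized to cohort Z-scores and oriented so the
coarctation-like class scores higher, form the shape risk score.
Classification performance is summarized by rank-based AUC both in
resubstitution (RS, train = test) and leave-one-out cross-validation
(LOOCV); sweeping k = 1..25 exposes the overfitting signature (growing
RS-LOOCV gap) used to select the working number of modes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .centerline import ArchCenterline
from .errors import ConditioningError, InsufficientDataError, ParameterError
from .shape_model import ShapeModel, disassemble_features, fit_pca, project

__all__ = [
    "DiscriminantAxis", "SweepResult", "fit_lda", "risk_scores", "auc",
    "loocv_scores", "sweep_modes", "lda_extreme_shapes", "scores_table",
]


@dataclass
class DiscriminantAxis:
    """Fisher LDA weights over the first k shape coefficients.

    Scores are standardized with the training-cohort mean/SD (Z-scores)
    and oriented so the class-1 (coarctation-like) mean is positive.
    """

    k: int
    weights: np.ndarray      # (k,)
    score_mean: float        # cohort mean of raw projections
    score_sd: float          # cohort SD (ddof=1) of raw projections
    orientation: int = 1     # +1: higher score = class 1 (kept for audit)

    def to_dict(self) -> dict:
        return {"k": int(self.k), "weights": self.weights.tolist(),
                "score_mean": float(self.score_mean),
                "score_sd": float(self.score_sd),
                "orientation": int(self.orientation)}

    @classmethod
    def from_dict(cls, d: dict) -> "DiscriminantAxis":
        return cls(int(d["k"]), np.asarray(d["weights"], dtype=float),
                   float(d["score_mean"]), float(d["score_sd"]),
                   int(d.get("orientation", 1)))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "DiscriminantAxis":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _check_two_classes(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels).astype(int)
    if set(np.unique(labels)) != {0, 1}:
        raise InsufficientDataError("labels must contain both classes 0 and 1")
    return labels


def fit_lda(coefficients: np.ndarray, labels: np.ndarray,
            ridge: float = 1e-8) -> DiscriminantAxis:
    """Fit the Fisher direction w ~ S_w^-1 (mu_1 - mu_0).

    S_w is the pooled within-class covariance, ridge-regularized on the
    diagonal by ``ridge * trace(S_w) / k`` for invertibility when k
    approaches the class sizes.
    """
    X = np.atleast_2d(np.asarray(coefficients, dtype=float))
    labels = _check_two_classes(labels)
    if X.shape[0] != labels.shape[0]:
        raise ParameterError("coefficients and labels disagree in length")
    k = X.shape[1]
    if k < 1:
        raise ParameterError("k must be >= 1")
    x0, x1 = X[labels == 0], X[labels == 1]
    n0, n1 = len(x0), len(x1)
    scatter = ((x0 - x0.mean(axis=0)).T @ (x0 - x0.mean(axis=0))
               + (x1 - x1.mean(axis=0)).T @ (x1 - x1.mean(axis=0)))
    dof = max(n0 + n1 - 2, 1)
    sw = scatter / dof
    tr = np.trace(sw)
    sw = sw + (ridge * tr / k if tr > 0 else ridge) * np.eye(k)
    try:
        w = np.linalg.solve(sw, x1.mean(axis=0) - x0.mean(axis=0))
    except np.linalg.LinAlgError as exc:
        raise ConditioningError(f"within-class scatter is singular: {exc}")
    if not np.all(np.isfinite(w)) or np.linalg.norm(w) == 0:
        raise ConditioningError("Fisher direction is degenerate")
    raw = X @ w
    if raw[labels == 1].mean() < raw[labels == 0].mean():
        w = -w
        raw = -raw
    sd = float(raw.std(ddof=1))
    if sd == 0:
        raise ConditioningError("scores are constant; cannot standardize")
    return DiscriminantAxis(k=k, weights=w, score_mean=float(raw.mean()),
                            score_sd=sd)


def risk_scores(axis: DiscriminantAxis, coefficients: np.ndarray) -> np.ndarray:
    """Standardized shape risk scores (Z-scores) for given coefficients."""
    X = np.atleast_2d(np.asarray(coefficients, dtype=float))[:, :axis.k]
    return (X @ axis.weights - axis.score_mean) / axis.score_sd


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based (Mann-Whitney) AUC; ties count 0.5."""
    labels = _check_two_classes(labels)
    scores = np.asarray(scores, dtype=float)
    ranks = stats.rankdata(scores)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    u = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n0 * n1))


def loocv_scores(coefficients: np.ndarray, labels: np.ndarray,
                 ridge: float = 1e-8) -> np.ndarray:
    """Score each case with an LDA refit on the remaining cases.

    Each fold's axis carries its own cohort standardization; the pooled
    out-of-fold Z-scores feed one rank AUC.
    """
    X = np.atleast_2d(np.asarray(coefficients, dtype=float))
    labels = _check_two_classes(labels)
    n = len(labels)
    out = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        fold = fit_lda(X[mask], labels[mask], ridge=ridge)
        out[i] = risk_scores(fold, X[i:i + 1])[0]
    return out


@dataclass
class SweepResult:
    """Per-k RS and LOOCV AUC for LDA models over growing mode counts."""

    ks: np.ndarray
    auc_rs: np.ndarray
    auc_loocv: np.ndarray
    selected_k: int
    gap_tol: float = 0.02
    overfit_tol: float = 0.05

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"k": self.ks, "auc_rs": self.auc_rs,
                             "auc_loocv": self.auc_loocv})


def select_k(ks: np.ndarray, auc_rs: np.ndarray, auc_loocv: np.ndarray,
             gap_tol: float = 0.02, overfit_tol: float = 0.05) -> int:
    """Pick the working mode count from a sweep.

    Rule (explicit stand-in for by-eye selection): the largest k whose
    LOOCV AUC is within ``gap_tol`` of the running LOOCV maximum and
    whose RS-LOOCV gap is at most ``overfit_tol``.
    """
    running_max = np.maximum.accumulate(auc_loocv)
    ok = (auc_loocv >= running_max - gap_tol) & (auc_rs - auc_loocv <= overfit_tol)
    if not ok.any():
        return int(ks[int(np.argmax(auc_loocv))])
    return int(ks[np.flatnonzero(ok)[-1]])


def sweep_modes(model: ShapeModel, labels: np.ndarray, k_max: int = 25,
                ridge: float = 1e-8, gap_tol: float = 0.02,
                overfit_tol: float = 0.05, refit_pca: bool = False,
                features: np.ndarray | None = None) -> SweepResult:
    """Build LDA models on the first k = 1..k_max modes and score each.

    By default LOOCV refits the LDA only, on the fixed full-cohort PCA
    basis.  With ``refit_pca=True`` (requires the raw ``features``
    matrix) the PCA basis itself is refit per fold and the held-out case
    is projected onto the fold basis before scoring.
    """
    labels = _check_two_classes(labels)
    if k_max < 1 or k_max > model.n_modes:
        raise ParameterError(f"k_max must be in [1, {model.n_modes}]")
    if refit_pca and features is None:
        raise ParameterError("refit_pca=True requires the feature matrix")
    ks = np.arange(1, k_max + 1)
    auc_rs = np.empty(k_max)
    auc_lo = np.empty(k_max)
    for j, k in enumerate(ks):
        coeffs = model.coefficients[:, :k]
        axis = fit_lda(coeffs, labels, ridge=ridge)
        auc_rs[j] = auc(risk_scores(axis, coeffs), labels)
        if refit_pca:
            lo = _loocv_scores_refit_pca(features, labels, k, ridge)
        else:
            lo = loocv_scores(coeffs, labels, ridge=ridge)
        auc_lo[j] = auc(lo, labels)
    sel = select_k(ks, auc_rs, auc_lo, gap_tol, overfit_tol)
    return SweepResult(ks=ks, auc_rs=auc_rs, auc_loocv=auc_lo, selected_k=sel,
                       gap_tol=gap_tol, overfit_tol=overfit_tol)


def _loocv_scores_refit_pca(features: np.ndarray, labels: np.ndarray,
                            k: int, ridge: float) -> np.ndarray:
    X = np.asarray(features, dtype=float)
    n = X.shape[0]
    out = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        fold_model = fit_pca(X[mask])
        kk = min(k, fold_model.n_modes)
        fold_axis = fit_lda(fold_model.coefficients[:, :kk], labels[mask],
                            ridge=ridge)
        b = project(fold_model, X[i], kk)
        out[i] = risk_scores(fold_axis, b[None])[0]
    return out


def lda_extreme_shapes(model: ShapeModel, axis: DiscriminantAxis,
                       sd_multiple: float = 3.0
                       ) -> tuple[ArchCenterline, ArchCenterline]:
    """Anatomies at Z = -sd_multiple and +sd_multiple along the risk axis.

    The score direction is mapped back to shape space through the PCA
    modes with the regression (conditional-mean) displacement per unit
    Z-score, d = s * Lambda w / (w' Lambda w), where Lambda holds the
    per-mode variances: the shape at Z is the population-typical anatomy
    at that score.  The emitted shape, re-projected and re-scored,
    returns exactly the requested Z (mean shape at Z = 0).
    """
    if axis.k > model.n_modes:
        raise ParameterError("axis uses more modes than the model provides")
    w = axis.weights
    lam_w = model.variances[:axis.k] * w
    d = axis.score_sd * lam_w / (w @ lam_w)
    shapes = []
    for z in (-sd_multiple, sd_multiple):
        vec = model.mean + (z * d) @ model.modes[:axis.k]
        shapes.append(disassemble_features(vec, model.counts))
    return shapes[0], shapes[1]


def scores_table(case_ids: list[str], labels: np.ndarray, z: np.ndarray,
                 loocv_z: np.ndarray | None = None) -> pd.DataFrame:
    """Per-case risk-score table (`case_id,label,z_score,loocv_z_score`)."""
    data = {"case_id": case_ids, "label": np.asarray(labels).astype(int),
            "z_score": np.asarray(z, dtype=float)}
    data["loocv_z_score"] = (np.full(len(case_ids), np.nan)
                             if loocv_z is None else np.asarray(loocv_z))
    return pd.DataFrame(data)
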