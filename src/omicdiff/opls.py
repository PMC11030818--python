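"""Orthogonal projections to latent structures discriminant analysis.

OPLS-DA splits the predictor matrix X into a component predictive of
the class vector y and components orthogonal to it (systematic
variation uncorrelated with class).  For a single response the model
is::

    X = t p' + sum_a t_o,a p_o,a' + E,      y = t q + f

where the orthogonal weights are deflated from the X-space before the
single predictive component is extracted.  Variable influence on
projection (VIP) scores are computed from the predictive component
only; their squares average to 1, so VIP >= 1 marks variables with
above-average influence.  Model quality is summarized by R2Y (fitted
fraction of y-variance), Q2 (cross-validated fraction) and a label
permutation test guarding against overfitting.

Preprocessing follows common metabolomics practice for peak-area
matrices: missing areas are floored at half the metabolite's minimum
observed area, then log2-transformed and mean-centered per variable
(no unit-variance scaling).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .io import MetaboliteTable, SampleSheet

__all__ = [
    "OplsModel",
    "PermutationResult",
    "preprocess",
    "fit_opls_da",
    "vip_scores",
    "predict",
    "q2_cross_validation",
    "permutation_test",
]


@dataclass
class OplsModel:
    """Fitted OPLS-DA decomposition for a single two-class response."""

    weights: np.ndarray          # predictive weights w, unit norm, shape (p,)
    scores: np.ndarray           # predictive scores t, shape (n,)
    loadings: np.ndarray         # predictive loadings p, shape (p,)
    y_loading: float             # q
    ortho_weights: np.ndarray    # shape (k_ortho, p)
    ortho_scores: np.ndarray     # shape (n, k_ortho)
    ortho_loadings: np.ndarray   # shape (k_ortho, p)
    r2x: float
    r2y: float
    q2: float | None = None

    @property
    def n_ortho(self) -> int:
        return self.ortho_weights.shape[0]


@dataclass
class PermutationResult:
    """Observed vs label-permuted model statistics.

    ``p = (1 + #{permuted >= observed}) / (1 + n_perm)`` — the add-one
    rule keeps p strictly positive, with floor ``1/(n_perm+1)``.
    """

    observed_q2: float
    observed_r2y: float
    permuted_q2: list[float] = field(default_factory=list)
    permuted_r2y: list[float] = field(default_factory=list)
    p_value_q2: float = 1.0
    p_value_r2y: float = 1.0


def preprocess(
    table: MetaboliteTable,
    contrast: tuple[str, str],
    sheet: SampleSheet,
) -> tuple[np.ndarray, np.ndarray, list[str], list[str]]:
    """Build the (samples x metabolites) model matrix for a contrast.

    Missing areas are replaced by half the metabolite's minimum
    observed area over the selected samples; the matrix is then
    log2-transformed and column-wise mean-centered.  y is +1 for the
    first (numerator) group and -1 for the second.

    Returns ``(X, y, metabolite_ids, sample_ids)``.
    """
    group_a, group_b = contrast
    samples_a = sheet.samples(group_a)
    samples_b = sheet.samples(group_b)
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError("each group needs >= 2 samples for OPLS-DA cross-validation")
    cols = samples_a + samples_b
    missing_cols = [c for c in cols if c not in table.values.columns]
    if missing_cols:
        raise KeyError(f"samples missing from metabolite table: {missing_cols}")
    areas = table.values[cols].copy()

    # floor imputation: half the row's minimum observed area
    row_min = areas.min(axis=1, skipna=True)
    fill = row_min / 2.0
    keep = row_min.notna() & (row_min > 0)
    if not keep.all():
        areas = areas.loc[keep]
        fill = fill.loc[keep]
    areas = areas.apply(lambda row: row.fillna(fill[row.name]), axis=1)
    if (areas.to_numpy() <= 0).any():
        raise ValueError("non-positive area after imputation; cannot log-transform")

    X = np.log2(areas.to_numpy(dtype=float).T)      # samples x metabolites
    X = X - X.mean(axis=0, keepdims=True)
    y = np.array([1.0] * len(samples_a) + [-1.0] * len(samples_b))
    return X, y, list(areas.index), cols


def fit_opls_da(X: np.ndarray, y: np.ndarray, k_ortho: int = 1) -> OplsModel:
    """Fit an OPLS model with ``k_ortho`` orthogonal components.

    X must be column-centered; y is a two-class vector.  The fit is
    fully deterministic (closed-form component extraction, no random
    initialization).  With ``k_ortho=0`` the model reduces to
    single-component PLS with ``w`` proportional to ``X'y``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be (n_samples, n_vars) aligned with y")
    ssx_total = float((X ** 2).sum())
    if ssx_total == 0:
        raise ValueError("X has zero variance")
    yc = y - y.mean()
    ssy_total = float((yc ** 2).sum())
    if ssy_total == 0:
        raise ValueError("y has a single class")

    n, p = X.shape
    Xr = X.copy()
    w_orthos, t_orthos, p_orthos = [], [], []
    for _ in range(k_ortho):
        w = Xr.T @ yc
        w_norm = np.linalg.norm(w)
        if w_norm == 0:
            break
        w = w / w_norm
        t = Xr @ w
        p_load = Xr.T @ t / (t @ t)
        w_o = p_load - (w @ p_load) * w
        w_o_norm = np.linalg.norm(w_o)
        if w_o_norm < 1e-12:       # no y-orthogonal variation left
            break
        w_o = w_o / w_o_norm
        t_o = Xr @ w_o
        p_o = Xr.T @ t_o / (t_o @ t_o)
        Xr = Xr - np.outer(t_o, p_o)
        w_orthos.append(w_o)
        t_orthos.append(t_o)
        p_orthos.append(p_o)

    w = Xr.T @ yc
    w_norm = np.linalg.norm(w)
    if w_norm == 0:
        raise ValueError("predictive weight vector is zero; X carries no y-covariance")
    w = w / w_norm
    t = Xr @ w
    p_load = Xr.T @ t / (t @ t)
    q = float(yc @ t / (t @ t))

    modeled = np.outer(t, p_load)
    for t_o, p_o in zip(t_orthos, p_orthos):
        modeled = modeled + np.outer(t_o, p_o)
    r2x = float((modeled ** 2).sum() / ssx_total)
    r2y = float(1.0 - ((yc - t * q) ** 2).sum() / ssy_total)

    k = len(w_orthos)
    return OplsModel(
        weights=w,
        scores=t,
        loadings=p_load,
        y_loading=q,
        ortho_weights=np.array(w_orthos).reshape(k, p),
        ortho_scores=np.array(t_orthos).T.reshape(X.shape[0], k),
        ortho_loadings=np.array(p_orthos).reshape(k, p),
        r2x=r2x,
        r2y=r2y,
    )


def predict(model: OplsModel, X_new: np.ndarray) -> np.ndarray:
    """Predict the (centered) response for new centered rows.

    Orthogonal components are filtered from ``X_new`` with the stored
    weights/loadings before projecting onto the predictive component.
    """
    Xf = np.asarray(X_new, dtype=float).copy()
    for w_o, p_o in zip(model.ortho_weights, model.ortho_loadings):
        t_o = Xf @ w_o
        Xf = Xf - np.outer(t_o, p_o)
    return (Xf @ model.weights) * model.y_loading


def vip_scores(model: OplsModel) -> np.ndarray:
    """Variable influence on projection from the predictive component.

    With one predictive component of unit-norm weights,
    ``VIP_j = sqrt(p) * |w_j|``; the mean of VIP^2 over the p variables
    is exactly 1.
    """
    p = model.weights.shape[0]
    return np.sqrt(p) * np.abs(model.weights)


def _fold_indices(y: np.ndarray, n_folds: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    n = y.shape[0]
    _, counts = np.unique(y, return_counts=True)
    min_class = int(counts.min())
    if n_folds >= n:                      # leave-one-out
        idx = np.arange(n)
        return [(np.delete(idx, i), np.array([i])) for i in range(n)]
    n_splits = min(n_folds, min_class)
    if n_splits < 2:
        raise ValueError("cannot form >= 2 stratified folds with a class of size 1")
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed % (2 ** 31))
    return list(skf.split(np.zeros(n), y))


def q2_cross_validation(
    X: np.ndarray,
    y: np.ndarray,
    k_ortho: int = 1,
    n_folds: int = 7,
    seed: int = 0,
) -> float:
    """Cross-validated Q2 = 1 - PRESS/TSS for the OPLS model.

    Folds are stratified by class (clamped to the minority class size
    when n is small; ``n_folds >= n`` gives leave-one-out) and the
    assignment is deterministic given ``seed``.  Each training fold is
    re-centered before fitting and held-out samples are centered with
    the training means.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    press = 0.0
    for train, test in _fold_indices(y, n_folds, seed):
        y_train = y[train]
        if np.unique(y_train).size < 2:
            raise ValueError("degenerate fold: training set has one class")
        x_mean = X[train].mean(axis=0)
        y_mean = y_train.mean()
        model = fit_opls_da(X[train] - x_mean, y_train, k_ortho=k_ortho)
        y_hat = predict(model, X[test] - x_mean) + y_mean
        press += float(((y[test] - y_hat) ** 2).sum())
    tss = float(((y - y.mean()) ** 2).sum())
    return 1.0 - press / tss


def permutation_test(
    X: np.ndarray,
    y: np.ndarray,
    k_ortho: int = 1,
    n_perm: int = 200,
    seed: int = 0,
    n_folds: int = 7,
) -> PermutationResult:
    """Label permutation test of R2Y and Q2.

    y is permuted uniformly at random ``n_perm`` times; R2Y and Q2 are
    recomputed for each permutation with the same fold scheme as the
    observed model.  Deterministic given ``seed``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    fold_seed = int(rng.integers(2 ** 31))
    observed_r2y = fit_opls_da(X, y, k_ortho=k_ortho).r2y
    observed_q2 = q2_cross_validation(X, y, k_ortho=k_ortho, n_folds=n_folds, seed=fold_seed)

    permuted_r2y: list[float] = []
    permuted_q2: list[float] = []
    for _ in range(n_perm):
        y_perm = rng.permutation(y)
        permuted_r2y.append(fit_opls_da(X, y_perm, k_ortho=k_ortho).r2y)
        permuted_q2.append(
            q2_cross_validation(X, y_perm, k_ortho=k_ortho, n_folds=n_folds, seed=fold_seed)
        )

    p_q2 = (1 + sum(q >= observed_q2 for q in permuted_q2)) / (1 + n_perm)
    p_r2y = (1 + sum(r >= observed_r2y for r in permuted_r2y)) / (1 + n_perm)
    return PermutationResult(
        observed_q2=observed_q2,
        observed_r2y=observed_r2y,
        permuted_q2=permuted_q2,
        permuted_r2y=permuted_r2y,
        p_value_q2=p_q2,
        p_value_r2y=p_r2y,
    )
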