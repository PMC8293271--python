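"""One-component PLS1 with SIMCA-style diagnostics.

All models in the pipeline use exactly one latent variable: the weight
vector of a single-component NIPALS fit is the normalized covariance
direction ``w = X'y / ||X'y||``, so the fit is closed-form. Reported
diagnostics follow chemometrics conventions: R2X and R2Y (explained
variance of predictors and response), Q2 and RMSECv from k-fold
cross-validation with per-fold rescaling, RMSEE with n - 1 - A degrees
of freedom, VIP scores (mean VIP^2 = 1), response-permutation validation
with R2Y/Q2 intercepts, and a Hotelling-T2 PCA outlier screen.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from hepamark._rng import child_rng
from hepamark.preprocess import pareto_scale

__all__ = [
    "DegenerateModelError",
    "PLSModel",
    "PermutationResult",
    "OutlierScreen",
    "fit_pls1",
    "vip",
    "rmsee",
    "q2_rmsecv",
    "permutation_validation",
    "pca_outlier_screen",
]


class DegenerateModelError(ValueError):
    """No latent direction exists (X'y vanishes or y is constant)."""


@dataclass
class PLSModel:
    """A fitted one-component PLS1 model.

    ``weights`` has unit norm; scores ``t = X w``; predictions in
    original response units are ``y_loading * t + y_center``.
    """

    weights: np.ndarray
    scores: np.ndarray
    x_loadings: np.ndarray
    y_loading: float
    y_center: float
    r2x: float
    r2y: float
    vip: np.ndarray
    feature_names: list = field(default_factory=list)
    n_components: int = 1

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return self.y_loading * (X @ self.weights) + self.y_center


def _as_matrix(X) -> tuple[np.ndarray, list]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    X = np.asarray(X, dtype=float)
    return X, list(range(X.shape[1]))


def fit_pls1(X, y, center_y: bool = True) -> PLSModel:
    """Fit a one-component PLS1 model to a pre-scaled predictor matrix.

    ``X`` is expected already column-scaled (Pareto in this pipeline);
    only ``y`` is centered here. Raises :class:`DegenerateModelError`
    when the response has no covariance with any predictor.
    """
    Xm, names = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    n, p = Xm.shape
    if n != len(y):
        raise ValueError("X and y have incompatible shapes")
    if n < 3:
        raise ValueError("need at least 3 samples")

    y_center = y.mean() if center_y else 0.0
    yc = y - y_center

    cov = Xm.T @ yc
    cov_norm = np.linalg.norm(cov)
    if cov_norm == 0:
        raise DegenerateModelError("X'y = 0: no latent direction")
    w = cov / cov_norm
    t = Xm @ w
    tt = float(t @ t)
    if tt == 0:
        raise DegenerateModelError("zero score vector")
    p_load = Xm.T @ t / tt
    q = float(yc @ t / tt)

    ss_x = float(np.sum(Xm * Xm))
    ss_y = float(yc @ yc)
    if ss_y == 0:
        raise DegenerateModelError("constant response")
    r2x = tt * float(p_load @ p_load) / ss_x if ss_x > 0 else 0.0
    r2y = q * q * tt / ss_y

    vip_scores = np.sqrt(p) * np.abs(w)
    return PLSModel(
        weights=w,
        scores=t,
        x_loadings=p_load,
        y_loading=q,
        y_center=y_center,
        r2x=r2x,
        r2y=r2y,
        vip=vip_scores,
        feature_names=names,
    )


def vip(model: PLSModel) -> np.ndarray:
    """Variable importance in the projection.

    With one component ``VIP_j = sqrt(p) * |w_j|``, hence
    ``sum(VIP^2) = p`` and ``mean(VIP^2) = 1``.
    """
    return model.vip


def rmsee(model: PLSModel, X, y) -> float:
    """Root mean square error of estimation, ``sqrt(RSS / (n - 1 - A))``
    with A = 1 fitted component, in original response units."""
    Xm, _ = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n <= 2:
        raise ValueError("RMSEE undefined for n <= 2 with one component")
    resid = y - model.predict(Xm)
    return float(np.sqrt(resid @ resid / (n - 1 - model.n_components)))


def _fold_assignment(n: int, folds: int, seed: int) -> np.ndarray:
    """Seeded shuffle then round-robin fold ids."""
    order = child_rng(seed, "cv").permutation(n)
    fold_of = np.empty(n, dtype=int)
    fold_of[order] = np.arange(n) % folds
    return fold_of


def _prepare_folds(Xdf: pd.DataFrame, folds: int, seed: int, scale: str) -> list:
    """Precompute per-fold train/test masks and scaled matrices.

    The scaling depends only on X and the fold assignment, so permuting
    the response can reuse this cache.
    """
    n = len(Xdf)
    if folds < 2 or folds > n:
        raise ValueError("need 2 <= folds <= n")
    fold_of = _fold_assignment(n, folds, seed)
    prepared = []
    for k in range(folds):
        test = fold_of == k
        train = ~test
        if train.sum() < 2:
            raise ValueError(f"fold {k} leaves fewer than 2 training samples")
        Xtr, Xte = Xdf.loc[train], Xdf.loc[test]
        if scale == "pareto":
            sc = pareto_scale(Xtr)
            Xtr_s = sc.scaled.to_numpy()
            safe = sc.scale.replace(0.0, np.nan)
            Xte_s = Xte.sub(sc.center, axis=1).div(safe, axis=1).fillna(0.0).to_numpy()
        elif scale == "none":
            Xtr_s, Xte_s = Xtr.to_numpy(dtype=float), Xte.to_numpy(dtype=float)
        else:
            raise ValueError(f"unknown scale {scale!r}")
        prepared.append((train, test, Xtr_s, Xte_s))
    return prepared


def _cv_press(prepared: list, y: np.ndarray) -> tuple[float, float]:
    """PRESS and training-centered SS for one response vector."""
    press = 0.0
    ss_total = 0.0
    for train, test, Xtr_s, Xte_s in prepared:
        ytr, yte = y[train], y[test]
        model = fit_pls1(Xtr_s, ytr)
        yhat = model.predict(Xte_s)
        press += float(np.sum((yte - yhat) ** 2))
        ss_total += float(np.sum((yte - ytr.mean()) ** 2))
    return press, ss_total


def q2_rmsecv(
    X,
    y,
    folds: int = 7,
    seed: int = 0,
    scale: str = "pareto",
    ss: str = "train_centered",
) -> tuple[float, float]:
    """Cross-validated predictive ability and prediction error.

    ``X`` is the unscaled matrix: scaling (Pareto by default, ``scale=
    "none"`` to disable) and the PLS refit happen inside each training
    fold, and test rows are transformed with training factors only.
    Samples are assigned to folds round-robin after a seeded shuffle.
    ``Q2 = 1 - PRESS/SS`` where SS centers each test response on its
    training-fold mean (SIMCA convention; ``ss="global"`` uses the
    overall centered sum of squares). ``RMSECv = sqrt(PRESS / n)``.
    """
    Xdf = pd.DataFrame(X)
    y = np.asarray(y, dtype=float)
    n = len(y)
    prepared = _prepare_folds(Xdf, folds, seed, scale)
    press, ss_total = _cv_press(prepared, y)
    if ss == "global":
        ss_total = float(np.sum((y - y.mean()) ** 2))
    elif ss != "train_centered":
        raise ValueError(f"unknown ss {ss!r}")
    q2 = 1.0 - press / ss_total
    return q2, float(np.sqrt(press / n))


@dataclass
class PermutationResult:
    """Response-permutation validation of a PLS1 model.

    ``records`` holds one row per permutation (correlation of the
    permuted response with the original, refitted R2Y, cross-validated
    Q2); the original model appears as the point at correlation 1.0.
    Least-squares lines through each series give the reported intercepts;
    a Q2 intercept below zero is the conventional sign of a valid model.
    """

    records: pd.DataFrame
    original_r2y: float
    original_q2: float
    intercept_r2y: float
    intercept_q2: float
    n_perm: int
    seed: int
    degenerate: bool = False


def permutation_validation(
    X,
    y,
    n_perm: int = 500,
    seed: int = 0,
    folds: int = 7,
) -> PermutationResult:
    """Refit the model on ``n_perm`` response-permuted copies of the data.

    ``X`` is unscaled; each permuted fit Pareto-scales the full matrix
    (the X block is kept intact, only y is permuted) and the Q2 of each
    permuted model comes from the same cross-validation scheme as the
    original. Deterministic given ``seed``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    y = np.asarray(y, dtype=float)
    if np.std(y) == 0:
        return PermutationResult(
            records=pd.DataFrame(columns=["corr", "r2y", "q2"]),
            original_r2y=np.nan,
            original_q2=np.nan,
            intercept_r2y=np.nan,
            intercept_q2=np.nan,
            n_perm=0,
            seed=seed,
            degenerate=True,
        )

    Xdf = pd.DataFrame(X)
    X_scaled = pareto_scale(Xdf).scaled.to_numpy()
    original = fit_pls1(X_scaled, y)
    prepared = _prepare_folds(Xdf, folds, seed, "pareto")
    press, ss_tot = _cv_press(prepared, y)
    original_q2 = 1.0 - press / ss_tot

    rows = []
    for i in range(n_perm):
        rng = child_rng(seed, "perm", i)
        yp = rng.permutation(y)
        corr = float(np.corrcoef(yp, y)[0, 1])
        try:
            m = fit_pls1(X_scaled, yp)
            r2y_p = m.r2y
            press_p, ss_p = _cv_press(prepared, yp)
            q2_p = 1.0 - press_p / ss_p
        except DegenerateModelError:  # pragma: no cover - pathological
            r2y_p, q2_p = np.nan, np.nan
        rows.append({"corr": corr, "r2y": r2y_p, "q2": q2_p})
    records = pd.DataFrame(rows)

    cx = np.append(records["corr"].to_numpy(), 1.0)
    int_r2y = np.polyfit(cx, np.append(records["r2y"].to_numpy(), original.r2y), 1)[1]
    int_q2 = np.polyfit(cx, np.append(records["q2"].to_numpy(), original_q2), 1)[1]
    return PermutationResult(
        records=records,
        original_r2y=original.r2y,
        original_q2=original_q2,
        intercept_r2y=float(int_r2y),
        intercept_q2=float(int_q2),
        n_perm=n_perm,
        seed=seed,
    )


@dataclass
class OutlierScreen:
    """Hotelling-T2 screen on the leading principal components.

    Advisory only: flagged samples are reported, never dropped
    automatically.
    """

    t2: np.ndarray
    limit: float
    flags: np.ndarray
    n_pc: int


def pca_outlier_screen(X, n_pc: int = 2, alpha: float = 0.05) -> OutlierScreen:
    """Flag samples outside the (1 - alpha) Hotelling-T2 ellipse of the
    first ``n_pc`` PCA scores."""
    if n_pc <= 0:
        raise ValueError("n_pc must be >= 1")
    Xm, _ = _as_matrix(X)
    n = Xm.shape[0]
    if n < n_pc + 2:
        raise ValueError("need n >= n_pc + 2 samples")
    Xc = Xm - Xm.mean(axis=0)
    u, s, _ = np.linalg.svd(Xc, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-12)) if s.size else 0
    if rank < n_pc:
        warnings.warn(f"rank {rank} < n_pc={n_pc}; reducing", stacklevel=2)
        n_pc = rank
    scores = u[:, :n_pc] * s[:n_pc]
    var = (s[:n_pc] ** 2) / (n - 1)
    t2 = np.sum(scores**2 / var, axis=1)
    f_crit = stats.f.ppf(1 - alpha, n_pc, n - n_pc)
    limit = n_pc * (n - 1) * (n + 1) / (n * (n - n_pc)) * f_crit
    return OutlierScreen(t2=t2, limit=float(limit), flags=t2 > limit, n_pc=n_pc)
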