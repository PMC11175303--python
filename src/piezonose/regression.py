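"""PLS1 regression (projection on latent structures) with full cross-validation.

The model is fitted by the NIPALS algorithm on block-scaled features with a
centered response, giving a deterministic factorisation (no random
initialisation).  Model checking uses full (leave-one-out) cross-validation
in which the scaling is re-learned inside every fold.  Variable selection
iteratively removes features with small regression coefficients or high
variable leverage until the cross-validated RMSEP stops improving.

Reported metrics follow the usual chemometrics conventions:
RMSEP = sqrt(mean squared cross-validated residual); R^2 computed on the
cross-validated predictions; the relative prediction error
Delta% = 100 * RMSEP / max(y_train).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .preprocessing import (
    BLOCK_CURVE,
    BLOCK_MAX,
    BLOCK_PARAM,
    ScalingRecipe,
    apply_block_scaling,
    fit_block_scaling,
)
from .features import block_label
from .signal_io import RunConfig

_EPS = 1e-12


# ---------------------------------------------------------------------------
# NIPALS core (scaled space)
# ---------------------------------------------------------------------------


def _nipals_path(
    Xs: np.ndarray, yc: np.ndarray, n_factors: int
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, List[np.ndarray]]:
    """NIPALS PLS1 on scaled X and centered y.

    Returns weights W, loadings P, y-loadings q, score norms (t_f' t_f) and
    the cumulative coefficient vector after each factor.  Stops early when
    the residual covariance vanishes.
    """
    n, p = Xs.shape
    X = Xs.copy()
    y = yc.copy()
    W, P, q, tss = [], [], [], []
    b_path: List[np.ndarray] = []
    for _ in range(n_factors):
        w = X.T @ y
        nw = np.linalg.norm(w)
        if nw < _EPS:
            break
        w = w / nw
        t = X @ w
        tt = float(t @ t)
        if tt < _EPS:
            break
        pl = X.T @ t / tt
        ql = float(y @ t / tt)
        X = X - np.outer(t, pl)
        y = y - ql * t
        W.append(w)
        P.append(pl)
        q.append(ql)
        tss.append(tt)
        Wm = np.column_stack(W)
        Pm = np.column_stack(P)
        qv = np.asarray(q)
        b_path.append(Wm @ np.linalg.solve(Pm.T @ Wm, qv))
    if not W:
        raise ValueError("response has no covariance with the features")
    return (
        np.column_stack(W),
        np.column_stack(P),
        np.asarray(q),
        np.asarray(tss),
        b_path,
    )


# ---------------------------------------------------------------------------
# Public model
# ---------------------------------------------------------------------------


@dataclass
class PLSModel:
    """Fitted PLS1 model in the block-scaled feature space."""

    recipe: ScalingRecipe
    columns: pd.Index  # training columns (before recipe exclusions)
    n_factors: int
    weights: np.ndarray  # p_kept x f
    loadings: np.ndarray  # p_kept x f
    y_loadings: np.ndarray  # f
    coef: np.ndarray  # p_kept, scaled space
    score_norms: np.ndarray  # t_f' t_f per factor
    y_mean: float
    y_max: float
    n_train: int
    rmsep: Optional[float] = None  # cross-validated, set after model checking

    @property
    def rotation(self) -> np.ndarray:
        """R = W (P'W)^-1, mapping scaled X to scores."""
        return self.weights @ np.linalg.inv(self.loadings.T @ self.weights)


def fit_pls(
    X: pd.DataFrame,
    y: Sequence[float],
    n_factors: int,
    block_labels: Optional[Dict[str, str]] = None,
) -> PLSModel:
    """Fit PLS1 on raw features; scaling is learned here and stored."""
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if len(y) != n:
        raise ValueError("X and y row counts differ")
    if np.std(y) == 0:
        raise ValueError("response is constant")
    if not 1 <= n_factors <= min(n - 1, p):
        raise ValueError(f"n_factors must be in [1, {min(n - 1, p)}]")
    labels = block_labels or {c: block_label(c) for c in X.columns}
    recipe = fit_block_scaling(X, labels)
    Xs = apply_block_scaling(X, recipe).to_numpy()
    y_mean = float(y.mean())
    W, P, q, tss, b_path = _nipals_path(Xs, y - y_mean, n_factors)
    return PLSModel(
        recipe=recipe,
        columns=X.columns,
        n_factors=W.shape[1],
        weights=W,
        loadings=P,
        y_loadings=q,
        coef=b_path[-1],
        score_norms=tss,
        y_mean=y_mean,
        y_max=float(y.max()),
        n_train=n,
    )


def predict(
    model: PLSModel, X_new: pd.DataFrame
) -> Tuple[np.ndarray, np.ndarray]:
    """Predict new samples; deviation = RMSEP * sqrt(1 + leverage).

    The new-sample leverage is computed in score space, so samples far from
    the training cloud get proportionally wider deviations; the deviation is
    never smaller than the model's RMSEP.  Requires ``model.rmsep`` (set by
    model checking); otherwise deviations are NaN.
    """
    missing = [c for c in model.columns if c not in X_new.columns]
    if missing:
        raise ValueError(f"missing feature columns: {missing[:5]}")
    Xs = apply_block_scaling(X_new[model.columns], model.recipe).to_numpy()
    yhat = model.y_mean + Xs @ model.coef
    scores = Xs @ model.rotation
    leverage = 1.0 / model.n_train + np.sum(scores**2 / model.score_norms, axis=1)
    if model.rmsep is None:
        deviation = np.full(len(yhat), np.nan)
    else:
        deviation = model.rmsep * np.sqrt(1.0 + leverage)
    return yhat, deviation


# ---------------------------------------------------------------------------
# Full (leave-one-out) cross-validation
# ---------------------------------------------------------------------------


@dataclass
class CVResult:
    rmsep_by_factor: pd.Series  # indexed by factor count
    n_factors: int  # argmin RMSEP, ties toward fewer factors
    predictions: np.ndarray  # LOO predictions at the chosen factor count


def _scale_fold(
    Xtr: np.ndarray, scaled_col: np.ndarray
) -> Tuple[np.ndarray, np.ndarray]:
    """Column means/scales learned on a training fold (NaN-aware).

    Zero-variance scaled columns get unit scale; after centering they are
    identically zero and carry no weight in NIPALS, which matches excluding
    them.
    """
    means = np.nanmean(Xtr, axis=0)
    filled = np.where(np.isnan(Xtr), means, Xtr)
    sds = np.std(filled, axis=0, ddof=1)
    scale = np.ones_like(sds)
    ok = scaled_col & (sds > 0)
    scale[ok] = sds[ok]
    return means, scale


def cross_validate(
    X: pd.DataFrame,
    y: Sequence[float],
    max_factors: int,
    block_labels: Optional[Dict[str, str]] = None,
) -> CVResult:
    """Leave-one-out RMSEP curve; scaling is re-learned without the held-out row."""
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n < 3:
        raise ValueError("need at least 3 rows for cross-validation")
    if max_factors >= n:
        raise ValueError("max_factors must be smaller than the row count")
    max_factors = min(max_factors, n - 2, p)
    labels = block_labels or {c: block_label(c) for c in X.columns}
    scaled_col = np.array(
        [labels[c] in (BLOCK_CURVE, BLOCK_MAX) for c in X.columns]
    )
    Xa = X.to_numpy(dtype=float)
    preds = np.full((n, max_factors), np.nan)
    for i in range(n):
        idx = np.arange(n) != i
        Xtr, ytr = Xa[idx], y[idx]
        means, scale = _scale_fold(Xtr, scaled_col)
        Xtr_s = (np.where(np.isnan(Xtr), means, Xtr) - means) / scale
        xi = Xa[i]
        xi_s = (np.where(np.isnan(xi), means, xi) - means) / scale
        y_mean = ytr.mean()
        _, _, _, _, b_path = _nipals_path(Xtr_s, ytr - y_mean, max_factors)
        for f, b in enumerate(b_path):
            preds[i, f] = y_mean + xi_s @ b
        # factors that vanished early keep the last available prediction
        for f in range(len(b_path), max_factors):
            preds[i, f] = preds[i, len(b_path) - 1]
    rmsep = np.sqrt(np.mean((preds - y[:, None]) ** 2, axis=0))
    chosen = int(np.argmin(rmsep)) + 1
    return CVResult(
        rmsep_by_factor=pd.Series(rmsep, index=np.arange(1, max_factors + 1)),
        n_factors=chosen,
        predictions=preds[:, chosen - 1],
    )


def grouped_rmsep(
    X: pd.DataFrame,
    y: Sequence[float],
    groups: Sequence,
    n_factors: int,
    block_labels: Optional[Dict[str, str]] = None,
) -> float:
    """Leave-one-group-out RMSEP at a fixed factor count.

    With replicated specimens, record-level leave-one-out keeps a specimen's
    sibling replicates in training and underestimates the error for a new
    specimen; holding out whole groups (specimens) estimates it honestly.
    Used to scale prediction deviations.
    """
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    labels = block_labels or {c: block_label(c) for c in X.columns}
    scaled_col = np.array(
        [labels[c] in (BLOCK_CURVE, BLOCK_MAX) for c in X.columns]
    )
    Xa = X.to_numpy(dtype=float)
    unique = pd.unique(groups)
    if len(unique) < 3:
        raise ValueError("need at least 3 groups")
    sq_sum, count = 0.0, 0
    for g in unique:
        held = groups == g
        Xtr, ytr = Xa[~held], y[~held]
        means, scale = _scale_fold(Xtr, scaled_col)
        Xtr_s = (np.where(np.isnan(Xtr), means, Xtr) - means) / scale
        Xte_s = (np.where(np.isnan(Xa[held]), means, Xa[held]) - means) / scale
        y_mean = ytr.mean()
        f = min(n_factors, len(ytr) - 1)
        _, _, _, _, b_path = _nipals_path(Xtr_s, ytr - y_mean, f)
        pred = y_mean + Xte_s @ b_path[-1]
        sq_sum += float(np.sum((pred - y[held]) ** 2))
        count += int(held.sum())
    return float(np.sqrt(sq_sum / count))


# ---------------------------------------------------------------------------
# Variable selection
# ---------------------------------------------------------------------------


def _variable_leverage(model: PLSModel) -> np.ndarray:
    """Per-variable leverage from normalized loadings.

    Raw loading leverage (sum of squared normalized loadings) averages
    n_factors / n_variables; it is rescaled so that its mean equals
    (n_factors + 1) / n_train, making the classic "twice the average"
    cutoff 2 * (f + 1) / n meaningful for any matrix shape.
    """
    P = model.loadings
    norms = np.linalg.norm(P, axis=0)
    norms[norms == 0] = 1.0
    raw = np.sum((P / norms) ** 2, axis=1)
    f = P.shape[1]
    target_mean = (f + 1) / model.n_train
    return raw * target_mean / (f / P.shape[0])


def select_variables(
    X: pd.DataFrame,
    y: Sequence[float],
    config: Optional[RunConfig] = None,
    block_labels: Optional[Dict[str, str]] = None,
) -> Tuple[pd.Series, List[dict]]:
    """Iterative variable optimisation by coefficient size and leverage.

    Each pass drops variables whose |coefficient| falls strictly below the
    configured quantile of the current model, or whose variable leverage
    exceeds ``vs_leverage_multiplier * (factors + 1) / rows``; it stops when
    the cross-validated RMSEP stops improving, the mask stabilises, or the
    iteration cap is reached.  Deterministic given (X, y, config).
    """
    config = config or RunConfig()
    y = np.asarray(y, dtype=float)
    labels = block_labels or {c: block_label(c) for c in X.columns}
    n = len(X)
    mask = pd.Series(True, index=X.columns)
    accepted_mask = mask.copy()
    best_rmsep = np.inf
    log: List[dict] = []
    for iteration in range(config.vs_max_iter):
        cols = mask.index[mask.to_numpy()]
        max_f = min(config.pls_max_factors, n - 2, len(cols))
        cv = cross_validate(X[cols], y, max_f, {c: labels[c] for c in cols})
        f = cv.n_factors
        rmsep = float(cv.rmsep_by_factor[f])
        log.append(
            {
                "iteration": iteration,
                "n_variables": int(len(cols)),
                "n_factors": f,
                "rmsep": rmsep,
            }
        )
        best_rmsep = min(best_rmsep, rmsep)
        # parsimony within tolerance: keep shrinking while the CV error stays
        # within vs_rmsep_tolerance of the best seen; otherwise roll back
        if rmsep > best_rmsep * (1.0 + config.vs_rmsep_tolerance) + 1e-12:
            break
        accepted_mask = mask.copy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = fit_pls(X[cols], y, f, {c: labels[c] for c in cols})
        kept = model.recipe.kept_columns
        absb = pd.Series(np.abs(model.coef), index=kept)
        leverage = pd.Series(_variable_leverage(model), index=kept)
        h_star = config.vs_leverage_multiplier * (f + 1) / n
        threshold = float(absb.quantile(config.vs_coef_quantile))
        # leverage acts as an instability safeguard only: a variable whose
        # coefficient is in the top half carries the model and is never
        # removed for leverage alone
        drop = (absb < threshold) | (
            (leverage > h_star) & (absb < float(absb.median()))
        )
        # columns the recipe excluded (zero variance) are dropped as well
        excluded = [c for c in cols if c not in kept]
        if not drop.any() and not excluded:
            break
        if drop.all():
            warnings.warn("variable selection would empty the mask; stopping")
            break
        mask[drop.index[drop.to_numpy()]] = False
        mask[excluded] = False
    return accepted_mask, log


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------


@dataclass
class ModelReport:
    """Cross-validated performance summary of one indicator model."""

    rmsep: float
    r_squared: float
    delta_pct: float  # 100 * RMSEP / max(y_train)
    n_factors: int
    rmsep_by_factor: pd.Series
    n_curve_points: int
    n_calc_params: int
    selected_columns: List[str] = field(default_factory=list)


def delta_percent(rmsep: float, y_train_max: float) -> float:
    """Relative prediction error: RMSEP as a percentage of the largest target."""
    if y_train_max <= 0:
        raise ValueError("y_train_max must be positive")
    return 100.0 * rmsep / y_train_max


def report_metrics(
    cv: CVResult, y: Sequence[float], model: PLSModel
) -> ModelReport:
    """Assemble RMSEP / R^2 / Delta% from LOO predictions."""
    y = np.asarray(y, dtype=float)
    if np.std(y) == 0:
        raise ValueError("response is constant")
    resid = y - cv.predictions
    rmsep = float(np.sqrt(np.mean(resid**2)))
    r2 = float(1.0 - np.sum(resid**2) / np.sum((y - y.mean()) ** 2))
    selected = list(model.recipe.kept_columns)
    blocks = [block_label(c) for c in selected]
    return ModelReport(
        rmsep=rmsep,
        r_squared=r2,
        delta_pct=delta_percent(rmsep, model.y_max),
        n_factors=cv.n_factors,
        rmsep_by_factor=cv.rmsep_by_factor,
        n_curve_points=sum(b in (BLOCK_CURVE, BLOCK_MAX) for b in blocks),
        n_calc_params=sum(b == BLOCK_PARAM for b in blocks),
        selected_columns=selected,
    )


@dataclass
class IndicatorModel:
    """Variable-selected, cross-validated model for one microbiological indicator."""

    indicator: str
    model: PLSModel
    report: ModelReport
    mask: pd.Series
    selection_log: List[dict]


def train_indicator(
    X: pd.DataFrame,
    y: Sequence[float],
    indicator: str,
    config: Optional[RunConfig] = None,
    groups: Optional[Sequence] = None,
) -> IndicatorModel:
    """Variable selection, final fit and LOO model checking in one step.

    ``groups`` (e.g. specimen ids of replicated measurements), when given,
    re-scale the prediction deviation via leave-one-group-out RMSEP; the
    reported RMSEP/R2/Delta% always come from record-level full
    cross-validation.
    """
    config = config or RunConfig()
    y = np.asarray(y, dtype=float)
    mask, log = select_variables(X, y, config)
    cols = mask.index[mask.to_numpy()]
    n = len(X)
    max_f = min(config.pls_max_factors, n - 2, len(cols))
    cv = cross_validate(X[cols], y, max_f)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = fit_pls(X[cols], y, cv.n_factors)
    if groups is not None:
        model.rmsep = grouped_rmsep(X[cols], y, groups, cv.n_factors)
    else:
        model.rmsep = float(cv.rmsep_by_factor[cv.n_factors])
    report = report_metrics(cv, y, model)
    return IndicatorModel(
        indicator=indicator, model=model, report=report, mask=mask, selection_log=log
    )
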