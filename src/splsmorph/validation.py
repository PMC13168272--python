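"""Nested leave-one-out validation of the sparse-PLS pipeline.

The outer LOO loop estimates generalization: each subject is held out in
turn, and *all* preprocessing (near-zero-variance removal, centering,
scaling) plus keepX tuning happen inside the training fold, so no
information leaks from the held-out subject into model building.  An inner
LOO loop on each training fold picks the keepX feature budget by mean
squared prediction error.  Component count is chosen by a BIC computed on
the outer cross-validated residuals,

    BIC = n * log(RSS / n) + k * log(n)   (natural log),

with k the number of latent components.  Predictive performance is
summarised by RMSEP, the cross-validated Q^2 (1 - PRESS/TSS; negative means
worse than predicting the mean) and the squared Pearson correlation between
observed and cross-validated predictions.  Significance of Q^2 comes from a
permutation test that reshuffles the response and reruns the pipeline,
retuning keepX per fold, with the component count frozen at the observed
selection (full reselection per permutation is available via
``retune_components``).

For single-component models the inner LOO is evaluated in closed form for
all folds at once (rank-one update formulas for fold means/SDs and the
feature-response covariance); the generic per-fold loop is used otherwise
and the two paths agree to numerical precision (unit-tested).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .spls import (
    DEFAULT_VAR_TOL,
    apply_standardizer,
    fit_spls,
    fit_standardizer,
    soft_threshold_topk,
    variance_filter,
)

logger = logging.getLogger(__name__)

_TINY = 1e-30


# ---------------------------------------------------------------------------
# performance metrics
# ---------------------------------------------------------------------------

def rmsep(y_obs, y_pred) -> float:
    """Root mean square error of prediction: sqrt(sum((obs-pred)^2)/n)."""
    y_obs = np.asarray(y_obs, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_obs.shape != y_pred.shape:
        raise ValueError("y_obs and y_pred must have equal length")
    return float(np.sqrt(np.mean((y_obs - y_pred) ** 2)))


def q_squared(y_obs, y_pred) -> float:
    """Cross-validated R^2: 1 - PRESS/TSS with the full observed mean as baseline.

    Negative values mean the model predicts worse than the mean of the
    observed responses.
    """
    y_obs = np.asarray(y_obs, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_obs.shape != y_pred.shape:
        raise ValueError("y_obs and y_pred must have equal length")
    tss = float(np.sum((y_obs - y_obs.mean()) ** 2))
    if tss == 0.0:
        raise ValueError("q_squared undefined: observed responses are constant")
    press = float(np.sum((y_obs - y_pred) ** 2))
    return 1.0 - press / tss


def r_squared_cv(y_obs, y_pred) -> float:
    """Squared Pearson correlation between observed and CV-predicted values.

    Returns NaN with a warning when either vector is constant (e.g. every
    fold fell back to the training-mean prediction).
    """
    y_obs = np.asarray(y_obs, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_obs.shape != y_pred.shape:
        raise ValueError("y_obs and y_pred must have equal length")
    if np.std(y_obs) == 0.0 or np.std(y_pred) == 0.0:
        warnings.warn(
            "r_squared_cv undefined for constant input; returning NaN",
            stacklevel=2,
        )
        return float("nan")
    r = float(np.corrcoef(y_obs, y_pred)[0, 1])
    return r * r


def cv_bic(residuals, n: int, k: int) -> float:
    """BIC on cross-validated residuals: n*log(RSS/n) + k*log(n).

    ``k`` counts latent components.  RSS=0 returns -inf with a warning.
    """
    residuals = np.asarray(residuals, dtype=float)
    if residuals.size != n:
        raise ValueError(f"expected {n} residuals, got {residuals.size}")
    rss = float(np.sum(residuals**2))
    if rss == 0.0:
        warnings.warn("zero cross-validated RSS; BIC is -inf", stacklevel=2)
        return float("-inf")
    return n * np.log(rss / n) + k * np.log(n)


# ---------------------------------------------------------------------------
# configuration and result containers
# ---------------------------------------------------------------------------

@dataclass
class NestedCvConfig:
    """Settings for the nested LOO evaluation.

    ``keepx_grid=None`` means the default grid: multiples of 5 from 5 up to
    the training fold's retained feature count.  Grid values above a fold's
    retained count are dropped and the retained count itself is appended, so
    the dense model stays reachable.
    """

    keepx_grid: Sequence[int] | None = None
    component_candidates: Sequence[int] | None = None
    var_tol: float = DEFAULT_VAR_TOL
    retune_components: bool = False

    def __post_init__(self) -> None:
        if self.keepx_grid is not None:
            grid = sorted(int(g) for g in self.keepx_grid)
            if not grid or grid[0] < 1:
                raise ValueError("keepx grid values must be >= 1")
            self.keepx_grid = grid
        if self.component_candidates is not None:
            cands = sorted(int(k) for k in self.component_candidates)
            if not cands or cands[0] < 1:
                raise ValueError("component candidates must be >= 1")
            self.component_candidates = cands


def default_keepx_grid(n_features: int) -> list[int]:
    """Multiples of 5 from 5 up to the feature count."""
    return list(range(5, n_features + 1, 5)) or [n_features]


@dataclass
class CvPredictions:
    """Outer-LOO predictions: exactly one per subject, fold f never saw f."""

    y_obs: np.ndarray
    y_pred: np.ndarray
    keepx: np.ndarray  # tuned keepX per fold (0 where fallback)
    n_retained: np.ndarray  # retained feature count per fold
    fallback: np.ndarray  # True where the fold predicted the training mean

    @property
    def residuals(self) -> np.ndarray:
        return self.y_obs - self.y_pred


@dataclass
class ComponentSelection:
    """Per-candidate cross-validated RSS and BIC; chosen k = argmin BIC."""

    candidates: list[int]
    rss: np.ndarray
    bic: np.ndarray
    chosen: int
    predictions: dict[int, CvPredictions] = field(repr=False, default_factory=dict)


@dataclass
class EvaluationReport:
    """Cross-validated performance of the nested pipeline on one cohort."""

    n: int
    y_mean: float
    rmsep: float
    q2: float
    r2: float
    selection: ComponentSelection
    predictions: CvPredictions
    permutation_p: float | None = None
    null_q2: np.ndarray | None = None
    n_permutations: int = 0


# ---------------------------------------------------------------------------
# inner loop: keepX tuning
# ---------------------------------------------------------------------------

def _cap_grid(grid: Sequence[int], n_retained: int) -> list[int]:
    capped = sorted({g for g in grid if g <= n_retained} | {n_retained})
    return capped


def _fold_fit_predict(X_tr, y_tr, X_te, n_components, keep_x, var_tol):
    """Filter+standardize+fit on training rows; predict test rows.

    Returns (predictions, n_retained).  Falls back to the training mean when
    no feature survives the variance filter or no component can be fit.
    """
    y_mean = float(np.mean(y_tr))
    try:
        params = fit_standardizer(X_tr, var_tol)
    except ValueError:
        logger.info("fold fallback: zero retained features")
        return np.full(X_te.shape[0], y_mean), 0
    r = len(params.retained_idx)
    k_eff = min(n_components, X_tr.shape[0] - 1, r)
    if k_eff < 1:
        return np.full(X_te.shape[0], y_mean), r
    Z_tr = apply_standardizer(X_tr, params)
    core = fit_spls(Z_tr, np.asarray(y_tr, float) - y_mean, k_eff, min(keep_x, r))
    Z_te = apply_standardizer(X_te, params)
    return y_mean + Z_te @ core.beta, r


def _inner_loo_mse_naive(X, y, n_components, grid, var_tol):
    """Inner-LOO mean squared prediction error per grid value, fold loop."""
    m = X.shape[0]
    sse = {g: 0.0 for g in grid}
    for j in range(m):
        mask = np.ones(m, dtype=bool)
        mask[j] = False
        X_tr, y_tr, X_te = X[mask], y[mask], X[j : j + 1]
        for g in grid:
            pred, _ = _fold_fit_predict(X_tr, y_tr, X_te, n_components, g, var_tol)
            sse[g] += (y[j] - pred[0]) ** 2
    return {g: sse[g] / m for g in grid}


def _inner_loo_mse_fast_k1(X, y, grid, var_tol):
    """Closed-form inner-LOO errors for single-component models.

    For every held-out row j, the training mean/SD, the feature-response
    covariance, and the score norm of the sparse one-component fit are
    computed from full-data sums via rank-one downdates, so all m folds are
    evaluated with a handful of vectorized operations per grid value.
    Matches ``_inner_loo_mse_naive`` with n_components=1 to numerical
    precision.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    m, p = X.shape
    q = m - 1
    S = X.sum(axis=0)
    Q = (X * X).sum(axis=0)
    Sy = float(y.sum())
    A = X.T @ y

    mu = (S - X) / q  # (m, p): training mean when row j is held out
    var = (Q - X * X - q * mu * mu) / (q - 1)
    sd = np.sqrt(np.maximum(var, 0.0))
    mask = sd > var_tol
    sd_safe = np.where(mask, sd, 1.0)
    ybar = (Sy - y) / q  # (m,)

    # Z_T^T y_c for each fold: cov of standardized training X with centered y
    cross = A - X * y[:, None] - q * mu * ybar[:, None]
    w_raw = np.where(mask, cross / sd_safe, 0.0)
    absw = np.abs(w_raw)

    out = {}
    for g in grid:
        if g < p:
            lam = np.partition(absw, p - g - 1, axis=1)[:, p - g - 1][:, None]
            w = np.sign(w_raw) * np.maximum(absw - lam, 0.0)
        else:
            w = w_raw.copy()
        norms = np.linalg.norm(w, axis=1)
        ok = norms > 0.0
        w /= np.where(ok, norms, 1.0)[:, None]

        u = np.where(mask, w / sd_safe, 0.0)
        M = X @ u.T  # M[i, j] = x_i . u_j
        b = (mu * u).sum(axis=1)  # per-fold score offset mu_j . u_j
        colsum = M.sum(axis=0)
        colsq = (M * M).sum(axis=0)
        diag = np.diagonal(M)
        z_held = diag - b  # held-out row's component score
        tt = colsq - 2.0 * b * colsum + m * b * b - z_held**2
        t_yc = (w * w_raw).sum(axis=1)  # t^T y_c = w . (Z^T y_c)
        good = ok & (tt > _TINY)
        c = np.where(good, t_yc / np.where(good, tt, 1.0), 0.0)
        y_hat = ybar + c * z_held
        out[g] = float(np.mean((y - y_hat) ** 2))
    return out


def tune_keepx_inner(X_train, y_train, n_components, config: NestedCvConfig) -> int:
    """Tune keepX by inner LOO over the training set; ties -> smallest keepX.

    The grid is capped at the training set's retained feature count (which is
    appended if absent).  Raises on fewer than 3 training rows or when no
    feature has variance.
    """
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train, dtype=float)
    if X_train.shape[0] < 3:
        raise ValueError("inner LOO tuning needs at least 3 training subjects")
    n_retained = len(variance_filter(X_train, config.var_tol))  # raises if 0
    grid = config.keepx_grid or default_keepx_grid(X_train.shape[1])
    grid = _cap_grid(grid, n_retained)
    if n_components == 1:
        mse = _inner_loo_mse_fast_k1(X_train, y_train, grid, config.var_tol)
    else:
        mse = _inner_loo_mse_naive(
            X_train, y_train, n_components, grid, config.var_tol
        )
    best = grid[0]
    for g in grid[1:]:
        if mse[g] < mse[best]:
            best = g
    return best


# ---------------------------------------------------------------------------
# outer loop and component selection
# ---------------------------------------------------------------------------

def outer_loocv(X, y, n_components, config: NestedCvConfig) -> CvPredictions:
    """Leave-one-out predictions with fold-internal preprocessing and tuning.

    For each subject: remove it, variance-filter/standardize/tune keepX/fit
    on the remaining rows, then predict the held-out subject with the
    training-derived transforms.  Folds with no retained feature fall back to
    the training-mean prediction (logged).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    if n < 3:
        raise ValueError("outer LOO requires n >= 3 subjects")
    y_pred = np.empty(n)
    keepx = np.zeros(n, dtype=int)
    n_ret = np.zeros(n, dtype=int)
    fallback = np.zeros(n, dtype=bool)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        X_tr, y_tr = X[mask], y[mask]
        try:
            n_retained = len(variance_filter(X_tr, config.var_tol))
            grid = _cap_grid(
                config.keepx_grid or default_keepx_grid(X.shape[1]), n_retained
            )
            if len(grid) == 1:
                kx = grid[0]  # nothing to tune
            else:
                kx = tune_keepx_inner(X_tr, y_tr, n_components, config)
        except ValueError:
            # no usable feature (or too few rows to tune) in this fold
            y_pred[i] = float(y_tr.mean())
            fallback[i] = True
            logger.info("outer fold %d: fallback to training mean", i)
            continue
        pred, r = _fold_fit_predict(
            X_tr, y_tr, X[i : i + 1], n_components, kx, config.var_tol
        )
        y_pred[i] = pred[0]
        keepx[i] = kx
        n_ret[i] = r
    return CvPredictions(
        y_obs=y.copy(), y_pred=y_pred, keepx=keepx, n_retained=n_ret,
        fallback=fallback,
    )


def select_components(X, y, config: NestedCvConfig) -> ComponentSelection:
    """Choose the component count by BIC on outer-CV residuals.

    Each candidate k gets a full nested LOO run; the k with the lowest BIC
    wins, ties going to the smaller k.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    candidates = list(config.component_candidates or range(1, n))
    if any(k >= n for k in candidates):
        raise ValueError("component candidates must be < n")
    rss = np.empty(len(candidates))
    bic = np.empty(len(candidates))
    preds: dict[int, CvPredictions] = {}
    for i, k in enumerate(candidates):
        cvp = outer_loocv(X, y, k, config)
        preds[k] = cvp
        rss[i] = float(np.sum(cvp.residuals**2))
        bic[i] = cv_bic(cvp.residuals, n, k)
    chosen = candidates[int(np.argmin(bic))]  # argmin takes first -> smallest k
    return ComponentSelection(
        candidates=candidates, rss=rss, bic=bic, chosen=chosen, predictions=preds
    )


def evaluate(X, y, config: NestedCvConfig | None = None) -> EvaluationReport:
    """Full nested pipeline: component selection + CV performance metrics.

    The outer-CV residuals of the chosen component count serve both the BIC
    selection and the reported metrics; this double use is optimistic by
    construction and flagged in the written report.
    """
    config = config or NestedCvConfig()
    y = np.asarray(y, dtype=float)
    selection = select_components(X, y, config)
    cvp = selection.predictions[selection.chosen]
    return EvaluationReport(
        n=len(y),
        y_mean=float(y.mean()),
        rmsep=rmsep(cvp.y_obs, cvp.y_pred),
        q2=q_squared(cvp.y_obs, cvp.y_pred),
        r2=r_squared_cv(cvp.y_obs, cvp.y_pred),
        selection=selection,
        predictions=cvp,
    )


# ---------------------------------------------------------------------------
# permutation inference
# ---------------------------------------------------------------------------

def permutation_test(
    X,
    y,
    config: NestedCvConfig | None = None,
    n_permutations: int = 1000,
    seed: int | None = None,
    report: EvaluationReport | None = None,
) -> EvaluationReport:
    """Permutation test of the cross-validated Q^2.

    The observed statistic is Q^2 from the full nested pipeline.  Each
    permutation reshuffles the responses and reruns the pipeline — variance
    filtering, standardization and keepX tuning redone per fold — with the
    component count frozen at the observed selection (or fully reselected
    when ``config.retune_components``).  The add-one convention
    p = (1 + #{Q^2_b >= Q^2_obs}) / (B + 1) avoids p = 0.  Permutations are
    drawn from independent substreams spawned from the master seed, so the
    result is reproducible and independent of execution order.
    """
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    config = config or NestedCvConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if report is None:
        report = evaluate(X, y, config)
    k_obs = report.selection.chosen
    children = np.random.SeedSequence(seed).spawn(n_permutations)
    null_q2 = np.empty(n_permutations)
    for b in range(n_permutations):
        rng = np.random.default_rng(children[b])
        y_perm = rng.permutation(y)
        if config.retune_components:
            sel = select_components(X, y_perm, config)
            cvp = sel.predictions[sel.chosen]
        else:
            cvp = outer_loocv(X, y_perm, k_obs, config)
        null_q2[b] = q_squared(y_perm, cvp.y_pred)
    p = (1.0 + float(np.sum(null_q2 >= report.q2))) / (n_permutations + 1.0)
    report.permutation_p = p
    report.null_q2 = null_q2
    report.n_permutations = n_permutations
    return report
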