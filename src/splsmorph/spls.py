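"""Sparse partial least squares regression (single response).

The estimator is the sparse variant of PLS1: each latent component is built
from the covariance between the (standardized) features and the current
response, with an L1-style soft-threshold that keeps at most ``keep_x``
features per component.  Components are extracted NIPALS-style with
regression-mode deflation of both the feature matrix and the response, so
successive score vectors are mutually orthogonal ("uncorrelated latent
variables").

The module exposes both the low-level building blocks (``variance_filter``,
``Standardizer``, ``fit_spls``) and a statsmodels-flavoured model surface
(``SparsePLS`` -> ``SparsePLSResults``) that handles the preprocessing a fit
requires: near-zero-variance removal, then centering and scaling.  Sparse
selection is scale-sensitive, so standardization keeps high-variance parcels
from dominating the feature ranking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

#: Features with training-sample SD at or below this are treated as
#: (near-)zero variance and removed before fitting.
DEFAULT_VAR_TOL = 1e-8


def variance_filter(X: np.ndarray, tol: float = DEFAULT_VAR_TOL) -> np.ndarray:
    """Indices of features whose sample SD (ddof=1) exceeds ``tol``.

    Order is preserved.  Raises if no feature survives, since the model is
    undefined on an empty feature set.
    """
    X = np.asarray(X, dtype=float)
    sd = X.std(axis=0, ddof=1)
    retained = np.flatnonzero(sd > tol)
    if retained.size == 0:
        raise ValueError("variance filter removed every feature")
    return retained


@dataclass
class StandardizationParams:
    """Training-fold centering/scaling parameters for the retained features."""

    retained_idx: np.ndarray
    mean: np.ndarray
    sd: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.sd <= 0):
            raise ValueError("standardizer requires strictly positive SDs")


def fit_standardizer(
    X_train: np.ndarray, tol: float = DEFAULT_VAR_TOL
) -> StandardizationParams:
    """Variance-filter then learn per-feature mean/SD from training rows only."""
    X_train = np.asarray(X_train, dtype=float)
    idx = variance_filter(X_train, tol)
    Xr = X_train[:, idx]
    return StandardizationParams(
        retained_idx=idx,
        mean=Xr.mean(axis=0),
        sd=Xr.std(axis=0, ddof=1),
    )


def apply_standardizer(X: np.ndarray, params: StandardizationParams) -> np.ndarray:
    """Apply stored training mean/SD (never refit) to any matrix."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] <= params.retained_idx.max():
        raise ValueError(
            f"matrix with {X.shape[1] if X.ndim == 2 else '?'} columns cannot "
            f"supply retained feature index {params.retained_idx.max()}"
        )
    return (X[:, params.retained_idx] - params.mean) / params.sd


def soft_threshold_topk(z: np.ndarray, keep: int) -> np.ndarray:
    """Soft-threshold ``z`` at the magnitude of its (keep+1)-th largest entry.

    At most ``keep`` entries remain nonzero; exact ties with the threshold
    (and exact zeros) give fewer.
    """
    z = np.asarray(z, dtype=float)
    p = z.size
    if keep >= p:
        return z.copy()
    lam = np.partition(np.abs(z), p - keep - 1)[p - keep - 1]
    return np.sign(z) * np.maximum(np.abs(z) - lam, 0.0)


@dataclass
class SplsFit:
    """Core sparse-PLS1 decomposition on standardized X, centered y.

    ``beta`` maps standardized features to the centered response; prediction
    on the original scale adds back the training response mean (stored by the
    model wrapper, not here).
    """

    n_components: int
    keep_x: int
    x_weights: np.ndarray  # (p, K) unit-norm sparse weight vectors
    x_loadings: np.ndarray  # (p, K)
    y_loadings: np.ndarray  # (K,)
    beta: np.ndarray  # (p,)
    scores: np.ndarray  # (n, K) training component scores


def fit_spls(
    X_std: np.ndarray,
    y_centered: np.ndarray,
    n_components: int,
    keep_x: int,
) -> SplsFit:
    """Fit sparse PLS1 by iterative component extraction with deflation.

    Per component: the candidate weight is proportional to ``X^T y`` on the
    current (deflated) data; it is sparsified by soft-thresholding to at most
    ``keep_x`` nonzeros, normalized to unit length, and turned into a score
    ``t = X w``.  X- and y-loadings are least-squares projections onto the
    score, and both X and y are deflated before the next component.  A
    degenerate score (``t^T t = 0``) truncates the decomposition early with a
    warning.
    """
    X = np.array(X_std, dtype=float)
    y = np.array(y_centered, dtype=float)
    n, p = X.shape
    if not 1 <= n_components <= min(n - 1, p):
        raise ValueError(
            f"n_components={n_components} outside [1, min(n-1, p)]="
            f"[1, {min(n - 1, p)}]"
        )
    if not 1 <= keep_x <= p:
        raise ValueError(f"keep_x={keep_x} outside [1, {p}]")

    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    c = np.zeros(n_components)
    T = np.zeros((n, n_components))
    k_eff = 0
    for k in range(n_components):
        w = soft_threshold_topk(X.T @ y, keep_x)
        norm = np.linalg.norm(w)
        if norm == 0.0:
            warnings.warn(
                f"degenerate component {k + 1}: zero weight vector; "
                f"truncating to {k_eff} component(s)",
                stacklevel=2,
            )
            break
        w /= norm
        t = X @ w
        tt = float(t @ t)
        if tt <= 0.0:
            warnings.warn(
                f"degenerate component {k + 1}: zero score norm; "
                f"truncating to {k_eff} component(s)",
                stacklevel=2,
            )
            break
        pk = X.T @ t / tt
        ck = float(y @ t / tt)
        X = X - np.outer(t, pk)
        y = y - t * ck
        W[:, k], P[:, k], c[k], T[:, k] = w, pk, ck, t
        k_eff += 1

    W, P, c, T = W[:, :k_eff], P[:, :k_eff], c[:k_eff], T[:, :k_eff]
    if k_eff == 0:
        beta = np.zeros(p)
    else:
        # beta = W (P^T W)^{-1} c maps the original standardized X to the
        # accumulated fitted values sum_k t_k c_k.
        beta = W @ np.linalg.solve(P.T @ W, c)
    return SplsFit(
        n_components=k_eff,
        keep_x=keep_x,
        x_weights=W,
        x_loadings=P,
        y_loadings=c,
        beta=beta,
        scores=T,
    )


class SparsePLS:
    """Sparse PLS1 regression model with fold-safe preprocessing.

    Parameters
    ----------
    endog : array-like, shape (n,)
        Response (e.g. TEQ sum score).
    exog : array-like, shape (n, p)
        Feature matrix on the original scale (e.g. parcel-wise cortical
        thickness).  Near-zero-variance features are removed and the rest
        centered/scaled using these training rows only.
    n_components : int
        Number of latent components K.
    keep_x : int
        Feature budget per component.  Values above the retained feature
        count act as a dense (keep-all) budget.
    var_tol : float
        Near-zero-variance threshold on the training SD.
    feature_names : sequence of str, optional
        Labels used by :meth:`SparsePLSResults.variable_importance`.
    """

    def __init__(
        self,
        endog,
        exog,
        n_components: int = 1,
        keep_x: int | None = None,
        var_tol: float = DEFAULT_VAR_TOL,
        feature_names=None,
    ) -> None:
        self.endog = np.asarray(endog, dtype=float)
        self.exog = np.asarray(exog, dtype=float)
        if self.exog.ndim != 2 or self.endog.ndim != 1:
            raise ValueError("exog must be 2-D and endog 1-D")
        if self.exog.shape[0] != self.endog.shape[0]:
            raise ValueError("endog and exog disagree on n")
        self.n_components = int(n_components)
        self.keep_x = (
            int(keep_x) if keep_x is not None else self.exog.shape[1]
        )
        self.var_tol = float(var_tol)
        if feature_names is None:
            feature_names = [f"x{j}" for j in range(self.exog.shape[1])]
        if len(feature_names) != self.exog.shape[1]:
            raise ValueError("feature_names length must equal n features")
        self.feature_names = list(feature_names)

    @classmethod
    def from_tables(
        cls, morphometry, phenotypes, n_components=1, keep_x=None, var_tol=DEFAULT_VAR_TOL
    ) -> "SparsePLS":
        """Build the model from aligned Morphometry/Phenotype tables."""
        if morphometry.subject_ids != phenotypes.subject_ids:
            raise ValueError("tables are not row-aligned by subject id")
        return cls(
            phenotypes.teq.astype(float),
            morphometry.values,
            n_components=n_components,
            keep_x=keep_x,
            var_tol=var_tol,
            feature_names=morphometry.parcel_labels,
        )

    def fit(self) -> "SparsePLSResults":
        params = fit_standardizer(self.exog, self.var_tol)
        X_std = apply_standardizer(self.exog, params)
        y_mean = float(self.endog.mean())
        keep = min(self.keep_x, len(params.retained_idx))
        core = fit_spls(X_std, self.endog - y_mean, self.n_components, keep)
        return SparsePLSResults(self, core, params, y_mean)


@dataclass
class SparsePLSResults:
    """Fitted sparse PLS1 model: coefficients, selection, prediction."""

    model: SparsePLS
    core: SplsFit
    standardization: StandardizationParams
    y_mean: float
    _beta_full: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        p_all = self.model.exog.shape[1]
        beta = np.zeros(p_all)
        beta[self.standardization.retained_idx] = self.core.beta
        self._beta_full = beta

    @property
    def params(self) -> np.ndarray:
        """Coefficients on the standardized feature scale, full feature order
        (zeros for filtered-out features)."""
        return self._beta_full

    @property
    def selected_features(self) -> np.ndarray:
        """Indices (original order) of features with nonzero coefficient."""
        return np.flatnonzero(self._beta_full)

    def predict(self, X_new=None) -> np.ndarray:
        """Predict responses: training mean + standardized features @ beta.

        ``X_new`` must carry the full pre-filter feature set; the stored
        variance filter and training standardizer are applied, never refit.
        """
        if X_new is None:
            X_new = self.model.exog
        X_new = np.asarray(X_new, dtype=float)
        if X_new.ndim != 2 or X_new.shape[1] != self.model.exog.shape[1]:
            raise ValueError(
                f"expected {self.model.exog.shape[1]} features, "
                f"got {X_new.shape[1] if X_new.ndim == 2 else '?'}"
            )
        Z = apply_standardizer(X_new, self.standardization)
        return self.y_mean + Z @ self.core.beta

    def fittedvalues(self) -> np.ndarray:
        return self.predict()

    def variable_importance(self) -> list[tuple[str, float]]:
        """Features ranked by |coefficient| descending, zeros excluded.

        Ties in magnitude are broken by ascending feature index.
        """
        beta = self._beta_full
        nz = np.flatnonzero(beta)
        order = nz[np.lexsort((nz, -np.abs(beta[nz])))]
        names = self.model.feature_names
        return [(names[j], float(beta[j])) for j in order]

    def summary(self) -> str:
        lines = [
            "Sparse PLS1 regression results",
            "==============================",
            f"n obs:              {self.model.exog.shape[0]}",
            f"features (input):   {self.model.exog.shape[1]}",
            f"features retained:  {len(self.standardization.retained_idx)}",
            f"components:         {self.core.n_components}",
            f"keepX per comp.:    {self.core.keep_x}",
            f"selected features:  {len(self.selected_features)}",
            f"response mean:      {self.y_mean:.4f}",
            "",
            "Top coefficients (standardized scale):",
        ]
        for name, coef in self.variable_importance()[:15]:
            lines.append(f"  {name:<30s} {coef:+.4f}")
        return "\n".join(lines)
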