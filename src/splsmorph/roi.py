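"""Region-of-interest statistics: outlier screening, polynomial trait models,
BIC comparison, and nonparametric checks.

The trait model regresses the TEQ sum score on centered powers of one
parcel's morphometric value (degree 1-4) plus age and a female indicator.
With a single observation per subject, a subject-level random intercept is
not identifiable — its variance cannot be separated from the residual — so
the model is estimated as fixed-effects least squares and the intercept
variance is absorbed into sigma^2.  Degrees are compared by the Gaussian
log-likelihood BIC.  No multiple-comparison correction is applied across ROI
hypotheses (a small set of a-priori regions); reported output states this.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)

#: MAD-to-SD consistency constant for the normal distribution.
MAD_SCALE = 1.4826


def mad_outliers(values, threshold: float = 3.0, scale: float = MAD_SCALE) -> np.ndarray:
    """Indices whose scaled absolute deviation from the median exceeds ``threshold``.

    Flags i where |x_i - median| / (scale * MAD) > threshold, with MAD the
    median absolute deviation from the median.  When MAD = 0 the rule
    degenerates; any value different from the median is flagged (logged).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("MAD screening needs at least 3 values")
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0.0:
        logger.warning("MAD is zero; flagging every value differing from the median")
        return np.flatnonzero(x != med)
    return np.flatnonzero(np.abs(x - med) / (scale * mad) > threshold)


@dataclass
class RoiFit:
    """Fitted polynomial trait model for one ROI."""

    degree: int
    roi_label: str
    param_names: list[str]
    params: np.ndarray
    bse: np.ndarray
    conf_int: np.ndarray  # (k, 2) 95% bounds
    pvalues: np.ndarray
    sigma2: float
    bic: float
    n: int
    fittedvalues: np.ndarray
    resid: np.ndarray

    @property
    def rss(self) -> float:
        return float(np.sum(self.resid**2))

    def summary(self) -> str:
        head = (
            f"TEQ ~ poly({self.roi_label}, {self.degree}) + age + female"
            f"   [n={self.n}, BIC={self.bic:.2f}, sigma2={self.sigma2:.3f}]"
        )
        rows = [head, f"{'term':<14}{'coef':>10}{'se':>10}{'p':>10}"
                      f"{'ci_low':>10}{'ci_high':>10}"]
        for i, name in enumerate(self.param_names):
            rows.append(
                f"{name:<14}{self.params[i]:>10.3f}{self.bse[i]:>10.3f}"
                f"{self.pvalues[i]:>10.4f}{self.conf_int[i, 0]:>10.3f}"
                f"{self.conf_int[i, 1]:>10.3f}"
            )
        rows.append("No multiple-comparison correction across ROI hypotheses.")
        return "\n".join(rows)


class RoiPolynomial:
    """Polynomial regression of the trait on one ROI value, adjusted for
    age and gender.

    Parameters
    ----------
    teq : array-like
        TEQ sum scores (response).
    roi_values : array-like
        Morphometric values of one parcel (e.g. mean thickness in mm).
    age : array-like
        Age in years.
    female : array-like
        1 for female, 0 for male (female-coded indicator).
    degree : int
        Polynomial degree in the ROI value, 1-4.  Powers are of the centered
        ROI value, keeping coefficients on an interpretable scale; fitted
        values and BIC are invariant to this centering.
    """

    def __init__(self, teq, roi_values, age, female, degree: int = 1,
                 roi_label: str = "roi") -> None:
        self.y = np.asarray(teq, dtype=float)
        self.x = np.asarray(roi_values, dtype=float)
        self.age = np.asarray(age, dtype=float)
        self.female = np.asarray(female, dtype=float)
        self.roi_label = roi_label
        if degree not in (1, 2, 3, 4):
            raise ValueError("degree must be 1, 2, 3 or 4")
        self.degree = degree
        n = self.y.size
        if not (self.x.size == self.age.size == self.female.size == n):
            raise ValueError("input vectors disagree on n")
        if n <= degree + 3:
            raise ValueError(f"need n > degree + 3 = {degree + 3}, got n={n}")

    @classmethod
    def from_tables(cls, morphometry, phenotypes, parcel_label: str,
                    degree: int = 1) -> "RoiPolynomial":
        if morphometry.subject_ids != phenotypes.subject_ids:
            raise ValueError("tables are not row-aligned by subject id")
        try:
            j = morphometry.parcel_labels.index(parcel_label)
        except ValueError:
            raise KeyError(f"parcel {parcel_label!r} not in morphometry table")
        return cls(
            phenotypes.teq, morphometry.values[:, j], phenotypes.age,
            phenotypes.female, degree=degree, roi_label=parcel_label,
        )

    def _design(self) -> tuple[np.ndarray, list[str]]:
        xc = self.x - self.x.mean()
        cols = [xc**d for d in range(1, self.degree + 1)]
        names = ["intercept"] + [
            f"{self.roi_label}^{d}" if d > 1 else self.roi_label
            for d in range(1, self.degree + 1)
        ] + ["age", "female"]
        X = np.column_stack([np.ones_like(xc), *cols, self.age, self.female])
        return X, names

    def fit(self) -> RoiFit:
        X, names = self._design()
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            # name the first column that is linearly dependent on its predecessors
            for j in range(1, X.shape[1]):
                if np.linalg.matrix_rank(X[:, : j + 1]) <= np.linalg.matrix_rank(X[:, :j]):
                    raise ValueError(f"rank-deficient design: term {names[j]!r} "
                                     "is collinear with earlier terms")
            raise ValueError("rank-deficient design")
        res = sm.OLS(self.y, X).fit()
        return RoiFit(
            degree=self.degree,
            roi_label=self.roi_label,
            param_names=names,
            params=np.asarray(res.params),
            bse=np.asarray(res.bse),
            conf_int=np.asarray(res.conf_int(alpha=0.05)),
            pvalues=np.asarray(res.pvalues),
            sigma2=float(res.scale),
            bic=float(res.bic),
            n=int(res.nobs),
            fittedvalues=np.asarray(res.fittedvalues),
            resid=np.asarray(res.resid),
        )


def fit_polynomial_roi(roi_values, phenotypes, degree: int = 1,
                       roi_label: str = "roi") -> RoiFit:
    """Convenience wrapper: fit TEQ ~ poly(ROI, degree) + age + female."""
    return RoiPolynomial(
        phenotypes.teq, roi_values, phenotypes.age, phenotypes.female,
        degree=degree, roi_label=roi_label,
    ).fit()


def compare_bic(fits: list[RoiFit]) -> tuple[list[RoiFit], RoiFit]:
    """Rank fits ascending by BIC (ties -> lower degree); return (ranking, best).

    All fits must be on the same response (same n).
    """
    if not fits:
        raise ValueError("no fits to compare")
    ns = {f.n for f in fits}
    if len(ns) != 1:
        raise ValueError(f"fits disagree on n: {sorted(ns)}")
    ranking = sorted(fits, key=lambda f: (f.bic, f.degree))
    return ranking, ranking[0]


def spearman_assoc(roi_values, teq) -> tuple[float, float]:
    """Spearman rank correlation (mid-ranks for ties) with t-approximation p."""
    x = np.asarray(roi_values, dtype=float)
    y = np.asarray(teq, dtype=float)
    if x.size < 4:
        raise ValueError("Spearman association needs n >= 4")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        raise ValueError("Spearman association undefined for constant input")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


@dataclass
class GroupComparison:
    """Two-sample rank test with rank-biserial effect size."""

    labels: tuple[str, str]
    sizes: tuple[int, int]
    statistic: float  # W = Mann-Whitney U of the first group
    pvalue: float
    rank_biserial: float  # 1 - 2U/(n1*n2); positive when group 1 ranks lower

    def summary(self) -> str:
        return (
            f"{self.labels[0]} (n={self.sizes[0]}) vs {self.labels[1]} "
            f"(n={self.sizes[1]}): W = {self.statistic:g}, p = {self.pvalue:.4g}, "
            f"rbc = {self.rank_biserial:.3f}"
        )


def group_compare(values, grouping) -> GroupComparison:
    """Two-sided Wilcoxon rank-sum comparison of exactly two groups.

    ``W`` is the Mann-Whitney U statistic of the first group (pairs where a
    first-group value exceeds a second-group value, half credit for ties).
    The rank-biserial effect size is rbc = 1 - 2U/(n1*n2): positive when the
    first group tends to score *lower* than the second, negative when higher,
    and +/-1 at complete separation.
    """
    values = np.asarray(values, dtype=float)
    grouping = np.asarray(grouping)
    labels = sorted(set(grouping.tolist()))
    if len(labels) != 2:
        raise ValueError(f"expected exactly 2 groups, got {len(labels)}")
    g1 = values[grouping == labels[0]]
    g2 = values[grouping == labels[1]]
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("each group needs at least 2 observations")
    res = stats.mannwhitneyu(g1, g2, alternative="two-sided")
    u1 = float(res.statistic)
    rbc = 1.0 - 2.0 * u1 / (len(g1) * len(g2))
    return GroupComparison(
        labels=(str(labels[0]), str(labels[1])),
        sizes=(len(g1), len(g2)),
        statistic=u1,
        pvalue=float(res.pvalue),
        rank_biserial=rbc,
    )
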