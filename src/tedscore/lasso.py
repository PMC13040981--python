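"""L1-penalized logistic regression by coordinate descent.

Objective (glmnet convention):

    min_{b0, b}  (1/n) * sum_i log(1 + exp(-(2 y_i - 1) * (b0 + x_i b)))
                 + lambda * ||b||_1

with the intercept unpenalized. The fit alternates an outer
iteratively-reweighted quadratic approximation with inner cyclic coordinate
descent using soft-thresholding updates. On this scale the smallest penalty
that zeroes every coefficient is lambda_max = max_j |x_j'(y - ybar)| / n for
standardized columns.

The module also provides the standardization helper (population sd; penalty
comparability requires columns on a common scale), the warm-started lambda
path, stratified cross-validation selecting lambda_min by out-of-fold binomial
deviance, and bootstrap selection-stability at a fixed lambda.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .roc import auc as _auc
from .synthetic import CohortTable

__all__ = ["PenalizedModel", "LambdaPath", "CvResult", "StabilityResult",
           "standardize", "fit_lasso_logistic", "lambda_max", "lambda_path",
           "cv_lambda_min", "bootstrap_stability", "cohort_design_matrix",
           "PREDICTOR_NAMES"]

# the six clinical predictors entered into the penalized model, in fixed order
PREDICTOR_NAMES = ("fgl2", "tsab_quartile", "smoking", "age", "female",
                   "hyperthyroid")

_BETA_CAP = 50.0          # quasi-separation guard on the standardized scale
_WEIGHT_FLOOR = 1e-5
_PROB_CLIP = 1e-12


@dataclass
class PenalizedModel:
    intercept: float
    coefficients: np.ndarray          # on the scale of the X that was fitted
    lambda_: float
    n_iter: int
    converged: bool
    quasi_separated: bool = False
    # populated by the standardizing wrappers for interpretability
    coefficients_original: np.ndarray | None = None
    intercept_original: float | None = None

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return expit(self.intercept + X @ self.coefficients)


@dataclass
class LambdaPath:
    lambdas: np.ndarray               # strictly decreasing
    models: list[PenalizedModel]
    lambda_max: float


@dataclass
class CvResult:
    lambda_min: float
    lambdas: np.ndarray
    cv_mean: np.ndarray
    cv_se: np.ndarray
    folds: int
    seed: int


@dataclass
class StabilityResult:
    selection_frequency: np.ndarray
    b_iterations: int
    auc_distribution: np.ndarray
    n_redrawn: int


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------

def standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Center to mean 0 and scale to population sd 1, column-wise.

    Returns (X_std, means, sds); raises on a constant column, which cannot be
    given a comparable penalty.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-d design with at least 2 rows")
    means = X.mean(axis=0)
    sds = X.std(axis=0)  # population sd
    const = np.where(sds == 0)[0]
    if const.size:
        raise ValueError(f"constant column(s) at index {const.tolist()}")
    return (X - means) / sds, means, sds


def _back_transform(model: PenalizedModel, means: np.ndarray,
                    sds: np.ndarray) -> None:
    beta_orig = model.coefficients / sds
    model.coefficients_original = beta_orig
    model.intercept_original = model.intercept - float(means @ beta_orig)


# ---------------------------------------------------------------------------
# core fit
# ---------------------------------------------------------------------------

def _soft_threshold(z: float, g: float) -> float:
    # the 1e-15 snap keeps coefficients exactly zero at the lambda_max
    # boundary, where rounding can leave |z| - g at machine epsilon
    if z > g + 1e-15:
        return z - g
    if z < -(g + 1e-15):
        return z + g
    return 0.0


def objective(X: np.ndarray, y: np.ndarray, intercept: float,
              beta: np.ndarray, lam: float) -> float:
    """Penalized mean log-loss (the quantity the fit minimizes)."""
    eta = intercept + X @ beta
    # log(1 + exp(-s*eta)) computed stably
    s = 2.0 * y - 1.0
    loss = np.logaddexp(0.0, -s * eta).mean()
    return float(loss + lam * np.abs(beta).sum())


def fit_lasso_logistic(
    X: np.ndarray,
    y: np.ndarray,
    lambda_: float,
    tol: float = 1e-8,
    max_iter: int = 1000,
    beta0: float | None = None,
    beta: np.ndarray | None = None,
) -> PenalizedModel:
    """Fit at a single penalty by IRLS + cyclic coordinate descent.

    ``X`` is used as given (standardize first for comparable penalties);
    ``beta0``/``beta`` allow warm starts along a path. ``n_iter`` counts
    coordinate-descent sweeps; ``converged`` is False when the sweep budget is
    exhausted or a quasi-separation guard triggers.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if lambda_ < 0:
        raise ValueError("lambda must be non-negative")
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("y must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("y must contain both classes")
    n, p = X.shape
    ybar = float(y.mean())
    b0 = math.log(ybar / (1.0 - ybar)) if beta0 is None else float(beta0)
    b = np.zeros(p) if beta is None else np.asarray(beta, dtype=float).copy()

    sweeps = 0
    converged = False
    quasi = False
    inner_cap = min(max_iter, 100)  # re-linearize at least every 100 sweeps
    while sweeps < max_iter:
        eta = b0 + X @ b
        prob = expit(eta)
        # an unpenalized fit whose probabilities all saturate has no interior
        # optimum: the data are (quasi-)separated and beta diverges (slowly,
        # since the gradient decays exponentially), so stop and flag
        if lambda_ == 0.0 and float(np.abs(y - prob).max()) < 1e-8:
            quasi = True
            break
        w = np.clip(prob * (1.0 - prob), _WEIGHT_FLOOR, None)
        z = eta + (y - prob) / w
        # inner CD on the weighted least-squares surrogate
        wx2 = (w[:, None] * X * X).mean(axis=0)
        resid = z - eta  # working residual z - b0 - Xb
        b_before_outer = b.copy()
        b0_before_outer = b0
        for _inner in range(inner_cap):
            sweeps += 1
            max_delta = 0.0
            for j in range(p):
                bj_old = b[j]
                rho = float((w * X[:, j] * (resid + X[:, j] * bj_old)).mean())
                bj_new = _soft_threshold(rho, lambda_) / wx2[j]
                if bj_new != bj_old:
                    resid -= X[:, j] * (bj_new - bj_old)
                    b[j] = bj_new
                    max_delta = max(max_delta, abs(bj_new - bj_old))
            # unpenalized intercept update
            b0_new = b0 + float((w * resid).sum() / w.sum())
            if b0_new != b0:
                resid -= b0_new - b0
                max_delta = max(max_delta, abs(b0_new - b0))
                b0 = b0_new
            if max_delta < tol:
                break
            if sweeps >= max_iter:
                break
        if np.abs(b).max(initial=0.0) > _BETA_CAP:
            quasi = True
            break
        outer_delta = max(abs(b0 - b0_before_outer),
                          float(np.abs(b - b_before_outer).max(initial=0.0)))
        if outer_delta < tol:
            converged = True
            break
        if sweeps >= max_iter:
            break
    return PenalizedModel(b0, b, lambda_, sweeps, converged and not quasi,
                          quasi_separated=quasi)


# ---------------------------------------------------------------------------
# path, cross-validation, stability
# ---------------------------------------------------------------------------

def lambda_max(X: np.ndarray, y: np.ndarray) -> float:
    """Smallest penalty with an all-zero solution: max_j |x_j'(y - ybar)|/n."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    return float(np.abs(X.T @ (y - y.mean())).max() / len(y))


def lambda_path(
    X: np.ndarray,
    y: np.ndarray,
    n_lambda: int = 100,
    eps_ratio: float = 1e-3,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> LambdaPath:
    """Warm-started fits along a log-spaced penalty grid from lambda_max down."""
    if n_lambda < 2:
        raise ValueError("need at least 2 path points")
    lmax = lambda_max(X, y)
    lambdas = np.exp(np.linspace(math.log(lmax), math.log(lmax * eps_ratio),
                                 n_lambda))
    models: list[PenalizedModel] = []
    b0, b = None, None
    for lam in lambdas:
        m = fit_lasso_logistic(X, y, lam, tol=tol, max_iter=max_iter,
                               beta0=b0, beta=b)
        models.append(m)
        b0, b = m.intercept, m.coefficients
    return LambdaPath(lambdas, models, lmax)


def _stratified_folds(y: np.ndarray, k: int,
                      rng: np.random.Generator) -> list[np.ndarray]:
    """Round-robin deal of shuffled indices within each class."""
    folds: list[list[int]] = [[] for _ in range(k)]
    for cls in (0.0, 1.0):
        idx = np.where(y == cls)[0]
        if idx.size < k:
            raise ValueError(f"class {int(cls)} has fewer observations ({idx.size}) "
                             f"than folds ({k})")
        idx = rng.permutation(idx)
        for i, ix in enumerate(idx):
            folds[i % k].append(int(ix))
    return [np.sort(np.array(f)) for f in folds]


def _deviance(y: np.ndarray, prob: np.ndarray) -> float:
    prob = np.clip(prob, _PROB_CLIP, 1.0 - _PROB_CLIP)
    return float(-2.0 * np.mean(y * np.log(prob) + (1 - y) * np.log(1 - prob)))


def cv_lambda_min(
    X: np.ndarray,
    y: np.ndarray,
    folds: int = 5,
    seed: int = 0,
    n_lambda: int = 100,
    eps_ratio: float = 1e-3,
    metric: str = "deviance",
) -> CvResult:
    """lambda_min by stratified k-fold CV on the full-data penalty grid.

    Default criterion is the mean out-of-fold binomial deviance; ``metric=
    'auc'`` maximizes the out-of-fold AUC instead. Ties go to the larger
    (sparser) penalty.
    """
    if metric not in ("deviance", "auc"):
        raise ValueError(f"unknown metric: {metric!r}")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    fold_idx = _stratified_folds(y, folds, rng)
    grid = lambda_path(X, y, n_lambda=n_lambda, eps_ratio=eps_ratio).lambdas

    per_fold = np.empty((folds, len(grid)))
    for f, test_idx in enumerate(fold_idx):
        train = np.setdiff1d(np.arange(len(y)), test_idx)
        b0, b = None, None
        for li, lam in enumerate(grid):
            m = fit_lasso_logistic(X[train], y[train], lam, beta0=b0, beta=b)
            b0, b = m.intercept, m.coefficients
            prob = m.predict_proba(X[test_idx])
            if metric == "deviance":
                per_fold[f, li] = _deviance(y[test_idx], prob)
            else:
                per_fold[f, li] = -_auc(prob, y[test_idx].astype(bool))
    cv_mean = per_fold.mean(axis=0)
    cv_se = per_fold.std(axis=0, ddof=1) / math.sqrt(folds)
    # argmin over the grid; grid is decreasing, so the first minimum is the
    # largest (sparsest) lambda among ties
    best = int(np.argmin(cv_mean))
    if metric == "auc":
        cv_mean = -cv_mean
    return CvResult(float(grid[best]), grid, cv_mean, cv_se, folds, seed)


def bootstrap_stability(
    X: np.ndarray,
    y: np.ndarray,
    B: int,
    seed: int,
    lambda_: float,
) -> StabilityResult:
    """Refit at a fixed penalty on B row resamples; non-zero selection rates.

    Resamples missing a class are redrawn so exactly B refits contribute.
    X is used as given (standardized once on the full data), keeping the
    penalty comparable across resamples.
    """
    if B < 1:
        raise ValueError("B must be at least 1")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if y.min() == y.max():
        raise ValueError("cannot resample a single-class cohort")
    rng = np.random.default_rng(seed)
    n, p = X.shape
    nonzero = np.zeros(p)
    aucs = np.empty(B)
    redrawn = 0
    for b_i in range(B):
        while True:
            idx = rng.integers(0, n, size=n)
            if 0.0 < y[idx].mean() < 1.0:
                break
            redrawn += 1
        m = fit_lasso_logistic(X[idx], y[idx], lambda_)
        nonzero += m.coefficients != 0.0
        prob = m.predict_proba(X[idx])
        aucs[b_i] = _auc(prob, y[idx].astype(bool))
    return StabilityResult(nonzero / B, B, aucs, redrawn)


# ---------------------------------------------------------------------------
# clinical design matrix
# ---------------------------------------------------------------------------

def cohort_design_matrix(cohort: CohortTable) -> tuple[np.ndarray, np.ndarray]:
    """(X, y) with the six clinical predictors in :data:`PREDICTOR_NAMES` order.

    y = 1 for non-responders (the positive, steroid-resistant class).
    """
    X = np.array([
        [r.fgl2, r.tsab_quartile, float(r.smoking), r.age,
         float(r.female), float(r.hyperthyroid)]
        for r in cohort.records
    ])
    y = np.array([0.0 if r.responder else 1.0 for r in cohort.records])
    return X, y
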