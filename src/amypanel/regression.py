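"""Linear prediction of amyloid burden with leave-one-out validation.

The model is ordinary least squares of the continuous amyloid burden on
the five covariates plus a candidate analyte subset.  Analyte columns
are rescaled to unit sample standard deviation (without centering, so
every analyte gets equal influence while intercept interpretation is
preserved for comparability with prior work).  Predictive performance is
the LOO CV R^2: the squared Pearson correlation between the n
leave-one-out predictions and the observed burden -- note this is *not*
1 - PRESS/SST.  Significance comes from a permutation null (burden
permuted across subjects, design fixed), and clinical utility from
dichotomizing both observed and predicted burden at a fixed threshold
(default 1.5) into PiB-positive/negative classes.

LOO predictions are computed exactly via the hat-matrix identity
e_i / (1 - h_ii) rather than n refits; tests verify equality with the
naive refit loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CohortTable, complete_cases
from .cluster import ClusterReduction, cut_and_represent
from .screen import ScreenResult

__all__ = [
    "CVFit",
    "PiBClassification",
    "SweepResult",
    "scale_unit_sd",
    "fit_ols",
    "loo_cv_r2",
    "permutation_test",
    "sweep_cutoffs",
    "classify_pib",
]


@dataclass
class CVFit:
    """Full-data coefficients plus leave-one-out predictive summary."""

    predictors: tuple[str, ...]
    coefficients: np.ndarray  # intercept first
    loo_predictions: np.ndarray
    cv_r2: float
    full_r2: float
    n: int
    perm_p: float | None = None


@dataclass(frozen=True)
class PiBClassification:
    """Confusion of predicted vs actual PiB class at a burden threshold."""

    threshold: float
    tp: int
    fn: int
    fp: int
    tn: int

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)


def scale_unit_sd(matrix):
    """Divide each column by its sample SD (ddof=1); no centering.

    Accepts a DataFrame or 2-d array; returns the same type.  A
    zero-variance column raises, naming the analyte where possible.
    """
    if isinstance(matrix, pd.DataFrame):
        sd = matrix.std(ddof=1)
        zero = sd[~(sd > 0)]
        if len(zero):
            raise ValueError(f"zero-variance analyte column {zero.index[0]!r}")
        return matrix / sd
    arr = np.asarray(matrix, dtype=float)
    sd = arr.std(axis=0, ddof=1)
    if np.any(~(sd > 0)):
        j = int(np.flatnonzero(~(sd > 0))[0])
        raise ValueError(f"zero-variance column at index {j}")
    return arr / sd


def _design(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return np.column_stack([np.ones(len(X)), X])


def _check_rank(A: np.ndarray, names: list[str] | None) -> None:
    """Raise listing the collinear columns if A is rank deficient."""
    n, p = A.shape
    if np.linalg.matrix_rank(A) == p:
        return
    bad = []
    rank = 0
    for j in range(1, p):  # skip intercept
        r = np.linalg.matrix_rank(A[:, : j + 1])
        if r == rank + 1:
            rank = r
        else:
            bad.append(names[j - 1] if names else f"column {j - 1}")
    raise ValueError(f"design matrix is rank deficient; collinear: {bad}")


def fit_ols(y, X, names: list[str] | None = None) -> np.ndarray:
    """Least-squares coefficients with intercept (intercept first)."""
    y = np.asarray(y, dtype=float)
    A = _design(X)
    if len(y) <= A.shape[1]:
        raise ValueError("more coefficients than observations")
    _check_rank(A, names)
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return coef


def _hat_and_q(A: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    q, _ = np.linalg.qr(A)
    return (q * q).sum(axis=1), q


def loo_cv_r2(y, X, names: list[str] | None = None) -> CVFit:
    """Leave-one-out predictions and CV R^2 (squared Pearson).

    Each subject is predicted from a model fit to the other n-1; the CV
    R^2 is the squared Pearson correlation between those predictions and
    the observed values.
    """
    y = np.asarray(y, dtype=float)
    A = _design(X)
    n, p1 = A.shape
    if n <= p1 + 1:
        raise ValueError("need n > number of predictors + 2 for LOO")
    _check_rank(A, names)
    h, q = _hat_and_q(A)
    if np.any(h >= 1.0 - 1e-10):
        raise ValueError("a leave-one-out fit is rank deficient (leverage 1)")
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    loo_pred = y - resid / (1.0 - h)
    cv_r2 = _pearson_sq(loo_pred, y)
    sst = np.sum((y - y.mean()) ** 2)
    full_r2 = float(1.0 - (resid @ resid) / sst) if sst > 0 else 0.0
    preds = tuple(names) if names else tuple(f"x{j}" for j in range(p1 - 1))
    return CVFit(
        predictors=preds,
        coefficients=coef,
        loo_predictions=loo_pred,
        cv_r2=cv_r2,
        full_r2=full_r2,
        n=n,
    )


def _pearson_sq(a: np.ndarray, b: np.ndarray) -> float:
    sa = a.std()
    sb = b.std()
    if sa == 0 or sb == 0:
        return 0.0
    r = float(np.corrcoef(a, b)[0, 1])
    return min(1.0, r * r)


def permutation_test(
    y,
    X,
    B: int,
    seed: int | np.random.Generator = 0,
    convention: str = "count",
) -> float:
    """Permutation p-value for the LOO CV R^2.

    The burden vector y is permuted uniformly B times with the design
    fixed, the LOO CV R^2 recomputed each time, and the p-value is the
    fraction of permutations whose CV R^2 reaches the observed one.
    ``convention='count'`` gives count/B (can be exactly 0);
    ``'add_one'`` gives (count+1)/(B+1).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if convention not in {"count", "add_one"}:
        raise ValueError("convention must be 'count' or 'add_one'")
    y = np.asarray(y, dtype=float)
    A = _design(X)
    _check_rank(A, None)
    h, q = _hat_and_q(A)
    if np.any(h >= 1.0 - 1e-10):
        raise ValueError("a leave-one-out fit is rank deficient (leverage 1)")
    one_minus_h = 1.0 - h

    def cv(yv: np.ndarray) -> float:
        resid = yv - q @ (q.T @ yv)
        return _pearson_sq(yv - resid / one_minus_h, yv)

    observed = cv(y)
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    count = 0
    for _ in range(B):
        if cv(y[rng.permutation(len(y))]) >= observed:
            count += 1
    if convention == "count":
        return count / B
    return (count + 1) / (B + 1)


@dataclass
class SweepResult:
    """Per-cut CV fits over the clustering sweep, plus the baseline."""

    per_k: dict[int, CVFit]
    best_k: int
    baseline: CVFit  # covariates only

    @property
    def best(self) -> CVFit:
        return self.per_k[self.best_k]

    def frame(self) -> pd.DataFrame:
        ks = sorted(self.per_k)
        return pd.DataFrame(
            {
                "k": ks,
                "cv_r2": [self.per_k[k].cv_r2 for k in ks],
                "full_r2": [self.per_k[k].full_r2 for k in ks],
                "n_predictors": [len(self.per_k[k].predictors) for k in ks],
                "chosen": [k == self.best_k for k in ks],
            }
        )


def sweep_cutoffs(
    table: CohortTable,
    reduction: ClusterReduction,
    screen: list[ScreenResult],
    covariates: list[str],
    endophenotype: str = "amyloid_burden",
    per_fold_scaling: bool = False,
) -> SweepResult:
    """LOO CV R^2 at every clustering cut, on one shared sample.

    For k = m..1 the design is covariates plus the k cluster
    representatives (analytes unit-SD scaled); the chosen k maximizes
    the CV R^2, ties resolved toward fewer analytes.  The
    covariates-only model is returned as the baseline.  By default
    analytes are scaled once on the full sample before the LOO loop;
    ``per_fold_scaling=True`` recomputes the scale inside each fold
    (leakage-free variant).
    """
    m = reduction.m
    analytes = list(reduction.analytes)
    sub = complete_cases(table, [endophenotype, *covariates, *analytes])
    y = sub.data[endophenotype].to_numpy()
    cov = sub.data[list(covariates)].to_numpy() if covariates else np.empty((len(y), 0))
    panel = sub.data[analytes]
    scaled = scale_unit_sd(panel)
    per_k: dict[int, CVFit] = {}
    for k in range(m, 0, -1):
        reps = cut_and_represent(reduction, screen, k)
        names = [*covariates, *reps]
        if per_fold_scaling:
            fit = _loo_per_fold_scaled(y, cov, panel[reps].to_numpy(), names)
        else:
            X = np.column_stack([cov, scaled[reps].to_numpy()])
            fit = loo_cv_r2(y, X, names)
        per_k[k] = fit
    best_k = min(per_k, key=lambda k: (-per_k[k].cv_r2, k))
    baseline = loo_cv_r2(y, cov, list(covariates))
    return SweepResult(per_k=per_k, best_k=best_k, baseline=baseline)


def _loo_per_fold_scaled(
    y: np.ndarray, cov: np.ndarray, panel: np.ndarray, names: list[str]
) -> CVFit:
    """Naive LOO loop rescaling the analyte SDs within every fold."""
    n = len(y)
    preds = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        sd = panel[keep].std(axis=0, ddof=1)
        if np.any(~(sd > 0)):
            raise ValueError("zero-variance analyte inside a fold")
        A = _design(np.column_stack([cov[keep], panel[keep] / sd]))
        coef, *_ = np.linalg.lstsq(A, y[keep], rcond=None)
        xi = np.concatenate([[1.0], cov[i], panel[i] / sd])
        preds[i] = xi @ coef
    sd = panel.std(axis=0, ddof=1)
    full = loo_cv_r2(y, np.column_stack([cov, panel / sd]), names)
    full.loo_predictions = preds
    full.cv_r2 = _pearson_sq(preds, y)
    return full


def classify_pib(actual, predicted, threshold: float = 1.5) -> PiBClassification:
    """Dichotomize both vectors at the threshold and cross-tabulate.

    Positive means strictly greater than the threshold.  Sensitivity is
    tp/(tp+fn) over actual positives, specificity tn/(tn+fp) over actual
    negatives; either class being empty in ``actual`` raises, because
    the corresponding rate is undefined.
    """
    actual = np.asarray(actual, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if actual.shape != predicted.shape:
        raise ValueError("actual and predicted must have equal length")
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    a = actual > threshold
    p = predicted > threshold
    tp = int(np.sum(a & p))
    fn = int(np.sum(a & ~p))
    fp = int(np.sum(~a & p))
    tn = int(np.sum(~a & ~p))
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError(
            "one actual PiB class is empty; sensitivity/specificity undefined"
        )
    return PiBClassification(threshold=threshold, tp=tp, fn=fn, fp=fp, tn=tn)
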