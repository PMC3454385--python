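"""LMG relative-importance decomposition of regression R^2.

The LMG score of predictor j is its average sequential contribution to
in-sample R^2 over all p! orderings of the predictors -- a Shapley
value on R^2.  It is computed exactly by subset enumeration:

    share_j = sum over S subset of P\\{j} of w(|S|) * (R^2(S+j) - R^2(S)),
    w(s) = s! (p-s-1)! / p!

The shares are non-negative (adding a predictor never lowers in-sample
R^2) and sum to the full-model R^2.  Exact enumeration costs 2^p model
fits and is capped at p = 20 (~10^6 fits); the amyloid model of
interest has 18 predictors (5 covariates + 13 analytes), inside the cap.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import factorial

import numpy as np

__all__ = ["ImportanceResult", "lmg", "MAX_PREDICTORS"]

MAX_PREDICTORS = 20


@dataclass
class ImportanceResult:
    predictors: tuple[str, ...]
    shares: np.ndarray
    full_r2: float

    def frame(self):
        import pandas as pd

        order = np.argsort(-self.shares, kind="stable")
        return pd.DataFrame(
            {
                "predictor": [self.predictors[i] for i in order],
                "lmg_share": self.shares[order],
                "share_of_r2": self.shares[order] / self.full_r2
                if self.full_r2 > 0
                else np.nan,
            }
        )


def _subset_r2(Xc: np.ndarray, yc: np.ndarray, p: int) -> np.ndarray:
    """In-sample R^2 for every predictor subset, indexed by bitmask."""
    C = Xc.T @ Xc
    cxy = Xc.T @ yc
    ssy = float(yc @ yc)
    r2 = np.zeros(1 << p)
    idx_lists: list[list[int]] = [[] for _ in range(1 << p)]
    for mask in range(1, 1 << p):
        low = mask & -mask
        idx_lists[mask] = idx_lists[mask ^ low] + [low.bit_length() - 1]
    for mask in range(1, 1 << p):
        idx = idx_lists[mask]
        b = np.linalg.solve(C[np.ix_(idx, idx)], cxy[idx])
        r2[mask] = float(b @ cxy[idx]) / ssy
    return r2


def lmg(y, X, names: list[str] | None = None) -> ImportanceResult:
    """Exact LMG shares of the in-sample R^2 across predictors.

    ``X`` is the (n, p) predictor matrix (intercept handled
    internally); shares come back in column order and sum to the
    full-model R^2 (asserted to 1e-8).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if p > MAX_PREDICTORS:
        raise ValueError(
            f"{p} predictors exceed the exact-enumeration bound "
            f"{MAX_PREDICTORS}; reduce the predictor subset first"
        )
    if names is None:
        names = [f"x{j}" for j in range(p)]
    if len(names) != p:
        raise ValueError("names length must match predictor count")
    A = np.column_stack([np.ones(n), X])
    if np.linalg.matrix_rank(A) < p + 1:
        raise ValueError("design matrix (with intercept) is rank deficient")
    yc = y - y.mean()
    if not np.any(yc):
        raise ValueError("response is constant; R^2 undefined")
    Xc = X - X.mean(axis=0)

    r2 = _subset_r2(Xc, yc, p)
    w = np.array(
        [factorial(s) * factorial(p - s - 1) / factorial(p) for s in range(p)]
    )
    masks = np.arange(1 << p, dtype=np.int64)
    sizes = np.zeros(1 << p, dtype=np.int64)
    mm = masks.copy()
    while np.any(mm):
        sizes += mm & 1
        mm >>= 1
    shares = np.empty(p)
    for j in range(p):
        bit = 1 << j
        without = masks[(masks & bit) == 0]
        shares[j] = float(
            np.sum(w[sizes[without]] * (r2[without | bit] - r2[without]))
        )
    full = float(r2[-1])
    if abs(shares.sum() - full) > 1e-8:
        raise AssertionError(
            f"LMG shares sum {shares.sum():.12f} != full R^2 {full:.12f}"
        )
    return ImportanceResult(tuple(names), shares, full)
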