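"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths: ranking plus
normal-equations residualization for the partial Spearman, per-subject
refits for LOO, scipy's linkage for complete-linkage clustering, and
explicit enumeration of all predictor orderings for the LMG shares.
"""

from itertools import permutations
from math import factorial

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from scipy.stats import rankdata


def partial_spearman_oracle(x, y, Z=None):
    """Rank, residualize by explicit normal equations, correlate."""
    rx = rankdata(x).astype(float)
    ry = rankdata(y).astype(float)
    if Z is None or np.size(Z) == 0:
        return float(np.corrcoef(rx, ry)[0, 1])
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if Z.shape[0] != len(rx):
        Z = Z.T
    rz = np.column_stack([rankdata(Z[:, j]) for j in range(Z.shape[1])])
    A = np.column_stack([np.ones(len(rx)), rz])
    AtA = A.T @ A
    ex = rx - A @ np.linalg.solve(AtA, A.T @ rx)
    ey = ry - A @ np.linalg.solve(AtA, A.T @ ry)
    return float((ex @ ey) / np.sqrt((ex @ ex) * (ey @ ey)))


def loo_predictions_oracle(y, X):
    """Refit on n-1 subjects for each held-out subject, predict it."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n = len(y)
    A = np.column_stack([np.ones(n), X])
    preds = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        coef, *_ = np.linalg.lstsq(A[keep], y[keep], rcond=None)
        preds[i] = A[i] @ coef
    return preds


def complete_linkage_oracle(D):
    """scipy complete linkage, translated to per-k leaf partitions.

    Returns (heights, partitions) where partitions[k] is the set of
    frozensets of leaf indices at cluster count k.
    """
    m = D.shape[0]
    Z = linkage(squareform(D, checks=False), method="complete")
    members = {i: frozenset([i]) for i in range(m)}
    partitions = {m: set(members.values())}
    heights = []
    for step, (a, b, h, _) in enumerate(Z):
        new = members.pop(int(a)) | members.pop(int(b))
        members[m + step] = new
        heights.append(float(h))
        partitions[m - step - 1] = set(members.values())
    return heights, partitions


def kruskal_oracle(values, groups):
    """Tie-corrected Kruskal-Wallis H from the defining formula."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    n = len(values)
    r = rankdata(values)
    h = 0.0
    for g in np.unique(groups):
        rg = r[groups == g]
        h += rg.sum() ** 2 / len(rg)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(values, return_counts=True)
    correction = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
    return h / correction


def lmg_orderings_oracle(y, X):
    """Average sequential R^2 contribution over all p! orderings."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape

    def r2(cols):
        A = np.column_stack([np.ones(n), X[:, list(cols)]]) if cols else np.ones((n, 1))
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ coef
        sst = np.sum((y - y.mean()) ** 2)
        return 1.0 - (resid @ resid) / sst

    shares = np.zeros(p)
    for order in permutations(range(p)):
        prev: tuple = ()
        for j in order:
            shares[j] += r2(prev + (j,)) - r2(prev)
            prev = prev + (j,)
    return shares / factorial(p)
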