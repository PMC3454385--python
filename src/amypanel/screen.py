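"""Nonparametric association screening.

The central statistic is the partial Spearman rank correlation (partial
SRC): all variables -- response, predictor, covariates -- are replaced
by their ranks (average ranks for ties) and the partial Pearson
correlation of the ranked response and predictor given the ranked
covariates is computed.  Its two-sided p-value uses the t approximation
t = rho * sqrt((n-2-k)/(1-rho^2)) on n-2-k degrees of freedom, k being
the number of covariates.

Also here: Benjamini-Hochberg step-up adjustment over the full panel
size, tie-corrected Kruskal-Wallis group tests, and Monte-Carlo
contingency-table p-values with fixed margins (Patefield sampling).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .cohort import CohortTable, complete_cases

__all__ = [
    "ScreenResult",
    "GroupTestResult",
    "partial_spearman",
    "screen_panel",
    "screen_frame",
    "bh_adjust",
    "kruskal_wallis",
    "mc_contingency_p",
]


@dataclass(frozen=True)
class ScreenResult:
    """Per-analyte association with a named endophenotype."""

    analyte: str
    rho_partial: float
    p_raw: float
    p_bh: float
    n_used: int
    covariates_used: tuple[str, ...]
    selected: bool


@dataclass(frozen=True)
class GroupTestResult:
    statistic: float
    p_value: float
    groups: tuple
    method: str
    n_mc: int = 0


def _residualize(r: np.ndarray, rz: np.ndarray) -> np.ndarray:
    """Least-squares residuals of r on [1, rz]."""
    design = np.column_stack([np.ones(len(r)), rz])
    coef, *_ = np.linalg.lstsq(design, r, rcond=None)
    return r - design @ coef


def partial_spearman(
    x: np.ndarray, y: np.ndarray, Z: np.ndarray | None = None
) -> tuple[float, float]:
    """Partial Spearman rank correlation of x and y given covariates Z.

    Parameters
    ----------
    x, y : 1-d arrays of equal length n, no missing values.
    Z : optional (n, k) covariate matrix; ``None`` or zero columns
        reduces to the plain Spearman correlation.

    Returns
    -------
    (rho, p) : the partial SRC and its two-sided t-approximation
    p-value on n - 2 - k degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or len(x) != len(y):
        raise ValueError("x and y must be 1-d arrays of equal length")
    n = len(x)
    if Z is None:
        Z = np.empty((n, 0))
    Z = np.asarray(Z, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    if Z.shape[0] != n:
        raise ValueError("covariate matrix row count does not match x")
    k = Z.shape[1]
    if n <= k + 2:
        raise ValueError(f"need n > k + 2 observations (n={n}, k={k})")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise ValueError("constant variable after ranking; correlation undefined")
    if k:
        rz = np.column_stack([stats.rankdata(Z[:, j]) for j in range(k)])
        if np.linalg.matrix_rank(np.column_stack([np.ones(n), rz])) < k + 1:
            raise ValueError("rank-deficient covariate matrix")
        ex = _residualize(rx, rz)
        ey = _residualize(ry, rz)
        denom = np.sqrt(ex @ ex) * np.sqrt(ey @ ey)
        if denom == 0:
            raise ValueError("covariates explain a variable exactly; correlation undefined")
        rho = float((ex @ ey) / denom)
    else:
        rho = float(np.corrcoef(rx, ry)[0, 1])
    rho = float(np.clip(rho, -1.0, 1.0))
    df = n - 2 - k
    if abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt(df / (1.0 - rho * rho))
        p = float(2.0 * stats.t.sf(abs(t), df))
    return rho, p


def bh_adjust(p: np.ndarray, m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    ``m`` may exceed ``len(p)`` when tests not individually listed still
    count toward the correction (e.g. the full analyte panel when only
    significant rows are carried forward).
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be a 1-d vector")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = len(p)
    if m < len(p):
        raise ValueError("m must be at least len(p)")
    order = np.argsort(p, kind="stable")
    ranks = np.arange(1, len(p) + 1)
    q = np.minimum(1.0, p[order] * m / ranks)
    q = np.minimum.accumulate(q[::-1])[::-1]
    out = np.empty_like(q)
    out[order] = q
    # guard the p_bh >= p_raw invariant against rounding in p*m/rank
    return np.maximum(out, p)


def screen_panel(
    table: CohortTable,
    endophenotype: str,
    covariates: list[str],
    alpha: float = 0.05,
) -> list[ScreenResult]:
    """Partial-SRC screen of every analyte against an endophenotype.

    Each analyte is tested over its own complete cases (analyte,
    endophenotype and covariates all observed).  BH adjustment uses the
    full panel size m.  Results are sorted by raw p ascending; those
    with p_raw < alpha carry the selected flag.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    analytes = table.analyte_names
    if not analytes:
        raise ValueError("cohort table has no analytes")
    for col in [endophenotype, *covariates]:
        if col not in table.data.columns:
            raise ValueError(f"column {col!r} not in table")
    rows = []
    for name in analytes:
        sub = complete_cases(table, [name, endophenotype, *covariates])
        rho, p = partial_spearman(
            sub.data[name].to_numpy(),
            sub.data[endophenotype].to_numpy(),
            sub.data[list(covariates)].to_numpy() if covariates else None,
        )
        rows.append((name, rho, p, sub.n_subjects))
    p_raw = np.array([r[2] for r in rows])
    p_bh = bh_adjust(p_raw, m=len(analytes))
    results = [
        ScreenResult(
            analyte=name,
            rho_partial=rho,
            p_raw=p,
            p_bh=float(q),
            n_used=n,
            covariates_used=tuple(covariates),
            selected=bool(p < alpha),
        )
        for (name, rho, p, n), q in zip(rows, p_bh)
    ]
    results.sort(key=lambda r: (r.p_raw, -abs(r.rho_partial), r.analyte))
    return results


def screen_frame(results: list[ScreenResult]) -> pd.DataFrame:
    """Tabular view of a screen (Table-2-style columns)."""
    return pd.DataFrame(
        {
            "analyte": [r.analyte for r in results],
            "rho_partial": [r.rho_partial for r in results],
            "p_raw": [r.p_raw for r in results],
            "p_bh": [r.p_bh for r in results],
            "n_used": [r.n_used for r in results],
            "selected": [r.selected for r in results],
        }
    )


def kruskal_wallis(values, groups) -> GroupTestResult:
    """Tie-corrected Kruskal-Wallis chi-square test across groups."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if len(values) != len(groups):
        raise ValueError("values and groups must have equal length")
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    samples = [values[groups == g] for g in labels]
    if any(len(s) == 0 for s in samples):
        raise ValueError("every group needs at least one observation")
    if np.ptp(values) == 0:
        raise ValueError("all values identical; statistic undefined after tie correction")
    h, p = stats.kruskal(*samples)
    return GroupTestResult(float(h), float(p), tuple(labels), "kruskal_wallis", 0)


def _log_cond_prob(table: np.ndarray) -> float:
    """Log conditional probability of a contingency table given margins."""
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    n = table.sum()
    return float(
        gammaln(rows + 1).sum()
        + gammaln(cols + 1).sum()
        - gammaln(n + 1)
        - gammaln(table + 1).sum()
    )


def mc_contingency_p(
    table2d, n_mc: int = 2000, seed: int | np.random.Generator = 0
) -> GroupTestResult:
    """Monte-Carlo contingency-table p-value with fixed margins.

    Samples ``n_mc`` tables uniformly conditional on the observed
    margins (Patefield algorithm) and reports the add-one estimate
    p = (1 + #{tables at most as probable as observed}) / (n_mc + 1),
    the ordering being by conditional table probability.  The reported
    statistic is -log conditional probability of the observed table.
    """
    obs = np.asarray(table2d)
    if obs.ndim != 2:
        raise ValueError("need a 2-d contingency table")
    if np.any(obs < 0) or not np.issubdtype(obs.dtype, np.integer):
        raise ValueError("table must contain non-negative integer counts")
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    if np.any(rows == 0) or np.any(cols == 0):
        raise ValueError("zero row or column margin")
    if n_mc < 1:
        raise ValueError("n_mc must be >= 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    dist = stats.random_table(rows, cols)
    sims = np.asarray(
        dist.rvs(n_mc, method="patefield", random_state=rng)
    ).reshape(n_mc, *obs.shape)
    lp_obs = _log_cond_prob(obs)
    const = lp_obs + gammaln(obs + 1).sum()
    lp_sim = const - gammaln(sims + 1).sum(axis=(1, 2))
    # R-style tolerance: a simulated table "as extreme" if its log
    # probability does not exceed the observed one by more than rounding.
    tol = 64 * np.finfo(float).eps * abs(lp_obs)
    count = int(np.sum(lp_sim <= lp_obs + tol))
    p = (1 + count) / (n_mc + 1)
    return GroupTestResult(
        statistic=-lp_obs,
        p_value=float(p),
        groups=tuple(range(obs.shape[1])),
        method="mc_contingency",
        n_mc=n_mc,
    )
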