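"""Redundancy reduction of a screened analyte set.

Screened analytes are often strongly inter-correlated (e.g. acute-phase
proteins moving together), so using all of them in one regression
overfits a small cohort.  The panel is therefore clustered by
complete-linkage agglomeration on the signed correlation distance
d_ij = 1 - rho_ij, where rho_ij is the partial Spearman correlation
between analytes i and j given the covariates (anti-correlated analytes
are far apart, d up to 2).  Cutting the tree at every cluster count k
and keeping the most-associated analyte per cluster yields a nested
family of candidate predictor sets and a deterministic removal order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CohortTable, complete_cases
from .screen import ScreenResult, partial_spearman

__all__ = [
    "ClusterReduction",
    "pairwise_partial_src",
    "agglomerate",
    "reduce_panel",
    "cut_and_represent",
    "removal_order",
]


def pairwise_partial_src(
    table: CohortTable, analytes: list[str], covariates: list[str]
) -> pd.DataFrame:
    """Matrix of pairwise partial Spearman correlations between analytes.

    Computed on the subjects with complete data across *all* listed
    analytes and covariates, so every entry shares one sample.
    """
    if len(analytes) < 2:
        raise ValueError("need at least two analytes")
    sub = complete_cases(table, [*analytes, *covariates])
    Z = sub.data[list(covariates)].to_numpy() if covariates else None
    m = len(analytes)
    rho = np.eye(m)
    for i in range(m):
        xi = sub.data[analytes[i]].to_numpy()
        for j in range(i + 1, m):
            r, _ = partial_spearman(xi, sub.data[analytes[j]].to_numpy(), Z)
            rho[i, j] = rho[j, i] = r
    return pd.DataFrame(rho, index=analytes, columns=analytes)


def agglomerate(distance: np.ndarray) -> list[tuple[int, int, float]]:
    """Complete-linkage agglomerative merge sequence.

    ``distance`` is a symmetric matrix with finite entries (zero
    diagonal).  Returns m-1 merges as (id_a, id_b, height) with leaves
    numbered 0..m-1 and each new cluster numbered m, m+1, ...; the
    inter-cluster distance is the maximum pairwise member distance, so
    heights are non-decreasing.  Ties in the minimum inter-cluster
    distance are broken toward the pair with lexicographically smallest
    member indices, making the sequence deterministic.
    """
    D = np.asarray(distance, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance must be a square matrix")
    if not np.all(np.isfinite(D)):
        raise ValueError("distance matrix contains non-finite entries")
    if not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    m = D.shape[0]
    members: dict[int, tuple[int, ...]] = {i: (i,) for i in range(m)}
    merges: list[tuple[int, int, float]] = []
    next_id = m
    while len(members) > 1:
        best = None
        ids = sorted(members)
        for ai, a in enumerate(ids):
            for b in ids[ai + 1 :]:
                d = float(
                    max(D[i, j] for i in members[a] for j in members[b])
                )
                key = (d, tuple(sorted(members[a] + members[b])))
                if best is None or key < best[0]:
                    best = (key, a, b)
        (d, _), a, b = best
        merges.append((a, b, d))
        members[next_id] = tuple(sorted(members[a] + members[b]))
        del members[a], members[b]
        next_id += 1
    return merges


@dataclass
class ClusterReduction:
    """Merge tree over analytes with per-cut groupings.

    ``merges`` uses the scheme of :func:`agglomerate`; ``groups(k)``
    replays the first m-k merges and returns the k clusters (each a
    name list, leaf order).
    """

    analytes: tuple[str, ...]
    distance: pd.DataFrame
    merges: list[tuple[int, int, float]]

    @property
    def m(self) -> int:
        return len(self.analytes)

    def groups(self, k: int) -> list[list[str]]:
        if not 1 <= k <= self.m:
            raise ValueError(f"k must be in 1..{self.m}")
        members: dict[int, tuple[int, ...]] = {i: (i,) for i in range(self.m)}
        next_id = self.m
        for a, b, _ in self.merges[: self.m - k]:
            members[next_id] = tuple(sorted(members[a] + members[b]))
            del members[a], members[b]
            next_id += 1
        clusters = sorted(members.values())
        return [[self.analytes[i] for i in c] for c in clusters]


def reduce_panel(
    table: CohortTable, analytes: list[str], covariates: list[str]
) -> ClusterReduction:
    """Cluster a screened analyte set on 1 - pairwise partial SRC."""
    rho = pairwise_partial_src(table, analytes, covariates)
    distance = 1.0 - rho
    np.fill_diagonal(distance.values, 0.0)
    merges = agglomerate(distance.to_numpy())
    return ClusterReduction(tuple(analytes), distance, merges)


def _rank_key(screen_by_name: dict[str, ScreenResult], name: str):
    r = screen_by_name[name]
    return (r.p_raw, -abs(r.rho_partial), r.analyte)


def cut_and_represent(
    reduction: ClusterReduction, screen: list[ScreenResult], k: int
) -> list[str]:
    """Representatives at cluster count k: smallest screening p per group.

    Ties go to the larger |rho|, then the lexicographically smaller
    name.  Returned in order of increasing p (best first).
    """
    by_name = {r.analyte: r for r in screen}
    missing = [a for a in reduction.analytes if a not in by_name]
    if missing:
        raise ValueError(f"screen results missing for analytes: {missing}")
    reps = [
        min(group, key=lambda name: _rank_key(by_name, name))
        for group in reduction.groups(k)
    ]
    reps.sort(key=lambda name: _rank_key(by_name, name))
    return reps


def removal_order(
    reduction: ClusterReduction, screen: list[ScreenResult]
) -> list[str]:
    """Analyte dropped at each successive merge, length m-1.

    Walking k = m-1 down to 1, the dropped analyte is the representative
    present at k+1 but absent at k (the losing child of the new merge).
    """
    order = []
    prev = set(cut_and_represent(reduction, screen, reduction.m))
    for k in range(reduction.m - 1, 0, -1):
        cur = set(cut_and_represent(reduction, screen, k))
        dropped = prev - cur
        if len(dropped) != 1:
            raise AssertionError("representative sets are not nested")
        order.append(dropped.pop())
        prev = cur
    return order
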