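import numpy as np
import pandas as pd
import pytest

from amypanel.cluster import (
    ClusterReduction,
    agglomerate,
    cut_and_represent,
    pairwise_partial_src,
    reduce_panel,
    removal_order,
)
from amypanel.cohort import COVARIATES, CohortSchema, CohortTable
from amypanel.screen import ScreenResult, partial_spearman

from oracles import complete_linkage_oracle


def _screen(pairs):
    """Build ScreenResults from (name, p, rho) triples."""
    return [
        ScreenResult(name, rho, p, p, 50, (), True) for name, p, rho in pairs
    ]


def _merge_partitions(analytes, merges):
    m = len(analytes)
    members = {i: frozenset([i]) for i in range(m)}
    parts = {m: set(members.values())}
    for step, (a, b, _) in enumerate(merges):
        members[m + step] = members.pop(a) | members.pop(b)
        parts[m - step - 1] = set(members.values())
    return parts


class TestAgglomerate:
    def test_worked_three_point_example(self):
        D = np.array([[0.0, 0.2, 0.9], [0.2, 0.0, 0.8], [0.9, 0.8, 0.0]])
        merges = agglomerate(D)
        assert merges[0][:2] == (0, 1)
        assert merges[0][2] == pytest.approx(0.2)
        assert merges[1][2] == pytest.approx(0.9)  # complete linkage: max(0.9, 0.8)

    def test_identical_analytes_merge_first_at_zero(self):
        D = np.array([[0.0, 0.0, 0.5], [0.0, 0.0, 0.5], [0.5, 0.5, 0.0]])
        merges = agglomerate(D)
        assert merges[0] == (0, 1, 0.0)

    def test_heights_non_decreasing(self, rng):
        for _ in range(20):
            m = rng.integers(3, 10)
            A = rng.uniform(0, 2, size=(m, m))
            D = (A + A.T) / 2
            np.fill_diagonal(D, 0)
            heights = [h for *_, h in agglomerate(D)]
            assert all(a <= b + 1e-12 for a, b in zip(heights, heights[1:]))

    def test_matches_scipy_linkage_on_random_matrices(self, rng):
        for _ in range(30):
            m = int(rng.integers(3, 12))
            A = rng.uniform(0, 2, size=(m, m))
            D = (A + A.T) / 2
            np.fill_diagonal(D, 0)
            merges = agglomerate(D)
            ref_heights, ref_parts = complete_linkage_oracle(D)
            assert np.allclose([h for *_, h in merges], ref_heights)
            parts = _merge_partitions(list(range(m)), merges)
            for k in range(1, m + 1):
                assert parts[k] == ref_parts[k]

    def test_permutation_equivariance(self, rng):
        m = 7
        A = rng.uniform(0, 2, size=(m, m))
        D = (A + A.T) / 2
        np.fill_diagonal(D, 0)
        perm = rng.permutation(m)
        parts = _merge_partitions(list(range(m)), agglomerate(D))
        parts_p = _merge_partitions(list(range(m)), agglomerate(D[np.ix_(perm, perm)]))
        relabel = {
            k: {frozenset(int(perm[i]) for i in grp) for grp in v}
            for k, v in parts_p.items()
        }
        assert relabel == parts

    def test_nan_rejected(self):
        D = np.array([[0.0, np.nan], [np.nan, 0.0]])
        with pytest.raises(ValueError, match="finite"):
            agglomerate(D)


class TestPairwise:
    def test_duplicated_analyte_has_unit_off_diagonal(self, rng):
        n = 60
        a = rng.normal(size=n)
        df = pd.DataFrame(
            {
                "amyloid_burden": rng.normal(size=n),
                "a_one": a,
                "a_two": a.copy(),
                "a_other": rng.normal(size=n),
            },
            index=pd.Index([f"S{i}" for i in range(n)], name="subject_id"),
        )
        t = CohortTable(df, CohortSchema(covariates=()))
        rho = pairwise_partial_src(t, ["a_one", "a_two", "a_other"], [])
        assert rho.loc["a_one", "a_two"] == pytest.approx(1.0)
        assert np.allclose(rho.values, rho.values.T)
        assert np.allclose(np.diag(rho.values), 1.0)

    def test_independent_analytes_near_zero(self, rng):
        n = 1000
        df = pd.DataFrame(
            {f"a{i}": rng.normal(size=n) for i in range(4)}
            | {"amyloid_burden": rng.normal(size=n), "z": rng.normal(size=n)},
            index=pd.Index([f"S{i}" for i in range(n)], name="subject_id"),
        )
        t = CohortTable(df, CohortSchema(covariates=("z",)))
        rho = pairwise_partial_src(t, [f"a{i}" for i in range(4)], ["z"])
        off = rho.values[~np.eye(4, dtype=bool)]
        assert np.all(np.abs(off) < 0.1)

    def test_equals_elementwise_partial_spearman(self, transformed_small):
        table, truth = transformed_small
        analytes = list(truth.signal_analytes[:4])
        cov = list(COVARIATES)
        rho = pairwise_partial_src(table, analytes, cov)
        from amypanel.cohort import complete_cases

        sub = complete_cases(table, analytes + cov)
        Z = sub.data[cov].to_numpy()
        for i, ai in enumerate(analytes):
            for j, aj in enumerate(analytes):
                if i < j:
                    r, _ = partial_spearman(
                        sub.data[ai].to_numpy(), sub.data[aj].to_numpy(), Z
                    )
                    assert rho.iloc[i, j] == pytest.approx(r, abs=1e-12)


class TestRepresentatives:
    def _reduction(self):
        names = ("A", "B", "C")
        D = pd.DataFrame(
            [[0.0, 0.2, 0.9], [0.2, 0.0, 0.8], [0.9, 0.8, 0.0]],
            index=names,
            columns=names,
        )
        return ClusterReduction(names, D, agglomerate(D.to_numpy()))

    def test_singleton_cut_returns_everyone(self):
        red = self._reduction()
        screen = _screen([("A", 0.01, -0.3), ("B", 0.02, -0.25), ("C", 0.03, 0.2)])
        assert set(cut_and_represent(red, screen, 3)) == {"A", "B", "C"}

    def test_smallest_p_wins_within_group(self):
        red = self._reduction()
        screen = _screen([("A", 0.014, -0.3), ("B", 0.010, -0.25), ("C", 0.03, 0.2)])
        assert cut_and_represent(red, screen, 2) == ["B", "C"]

    def test_k_one_returns_global_best(self):
        red = self._reduction()
        screen = _screen([("A", 0.02, -0.3), ("B", 0.01, -0.25), ("C", 0.03, 0.2)])
        assert cut_and_represent(red, screen, 1) == ["B"]

    def test_tie_broken_by_larger_abs_rho_then_name(self):
        red = self._reduction()
        screen = _screen([("A", 0.01, -0.2), ("B", 0.01, -0.4), ("C", 0.5, 0.1)])
        assert cut_and_represent(red, screen, 2)[0] == "B"

    def test_k_out_of_range(self):
        red = self._reduction()
        screen = _screen([("A", 0.01, -0.3), ("B", 0.02, -0.2), ("C", 0.03, 0.1)])
        with pytest.raises(ValueError):
            cut_and_represent(red, screen, 0)
        with pytest.raises(ValueError):
            cut_and_represent(red, screen, 4)


class TestRemovalOrder:
    def test_hand_traced_three_analyte_order(self):
        # merge (A,B) first then C joins; p(A)<p(B)<p(C): B loses to A
        # at the first merge, C loses to A at the root
        names = ("A", "B", "C")
        D = pd.DataFrame(
            [[0.0, 0.2, 0.9], [0.2, 0.0, 0.8], [0.9, 0.8, 0.0]],
            index=names,
            columns=names,
        )
        red = ClusterReduction(names, D, agglomerate(D.to_numpy()))
        screen = _screen([("A", 0.01, -0.3), ("B", 0.02, -0.25), ("C", 0.03, 0.2)])
        assert removal_order(red, screen) == ["B", "C"]

    def test_length_and_nesting_on_random_trees(self, rng):
        for _ in range(10):
            m = int(rng.integers(3, 9))
            names = tuple(f"a{i}" for i in range(m))
            A = rng.uniform(0, 2, size=(m, m))
            D = (A + A.T) / 2
            np.fill_diagonal(D, 0)
            red = ClusterReduction(
                names, pd.DataFrame(D, index=names, columns=names), agglomerate(D)
            )
            screen = _screen(
                [(n, float(p), -0.3) for n, p in zip(names, rng.uniform(size=m))]
            )
            order = removal_order(red, screen)
            assert len(order) == m - 1
            for k in range(1, m):
                reps_k = set(cut_and_represent(red, screen, k))
                reps_k1 = set(cut_and_represent(red, screen, k + 1))
                assert reps_k <= reps_k1


def test_reduce_panel_groups_redundant_block(transformed_small):
    table, truth = transformed_small
    seed_name = next(iter(truth.block_members))
    analytes = [seed_name, *truth.block_members[seed_name],
                truth.signal_analytes[-1]]
    red = reduce_panel(table, analytes, list(COVARIATES))
    # the copies merge with their seed before the unrelated analyte joins
    parts = red.groups(2)
    block = {seed_name, *truth.block_members[seed_name]}
    assert any(set(g) == block for g in parts)
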