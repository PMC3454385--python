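import numpy as np
import pytest
from scipy import stats

from amypanel.cohort import CohortSchema, CohortTable
from amypanel.screen import (
    bh_adjust,
    kruskal_wallis,
    mc_contingency_p,
    partial_spearman,
    screen_panel,
)
from amypanel.simulate import SyntheticConfig, generate_cohort

from oracles import kruskal_oracle, partial_spearman_oracle

import pandas as pd


class TestPartialSpearman:
    def test_perfect_monotone(self):
        rho, p = partial_spearman([1, 2, 3, 4], [10, 20, 30, 40])
        assert rho == pytest.approx(1.0)
        assert p == pytest.approx(0.0)

    def test_perfect_anti_monotone(self):
        rho, _ = partial_spearman([1, 2, 3, 4], [8, 6, 4, 2])
        assert rho == pytest.approx(-1.0)

    def test_plain_case_matches_scipy(self, rng):
        x = rng.normal(size=25)
        y = rng.normal(size=25) + 0.5 * x
        rho, p = partial_spearman(x, y)
        ref = stats.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_residualization_oracle_with_one_covariate(self, rng):
        z = rng.normal(size=10)
        x = 0.6 * z + rng.normal(size=10)
        y = -0.4 * z + rng.normal(size=10)
        rho, _ = partial_spearman(x, y, z[:, None])
        assert rho == pytest.approx(partial_spearman_oracle(x, y, z), abs=1e-10)

    def test_invariant_under_monotone_transforms(self, rng):
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        Z = rng.normal(size=(30, 2))
        base, _ = partial_spearman(x, y, Z)
        warped, _ = partial_spearman(
            np.exp(x), y**3, np.column_stack([Z[:, 0], np.arctan(Z[:, 1])])
        )
        assert warped == pytest.approx(base, abs=1e-12)
        flipped, _ = partial_spearman(-x, y, Z)
        assert flipped == pytest.approx(-base, abs=1e-12)

    def test_constant_variable_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            partial_spearman([1, 1, 1, 1, 1], [1, 2, 3, 4, 5])

    def test_rank_deficient_covariates_rejected(self, rng):
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        z = rng.normal(size=12)
        with pytest.raises(ValueError, match="rank"):
            partial_spearman(x, y, np.column_stack([z, z]))

    def test_too_few_observations_rejected(self, rng):
        with pytest.raises(ValueError, match="n > k"):
            partial_spearman([1, 2, 3], [3, 1, 2], np.ones((3, 1)))

    def test_null_calibration_of_t_pvalue(self):
        # global null: across many independent panels the raw-p hit
        # rate at 0.05 must sit inside the 99% binomial envelope
        rng = np.random.default_rng(77)
        n_panels, panel, n, k = 200, 20, 50, 2
        hits = total = 0
        for _ in range(n_panels):
            y = rng.normal(size=n)
            Z = rng.normal(size=(n, k))
            for _ in range(panel):
                x = rng.normal(size=n)
                _, p = partial_spearman(x, y, Z)
                hits += p < 0.05
                total += 1
        rate = hits / total
        half = 2.576 * np.sqrt(0.05 * 0.95 / total)
        assert 0.05 - half < rate < 0.05 + half


class TestBHAdjust:
    def test_worked_step_up_examples(self):
        out = bh_adjust(np.array([0.01, 0.02, 0.03]))
        assert np.allclose(out, [0.03, 0.03, 0.03])
        # step-up: the rank-2 value is pulled down to the rank-3 minimum
        out = bh_adjust(np.array([0.005, 0.04, 0.05, 0.9]))
        assert np.allclose(out, [0.02, 0.05 * 4 / 3, 0.05 * 4 / 3, 0.9])

    def test_single_p_identity(self):
        assert bh_adjust(np.array([0.2])) == pytest.approx([0.2])

    def test_never_below_raw_and_permutation_equivariant(self, rng):
        p = rng.uniform(size=30)
        q = bh_adjust(p)
        assert np.all(q >= p - 1e-15)
        perm = rng.permutation(30)
        assert np.allclose(bh_adjust(p[perm]), q[perm])

    def test_matches_statsmodels_when_m_equals_len(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(size=40)
        _, q_ref, *_ = multipletests(p, method="fdr_bh")
        assert np.allclose(bh_adjust(p), q_ref, atol=1e-12)

    def test_external_m_scales_the_step_up(self):
        # tests not individually listed still count toward m
        out = bh_adjust(np.array([0.01, 0.02]), m=10)
        assert np.allclose(out, [0.1, 0.1])

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.5, 1.5]))
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.1, 0.2]), m=1)


class TestKruskalWallis:
    def test_equal_rank_sums_give_zero(self):
        res = kruskal_wallis([1, 4, 2, 3], ["a", "a", "b", "b"])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_separated_groups_hand_value(self):
        res = kruskal_wallis([1, 2, 3, 4, 5, 6], ["a", "a", "a", "b", "b", "b"])
        assert res.statistic == pytest.approx(3.857, abs=5e-4)

    def test_tie_correction_matches_defining_formula(self, rng):
        values = rng.integers(0, 5, size=40).astype(float)  # heavy ties
        groups = rng.integers(0, 3, size=40)
        res = kruskal_wallis(values, groups)
        assert res.statistic == pytest.approx(kruskal_oracle(values, groups), abs=1e-10)

    def test_all_identical_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            kruskal_wallis([2.0, 2.0, 2.0, 2.0], ["a", "a", "b", "b"])


class TestMCContingency:
    def test_p_bounds(self):
        res = mc_contingency_p(np.array([[5, 1], [1, 5]]), n_mc=50, seed=0)
        assert 1 / 51 <= res.p_value <= 1.0
        assert res.n_mc == 50

    def test_two_by_two_matches_fisher_exact(self):
        table = np.array([[20, 10], [10, 20]])
        res = mc_contingency_p(table, n_mc=20000, seed=3)
        p_exact = stats.fisher_exact(table).pvalue
        se = np.sqrt(p_exact * (1 - p_exact) / 20000)
        assert abs(res.p_value - p_exact) < 3 * se

    def test_proportional_table_near_one(self):
        res = mc_contingency_p(np.array([[10, 20], [20, 40]]), n_mc=4000, seed=1)
        assert res.p_value > 0.9

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            mc_contingency_p(np.array([[0, 0], [5, 5]]), n_mc=10)

    def test_non_integer_rejected(self):
        with pytest.raises(ValueError):
            mc_contingency_p(np.array([[1.5, 2.0], [2.0, 1.0]]), n_mc=10)


class TestScreenPanel:
    def _cohort(self, n=500, seed=11):
        cfg = SyntheticConfig(
            n_subjects=n, n_analytes=12, n_signal=3, blocks=(), seed=seed
        )
        import warnings

        from amypanel.cohort import apply_transforms

        table, truth = generate_cohort(cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return apply_transforms(table), truth

    def test_planted_signals_rank_first(self):
        from amypanel.cohort import COVARIATES

        table, truth = self._cohort()
        res = screen_panel(table, "amyloid_burden", list(COVARIATES))
        top3 = {r.analyte for r in res[:3]}
        assert top3 == set(truth.signal_analytes)

    def test_alpha_one_flags_everything(self):
        from amypanel.cohort import COVARIATES

        table, _ = self._cohort(n=60)
        res = screen_panel(table, "amyloid_burden", list(COVARIATES), alpha=1.0)
        assert all(r.selected for r in res)

    def test_single_analyte_bh_identity(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(
            {
                "amyloid_burden": rng.normal(size=30),
                "only": rng.normal(size=30),
            },
            index=pd.Index([f"S{i}" for i in range(30)], name="subject_id"),
        )
        table = CohortTable(df, CohortSchema(covariates=(), analytes=("only",)))
        res = screen_panel(table, "amyloid_burden", [])
        assert res[0].p_bh == pytest.approx(res[0].p_raw)

    def test_bh_uses_full_panel_size(self):
        from amypanel.cohort import COVARIATES

        table, _ = self._cohort()
        res = screen_panel(table, "amyloid_burden", list(COVARIATES))
        m = len(table.analyte_names)
        by_p = sorted(res, key=lambda r: r.p_raw)
        worst = by_p[-1]
        assert worst.p_bh >= worst.p_raw
        assert by_p[0].p_bh <= min(1.0, by_p[0].p_raw * m)

    def test_no_analytes_rejected(self):
        df = pd.DataFrame(
            {"amyloid_burden": [1.0, 2.0, 1.5]},
            index=pd.Index(["a", "b", "c"], name="subject_id"),
        )
        table = CohortTable(df, CohortSchema(covariates=(), analytes=()))
        table.schema = table.schema  # analytes stay empty
        with pytest.raises(ValueError, match="analyte"):
            screen_panel(table, "amyloid_burden", [])
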