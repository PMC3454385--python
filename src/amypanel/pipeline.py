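"""End-to-end orchestration: ingest/simulate -> transform -> summarize ->
screen -> reduce -> sweep -> permute -> classify -> importance.

``run_pipeline`` executes the stages in analysis order and writes a
reproducible report (delimited tables plus a JSON summary with a
provenance block).  Identical seed and configuration produce
byte-identical reports; no timestamps enter the output files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import (
    COVARIATES,
    CohortSchema,
    CohortTable,
    TransformRegistry,
    apply_transforms,
    collapse_transitions,
    complete_cases,
    read_cohort,
)
from .cluster import ClusterReduction, reduce_panel, removal_order
from .importance import MAX_PREDICTORS, ImportanceResult, lmg
from .regression import (
    SweepResult,
    classify_pib,
    loo_cv_r2,
    permutation_test,
    scale_unit_sd,
    sweep_cutoffs,
)
from .screen import (
    GroupTestResult,
    ScreenResult,
    kruskal_wallis,
    mc_contingency_p,
    screen_frame,
    screen_panel,
)
from .simulate import GroundTruth, SyntheticConfig, generate_cohort

logger = logging.getLogger("amypanel")

__all__ = ["RunConfig", "RunReport", "cohort_summary", "analyte_by_group", "run_pipeline"]


def _iqr(x: np.ndarray) -> float:
    # linear-interpolation (type 7) quantiles; the reported IQRs depend
    # on this convention
    q75, q25 = np.percentile(x, [75, 25])
    return float(q75 - q25)


def cohort_summary(
    table: CohortTable,
    group_column: str = "diagnosis",
    continuous: list[str] | None = None,
    categorical: list[str] | None = None,
    n_mc: int = 2000,
    seed: int = 0,
) -> dict[str, pd.DataFrame]:
    """Per-group median/IQR with KW p for continuous characteristics and
    counts with Monte-Carlo contingency p for categorical ones.

    Transition diagnosis labels are collapsed to their baseline group.
    """
    if group_column not in table.data.columns:
        raise ValueError(f"group column {group_column!r} not in table")
    groups = table.data[group_column]
    if groups.dtype == object:
        groups = collapse_transitions(groups.astype(str))
    labels = [g for g in pd.unique(groups.dropna())]
    if len(labels) < 2:
        raise ValueError("need at least two non-empty groups")
    if continuous is None:
        continuous = [
            c
            for c in ("age_years", "education_years", "scan_gap_days",
                      table.schema.endophenotype, *table.schema.secondary)
            if c in table.data.columns
        ]
    if categorical is None:
        categorical = [c for c in ("sex", "apoe_e4_count") if c in table.data.columns]

    rng = np.random.default_rng(seed)
    cont_rows = []
    for col in continuous:
        vals = table.data[col]
        ok = vals.notna()
        row: dict = {"characteristic": col}
        for g in labels:
            sub = vals[ok & (groups == g)].to_numpy()
            row[f"{g}_median"] = float(np.median(sub)) if len(sub) else np.nan
            row[f"{g}_iqr"] = _iqr(sub) if len(sub) else np.nan
        try:
            row["p_value"] = kruskal_wallis(
                vals[ok].to_numpy(), groups[ok].to_numpy()
            ).p_value
        except ValueError:
            row["p_value"] = np.nan
        cont_rows.append(row)

    cat_rows = []
    for col in categorical:
        vals = table.data[col]
        ok = vals.notna()
        ct = pd.crosstab(vals[ok], groups[ok])
        row = {"characteristic": col}
        for g in labels:
            counts = ct[g] if g in ct.columns else pd.Series(dtype=int)
            row[f"{g}_counts"] = "/".join(
                str(int(counts.get(lvl, 0))) for lvl in ct.index
            )
        try:
            res = mc_contingency_p(
                ct.to_numpy().astype(int), n_mc=n_mc, seed=rng
            )
            row["p_value"] = res.p_value
        except ValueError:
            row["p_value"] = np.nan
        cat_rows.append(row)

    return {
        "continuous": pd.DataFrame(cont_rows),
        "categorical": pd.DataFrame(cat_rows),
    }


def analyte_by_group(
    table: CohortTable, analyte: str, group_column: str = "apoe_e4_count"
) -> pd.DataFrame:
    """Median [IQR] of one analyte stratified by a grouping column,
    with a Kruskal-Wallis p (e.g. plasma ApoE level by e4 count)."""
    if analyte not in table.data.columns:
        raise ValueError(f"analyte {analyte!r} not in table")
    sub = complete_cases(table, [analyte, group_column])
    vals = sub.data[analyte]
    groups = sub.data[group_column]
    rows = []
    for g in sorted(pd.unique(groups)):
        x = vals[groups == g].to_numpy()
        rows.append(
            {"group": g, "n": len(x), "median": float(np.median(x)), "iqr": _iqr(x)}
        )
    p = kruskal_wallis(vals.to_numpy(), groups.to_numpy()).p_value
    out = pd.DataFrame(rows)
    out["p_value"] = p
    return out


@dataclass
class RunConfig:
    """Full-pipeline settings.

    ``source`` is either a path to a delimited cohort file or a
    :class:`SyntheticConfig`.  All referenced columns are validated
    before any computation or file output (fail fast).
    """

    source: str | SyntheticConfig = field(default_factory=SyntheticConfig)
    schema: CohortSchema = field(default_factory=CohortSchema)
    registry: TransformRegistry = field(default_factory=TransformRegistry)
    endophenotype: str = "amyloid_burden"
    covariates: tuple[str, ...] = COVARIATES
    alpha: float = 0.05
    permutations: int = 1000
    threshold: float = 1.5
    seed: int = 0
    outdir: str | None = None
    per_fold_scaling: bool = False
    perm_convention: str = "count"
    already_transformed: bool = False
    compute_importance: bool = True

    def hash(self) -> str:
        def enc(o):
            if is_dataclass(o) and not isinstance(o, type):
                return {"__type__": type(o).__name__, **asdict(o)}
            if isinstance(o, frozenset):
                return sorted(o)
            return str(o)

        fields = asdict(self)
        fields.pop("outdir", None)  # output location is not analysis input
        payload = json.dumps(fields, default=enc, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """Every number in the report traces to one stage's output."""

    summary: dict[str, pd.DataFrame]
    screen: list[ScreenResult]
    reduction: ClusterReduction | None
    removal: list[str]
    sweep: SweepResult
    e4_only_cv_r2: float
    perm_p: float
    classification: "object"
    importance: ImportanceResult | None
    provenance: dict
    truth: GroundTruth | None = None


def _load(config: RunConfig) -> tuple[CohortTable, GroundTruth | None]:
    if isinstance(config.source, SyntheticConfig):
        table, truth = generate_cohort(config.source)
        return table, truth
    return read_cohort(config.source, config.schema), None


def _validate(config: RunConfig, table: CohortTable) -> None:
    missing = [
        c
        for c in (config.endophenotype, *config.covariates)
        if c not in table.data.columns
    ]
    if missing:
        raise ValueError(f"configured columns not in cohort: {missing}")
    if not table.analyte_names:
        raise ValueError("cohort has no analyte columns")
    if not 0 < config.alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    if config.permutations < 1:
        raise ValueError("permutations must be >= 1")


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute all stages in analysis order; optionally write a report.

    Stages: load or simulate the cohort; apply QC exclusions and log
    transforms; summarize by diagnostic group; screen the panel with
    the partial SRC; cluster the hits and sweep the cuts with LOO CV;
    permutation-test the chosen model; dichotomize at the threshold;
    decompose the full-data R^2 with LMG (when the model is within the
    exact-enumeration bound).
    """
    table, truth = _load(config)
    _validate(config, table)
    ss = np.random.SeedSequence(config.seed)
    seed_mc, seed_perm = (int(s) for s in ss.generate_state(2) >> 1)

    if not (config.already_transformed or table.analytes_transformed):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # absent exempt names are expected
            table = apply_transforms(table, config.registry)
    logger.info("cohort: %d subjects, %d analytes", table.n_subjects, len(table.analyte_names))

    summary = cohort_summary(table, seed=seed_mc)
    screen = screen_panel(
        table, config.endophenotype, list(config.covariates), config.alpha
    )
    hits = [r.analyte for r in screen if r.selected]
    logger.info("screen: %d/%d analytes at alpha=%g", len(hits), len(screen), config.alpha)
    if not hits:
        raise ValueError("no analyte passed the screening threshold")

    if len(hits) >= 2:
        reduction = reduce_panel(table, hits, list(config.covariates))
        removal = removal_order(reduction, screen)
    else:
        reduction = ClusterReduction(
            tuple(hits), pd.DataFrame([[0.0]], index=hits, columns=hits), []
        )
        removal = []
    sweep = sweep_cutoffs(
        table,
        reduction,
        screen,
        list(config.covariates),
        config.endophenotype,
        per_fold_scaling=config.per_fold_scaling,
    )
    best = sweep.best
    logger.info("sweep: best k=%d, LOO CV R^2=%.3f", sweep.best_k, best.cv_r2)

    sub = complete_cases(
        table, [config.endophenotype, *config.covariates, *reduction.analytes]
    )
    y = sub.data[config.endophenotype].to_numpy()
    cov = sub.data[list(config.covariates)].to_numpy()
    reps = [p for p in best.predictors if p not in config.covariates]
    X_best = np.column_stack(
        [cov, scale_unit_sd(sub.data[reps]).to_numpy()]
    )
    perm_p = permutation_test(
        y, X_best, config.permutations, seed=seed_perm,
        convention=config.perm_convention,
    )
    best.perm_p = perm_p

    e4_fit = loo_cv_r2(y, sub.data[["apoe_e4_count"]].to_numpy(), ["apoe_e4_count"]) \
        if "apoe_e4_count" in sub.data.columns else None
    classification = classify_pib(y, best.loo_predictions, config.threshold)

    if config.compute_importance and X_best.shape[1] <= MAX_PREDICTORS:
        imp = lmg(y, X_best, [*config.covariates, *reps])
    else:
        imp = None
        if config.compute_importance:
            logger.info(
                "importance skipped: %d predictors exceed the exact bound %d",
                X_best.shape[1], MAX_PREDICTORS,
            )

    provenance = {
        "seed": config.seed,
        "config_hash": config.hash(),
        "version": __version__,
        "n_subjects": table.n_subjects,
        "n_analytes": len(table.analyte_names),
        "n_model": int(best.n),
        "n_screen_hits": len(hits),
    }
    report = RunReport(
        summary=summary,
        screen=screen,
        reduction=reduction,
        removal=removal,
        sweep=sweep,
        e4_only_cv_r2=e4_fit.cv_r2 if e4_fit else float("nan"),
        perm_p=perm_p,
        classification=classification,
        importance=imp,
        provenance=provenance,
        truth=truth,
    )
    if config.outdir is not None:
        write_report(report, config)
    return report


def write_report(report: RunReport, config: RunConfig) -> None:
    """Write the report as delimited tables plus report.json."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ff = "%.10g"
    report.summary["continuous"].to_csv(
        outdir / "summary_continuous.tsv", sep="\t", index=False, float_format=ff
    )
    report.summary["categorical"].to_csv(
        outdir / "summary_categorical.tsv", sep="\t", index=False, float_format=ff
    )
    screen_frame(report.screen).to_csv(
        outdir / "screen.tsv", sep="\t", index=False, float_format=ff
    )
    if report.reduction is not None and report.reduction.merges:
        pd.DataFrame(
            report.reduction.merges, columns=["left", "right", "height"]
        ).to_csv(outdir / "merges.tsv", sep="\t", index=False, float_format=ff)
    (outdir / "removal_order.txt").write_text(
        "".join(f"{i + 1}\t{name}\n" for i, name in enumerate(report.removal))
    )
    report.sweep.frame().to_csv(
        outdir / "cv_by_k.tsv", sep="\t", index=False, float_format=ff
    )
    best = report.sweep.best
    pd.DataFrame(
        {
            "term": ["intercept", *best.predictors],
            "coefficient": best.coefficients,
        }
    ).to_csv(outdir / "model_coefficients.tsv", sep="\t", index=False, float_format=ff)
    if report.importance is not None:
        report.importance.frame().to_csv(
            outdir / "importance.tsv", sep="\t", index=False, float_format=ff
        )
    cls = report.classification
    scalars = {
        "best_k": report.sweep.best_k,
        "cv_r2_best": best.cv_r2,
        "full_r2_best": best.full_r2,
        "cv_r2_covariates_only": report.sweep.baseline.cv_r2,
        "cv_r2_e4_only": report.e4_only_cv_r2,
        "perm_p": report.perm_p,
        "threshold": cls.threshold,
        "tp": cls.tp,
        "fn": cls.fn,
        "fp": cls.fp,
        "tn": cls.tn,
        "sensitivity": cls.sensitivity,
        "specificity": cls.specificity,
        "provenance": report.provenance,
    }
    (outdir / "report.json").write_text(
        json.dumps(scalars, indent=2, sort_keys=True) + "\n"
    )
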