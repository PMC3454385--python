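"""Cohort table I/O, analyte QC exclusion and log-transform handling.

A cohort table holds one row per subject: demographic covariates (age,
sex, years of education, APOE e4 allele count, days between PET scan and
plasma draw), diagnostic group, a continuous endophenotype (average PiB
uptake, i.e. brain amyloid burden), optional secondary phenotypes (CSF
Abeta42, MRI region measures, cognitive scores) and a panel of plasma
analyte concentrations measured on a multiplexed immunoassay platform.

Analyte concentrations arrive on the raw assay scale.  Before analysis,
panel members that failed assay quality control are dropped and the
remaining concentrations are log10-transformed -- except for a small
named set whose distributions are adequate on the raw scale.  A
transform-state flag on the table guards against double transformation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Default covariate set used throughout the analysis.
COVARIATES: tuple[str, ...] = (
    "age_years",
    "sex",
    "education_years",
    "apoe_e4_count",
    "scan_gap_days",
)

#: Analytes left on the raw concentration scale (no log10 transform).
DEFAULT_LOG_EXEMPT: frozenset[str] = frozenset(
    {
        "apolipoprotein_h",
        "complement_factor_h",
        "e_selectin",
        "epidermal_growth_factor",
        "fibrinogen",
        "interleukin_12_subunit_p40",
        "placenta_growth_factor",
        "serum_glutamic_oxaloacetic_transaminase",
        "thrombopoietin",
    }
)

DEFAULT_MISSING_TOKENS: tuple[str, ...] = ("", "NA", "NaN", "nan")

#: Secondary phenotype columns recognised by default (absent ones are
#: simply ignored); anything else unassigned is treated as an analyte.
DEFAULT_SECONDARY: tuple[str, ...] = (
    "csf_abeta42",
    "left_hippocampus_volume",
    "right_hippocampus_volume",
    "left_entorhinal_thickness",
    "right_entorhinal_thickness",
    "mmse",
    "adas_cog13",
)


@dataclass(frozen=True)
class CohortSchema:
    """Column-role mapping for a delimited cohort file.

    ``analytes`` may be left empty, in which case every column not
    claimed by another role is treated as an analyte.
    """

    subject_id: str = "subject_id"
    covariates: tuple[str, ...] = COVARIATES
    diagnosis: str = "diagnosis"
    endophenotype: str = "amyloid_burden"
    secondary: tuple[str, ...] = DEFAULT_SECONDARY
    analytes: tuple[str, ...] = ()

    @property
    def assigned(self) -> set[str]:
        cols = {self.subject_id, self.diagnosis, self.endophenotype}
        cols.update(self.covariates)
        cols.update(self.secondary)
        return cols


@dataclass
class CohortTable:
    """Subjects x {covariates, diagnosis, endophenotypes, analytes}.

    ``data`` is indexed by subject id; ``schema.analytes`` is always
    resolved (non-empty) on a constructed table.  ``analytes_transformed``
    records whether analyte columns are on the raw or log scale.
    """

    data: pd.DataFrame
    schema: CohortSchema
    analytes_transformed: bool = False

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValueError(f"duplicate subject id {dup!r}")
        if not self.schema.analytes:
            inferred = tuple(
                c for c in self.data.columns if c not in self.schema.assigned
            )
            self.schema = replace(self.schema, analytes=inferred)
        e4 = self.data.get(self.schema.covariates[3] if len(self.schema.covariates) > 3 else "apoe_e4_count")
        if e4 is not None:
            bad = e4.dropna()[~e4.dropna().isin([0, 1, 2])]
            if len(bad):
                raise ValueError(
                    f"apoe_e4_count outside {{0,1,2}} for subject {bad.index[0]!r}: {bad.iloc[0]!r}"
                )

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    @property
    def analyte_names(self) -> tuple[str, ...]:
        return self.schema.analytes

    @property
    def analytes(self) -> pd.DataFrame:
        return self.data[list(self.schema.analytes)]

    @property
    def covariates(self) -> pd.DataFrame:
        return self.data[list(self.schema.covariates)]

    def subset(self, mask_or_index) -> "CohortTable":
        """Row subset preserving schema and transform state."""
        return CohortTable(
            self.data.loc[mask_or_index],
            self.schema,
            self.analytes_transformed,
        )


@dataclass(frozen=True)
class TransformRegistry:
    """QC exclusions and log-transform exemptions for the analyte panel.

    Exclusion wins over exemption.  Only base-10 logarithms are
    supported; the base is recorded for provenance.
    """

    excluded: frozenset = frozenset()
    log_exempt: frozenset = DEFAULT_LOG_EXEMPT
    log_base: int = 10

    def __post_init__(self) -> None:
        if self.log_base != 10:
            raise ValueError("only log base 10 is supported")


def _infer_sep(path: Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "\t" if path.suffix.lower() in {".tsv", ".txt", ".tab"} else ","


def read_cohort(
    path: str | Path,
    schema: CohortSchema = CohortSchema(),
    sep: str | None = None,
    missing_tokens: Sequence[str] = DEFAULT_MISSING_TOKENS,
) -> CohortTable:
    """Read and validate a delimited cohort file.

    Missing cells (empty or a configured token) are preserved as NaN.
    Non-numeric values elsewhere raise, naming the offending subject and
    column; so do duplicated subject ids and APOE e4 counts outside
    {0, 1, 2}.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep=_infer_sep(path, sep), dtype=str, keep_default_na=False)
    if schema.subject_id not in raw.columns:
        raise ValueError(f"missing subject id column {schema.subject_id!r}")
    ids = raw[schema.subject_id].str.strip()
    dup = ids[ids.duplicated()]
    if len(dup):
        raise ValueError(f"duplicate subject id {dup.iloc[0]!r}")

    analyte_cols = list(schema.analytes) or [
        c for c in raw.columns if c not in schema.assigned
    ]
    numeric_cols = (
        [c for c in schema.covariates if c in raw.columns]
        + ([schema.endophenotype] if schema.endophenotype in raw.columns else [])
        + [c for c in schema.secondary if c in raw.columns]
        + analyte_cols
    )
    tokens = set(missing_tokens)
    columns: dict[str, np.ndarray | pd.Series] = {}
    for col in raw.columns:
        if col == schema.subject_id:
            continue
        s = raw[col].str.strip()
        miss = s.isin(tokens)
        if col in numeric_cols:
            bad = pd.to_numeric(s.where(~miss), errors="coerce").isna() & ~miss
            if bad.any():
                i = int(np.flatnonzero(bad.values)[0])
                raise ValueError(
                    f"non-numeric value {s.iloc[i]!r} for subject "
                    f"{ids.iloc[i]!r} in column {col!r}"
                )
            # numpy's parser is correctly rounded (pd.to_numeric is not),
            # keeping the write/read round trip bit-exact
            columns[col] = s.where(~miss, "nan").to_numpy().astype(np.float64)
        else:
            columns[col] = s.where(~miss).values
    out = pd.DataFrame(columns, index=pd.Index(ids.values, name=schema.subject_id))
    return CohortTable(out, replace(schema, analytes=tuple(analyte_cols)))


def write_cohort(
    table: CohortTable,
    path: str | Path,
    sep: str | None = None,
    missing_token: str = "NA",
) -> None:
    """Write a cohort table as delimited text (lossless round trip)."""
    path = Path(path)
    df = table.data.reset_index()
    # shortest round-trippable decimal representation for every float,
    # so write/read reproduces all cells bit-identically
    out = df.copy()
    for col in out.columns:
        if out[col].dtype.kind == "f":
            vals = out[col]
            out[col] = vals.map(lambda v: repr(v)).where(vals.notna(), missing_token)
    out.to_csv(path, sep=_infer_sep(path, sep), index=False, na_rep=missing_token)


def apply_transforms(
    table: CohortTable, registry: TransformRegistry = TransformRegistry()
) -> CohortTable:
    """Drop QC-excluded analytes and log10-transform the non-exempt ones.

    Raises if the table was already transformed, or if a to-be-logged
    analyte contains a non-positive value (named with its subject).
    Exempt analytes are passed through untouched; exempt names absent
    from the table trigger a warning only.
    """
    if table.analytes_transformed:
        raise ValueError("analytes already transformed; refusing to re-apply")
    missing_exempt = set(registry.log_exempt) - set(table.analyte_names)
    if missing_exempt:
        warnings.warn(
            "log-exempt analytes not present in table: "
            + ", ".join(sorted(missing_exempt)),
            stacklevel=2,
        )
    keep = [a for a in table.analyte_names if a not in registry.excluded]
    df = table.data.drop(
        columns=[a for a in table.analyte_names if a in registry.excluded]
    ).copy()
    for name in keep:
        if name in registry.log_exempt:
            continue
        col = df[name]
        bad = col.notna() & (col <= 0)
        if bad.any():
            subj = col.index[np.flatnonzero(bad.values)[0]]
            raise ValueError(
                f"non-positive value in analyte {name!r} for subject {subj!r}; "
                "cannot log-transform"
            )
        df[name] = np.log10(col)
    return CohortTable(df, replace(table.schema, analytes=tuple(keep)), True)


def complete_cases(table: CohortTable, required_columns: Iterable[str]) -> CohortTable:
    """Subjects with no missing value in any required column, order kept."""
    required = list(required_columns)
    absent = [c for c in required if c not in table.data.columns]
    if absent:
        raise ValueError(f"required columns not in table: {absent}")
    if not required:
        return table.subset(slice(None))
    mask = table.data[required].notna().all(axis=1)
    if not mask.any():
        raise ValueError(
            "no subject has complete data for the required columns; "
            "downstream statistics undefined"
        )
    return table.subset(mask)


def collapse_transitions(labels: pd.Series) -> pd.Series:
    """Collapse transition diagnosis labels ('control->MCI') to baseline."""
    return labels.str.split("->").str[0].str.strip()
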