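"""Gel-assay measurement records: schema, CSV I/O, and analysis-time filtering.

One record is one gel: the B16 tumor cell concentration recovered at a given
time from a gel inoculated with a desired tumor concentration and a CTL
concentration. All concentrations are cell/mL (the assay uses 0.1 mL gels, so
per-gel counts are 10x smaller than per-mL concentrations; the package
standardizes on cell/mL). Times are stored in hours; model evaluation converts
to days internally.

Zero-count gels (below the limit of detection of the clonogenic assay) are
kept in storage and handled only at analysis time through
:class:`FilterSpec.zero_policy`, so a sensitivity analysis over the limit of
detection is a re-run with a different policy, not a different file.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

#: Canonical CSV column order. ``otl_conc`` is the OT1 CTL concentration.
COLUMNS = (
    "dataset",
    "experiment",
    "replicate",
    "b16_desired",
    "otl_conc",
    "time_h",
    "b16_measured",
)


class SchemaError(ValueError):
    """A required column is missing from the input file."""


class ValidationError(ValueError):
    """A row violates a field constraint; the message names the row."""


@dataclass(frozen=True)
class GelMeasurement:
    """A single gel observation.

    Parameters
    ----------
    dataset_id, experiment_id, replicate_id
        Integer labels for the dataset (1-5), the experimental repeat (1-3),
        and the gel replicate within a condition.
    desired_tumor_conc
        Desired (inoculated) B16 concentration Ta, cell/mL, > 0.
    ctl_conc
        OT1 CTL concentration E, cell/mL, >= 0.
    time_h
        Hours since co-inoculation, >= 0.
    measured_conc
        Recovered B16 concentration T, cell/mL, >= 0 (0 = below detection).
    """

    dataset_id: int
    experiment_id: int
    replicate_id: int
    desired_tumor_conc: float
    ctl_conc: float
    time_h: float
    measured_conc: float

    def __post_init__(self) -> None:
        if not self.desired_tumor_conc > 0:
            raise ValidationError(f"desired_tumor_conc must be > 0, got {self.desired_tumor_conc}")
        if self.ctl_conc < 0:
            raise ValidationError(f"ctl_conc must be >= 0, got {self.ctl_conc}")
        if self.time_h < 0:
            raise ValidationError(f"time_h must be >= 0, got {self.time_h}")
        if self.measured_conc < 0:
            raise ValidationError(f"measured_conc must be >= 0, got {self.measured_conc}")


def records_to_frame(records: Iterable[GelMeasurement]) -> pd.DataFrame:
    """Pack records into the canonical DataFrame layout."""
    rows = [
        (
            r.dataset_id,
            r.experiment_id,
            r.replicate_id,
            r.desired_tumor_conc,
            r.ctl_conc,
            r.time_h,
            r.measured_conc,
        )
        for r in records
    ]
    return pd.DataFrame(rows, columns=list(COLUMNS))


def frame_to_records(df: pd.DataFrame) -> list[GelMeasurement]:
    """Unpack a canonical DataFrame into validated records."""
    return [
        GelMeasurement(
            dataset_id=int(row.dataset),
            experiment_id=int(row.experiment),
            replicate_id=int(row.replicate),
            desired_tumor_conc=float(row.b16_desired),
            ctl_conc=float(row.otl_conc),
            time_h=float(row.time_h),
            measured_conc=float(row.b16_measured),
        )
        for row in df.itertuples(index=False)
    ]


def _validate_frame(df: pd.DataFrame) -> None:
    checks = (
        ("b16_desired", df["b16_desired"] <= 0, "desired concentration must be > 0"),
        ("otl_conc", df["otl_conc"] < 0, "CTL concentration must be >= 0"),
        ("time_h", df["time_h"] < 0, "time must be >= 0"),
        ("b16_measured", df["b16_measured"] < 0, "measured concentration must be >= 0"),
    )
    problems = []
    for col, bad, msg in checks:
        nulls = df[col].isna()
        for idx in df.index[bad.fillna(False)]:
            problems.append(f"row {idx + 2}: {msg} (column {col!r})")  # +2: header + 1-based
        for idx in df.index[nulls]:
            problems.append(f"row {idx + 2}: missing value in column {col!r}")
    if problems:
        raise ValidationError("; ".join(problems))


def read_gel_csv(path: str | Path, schema: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read gel measurements from CSV into the canonical DataFrame.

    Parameters
    ----------
    path
        CSV file with a header row.
    schema
        Optional mapping from canonical column names to the names used in the
        file, e.g. ``{"otl_conc": "E_cells_per_ml"}``. Unmapped columns are
        assumed to carry their canonical names.

    Returns
    -------
    DataFrame with columns :data:`COLUMNS`, one row per gel, units cell/mL
    and hours. Raises :class:`SchemaError` on missing columns and
    :class:`ValidationError` naming the row for malformed values.
    """
    path = Path(path)
    raw = pd.read_csv(path)
    rename = {}
    schema = dict(schema or {})
    for canonical in COLUMNS:
        source = schema.get(canonical, canonical)
        if source not in raw.columns:
            raise SchemaError(f"column {source!r} (for {canonical!r}) not found in {path}")
        rename[source] = canonical
    df = raw.rename(columns=rename)[list(COLUMNS)].copy()
    for col in ("dataset", "experiment", "replicate"):
        df[col] = df[col].astype(int)
    for col in ("b16_desired", "otl_conc", "time_h", "b16_measured"):
        df[col] = df[col].astype(float)
    _validate_frame(df)
    return df.reset_index(drop=True)


def write_gel_csv(df: pd.DataFrame, path: str | Path) -> None:
    """Write a canonical DataFrame to CSV (lossless round trip)."""
    df[list(COLUMNS)].to_csv(path, index=False)


@dataclass(frozen=True)
class FilterSpec:
    """Analysis-time selection rules for gel measurements.

    ``zero_policy`` controls gels with zero recovered cells: ``"exclude"``
    drops them (required before log-transform fitting) while ``"impute_lod"``
    replaces the zero with ``lod_value`` — the assay's limit of detection,
    plausibly 2-10 cell/mL.
    """

    max_ctl_conc: float = math.inf
    allowed_dataset_ids: frozenset[int] | None = None
    allowed_desired_concs: frozenset[float] | None = None
    allowed_experiment_ids: frozenset[int] | None = None
    excluded_conditions: tuple[tuple[int, float, float], ...] = ()
    zero_policy: str = "exclude"
    lod_value: float | None = None

    def __post_init__(self) -> None:
        if self.zero_policy not in ("exclude", "impute_lod"):
            raise ValueError(f"unknown zero_policy {self.zero_policy!r}")
        if self.zero_policy == "impute_lod":
            if self.lod_value is None:
                raise ValueError("zero_policy='impute_lod' requires lod_value")
            if not (2.0 <= self.lod_value <= 10.0):
                raise ValueError("lod_value must lie in [2, 10] cell/mL")
        for attr in ("allowed_dataset_ids", "allowed_desired_concs", "allowed_experiment_ids"):
            value = getattr(self, attr)
            if value is not None and not isinstance(value, frozenset):
                object.__setattr__(self, attr, frozenset(value))


@dataclass
class FilterReport:
    """Per-rule tally of removed/imputed records."""

    removed: dict[str, int] = field(default_factory=dict)
    imputed: int = 0
    n_in: int = 0
    n_out: int = 0


def apply_filter(df: pd.DataFrame, spec: FilterSpec) -> tuple[pd.DataFrame, FilterReport]:
    """Apply a :class:`FilterSpec`, returning the kept records and a tally.

    Rules are applied in a fixed order (dataset, experiment, desired
    concentration, CTL ceiling, excluded conditions, zero policy); the report
    counts how many records each rule removed. Filtering is idempotent and
    never increases the record count.
    """
    report = FilterReport(n_in=len(df))
    out = df.copy()

    def drop(mask, rule: str):
        nonlocal out
        n = int(mask.sum())
        if n:
            report.removed[rule] = report.removed.get(rule, 0) + n
            out = out[~mask]

    if spec.allowed_dataset_ids is not None:
        drop(~out["dataset"].isin(spec.allowed_dataset_ids), "dataset")
    if spec.allowed_experiment_ids is not None:
        drop(~out["experiment"].isin(spec.allowed_experiment_ids), "experiment")
    if spec.allowed_desired_concs is not None:
        drop(~out["b16_desired"].isin(spec.allowed_desired_concs), "desired_conc")
    drop(out["otl_conc"] > spec.max_ctl_conc, "max_ctl_conc")
    for dataset_id, ta, e in spec.excluded_conditions:
        mask = (
            (out["dataset"] == dataset_id)
            & (out["b16_desired"] == ta)
            & (out["otl_conc"] == e)
        )
        drop(mask, "excluded_condition")

    zeros = out["b16_measured"] == 0
    if spec.zero_policy == "exclude":
        drop(zeros, "zero_count")
    else:
        report.imputed = int(zeros.sum())
        out.loc[zeros, "b16_measured"] = spec.lod_value

    report.n_out = len(out)
    if report.n_out == 0:
        warnings.warn("filter removed every record", stacklevel=2)
    return out.reset_index(drop=True), report
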