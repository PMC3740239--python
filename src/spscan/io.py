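"""File I/O and report rendering.

CSV dialects
------------
Continuous data: a header row naming at least the x and y columns;
optional group / subject / feature columns. Rows with non-numeric x or y
are dropped and counted.

Stratified 2x2 tables: long form with header ``stratum,row,col,count``,
``row`` in {group1, group2} and ``col`` in {success, failure}. Missing
cells are zero-filled with a warning; duplicated cells are summed with a
warning.

Reports serialize to JSON at full double precision, or to a text view
with statistics rounded to 2 decimal places and the warning templates
rendered byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .contingency import StratifiedTable, StratumTable, TableSPReport
from .detect import SPReport
from .errors import ConfigError, DataError
from .regress import BivariateSample

__all__ = [
    "RunConfig",
    "read_continuous_csv",
    "read_table_csv",
    "write_continuous_csv",
    "write_table_csv",
    "render_report",
]

log = logging.getLogger("spscan")

SCHEMA_VERSION = "1"

_ROWS = ("group1", "group2")
_COLS = ("success", "failure")


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration of one CLI run."""

    input_path: str
    mode: str  # continuous | table
    seed: int
    x_col: str | None = None
    y_col: str | None = None
    group_col: str | None = None
    subject_col: str | None = None
    feature_cols: tuple[str, ...] | None = None
    alpha: float = 0.05
    B: int = 1000
    k_max: int = 5
    continuity_correction: bool = True
    output_path: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("continuous", "table"):
            raise ConfigError(f"mode must be continuous or table, got {self.mode!r}")
        if self.mode == "continuous" and not (self.x_col and self.y_col):
            raise ConfigError("continuous mode requires x_col and y_col")
        if self.mode == "table" and (self.x_col or self.y_col):
            raise ConfigError("table mode takes no x/y columns")
        if not 0 < self.alpha < 1:
            raise ConfigError(f"alpha must be in (0,1), got {self.alpha}")


def read_continuous_csv(path: str, config: RunConfig) -> BivariateSample:
    """Read a bivariate sample, dropping rows with non-numeric x or y."""
    try:
        df = pd.read_csv(path)
    except FileNotFoundError as exc:
        raise ConfigError(f"input file not found: {path}") from exc
    except pd.errors.EmptyDataError as exc:
        raise DataError(f"empty input file: {path}") from exc

    needed = [config.x_col, config.y_col]
    for opt in (config.group_col, config.subject_col):
        if opt:
            needed.append(opt)
    if config.feature_cols:
        needed.extend(config.feature_cols)
    for col in needed:
        if col not in df.columns:
            raise ConfigError(f"column {col!r} not found in {path}")

    x = pd.to_numeric(df[config.x_col], errors="coerce")
    y = pd.to_numeric(df[config.y_col], errors="coerce")
    keep = x.notna() & y.notna()
    if config.feature_cols:
        for col in config.feature_cols:
            f = pd.to_numeric(df[col], errors="coerce")
            df[col] = f
            keep &= f.notna()
    dropped = int((~keep).sum())
    if dropped:
        log.warning("dropped %d rows with missing/non-numeric values", dropped)
    if keep.sum() == 0:
        raise DataError(f"no usable rows in {path}")
    df = df.loc[keep]
    return BivariateSample(
        x=x[keep].to_numpy(),
        y=y[keep].to_numpy(),
        group=df[config.group_col].to_numpy() if config.group_col else None,
        subject=df[config.subject_col].to_numpy() if config.subject_col else None,
        features=(
            df[list(config.feature_cols)].to_numpy(dtype=float)
            if config.feature_cols
            else None
        ),
    )


def read_table_csv(path: str) -> StratifiedTable:
    """Read a long-form stratified 2x2 table CSV.

    Order of rows in the file does not matter; strata appear in the
    output in order of first appearance.
    """
    try:
        df = pd.read_csv(path)
    except FileNotFoundError as exc:
        raise ConfigError(f"input file not found: {path}") from exc
    except pd.errors.EmptyDataError as exc:
        raise DataError(f"empty input file: {path}") from exc
    required = {"stratum", "row", "col", "count"}
    if not required.issubset(df.columns):
        raise ConfigError(
            f"table CSV needs columns {sorted(required)}, got {list(df.columns)}"
        )
    if len(df) == 0:
        raise DataError(f"no rows in {path}")
    bad_row = ~df["row"].isin(_ROWS)
    bad_col = ~df["col"].isin(_COLS)
    if bad_row.any() or bad_col.any():
        raise DataError(
            f"row values must be in {_ROWS} and col values in {_COLS}"
        )
    counts = pd.to_numeric(df["count"], errors="coerce")
    if counts.isna().any():
        raise DataError("non-numeric count")
    if (counts < 0).any():
        raise DataError("negative count")
    if not np.allclose(counts, counts.round()):
        raise DataError("counts must be integers")
    df = df.assign(count=counts.astype(int))

    strata: list[StratumTable] = []
    for label in df["stratum"].drop_duplicates():
        sub = df[df["stratum"] == label]
        cells = {}
        for r in _ROWS:
            for c in _COLS:
                vals = sub.loc[(sub["row"] == r) & (sub["col"] == c), "count"]
                if len(vals) == 0:
                    log.warning("stratum %r cell (%s,%s) missing; using 0", label, r, c)
                    cells[(r, c)] = 0
                else:
                    if len(vals) > 1:
                        log.warning(
                            "stratum %r cell (%s,%s) duplicated; summing", label, r, c
                        )
                    cells[(r, c)] = int(vals.sum())
        strata.append(
            StratumTable(
                str(label),
                cells[("group1", "success")],
                cells[("group1", "failure")],
                cells[("group2", "success")],
                cells[("group2", "failure")],
            )
        )
    return StratifiedTable(tuple(strata))


def write_continuous_csv(sample: BivariateSample, path: str) -> None:
    """Write a sample in the dialect read_continuous_csv consumes."""
    data: dict[str, np.ndarray] = {"x": sample.x, "y": sample.y}
    if sample.group is not None:
        data["group"] = sample.group
    if sample.subject is not None:
        data["subject"] = sample.subject
    if sample.features is not None:
        for j in range(sample.features.shape[1]):
            data[f"f{j + 1}"] = sample.features[:, j]
    pd.DataFrame(data).to_csv(path, index=False)


def write_table_csv(strat: StratifiedTable, path: str) -> None:
    rows = []
    for s in strat.strata:
        cells = {
            ("group1", "success"): s.n11,
            ("group1", "failure"): s.n12,
            ("group2", "success"): s.n21,
            ("group2", "failure"): s.n22,
        }
        for (r, c), v in cells.items():
            rows.append({"stratum": s.label, "row": r, "col": c, "count": v})
    pd.DataFrame(rows).to_csv(path, index=False)


def _to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_jsonable(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    return obj


def _sp_report_text(report: SPReport) -> str:
    lines = [
        f"Simpson's paradox scan (mode={report.mode}, seed={report.seed}, "
        f"alpha={report.alpha}, B={report.B})",
        f"Group fit: slope={report.group_fit.slope:.2f} "
        f"intercept={report.group_fit.intercept:.2f} r={report.group_fit.r:.2f} "
        f"(n={report.group_fit.n})",
    ]
    if report.model is not None:
        lines.append(
            f"Selected K={report.model.K} (BIC={report.model.bic:.2f})"
        )
    for f in report.findings:
        flag = " [SIGN REVERSED]" if f.sign_reversed else (
            " [deviates]" if f.significant else ""
        )
        lines.append(
            f"Cluster {f.cluster_id} (n={f.n}): slope={f.fit.slope:.2f} "
            f"r={f.fit.r:.2f} p_perm={f.p_perm:.4f}{flag}"
        )
    for s in report.skipped:
        lines.append(f"Cluster {s.cluster_id} (n={s.n}): skipped ({s.reason})")
    lines.extend(report.warnings)
    lines.extend(f"Note: {c}" for c in report.caveats)
    return "\n".join(lines) + "\n"


def _table_report_text(report: TableSPReport) -> str:
    a = report.aggregate
    lines = [
        "Conditional-independence scan (stratified 2x2)",
        f"Aggregate: chi2={a.statistic:.2f} df={a.df} p={a.p_value:.4g} "
        f"sign={a.sign:+d}{' (Yates)' if a.corrected else ''}",
    ]
    for label, r in report.per_stratum.items():
        lines.append(
            f"Stratum {label}: chi2={r.statistic:.2f} df={r.df} "
            f"p={r.p_value:.4g} sign={r.sign:+d}"
        )
    for label in report.untestable:
        lines.append(f"Stratum {label}: untestable (zero margin)")
    lines.append(f"Reversal: {report.reversal}")
    if report.significant_reversal:
        lines.append(
            f"All involved tests significant at alpha={report.alpha}: "
            "significant full reversal."
        )
    lines.append(report.narrative)
    return "\n".join(lines) + "\n"


def render_report(report: SPReport | TableSPReport, format: str = "json") -> str:
    """Serialize a report to JSON (full precision) or text (2 dp view)."""
    if format == "json":
        payload = {"schema_version": SCHEMA_VERSION, "report": _to_jsonable(report)}
        payload["report_type"] = type(report).__name__
        return json.dumps(payload, indent=2, sort_keys=True)
    if format == "text":
        if isinstance(report, SPReport):
            return _sp_report_text(report)
        return _table_report_text(report)
    raise ConfigError(f"unknown report format {format!r}")
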