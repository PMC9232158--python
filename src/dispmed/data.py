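"""Patient-table container, CSV I/O, complete-case filtering and descriptives.

The unit of analysis is one stroke admission record.  Binary variables are
coded {0,1}; age is stored in years as a continuous value (the display bins
used in descriptive tables are presentation only); calendar year is a
categorical variable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import CodingError, DegenerateDataError, SchemaError
from .schema import VariableSchema

logger = logging.getLogger(__name__)

DEFAULT_MISSING_TOKENS = ("", "NA")
DEFAULT_AGE_RANGE = (18.0, 110.0)

#: Display bins for age, lower-inclusive.  The top two labels follow the
#: registry's reporting convention ("75-84" then "84+"); we resolve the
#: overlapping boundary as [75, 85) and [85, inf).
AGE_BINS = ((18, 55, "18-54"), (55, 65, "55-64"), (65, 75, "65-74"),
            (75, 85, "75-84"), (85, np.inf, "84+"))


@dataclass(frozen=True)
class MissingnessReport:
    """Per-variable and any-variable missingness of a patient table."""

    per_variable: dict[str, float]
    any_missing: float
    n_total: int
    n_complete: int

    def to_frame(self) -> pd.DataFrame:
        rows = [{"variable": k, "missing_fraction": v} for k, v in self.per_variable.items()]
        rows.append({"variable": "<any variable>", "missing_fraction": self.any_missing})
        return pd.DataFrame(rows)


class StudyData:
    """A validated patient table together with its variable schema.

    Missing cells are represented as NaN in the underlying DataFrame.
    """

    def __init__(self, frame: pd.DataFrame, schema: VariableSchema,
                 age_range: tuple[float, float] = DEFAULT_AGE_RANGE,
                 validate: bool = True) -> None:
        self.schema = schema
        self.age_range = age_range
        self.frame = frame.reset_index(drop=True)
        if validate:
            self._validate()

    def _validate(self) -> None:
        missing_cols = [c for c in self.schema.all_columns if c not in self.frame.columns]
        if missing_cols:
            raise SchemaError(f"data are missing required columns: {missing_cols}")
        for col in self.schema.binary_columns:
            values = pd.to_numeric(self.frame[col], errors="coerce")
            raw_na = self.frame[col].isna()
            bad = (~values.isin([0, 1])) & ~raw_na
            unparseable = values.isna() & ~raw_na
            bad |= unparseable
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise CodingError(col, row, self.frame[col].iloc[row])
            self.frame[col] = values.astype(float)
        for conf in self.schema.confounders:
            if conf.type == "continuous":
                vals = pd.to_numeric(self.frame[conf.name], errors="coerce")
                raw_na = self.frame[conf.name].isna()
                unparseable = vals.isna() & ~raw_na
                if unparseable.any():
                    row = int(np.flatnonzero(unparseable.to_numpy())[0])
                    raise CodingError(conf.name, row, self.frame[conf.name].iloc[row])
                lo, hi = self.age_range
                out = ((vals < lo) | (vals > hi)) & ~raw_na
                if conf.name == "age" and out.any():
                    row = int(np.flatnonzero(out.to_numpy())[0])
                    raise CodingError(conf.name, row, self.frame[conf.name].iloc[row])
                self.frame[conf.name] = vals.astype(float)

    # -- simple queries ----------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.frame)

    def missing_counts(self) -> dict[str, int]:
        return {c: int(self.frame[c].isna().sum()) for c in self.schema.all_columns}

    def is_complete(self) -> bool:
        return not self.frame[self.schema.all_columns].isna().any().any()

    def subset(self, index) -> "StudyData":
        return StudyData(self.frame.iloc[index], self.schema, self.age_range,
                         validate=False)

    def copy(self) -> "StudyData":
        return StudyData(self.frame.copy(), self.schema, self.age_range, validate=False)

    # -- I/O ---------------------------------------------------------------
    def write_csv(self, path: str | Path) -> None:
        out = self.frame[self.schema.all_columns].copy()
        for col in self.schema.binary_columns:
            mask = out[col].notna()
            out[col] = out[col].astype("object")
            out.loc[mask, col] = out.loc[mask, col].astype(int)
        cat = [c.name for c in self.schema.confounders if c.type == "categorical"]
        for col in cat:
            mask = out[col].notna()
            as_num = pd.to_numeric(out[col], errors="coerce")
            if as_num.notna().all():
                out[col] = out[col].astype("object")
                out.loc[mask, col] = as_num[mask].astype(int)
        out.to_csv(path, index=False, na_rep="NA")


def load_study_data(path: str | Path, schema: VariableSchema,
                    missing_tokens: tuple[str, ...] = DEFAULT_MISSING_TOKENS,
                    age_range: tuple[float, float] = DEFAULT_AGE_RANGE) -> StudyData:
    """Read a patient CSV and validate it against `schema`.

    Unknown columns are dropped with a logged warning.  Tokens listed in
    `missing_tokens` (default: the empty string and "NA") are mapped to the
    missing marker in any column.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, dtype=str, keep_default_na=False,
                        na_values=list(missing_tokens))
    unknown = [c for c in frame.columns if c not in schema.all_columns]
    if unknown:
        logger.warning("ignoring columns not in schema: %s", unknown)
        frame = frame.drop(columns=unknown)
    return StudyData(frame, schema, age_range=age_range)


def complete_case_filter(data: StudyData) -> tuple[StudyData, MissingnessReport]:
    """Drop every row with any missing analysis variable.

    Returns the filtered data plus a report of per-variable and any-variable
    missing fractions computed on the *input*.
    """
    cols = data.schema.all_columns
    isna = data.frame[cols].isna()
    n = data.n
    per_var = {c: float(isna[c].mean()) if n else 0.0 for c in cols}
    any_row = isna.any(axis=1)
    report = MissingnessReport(
        per_variable=per_var,
        any_missing=float(any_row.mean()) if n else 0.0,
        n_total=n,
        n_complete=int((~any_row).sum()),
    )
    if report.n_complete == 0:
        raise DegenerateDataError("complete-case filter removed every row")
    filtered = data.subset(np.flatnonzero(~any_row.to_numpy()))
    return filtered, report


def _binary_row(name: str, series: pd.Series) -> dict:
    n1 = int((series == 1).sum())
    denom = int(series.notna().sum())
    pct = 100.0 * n1 / denom if denom else float("nan")
    return {"variable": name, "level": "1", "n": n1, "pct": pct}


def descriptive_table(data: StudyData, schema: VariableSchema | None = None) -> pd.DataFrame:
    """Counts and percentages for every analysis variable (registry Table-1 style).

    Binary variables report level 1; categorical confounders report every
    level; age is binned for display only.
    """
    schema = schema or data.schema
    rows: list[dict] = []
    rows.append(_binary_row(schema.exposure, data.frame[schema.exposure]))
    rows.append(_binary_row(schema.outcome, data.frame[schema.outcome]))
    for m in schema.mediator_names:
        rows.append(_binary_row(m, data.frame[m]))
    for conf in schema.confounders:
        s = data.frame[conf.name]
        if conf.type == "binary":
            rows.append(_binary_row(conf.name, s))
        elif conf.type == "categorical":
            counts = s.dropna().value_counts().sort_index()
            denom = counts.sum()
            for level, cnt in counts.items():
                rows.append({"variable": conf.name, "level": str(level),
                             "n": int(cnt), "pct": 100.0 * cnt / denom})
        else:  # continuous -> display bins
            vals = s.dropna().to_numpy(dtype=float)
            denom = len(vals)
            for lo, hi, label in AGE_BINS:
                cnt = int(((vals >= lo) & (vals < hi)).sum())
                rows.append({"variable": conf.name, "level": label,
                             "n": cnt, "pct": 100.0 * cnt / denom if denom else float("nan")})
    return pd.DataFrame(rows)
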