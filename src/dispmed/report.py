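"""Configuration-driven end-to-end runs and table rendering.

``run_analysis`` executes the full pipeline (load or generate -> missing
data policy -> descriptive table -> association table -> effect estimation
with bootstrap) and writes table1.csv/table2.csv/table3.csv,
missingness.csv, Markdown renderings, and a provenance log.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import association_table
from .bootstrap import BootstrapResult
from .data import (StudyData, complete_case_filter, descriptive_table,
                   load_study_data)
from .design import FormulaSpec
from .exceptions import ConfigError, DispmedError
from .impute import ImputationConfig, impute_chained
from .mediation import EFFECT_LABELS, EFFECT_NAMES, percent_of_total
from .model import DisparityMediationModel
from .schema import VariableSchema, riksstroke_schema

logger = logging.getLogger(__name__)

#: fixed row order of the effect table
_TABLE3_ORDER = ["ata", "de", "ie_all", "ie_a", "ie_b", "ie_dep"]


@dataclass
class RunConfig:
    """Flat configuration driving one full analysis run."""

    output_dir: str
    data_path: str | None = None
    schema_path: str | None = None
    preset: str | None = None          # "rikslike" generates instead of loading
    n: int = 100_000
    formula: str = "interactions"      # or "main_effects"
    mode: str = "mc"
    draws: int = 500
    n_boot: int = 1000
    seed: int | None = None
    reference: str = "exposed"
    anchor: str = "a_first"
    missing_policy: str = "complete_case"   # or "impute"
    burn_in: int = 10
    ridge: float = 0.0
    n_jobs: int = 1

    def __post_init__(self) -> None:
        if self.draws < 1 or self.n_boot < 0:
            raise ConfigError("draws must be positive and n_boot non-negative")
        if self.formula not in ("interactions", "main_effects"):
            raise ConfigError(f"unknown formula variant {self.formula!r}")
        if self.missing_policy not in ("complete_case", "impute"):
            raise ConfigError(f"unknown missing-data policy {self.missing_policy!r}")
        if self.data_path is None and self.preset is None:
            raise ConfigError("config needs either data_path or preset")

    @classmethod
    def load(cls, path: str | Path, **overrides) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        d.update({k: v for k, v in overrides.items() if v is not None})
        try:
            return cls(**d)
        except TypeError as exc:
            raise ConfigError(f"bad config key: {exc}") from exc

    def formula_spec(self) -> FormulaSpec:
        return (FormulaSpec.flexible() if self.formula == "interactions"
                else FormulaSpec.main_effects())


def format_p(p: float) -> str:
    if p != p:  # NaN
        return ""
    return "<0.001" if p < 0.001 else f"{p:.3f}"


def effect_table_frame(effects, bootstrap: BootstrapResult | None) -> pd.DataFrame:
    """Effect rows in fixed order with display-ready columns."""
    pct = percent_of_total(effects)
    rows = []
    for name in _TABLE3_ORDER:
        row = {"effect": EFFECT_LABELS[name],
               "risk_difference_pct": round(getattr(effects, name), 4)}
        if bootstrap is not None:
            row["ci_low"] = round(bootstrap.ci_low[name], 4)
            row["ci_high"] = round(bootstrap.ci_high[name], 4)
            row["p_value"] = format_p(bootstrap.p_values[name])
        else:
            row["ci_low"] = row["ci_high"] = np.nan
            row["p_value"] = ""
        if name == "ata":
            row["pct_of_total"] = ""
        else:
            val = pct[name]
            row["pct_of_total"] = "undefined" if val != val else round(val, 1)
        rows.append(row)
    return pd.DataFrame(rows)


def _to_markdown(frame: pd.DataFrame) -> str:
    cols = list(frame.columns)
    lines = ["| " + " | ".join(str(c) for c in cols) + " |",
             "| " + " | ".join("---" for _ in cols) + " |"]
    for _, row in frame.iterrows():
        cells = []
        for c in cols:
            v = row[c]
            if isinstance(v, float):
                cells.append("" if v != v else f"{v:.4g}")
            else:
                cells.append(str(v))
        lines.append("| " + " | ".join(cells) + " |")
    return "\n".join(lines) + "\n"


def render_tables(tables: dict[str, pd.DataFrame], out_dir: str | Path) -> list[Path]:
    """Write each table as CSV plus a Markdown rendering; returns paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, frame in tables.items():
        csv_path = out_dir / f"{name}.csv"
        frame.to_csv(csv_path, index=False)
        md_path = out_dir / f"{name}.md"
        md_path.write_text(_to_markdown(frame))
        written += [csv_path, md_path]
    return written


def run_analysis(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the report bundle as a dict.

    Any stage error is re-raised as DispmedError naming the stage.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise DispmedError(f"stage {name!r} failed: {exc}") from exc

    def _load():
        if config.preset is not None:
            from .simulate import generate_population, rikslike_preset
            if config.preset != "rikslike":
                raise ConfigError(f"unknown preset {config.preset!r}")
            return generate_population(rikslike_preset(n=config.n, seed=config.seed))
        schema = (VariableSchema.load(config.schema_path)
                  if config.schema_path else riksstroke_schema())
        return load_study_data(config.data_path, schema)

    data = stage("load", _load)

    def _missing():
        complete, report = complete_case_filter(data)
        if config.missing_policy == "impute":
            completed = impute_chained(
                data, config=ImputationConfig(burn_in=config.burn_in,
                                              seed=config.seed))
            return completed, report
        return complete, report

    analysis_data, missing_report = stage("missing_data", _missing)

    table1 = stage("descriptive", lambda: descriptive_table(analysis_data))
    table2 = stage("association", lambda: association_table(analysis_data))

    def _effects():
        model = DisparityMediationModel(analysis_data,
                                        formula=config.formula_spec())
        return model.fit(mode=config.mode, draws=config.draws,
                         n_boot=config.n_boot or None, seed=config.seed,
                         reference=config.reference, anchor=config.anchor,
                         ridge=config.ridge, n_jobs=config.n_jobs)

    results = stage("effects", _effects)
    table3 = effect_table_frame(results.effects, results.bootstrap)

    tables = {"table1": table1, "table2": table2, "table3": table3,
              "missingness": missing_report.to_frame()}
    stage("render", lambda: render_tables(tables, out_dir))

    log = {
        "config": {k: getattr(config, k) for k in vars(config)},
        "dispmed_version": __version__,
        "python": sys.version.split()[0],
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "n_input": missing_report.n_total,
        "n_analysis": analysis_data.n,
        "any_missing_fraction": missing_report.any_missing,
        "bootstrap_failed": (results.bootstrap.n_failed
                             if results.bootstrap else 0),
    }
    (out_dir / "run_log.json").write_text(json.dumps(log, indent=2, default=str))
    bundle.update(tables=tables, results=results, log=log)
    return bundle
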