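"""Model/Results front end for the disparity mediation analysis.

``DisparityMediationModel`` wraps a patient table and a variable schema;
``fit()`` runs the estimation engine (optionally with bootstrap inference)
and returns a ``DisparityMediationResults`` carrying the six effects, their
uncertainties and a printable summary table.

Example
-------
>>> from dispmed import DisparityMediationModel, rikslike_preset, generate_population
>>> data = generate_population(rikslike_preset(n=5000, seed=1))
>>> res = DisparityMediationModel(data).fit(mode="enumerate", n_boot=50, seed=1)
>>> print(res.summary())                                   # doctest: +SKIP
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .bootstrap import BootstrapResult, bootstrap_effects
from .data import StudyData, complete_case_filter
from .design import FormulaSpec
from .exceptions import DispmedError
from .mediation import (EFFECT_LABELS, EFFECT_NAMES, EffectEstimates,
                        estimate_effects, percent_of_total)
from .schema import VariableSchema


class DisparityMediationModel:
    """Interventional-disparity mediation model for a binary outcome.

    Parameters
    ----------
    data : StudyData
        Complete patient table (rows with missing values are dropped with a
        warning if present; use the imputation module for the sensitivity
        alternative).
    schema : VariableSchema, optional
        Defaults to the schema attached to ``data``.
    formula : FormulaSpec, optional
        Model flexibility; default includes all 2-way interactions and
        squared age.
    """

    def __init__(self, data: StudyData, schema: VariableSchema | None = None,
                 formula: FormulaSpec = FormulaSpec()) -> None:
        schema = schema or data.schema
        if not data.is_complete():
            data, report = complete_case_filter(data)
            self.missingness = report
        else:
            self.missingness = None
        self.data = data
        self.schema = schema
        self.formula = formula

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, schema: VariableSchema,
                       formula: FormulaSpec = FormulaSpec()) -> "DisparityMediationModel":
        return cls(StudyData(frame, schema), schema, formula)

    @property
    def nobs(self) -> int:
        return self.data.n

    def fit(self, mode: str = "mc", draws: int = 500, n_boot: int | None = None,
            seed: int | None = None, reference: str = "exposed",
            anchor: str = "a_first", ridge: float = 0.0,
            ci_method: str = "normal", n_jobs: int = 1) -> "DisparityMediationResults":
        """Estimate the decomposition; with ``n_boot`` set, add bootstrap
        SEs, 95% CIs and p-values (the published analysis used 1000
        replicates and 500 Monte-Carlo simulations)."""
        if n_boot:
            boot = bootstrap_effects(self.data, self.schema, formula=self.formula,
                                     mode=mode, draws=draws, n_boot=n_boot,
                                     seed=seed, reference=reference,
                                     anchor=anchor, ridge=ridge,
                                     ci_method=ci_method, n_jobs=n_jobs)
            return DisparityMediationResults(self, boot.estimates, boot)
        effects = estimate_effects(self.data, self.schema, formula=self.formula,
                                   mode=mode, draws=draws, seed=seed,
                                   reference=reference, anchor=anchor,
                                   ridge=ridge)
        return DisparityMediationResults(self, effects, None)


class DisparityMediationResults:
    """Fitted decomposition with optional bootstrap inference."""

    def __init__(self, model: DisparityMediationModel, effects: EffectEstimates,
                 bootstrap: BootstrapResult | None) -> None:
        self.model = model
        self.effects = effects
        self.bootstrap = bootstrap

    # statsmodels-style accessors ------------------------------------------
    @property
    def params(self) -> pd.Series:
        return pd.Series(self.effects.as_dict())

    @property
    def bse(self) -> pd.Series:
        if self.bootstrap is None:
            return pd.Series({k: np.nan for k in EFFECT_NAMES})
        return pd.Series(self.bootstrap.se)

    @property
    def pvalues(self) -> pd.Series:
        if self.bootstrap is None:
            return pd.Series({k: np.nan for k in EFFECT_NAMES})
        return pd.Series(self.bootstrap.p_values)

    def conf_int(self) -> pd.DataFrame:
        if self.bootstrap is None:
            return pd.DataFrame({"lower": np.nan, "upper": np.nan},
                                index=list(EFFECT_NAMES))
        return pd.DataFrame({"lower": self.bootstrap.ci_low,
                             "upper": self.bootstrap.ci_high})

    @property
    def pct_of_total(self) -> pd.Series:
        return pd.Series(percent_of_total(self.effects))

    def to_frame(self) -> pd.DataFrame:
        """Effect table: risk differences (pp), CI, p, percent of total."""
        pct = percent_of_total(self.effects)
        rows = []
        for name in EFFECT_NAMES:
            rows.append({
                "effect": name,
                "label": EFFECT_LABELS[name],
                "risk_difference_pp": getattr(self.effects, name),
                "ci_low": self.bse_get(self.bootstrap.ci_low, name),
                "ci_high": self.bse_get(self.bootstrap.ci_high, name),
                "se": self.bse_get(self.bootstrap.se, name),
                "p_value": self.bse_get(self.bootstrap.p_values, name),
                "pct_of_total": pct.get(name, np.nan),
            } if self.bootstrap is not None else {
                "effect": name,
                "label": EFFECT_LABELS[name],
                "risk_difference_pp": getattr(self.effects, name),
                "ci_low": np.nan, "ci_high": np.nan, "se": np.nan,
                "p_value": np.nan,
                "pct_of_total": pct.get(name, np.nan),
            })
        return pd.DataFrame(rows)

    @staticmethod
    def bse_get(d: dict, k: str) -> float:
        return float(d.get(k, np.nan))

    def summary(self) -> str:
        """Plain-text summary in the style of the published effect table."""
        eff = self.effects
        head = [
            "Interventional disparity mediation analysis",
            "=" * 78,
            f"No. observations: {self.model.nobs:>8}    mode: {eff.mode}"
            + (f" (K={eff.draws})" if eff.mode == "mc" else "")
            + f"    reference: {eff.reference}",
        ]
        if self.bootstrap is not None:
            head.append(
                f"Bootstrap replicates: {self.bootstrap.n_replicates}"
                f" (failed: {self.bootstrap.n_failed})"
                + ("  ** >5% replicates failed **" if self.bootstrap.flagged else ""))
        head.append("-" * 78)
        head.append(f"{'Effect':<34}{'Risk diff.':>10}{'95% CI':>18}"
                    f"{'P-value':>9}{'% total':>8}")
        lines = []
        pct = percent_of_total(self.effects)
        for name in EFFECT_NAMES:
            val = getattr(eff, name)
            if self.bootstrap is not None:
                lo = self.bootstrap.ci_low[name]
                hi = self.bootstrap.ci_high[name]
                p = self.bootstrap.p_values[name]
                ci = f"({lo:.2f}, {hi:.2f})"
                ptxt = "<0.001" if p < 0.001 else f"{p:.3f}"
            else:
                ci, ptxt = "", ""
            pc = pct.get(name)
            pctxt = "" if pc is None or (isinstance(pc, float) and np.isnan(pc)) \
                else f"{pc:.1f}"
            if name == "ata":
                pctxt = ""
            lines.append(f"{EFFECT_LABELS[name]:<34}{val:>9.2f}pp{ci:>18}"
                         f"{ptxt:>9}{pctxt:>8}")
        tail = ["-" * 78,
                "Risk differences in percentage points; CIs are normal-approximation"
                " bootstrap intervals." if self.bootstrap is not None else
                "-" * 0]
        return "\n".join(head + lines + [t for t in tail if t])
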