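"""Unadjusted and adjusted association table (separate logistic models).

One row per association in three panels: exposure -> outcome, exposure ->
each mediator, and each mediator -> outcome.  Exposure models adjust for
the confounders; mediator-outcome models adjust for the confounders and the
exposure.  Adjusted models use main effects plus squared age (no
interactions): the table reports single-coefficient odds ratios, which is
incompatible with exposure-by-covariate interaction terms; the
interaction-rich specification is reserved for the mediation engine.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data import StudyData
from .design import Encoding, FormulaSpec, design_info_for
from .exceptions import DispmedError
from .glm import fit_logistic
from .schema import VariableSchema

_Z95 = 1.959963984540054

_ADJUSTED_FORMULA = FormulaSpec(interactions=False, age_squared=True)
_UNADJUSTED_FORMULA = FormulaSpec(interactions=False, age_squared=False)


def _one_association(encoded, n, encoding, predictor: str, response: str,
                     adjust: list[str]) -> dict:
    row = {"association": f"{predictor} -> {response}"}
    for label, units, formula in (
            ("unadjusted", [predictor], _UNADJUSTED_FORMULA),
            ("adjusted", [predictor] + adjust, _ADJUSTED_FORMULA)):
        try:
            info = design_info_for(units, encoding, formula)
            X = info.matrix(encoded, n=n)
            model = fit_logistic(X, encoded[response], info, response=response)
            beta = model.coef(predictor)
            se = model.bse[info.term_names.index(predictor)]
            row[f"{label}_or"] = float(np.exp(beta))
            row[f"{label}_ci_low"] = float(np.exp(beta - _Z95 * se))
            row[f"{label}_ci_high"] = float(np.exp(beta + _Z95 * se))
            row[f"{label}_converged"] = model.converged
        except DispmedError as exc:
            row[f"{label}_or"] = np.nan
            row[f"{label}_ci_low"] = np.nan
            row[f"{label}_ci_high"] = np.nan
            row[f"{label}_converged"] = False
            row["error"] = str(exc)
    return row


def association_table(data: StudyData,
                      schema: VariableSchema | None = None) -> pd.DataFrame:
    """Odds ratios with 95% Wald CIs for every pairwise association panel.

    Fit errors are recorded per row (NaN estimates, convergence flag) and
    do not abort the remaining rows.
    """
    schema = schema or data.schema
    encoding = Encoding.from_data(data.frame, schema)
    encoded = encoding.encode(data.frame)
    n = data.n
    confs = schema.confounder_names
    rows = [_one_association(encoded, n, encoding, schema.exposure,
                             schema.outcome, confs)]
    for m in schema.mediator_names:
        rows.append(_one_association(encoded, n, encoding, schema.exposure,
                                     m, confs))
    for m in schema.mediator_names:
        rows.append(_one_association(encoded, n, encoding, m, schema.outcome,
                                     confs + [schema.exposure]))
    panel = (["exposure-outcome"]
             + ["exposure-mediator"] * len(schema.mediator_names)
             + ["mediator-outcome"] * len(schema.mediator_names))
    table = pd.DataFrame(rows)
    table.insert(0, "panel", panel)
    return table
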