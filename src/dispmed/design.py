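"""Design-matrix construction shared by every regression model in the package.

All models (exposure, mediator, outcome, association, imputation) are built
over one column encoding so that confounders enter identically everywhere:

* binary variables enter as 0/1 numeric columns;
* continuous variables are centered and scaled (for numerical stability;
  odds ratios are reported per original units by back-transformation);
* categorical variables expand to indicator columns against the first
  (lowest) level as reference.

A model's predictors are *term units* (one unit per raw variable); the full
specification optionally adds a squared term for each continuous unit and
one product term per unordered pair of units.  Column order is
deterministic: intercept, main effects in the given unit order, squared
terms, then interactions in lexicographic pair order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DegenerateDataError, SchemaError
from .schema import VariableSchema


@dataclass(frozen=True)
class FormulaSpec:
    """Model flexibility switches.

    ``interactions`` adds one product column per unordered pair of
    predictor units (categorical units expand over their indicator
    columns); ``age_squared`` adds a squared column for every continuous
    predictor.  The flexible default mirrors an analysis that includes all
    2-way interactions and age squared; ``main_effects()`` gives the plain
    variant used for robustness checks.
    """

    interactions: bool = True
    age_squared: bool = True

    @classmethod
    def main_effects(cls) -> "FormulaSpec":
        return cls(interactions=False, age_squared=False)

    @classmethod
    def flexible(cls) -> "FormulaSpec":
        return cls(interactions=True, age_squared=True)


class Encoding:
    """Fixed mapping from raw analysis columns to numeric encoded columns."""

    def __init__(self, schema: VariableSchema,
                 continuous: dict[str, tuple[float, float]],
                 categorical: dict[str, list]) -> None:
        self.schema = schema
        self.continuous = dict(continuous)   # name -> (center, scale)
        self.categorical = {k: list(v) for k, v in categorical.items()}

    @classmethod
    def from_data(cls, frame: pd.DataFrame, schema: VariableSchema,
                  standardize: bool = True) -> "Encoding":
        continuous, categorical = {}, {}
        for conf in schema.confounders:
            if conf.type == "continuous":
                vals = frame[conf.name].to_numpy(dtype=float)
                if standardize:
                    sd = float(np.std(vals))
                    continuous[conf.name] = (float(np.mean(vals)), sd if sd > 0 else 1.0)
                else:
                    continuous[conf.name] = (0.0, 1.0)
            elif conf.type == "categorical":
                levels = sorted(pd.unique(frame[conf.name].dropna()))
                categorical[conf.name] = levels
        return cls(schema, continuous, categorical)

    def columns_for(self, raw: str) -> list[str]:
        """Encoded column names for one raw variable (term unit)."""
        if raw in self.categorical:
            return [f"{raw}_{lvl}" for lvl in self.categorical[raw][1:]]
        return [raw]

    def encode(self, frame: pd.DataFrame) -> dict[str, np.ndarray]:
        """Encode every schema column present in `frame`."""
        out: dict[str, np.ndarray] = {}
        for col in self.schema.all_columns:
            if col not in frame.columns:
                continue
            if col in self.categorical:
                raw = frame[col].to_numpy()
                for lvl in self.categorical[col][1:]:
                    out[f"{col}_{lvl}"] = (raw == lvl).astype(float)
            elif col in self.continuous:
                center, scale = self.continuous[col]
                out[col] = (frame[col].to_numpy(dtype=float) - center) / scale
            else:
                out[col] = frame[col].to_numpy(dtype=float)
        return out


#: a term is a tuple of encoded-column names whose product forms the column;
#: the empty tuple is the intercept.
Term = tuple[str, ...]


def term_name(term: Term) -> str:
    if not term:
        return "const"
    if len(term) == 2 and term[0] == term[1]:
        return f"{term[0]}^2"
    return ":".join(term)


@dataclass(frozen=True)
class DesignInfo:
    """Ordered list of terms plus the encoding they are evaluated under."""

    terms: tuple[Term, ...]
    encoding: Encoding = field(repr=False)

    @property
    def term_names(self) -> list[str]:
        return [term_name(t) for t in self.terms]

    @property
    def n_columns(self) -> int:
        return len(self.terms)

    def matrix(self, encoded: dict[str, np.ndarray], n: int | None = None) -> np.ndarray:
        if n is None:
            n = len(next(iter(encoded.values())))
        X = np.empty((n, len(self.terms)))
        for k, term in enumerate(self.terms):
            if not term:
                X[:, k] = 1.0
            else:
                col = encoded[term[0]]
                for f in term[1:]:
                    col = col * encoded[f]
                X[:, k] = col
        return X


def model_terms(units: list[str], encoding: Encoding,
                formula: FormulaSpec) -> tuple[Term, ...]:
    """Terms for a model whose predictors are the given term units, in order."""
    terms: list[Term] = [()]
    for u in units:
        for c in encoding.columns_for(u):
            terms.append((c,))
    if formula.age_squared:
        for u in units:
            if u in encoding.continuous:
                terms.append((u, u))
    if formula.interactions:
        for i in range(len(units)):
            for j in range(i + 1, len(units)):
                for a in encoding.columns_for(units[i]):
                    for b in encoding.columns_for(units[j]):
                        terms.append((a, b))
    return tuple(terms)


def design_info_for(units: list[str], encoding: Encoding,
                    formula: FormulaSpec) -> DesignInfo:
    return DesignInfo(model_terms(units, encoding, formula), encoding)


def build_design(data, formula: FormulaSpec, response: str,
                 encoding: Encoding | None = None,
                 predictors: list[str] | None = None):
    """Design matrix + response vector for a complete patient table.

    Predictors default to every analysis column except the response, in
    schema order (exposure, mediators, confounders).  Raises
    DegenerateDataError when the response is constant.
    """
    schema = data.schema
    if response not in schema.all_columns:
        raise SchemaError(f"{response!r} is not an analysis column")
    if predictors is None:
        predictors = [c for c in schema.all_columns if c != response]
    if encoding is None:
        encoding = Encoding.from_data(data.frame, schema)
    y = data.frame[response].to_numpy(dtype=float)
    if np.all(y == y[0]):
        raise DegenerateDataError(f"response {response!r} is constant")
    info = design_info_for(predictors, encoding, formula)
    X = info.matrix(encoding.encode(data.frame), n=data.n)
    return X, y, info
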