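"""Synthetic stroke-registry generator and exact effect oracle.

The generator emulates the statistical structure the analysis assumes:
confounders C = (sex, age, calendar year) are drawn from fixed marginals,
the binary exposure X (low education) follows a logistic model given C, the
nine binary mediators follow sequential logistic models M_j | X, C,
M_1..M_{j-1} in schema order, and the binary outcome Y (lowered
consciousness) follows a logistic model given X, C and all mediators.
Because the generating mechanism is exactly the sequential factorization
the estimation engine assumes, every downstream stage can be tested for
parameter recovery, and ``true_effects`` computes the six estimands exactly
by enumeration over a confounder grid and all 2^9 mediator patterns.

``rikslike_preset`` returns a parameter set calibrated so that the implied
marginal prevalences match the published registry descriptives (low
education 43.5%, lowered consciousness 11.7%, atrial fibrillation 28.9%,
antihypertensives 66.5%, ...) via deterministic intercept adjustment, with
exposure-mediator and mediator-outcome coefficients taken from the
published adjusted odds ratios.
"""

from __future__ import annotations

import functools
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.stats import truncnorm

from .data import StudyData
from .design import DesignInfo, Encoding
from .exceptions import ConfigError, DispmedError
from .glm import FittedModel, sigmoid
from .mediation import (EffectEstimates, MediationEngine, MediatorModelSet,
                        Population, effects_from_engine)
from .schema import VariableSchema, riksstroke_schema

# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------


def _parse_term(key: str) -> tuple:
    if key == "const":
        return ()
    if key.endswith("^2"):
        base = key[:-2]
        return (base, base)
    if ":" in key:
        a, b = key.split(":")
        return (a, b)
    return (key,)


def model_from_coefficients(coefs: dict[str, float], encoding: Encoding) -> FittedModel:
    """Build a logistic model directly from named coefficients.

    Keys are encoded-column names, "name^2" squares, "a:b" products and
    "const" for the intercept.
    """
    terms = tuple(_parse_term(k) for k in coefs)
    info = DesignInfo(terms=terms, encoding=encoding)
    return FittedModel(design_info=info, params=np.array(list(coefs.values()), float))


@dataclass
class GeneratorParams:
    """Full specification of a synthetic registry.

    Coefficients are on the log-odds scale over encoded columns: binary
    variables 0/1, age as (age - age_center) / age_scale, year as indicator
    columns against the first level.
    """

    n: int
    seed: int | None
    schema: VariableSchema
    age_mean: float = 75.3
    age_sd: float = 12.0
    age_range: tuple[float, float] = (18.0, 100.0)
    sex_prev: float = 0.474
    year_probs: dict = field(default_factory=dict)
    beta_x: dict = field(default_factory=dict)
    beta_m: dict = field(default_factory=dict)   # mediator name -> coef dict
    beta_y: dict = field(default_factory=dict)
    age_center: float = 75.0
    age_scale: float = 10.0

    def __post_init__(self) -> None:
        probs = np.array(list(self.year_probs.values()), float)
        if probs.size == 0 or abs(probs.sum() - 1.0) > 1e-6 or (probs < 0).any():
            raise ConfigError("year_probs must be a probability vector")
        missing = [m for m in self.schema.mediator_names if m not in self.beta_m]
        if missing:
            raise ConfigError(f"beta_m missing mediators: {missing}")

    @property
    def encoding(self) -> Encoding:
        return Encoding(self.schema,
                        continuous={"age": (self.age_center, self.age_scale)},
                        categorical={"year": list(self.year_probs)})

    def exposure_model(self) -> FittedModel:
        return model_from_coefficients(self.beta_x, self.encoding)

    def sequential_models(self) -> list[FittedModel]:
        return [model_from_coefficients(self.beta_m[m], self.encoding)
                for m in self.schema.mediator_names]

    def outcome_model(self) -> FittedModel:
        return model_from_coefficients(self.beta_y, self.encoding)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        def clean(d):
            return {k: float(v) for k, v in d.items()}
        return {
            "n": self.n, "seed": self.seed, "schema": self.schema.to_dict(),
            "age_mean": self.age_mean, "age_sd": self.age_sd,
            "age_range": list(self.age_range), "sex_prev": self.sex_prev,
            "year_probs": {str(k): float(v) for k, v in self.year_probs.items()},
            "beta_x": clean(self.beta_x),
            "beta_m": {m: clean(d) for m, d in self.beta_m.items()},
            "beta_y": clean(self.beta_y),
            "age_center": self.age_center, "age_scale": self.age_scale,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorParams":
        return cls(
            n=d["n"], seed=d.get("seed"),
            schema=VariableSchema.from_dict(d["schema"]),
            age_mean=d["age_mean"], age_sd=d["age_sd"],
            age_range=tuple(d["age_range"]), sex_prev=d["sex_prev"],
            year_probs={int(k): v for k, v in d["year_probs"].items()},
            beta_x=d["beta_x"], beta_m=d["beta_m"], beta_y=d["beta_y"],
            age_center=d.get("age_center", 75.0), age_scale=d.get("age_scale", 10.0))

    def save(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2))
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "GeneratorParams":
        path = Path(path)
        d = (json.loads(path.read_text()) if path.suffix == ".json"
             else yaml.safe_load(path.read_text()))
        return cls.from_dict(d)


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def _check_finite(lp: np.ndarray, what: str) -> None:
    if not np.all(np.isfinite(lp)):
        raise ConfigError(f"non-finite linear predictor in the model for {what}")


def generate_population(params: GeneratorParams) -> StudyData:
    """Draw a complete synthetic registry: C, then X | C, then M_1..M_J
    sequentially, then Y | X, M, C.  Reproducible given the seed."""
    rng = np.random.default_rng(params.seed)
    n = params.n
    schema = params.schema
    lo, hi = params.age_range
    a = (lo - params.age_mean) / params.age_sd
    b = (hi - params.age_mean) / params.age_sd
    age = truncnorm.rvs(a, b, loc=params.age_mean, scale=params.age_sd,
                        size=n, random_state=rng)
    sex = (rng.random(n) < params.sex_prev).astype(float)
    levels = np.array(list(params.year_probs))
    probs = np.array(list(params.year_probs.values()), float)
    year = rng.choice(levels, p=probs / probs.sum(), size=n)

    frame = pd.DataFrame({"sex": sex, "age": age, "year": year})
    enc = params.encoding.encode(frame)

    lp = params.exposure_model().linear_predictor(enc, n=n)
    _check_finite(lp, schema.exposure)
    x = (rng.random(n) < sigmoid(lp)).astype(float)
    enc[schema.exposure] = x
    frame[schema.exposure] = x

    for name, model in zip(schema.mediator_names, params.sequential_models()):
        lp = model.linear_predictor(enc, n=n)
        _check_finite(lp, name)
        m = (rng.random(n) < sigmoid(lp)).astype(float)
        enc[name] = m
        frame[name] = m

    lp = params.outcome_model().linear_predictor(enc, n=n)
    _check_finite(lp, schema.outcome)
    frame[schema.outcome] = (rng.random(n) < sigmoid(lp)).astype(float)
    return StudyData(frame[schema.all_columns].copy(), schema)


# ---------------------------------------------------------------------------
# confounder grid + exact calibration
# ---------------------------------------------------------------------------

def confounder_grid(params: GeneratorParams, age_step: float = 0.5):
    """Discretized confounder distribution: encoded columns + weights.

    Ages are interval midpoints with truncated-normal interval masses, so
    grid weights sum to one exactly.
    """
    lo, hi = params.age_range
    a = (lo - params.age_mean) / params.age_sd
    b = (hi - params.age_mean) / params.age_sd
    edges = np.arange(lo, hi + age_step, age_step)
    edges[-1] = hi
    mids = 0.5 * (edges[:-1] + edges[1:])
    cdf = truncnorm.cdf(edges, a, b, loc=params.age_mean, scale=params.age_sd)
    age_w = np.diff(cdf)
    age_w /= age_w.sum()

    sex_vals = np.array([0.0, 1.0])
    sex_w = np.array([1 - params.sex_prev, params.sex_prev])
    years = np.array(list(params.year_probs))
    year_w = np.array(list(params.year_probs.values()), float)
    year_w /= year_w.sum()

    age_g, sex_g, year_g = np.meshgrid(mids, sex_vals, years, indexing="ij")
    w = (age_w[:, None, None] * sex_w[None, :, None] * year_w[None, None, :]).ravel()
    frame = pd.DataFrame({"age": age_g.ravel(), "sex": sex_g.ravel(),
                          "year": year_g.ravel()})
    return frame, w


def calibrate_intercepts(params: GeneratorParams, targets: dict[str, float],
                         age_step: float = 1.0) -> GeneratorParams:
    """Set model intercepts so implied marginal prevalences hit `targets`.

    Works forward through the factorization (X, then each mediator in
    order, then Y), maintaining the exact joint distribution over the
    discretized confounder grid and solving each intercept by root finding.
    Deterministic; accuracy is limited only by the age discretization.
    """
    schema = params.schema
    frame, w = confounder_grid(params, age_step=age_step)
    enc = params.encoding.encode(frame)
    weights = w.copy()

    def _solve(coefs: dict, response: str) -> dict:
        model = model_from_coefficients({**coefs, "const": 0.0}, params.encoding)
        lp = model.linear_predictor(enc, n=len(weights))
        target = targets[response]

        def gap(b0: float) -> float:
            return float(weights @ sigmoid(lp + b0)) - target

        b0 = brentq(gap, -25.0, 25.0, xtol=1e-12)
        out = dict(coefs)
        out["const"] = float(b0)
        return out, sigmoid(lp + b0)

    def _expand(name: str, p: np.ndarray) -> None:
        nonlocal weights
        for col in list(enc):
            enc[col] = np.concatenate([enc[col], enc[col]])
        enc[name] = np.concatenate([np.zeros(len(p)), np.ones(len(p))])
        weights = np.concatenate([weights * (1 - p), weights * p])

    new = replace(params)
    new.beta_x, p = _solve(params.beta_x, schema.exposure)
    _expand(schema.exposure, p)
    new_beta_m = {}
    for med in schema.mediator_names:
        new_beta_m[med], p = _solve(params.beta_m[med], med)
        _expand(med, p)
    new.beta_m = new_beta_m
    new.beta_y, _ = _solve(params.beta_y, schema.outcome)
    return new


# ---------------------------------------------------------------------------
# exact effects
# ---------------------------------------------------------------------------

class _ExactMarginalEngine(MediationEngine):
    """Enumeration engine whose per-mediator marginals are obtained by exact
    marginalization of the sequential factorization (generator truth)."""

    def _marginal_probs(self, x: int) -> np.ndarray:
        key = ("margp", x)
        if key not in self._cache:
            W = self._joint_weights(x)
            M = self._patterns()
            self._cache[key] = np.clip(W @ M, 1e-12, 1 - 1e-12)
        return self._cache[key]


def true_effects(params: GeneratorParams, c_grid=None, reference: str = "exposed",
                 anchor: str = "a_first", age_step: float = 0.5) -> EffectEstimates:
    """The six estimands computed exactly from the generating coefficients.

    Enumerates over the discretized confounder grid, both exposure levels
    and all 2^J mediator patterns, standardized to the requested reference
    population's confounder distribution (default: the exposed).

    ``c_grid`` may supply an explicit (confounder frame, weights) pair;
    weights must sum to 1.
    """
    if c_grid is None:
        frame, w = confounder_grid(params, age_step=age_step)
    else:
        frame, w = c_grid
        w = np.asarray(w, float)
        if abs(w.sum() - 1.0) > 1e-8:
            raise ConfigError("c_grid weights must sum to 1")
    enc = params.encoding.encode(frame)
    n = len(w)
    p_x = sigmoid(params.exposure_model().linear_predictor(enc, n=n))
    if reference == "exposed":
        ref_w = w * p_x
    elif reference == "unexposed":
        ref_w = w * (1 - p_x)
    elif reference == "all":
        ref_w = w.copy()
    else:
        raise DispmedError(f"unknown reference population {reference!r}")
    total = ref_w.sum()
    if total <= 0:
        raise DispmedError(f"reference population {reference!r} has zero mass")
    pop = Population(encoded=enc, weights=ref_w / total, n=n)

    seq = params.sequential_models()
    mset = MediatorModelSet(sequential=seq, marginal=seq, schema=params.schema,
                            encoding=params.encoding)
    eng = _ExactMarginalEngine(mset, params.outcome_model(), pop, mode="enumerate")
    return effects_from_engine(eng, anchor=anchor, reference=reference)


# ---------------------------------------------------------------------------
# the registry-like preset
# ---------------------------------------------------------------------------

#: published marginal prevalences used as calibration targets
RIKSLIKE_TARGETS = {
    "low_education": 0.435,
    "lowered_consciousness": 0.117,
    "smoking": 0.146,
    "diabetes": 0.215,
    "atrial_fibrillation": 0.289,
    "previous_stroke": 0.228,
    "adl_dependency": 0.120,
    "antihypertensives": 0.665,
    "statins": 0.298,
    "antiplatelets": 0.389,
    "anticoagulants": 0.101,
}

#: published year-of-stroke distribution (normalized)
_YEAR_PROBS = {2012: 0.219, 2013: 0.213, 2014: 0.203, 2015: 0.189, 2016: 0.176}


def _rikslike_slopes() -> tuple[dict, dict, dict]:
    """Slope coefficients for the registry-like preset.

    Exposure coefficients in the mediator models and mediator/exposure
    coefficients in the outcome model are the published adjusted log odds
    ratios; confounder and cross-mediator coefficients are fixed, clinically
    plausible choices (age strongly raises atrial fibrillation and ADL
    dependency; atrial fibrillation indicates anticoagulants; risk factors
    drive prevention-drug prescription, which creates the between-block
    dependence).  Intercepts are calibrated separately.
    """
    ln = np.log
    beta_x = {"age": 0.35, "sex": 0.10, "year_2013": -0.03, "year_2014": -0.06,
              "year_2015": -0.09, "year_2016": -0.12}
    beta_m = {
        "smoking": {"low_education": ln(1.37), "age": -0.45, "sex": -0.05},
        "diabetes": {"low_education": ln(1.25), "age": 0.10, "sex": -0.20,
                     "smoking": 0.10},
        "atrial_fibrillation": {"low_education": ln(0.98), "age": 0.55,
                                "sex": -0.15, "diabetes": 0.15},
        "previous_stroke": {"low_education": ln(1.05), "age": 0.25, "sex": -0.10,
                            "diabetes": 0.20, "atrial_fibrillation": 0.35},
        "adl_dependency": {"low_education": ln(1.26), "age": 0.75, "sex": 0.25,
                           "diabetes": 0.25, "previous_stroke": 0.70},
        "antihypertensives": {"low_education": ln(1.16), "age": 0.40, "sex": 0.05,
                              "diabetes": 0.55, "atrial_fibrillation": 0.65,
                              "previous_stroke": 0.35, "adl_dependency": 0.20},
        "statins": {"low_education": ln(1.08), "age": -0.10, "sex": -0.10,
                    "smoking": 0.15, "diabetes": 0.85, "previous_stroke": 0.55,
                    "antihypertensives": 0.40},
        "antiplatelets": {"low_education": ln(1.09), "age": 0.30,
                          "previous_stroke": 0.85, "atrial_fibrillation": -0.25,
                          "antihypertensives": 0.30},
        "anticoagulants": {"low_education": ln(0.92), "age": 0.15, "sex": -0.05,
                           "atrial_fibrillation": 2.30, "previous_stroke": 0.25,
                           "antiplatelets": -0.90},
    }
    beta_y = {"low_education": ln(1.16), "age": 0.35, "age^2": 0.10, "sex": 0.10,
              "smoking": ln(0.98), "diabetes": ln(1.11),
              "atrial_fibrillation": ln(1.90), "previous_stroke": ln(1.27),
              "adl_dependency": ln(2.88), "antihypertensives": ln(1.02),
              "statins": ln(0.89), "antiplatelets": ln(1.01),
              "anticoagulants": ln(1.09)}
    return beta_x, beta_m, beta_y


@functools.lru_cache(maxsize=1)
def _rikslike_calibrated() -> GeneratorParams:
    beta_x, beta_m, beta_y = _rikslike_slopes()
    raw = GeneratorParams(n=0, seed=None, schema=riksstroke_schema(),
                          year_probs=dict(_YEAR_PROBS), beta_x=beta_x,
                          beta_m=beta_m, beta_y=beta_y)
    return calibrate_intercepts(raw, RIKSLIKE_TARGETS, age_step=1.0)


def rikslike_preset(n: int = 100_000, seed: int | None = None) -> GeneratorParams:
    """Registry-like parameter set calibrated to the published marginals.

    The calibration is deterministic (iterative intercept adjustment on a
    1-year age grid) and cached; only ``n`` and ``seed`` vary per call.
    """
    base = _rikslike_calibrated()
    return replace(base, n=n, seed=seed)


# ---------------------------------------------------------------------------
# missingness injection
# ---------------------------------------------------------------------------

def riks_missingness_rates(schema: VariableSchema | None = None) -> dict[str, float]:
    """Per-variable missingness approximating the published registry rates:
    smoking 9.5%, ADL dependency 3%, small rates on the other exposure,
    outcome and mediator columns (chosen so the any-variable missing
    fraction lands at the published 14.8%); the administrative confounders
    sex, age and year stay fully observed."""
    schema = schema or riksstroke_schema()
    rates = {c: 0.0033 for c in [schema.exposure, schema.outcome]
             + schema.mediator_names}
    rates["smoking"] = 0.095
    rates["adl_dependency"] = 0.03
    return rates


def inject_missingness(data: StudyData, mechanism: str = "mcar",
                       rates: dict[str, float] | None = None,
                       seed: int | None = None, mar_driver: str | None = None,
                       mar_shift: float = 0.0) -> StudyData:
    """Mask cells MCAR or MAR; reproducible given the seed.

    MCAR masks each cell of variable v independently with probability
    ``rates[v]``.  MAR shifts the masking log-odds of every variable by
    ``mar_shift * value(mar_driver)``; the driver must stay fully observed
    (a rate for it is a configuration error).
    """
    rates = rates or {}
    for var, r in rates.items():
        if var not in data.schema.all_columns:
            raise ConfigError(f"missingness rate for unknown variable {var!r}")
        if not 0 <= r < 1:
            raise ConfigError(f"rate for {var!r} must be in [0, 1)")
    if mechanism not in ("mcar", "mar"):
        raise ConfigError(f"unknown missingness mechanism {mechanism!r}")
    if mechanism == "mar":
        if mar_driver is None:
            raise ConfigError("MAR requires a driver variable")
        if rates.get(mar_driver, 0.0) > 0:
            raise ConfigError("the MAR driver variable must stay fully observed")
        if data.frame[mar_driver].isna().any():
            raise ConfigError("the MAR driver variable has missing values")
    rng = np.random.default_rng(seed)
    frame = data.frame.copy()
    for var in data.schema.all_columns:
        r = rates.get(var, 0.0)
        if r <= 0:
            continue
        if mechanism == "mcar":
            p_miss = np.full(data.n, r)
        else:
            driver = data.frame[mar_driver].to_numpy(dtype=float)
            p_miss = sigmoid(np.log(r / (1 - r)) + mar_shift * driver)
        mask = rng.random(data.n) < p_miss
        frame.loc[mask, var] = np.nan
    return StudyData(frame, data.schema, data.age_range, validate=False)
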