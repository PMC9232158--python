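"""Interventional-disparity mediation engine.

The estimands are defined on the absolute-risk scale for a binary outcome Y,
binary exposure X, confounders C and binary mediators M = (M_A, M_B) in two
named blocks.  Writing r(x_out, source) for the standardized mean of the
outcome-model prediction at exposure level ``x_out`` with mediator vectors
drawn from ``source``, averaged over the reference population's confounder
distribution:

* ``joint(x_m)``   draws the full mediator vector from the sequential models
  at exposure x_m (schema order, block A then block B);
* ``indep(x_a, x_b)`` draws every block-A mediator from its marginal model at
  x_a and every block-B mediator from its marginal model at x_b, all
  mutually independently.

The six reported quantities are

    ATA    = r(1, joint(1)) - r(0, joint(0))      adjusted total association
    DE     = r(1, joint(0)) - r(0, joint(0))      direct effect
    IE_all = r(1, joint(1)) - r(1, joint(0))      indirect via all mediators
    IE_A   = r(1, indep(1,1)) - r(1, indep(0,1))  via block A (B held at 1)
    IE_B   = r(1, indep(0,1)) - r(1, indep(0,0))  via block B (A held at 0)
    IE_dep = IE_all - IE_A - IE_B                 mediator-dependence part

so that ATA = DE + IE_all and IE_all = IE_A + IE_B + IE_dep hold exactly by
construction.  Regime means are computed either by exact enumeration over
all 2^J mediator patterns or by Monte-Carlo simulation with common random
numbers shared across regimes.  IE_A/IE_B anchoring is order dependent; the
complementary anchoring (change block B first) is available via ``anchor``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import StudyData
from .design import DesignInfo, Encoding, FormulaSpec, design_info_for
from .exceptions import ConvergenceError, DegenerateDataError, DispmedError
from .glm import FittedModel, fit_logistic, sigmoid
from .schema import BLOCK_A, BLOCK_B, VariableSchema

_P_CLIP = 1e-12


# ---------------------------------------------------------------------------
# model sets and populations
# ---------------------------------------------------------------------------

@dataclass
class MediatorModelSet:
    """Sequential and marginal logistic models for all mediators.

    ``sequential[j]`` models M_j given (X, M_1..M_{j-1}, C); ``marginal[j]``
    models M_j given (X, C).  Both lists follow schema order.
    """

    sequential: list[FittedModel]
    marginal: list[FittedModel]
    schema: VariableSchema
    encoding: Encoding

    def __post_init__(self) -> None:
        J = len(self.schema.mediators)
        if len(self.sequential) != J or len(self.marginal) != J:
            raise DispmedError("model set must cover every mediator exactly once")

    @property
    def mediator_names(self) -> list[str]:
        return self.schema.mediator_names


@dataclass(frozen=True)
class Regime:
    """Exposure assignment for the outcome model and the mediator draw.

    ``source`` is "joint" (then ``x_m`` applies) or "independent" (then
    ``x_a``/``x_b`` apply to the two blocks).
    """

    x_out: int
    source: str
    x_m: int | None = None
    x_a: int | None = None
    x_b: int | None = None

    def __post_init__(self) -> None:
        if self.source not in ("joint", "independent"):
            raise DispmedError(f"unknown mediator source {self.source!r}")
        levels = (self.x_m,) if self.source == "joint" else (self.x_a, self.x_b)
        if self.x_out not in (0, 1) or any(v not in (0, 1) for v in levels):
            raise DispmedError("regime exposure levels must be 0 or 1")

    @classmethod
    def joint(cls, x_out: int, x_m: int) -> "Regime":
        return cls(x_out=x_out, source="joint", x_m=x_m)

    @classmethod
    def independent(cls, x_out: int, x_a: int, x_b: int) -> "Regime":
        return cls(x_out=x_out, source="independent", x_a=x_a, x_b=x_b)


@dataclass
class Population:
    """Confounder rows with standardization weights (encoded columns)."""

    encoded: dict[str, np.ndarray]
    weights: np.ndarray
    n: int


def standardization_population(data: StudyData, schema: VariableSchema | None = None,
                               encoding: Encoding | None = None,
                               reference: str = "exposed") -> Population:
    """Confounder distribution the effects are standardized to.

    ``reference="exposed"`` (default) uses the confounder vectors of all
    rows with X = 1 with equal weights; "all" and "unexposed" are the
    obvious alternatives.
    """
    schema = schema or data.schema
    if encoding is None:
        encoding = Encoding.from_data(data.frame, schema)
    x = data.frame[schema.exposure].to_numpy(dtype=float)
    if reference == "exposed":
        mask = x == 1
    elif reference == "unexposed":
        mask = x == 0
    elif reference == "all":
        mask = np.ones(len(x), dtype=bool)
    else:
        raise DispmedError(f"unknown reference population {reference!r}")
    if not mask.any():
        raise DegenerateDataError(f"reference population {reference!r} is empty")
    sub = data.frame.loc[mask]
    enc = encoding.encode(sub)
    n = int(mask.sum())
    return Population(encoded=enc, weights=np.full(n, 1.0 / n), n=n)


# ---------------------------------------------------------------------------
# model fitting
# ---------------------------------------------------------------------------

def fit_mediation_models(data: StudyData, schema: VariableSchema | None = None,
                         formula: FormulaSpec = FormulaSpec(),
                         encoding: Encoding | None = None,
                         ridge: float = 0.0) -> tuple[MediatorModelSet, FittedModel]:
    """Fit the outcome model and both mediator model sets.

    The outcome model regresses Y on (X, all M, C); sequential mediator
    model j regresses M_j on (X, M_1..M_{j-1}, C); marginal mediator model j
    regresses M_j on (X, C).  The FormulaSpec policy (interactions, squared
    continuous terms) is applied uniformly to each model's own predictor
    set.  Any non-convergent model raises ConvergenceError unless a ridge
    fallback is enabled.
    """
    schema = schema or data.schema
    if encoding is None:
        encoding = Encoding.from_data(data.frame, schema)
    encoded = encoding.encode(data.frame)
    meds = schema.mediator_names
    confs = schema.confounder_names

    def _fit(units: list[str], response: str) -> FittedModel:
        info = design_info_for(units, encoding, formula)
        X = info.matrix(encoded, n=data.n)
        model = fit_logistic(X, encoded[response], info, ridge=ridge, response=response)
        if not model.converged:
            raise ConvergenceError(
                f"model for {response!r} did not converge "
                "(separation or iteration limit); consider the ridge fallback")
        return model

    sequential = [_fit([schema.exposure] + meds[:j] + confs, meds[j])
                  for j in range(len(meds))]
    marginal = [_fit([schema.exposure] + confs, m) for m in meds]
    outcome = _fit([schema.exposure] + meds + confs, schema.outcome)
    mset = MediatorModelSet(sequential=sequential, marginal=marginal,
                            schema=schema, encoding=encoding)
    return mset, outcome


# ---------------------------------------------------------------------------
# linear-predictor profiles
# ---------------------------------------------------------------------------

def _mediator_profile(model: FittedModel, pop: Population, exposure: str,
                      x_val: float, mediators: list[str]):
    """Decompose a model's linear predictor over mediator patterns.

    For fixed exposure level and population confounders, every model in the
    term language satisfies  lp(m) = a0 + sum_j m_j a_j + sum_{j<k} m_j m_k b_jk
    with a0, a_j depending on the row.  Returns (a0 (n,), A (n, J), B (J, J)).
    """
    n = pop.n
    J = len(mediators)
    idx = {m: j for j, m in enumerate(mediators)}
    a0 = np.zeros(n)
    A = np.zeros((n, J)) if J else np.zeros((n, 0))
    B = np.zeros((J, J))
    for coef, term in zip(model.params, model.design_info.terms):
        if coef == 0.0:
            continue
        med = [f for f in term if f in idx]
        scalar = float(coef)
        vec = None
        for f in term:
            if f in idx:
                continue
            if f == exposure:
                scalar *= x_val
            else:
                vec = pop.encoded[f] if vec is None else vec * pop.encoded[f]
        contrib = scalar if vec is None else scalar * vec
        if len(med) == 0:
            a0 += contrib
        elif len(med) == 1:
            A[:, idx[med[0]]] += contrib
        else:
            B[idx[med[0]], idx[med[1]]] += scalar
    return a0, A, B


def _bit_matrix(j: int) -> np.ndarray:
    ints = np.arange(2 ** j)
    return ((ints[:, None] >> np.arange(j)) & 1).astype(float)


def _quad(patterns: np.ndarray, B: np.ndarray) -> np.ndarray:
    if not B.any():
        return np.zeros(patterns.shape[0])
    return np.einsum("pi,ij,pj->p", patterns, B, patterns)


# ---------------------------------------------------------------------------
# the engine
# ---------------------------------------------------------------------------

class MediationEngine:
    """Computes regime means for a fixed model set and population.

    In ``enumerate`` mode every regime mean is exact given the fitted
    models.  In ``mc`` mode each population row receives K simulated
    mediator vectors per regime, with the same uniform draws reused across
    regimes (common random numbers), which makes the decomposition
    identities exact and reduces the variance of the contrasts.
    """

    def __init__(self, models: MediatorModelSet, outcome_model: FittedModel,
                 population: Population, mode: str = "enumerate",
                 draws: int = 500, seed: int | None = None) -> None:
        if mode not in ("enumerate", "mc"):
            raise DispmedError(f"unknown mode {mode!r}")
        if mode == "mc" and draws < 1:
            raise DispmedError("mc mode needs draws >= 1")
        self.models = models
        self.outcome_model = outcome_model
        self.pop = population
        self.mode = mode
        self.draws = draws
        self.seed = seed
        self.schema = models.schema
        self.mediators = models.mediator_names
        self.J = len(self.mediators)
        self._cache: dict = {}
        if mode == "mc":
            ss = np.random.SeedSequence(0 if seed is None else seed)
            self._med_streams = ss.spawn(self.J)

    # -- shared pieces -----------------------------------------------------
    def _patterns(self) -> np.ndarray:
        key = ("patterns",)
        if key not in self._cache:
            self._cache[key] = _bit_matrix(self.J)
        return self._cache[key]

    def _outcome_table(self, x_out: int) -> np.ndarray:
        key = ("ytab", x_out)
        if key not in self._cache:
            a0, A, B = _mediator_profile(self.outcome_model, self.pop,
                                         self.schema.exposure, x_out, self.mediators)
            M = self._patterns()
            lp = a0[:, None] + A @ M.T + _quad(M, B)[None, :]
            self._cache[key] = sigmoid(lp)
        return self._cache[key]

    def _joint_weights(self, x_m: int) -> np.ndarray:
        key = ("jointw", x_m)
        if key not in self._cache:
            # grow the joint over prefixes: pattern int p has bit j = m_{j+1},
            # so appending mediator j doubles the table along axis 1
            W = np.ones((self.pop.n, 1))
            for j, model in enumerate(self.models.sequential):
                a0, A, B = _mediator_profile(model, self.pop, self.schema.exposure,
                                             x_m, self.mediators[:j])
                prefixes = _bit_matrix(j)
                lp = a0[:, None]
                if j:
                    lp = lp + A @ prefixes.T + _quad(prefixes, B)[None, :]
                pj = sigmoid(lp)                       # (n, 2^j)
                W = np.concatenate([W * (1.0 - pj), W * pj], axis=1)
            self._cache[key] = W
        return self._cache[key]

    def _marginal_probs(self, x: int) -> np.ndarray:
        key = ("margp", x)
        if key not in self._cache:
            cols = []
            for model in self.models.marginal:
                a0, _, _ = _mediator_profile(model, self.pop, self.schema.exposure,
                                             x, [])
                cols.append(sigmoid(a0))
            self._cache[key] = np.clip(np.column_stack(cols), _P_CLIP, 1 - _P_CLIP)
        return self._cache[key]

    def _independent_weights(self, x_a: int, x_b: int) -> np.ndarray:
        key = ("indepw", x_a, x_b)
        if key not in self._cache:
            block = np.array([m.block == BLOCK_B for m in self.schema.mediators])
            pa, pb = self._marginal_probs(x_a), self._marginal_probs(x_b)
            p = np.where(block[None, :], pb, pa)
            W = np.ones((self.pop.n, 1))
            for j in range(self.J):
                pj = p[:, j:j + 1]
                W = np.concatenate([W * (1.0 - pj), W * pj], axis=1)
            self._cache[key] = W
        return self._cache[key]

    # -- regime means ------------------------------------------------------
    def regime_mean(self, regime: Regime) -> float:
        key = ("mean", regime)
        if key not in self._cache:
            if self.mode == "enumerate":
                val = self._regime_mean_enum(regime)
            else:
                val = self._regime_mean_mc(regime)
            self._cache[key] = val
        return self._cache[key]

    def _regime_mean_enum(self, regime: Regime) -> float:
        probs = self._outcome_table(regime.x_out)
        if regime.source == "joint":
            W = self._joint_weights(regime.x_m)
        else:
            W = self._independent_weights(regime.x_a, regime.x_b)
        return float(np.einsum("r,rp,rp->", self.pop.weights, W, probs))

    def _draw_uniforms(self, j: int) -> np.ndarray:
        # fresh generator per mediator stream => identical draws across regimes
        rng = np.random.default_rng(self._med_streams[j])
        return rng.random((self.pop.n, self.draws))

    def _regime_mean_mc(self, regime: Regime) -> float:
        n, K, J = self.pop.n, self.draws, self.J
        m = np.empty((J, n, K))
        if regime.source == "joint":
            profiles = [
                _mediator_profile(mod, self.pop, self.schema.exposure,
                                  regime.x_m, self.mediators[:j])
                for j, mod in enumerate(self.models.sequential)]
            for j, (a0, A, B) in enumerate(profiles):
                lp = np.broadcast_to(a0[:, None], (n, K)).copy()
                for k in range(j):
                    lp += (A[:, k])[:, None] * m[k]
                    for l in range(k + 1, j):
                        if B[k, l] or B[l, k]:
                            lp += (B[k, l] + B[l, k]) * m[k] * m[l]
                m[j] = (self._draw_uniforms(j) < sigmoid(lp)).astype(float)
        else:
            block = [mm.block == BLOCK_B for mm in self.schema.mediators]
            pa, pb = self._marginal_probs(regime.x_a), self._marginal_probs(regime.x_b)
            for j in range(J):
                p = pb[:, j] if block[j] else pa[:, j]
                m[j] = (self._draw_uniforms(j) < p[:, None]).astype(float)
        a0, A, B = _mediator_profile(self.outcome_model, self.pop,
                                     self.schema.exposure, regime.x_out, self.mediators)
        lp = np.broadcast_to(a0[:, None], (n, K)).copy()
        for j in range(J):
            lp += (A[:, j])[:, None] * m[j]
        for j in range(J):
            for k in range(j + 1, J):
                if B[j, k] or B[k, j]:
                    lp += (B[j, k] + B[k, j]) * m[j] * m[k]
        return float(self.pop.weights @ sigmoid(lp).mean(axis=1))


def regime_mean(models: MediatorModelSet, outcome_model: FittedModel,
                population: Population, regime: Regime, mode: str = "enumerate",
                draws: int = 500, seed: int | None = None) -> float:
    """Standardized outcome mean under one regime (see module docstring)."""
    engine = MediationEngine(models, outcome_model, population, mode=mode,
                             draws=draws, seed=seed)
    return engine.regime_mean(regime)


# ---------------------------------------------------------------------------
# effect decomposition
# ---------------------------------------------------------------------------

EFFECT_NAMES = ("ata", "de", "ie_all", "ie_a", "ie_b", "ie_dep")

EFFECT_LABELS = {
    "ata": "Adjusted total association",
    "de": "Direct",
    "ie_all": "Indirect via all mediators",
    "ie_a": "Indirect via risk factors",
    "ie_b": "Indirect via prevention drugs",
    "ie_dep": "Indirect via block dependence",
}


@dataclass
class EffectEstimates:
    """The six-quantity decomposition in percentage points (absolute risk
    differences x 100)."""

    ata: float
    de: float
    ie_all: float
    ie_a: float
    ie_b: float
    ie_dep: float
    mode: str = "enumerate"
    draws: int = 0
    reference: str = "exposed"
    anchor: str = "a_first"
    regime_means: dict = field(default_factory=dict)

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in EFFECT_NAMES}

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in EFFECT_NAMES])

    def pct_of_total(self) -> dict[str, float]:
        return percent_of_total(self)


def percent_of_total(effects: EffectEstimates) -> dict[str, float]:
    """Each component as a percentage of the adjusted total association.

    Computed from unrounded values, so DE% + IE_all% = 100 exactly.  When
    ATA = 0 the percentages are undefined and returned as NaN.
    """
    if effects.ata == 0:
        return {k: float("nan") for k in EFFECT_NAMES if k != "ata"}
    return {k: 100.0 * getattr(effects, k) / effects.ata
            for k in EFFECT_NAMES if k != "ata"}


def effects_from_engine(eng: MediationEngine, anchor: str = "a_first",
                        reference: str = "exposed") -> EffectEstimates:
    """Decomposition from an engine's regime means (shared values, so the
    additivity identities hold exactly)."""
    if anchor not in ("a_first", "b_first"):
        raise DispmedError(f"unknown anchor {anchor!r}")
    r11 = eng.regime_mean(Regime.joint(1, 1))
    r10 = eng.regime_mean(Regime.joint(1, 0))
    r00 = eng.regime_mean(Regime.joint(0, 0))
    i11 = eng.regime_mean(Regime.independent(1, 1, 1))
    i01 = eng.regime_mean(Regime.independent(1, 0, 1))
    i10 = eng.regime_mean(Regime.independent(1, 1, 0))
    i00 = eng.regime_mean(Regime.independent(1, 0, 0))
    ata = r11 - r00
    de = r10 - r00
    ie_all = r11 - r10
    if anchor == "a_first":
        ie_a = i11 - i01
        ie_b = i01 - i00
    else:
        ie_b = i11 - i10
        ie_a = i10 - i00
    ie_dep = ie_all - ie_a - ie_b
    means = {
        "joint(x_out=1,x_m=1)": r11, "joint(x_out=1,x_m=0)": r10,
        "joint(x_out=0,x_m=0)": r00,
        "indep(x_out=1,x_a=1,x_b=1)": i11, "indep(x_out=1,x_a=0,x_b=1)": i01,
        "indep(x_out=1,x_a=1,x_b=0)": i10, "indep(x_out=1,x_a=0,x_b=0)": i00,
    }
    return EffectEstimates(
        ata=100 * ata, de=100 * de, ie_all=100 * ie_all, ie_a=100 * ie_a,
        ie_b=100 * ie_b, ie_dep=100 * ie_dep, mode=eng.mode,
        draws=eng.draws if eng.mode == "mc" else 0, reference=reference,
        anchor=anchor, regime_means=means)


def effects_from_models(models: MediatorModelSet, outcome_model: FittedModel,
                        population: Population, mode: str = "enumerate",
                        draws: int = 500, seed: int | None = None,
                        anchor: str = "a_first",
                        reference: str = "exposed") -> EffectEstimates:
    """Decomposition from an explicit model set (fitted or supplied)."""
    eng = MediationEngine(models, outcome_model, population, mode=mode,
                          draws=draws, seed=seed)
    return effects_from_engine(eng, anchor=anchor, reference=reference)


def estimate_effects(data: StudyData, schema: VariableSchema | None = None,
                     formula: FormulaSpec = FormulaSpec(), mode: str = "mc",
                     draws: int = 500, seed: int | None = None,
                     reference: str = "exposed", anchor: str = "a_first",
                     ridge: float = 0.0) -> EffectEstimates:
    """Fit all models on complete data and compute the decomposition."""
    schema = schema or data.schema
    encoding = Encoding.from_data(data.frame, schema)
    models, outcome_model = fit_mediation_models(
        data, schema, formula=formula, encoding=encoding, ridge=ridge)
    population = standardization_population(data, schema, encoding, reference)
    return effects_from_models(models, outcome_model, population, mode=mode,
                               draws=draws, seed=seed, anchor=anchor,
                               reference=reference)
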