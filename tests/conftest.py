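import numpy as np
import pandas as pd
import pytest

from dispmed import (Confounder, Encoding, FittedModel, GeneratorParams,
                     Mediator, MediatorModelSet, Population, StudyData,
                     VariableSchema)
from dispmed.simulate import model_from_coefficients


@pytest.fixture(scope="session")
def riks_schema():
    from dispmed import riksstroke_schema
    return riksstroke_schema()


# ---------------------------------------------------------------------------
# scenario S1: one binary confounder, two mediators (one per block),
# fully specified coefficient dictionaries for engine-vs-oracle checks
# ---------------------------------------------------------------------------

S1_SEQ = [
    {"const": -0.4, "x": 0.5, "c": 0.3},
    {"const": -0.8, "x": 0.3, "c": -0.2, "m1": 0.6},
]
S1_MARG = [
    {"const": -0.4, "x": 0.5, "c": 0.3},
    {"const": -0.7, "x": 0.35, "c": -0.15},
]
S1_OUT = {"const": -1.2, "x": 0.4, "c": 0.25, "m1": 0.7, "m2": -0.3,
          "m1:m2": 0.2, "x:m1": -0.1, "x:c": 0.15}
S1_ROWS = [{"c": 0.0}, {"c": 1.0}]
S1_WEIGHTS = [0.6, 0.4]


def s1_schema() -> VariableSchema:
    return VariableSchema(
        exposure="x", outcome="y",
        mediators=(Mediator("m1", "risk_factors"),
                   Mediator("m2", "prevention_drugs")),
        confounders=(Confounder("c", "binary"),))


@pytest.fixture
def s1():
    """Supplied-model S1 setup: (model set, outcome model, population)."""
    schema = s1_schema()
    enc = Encoding(schema, {}, {})
    seq = [model_from_coefficients(c, enc) for c in S1_SEQ]
    marg = [model_from_coefficients(c, enc) for c in S1_MARG]
    out = model_from_coefficients(S1_OUT, enc)
    mset = MediatorModelSet(sequential=seq, marginal=marg, schema=schema,
                            encoding=enc)
    pop = Population(
        encoded={"c": np.array([r["c"] for r in S1_ROWS])},
        weights=np.array(S1_WEIGHTS), n=len(S1_ROWS))
    return mset, out, pop


def s1_generator_params(n: int, seed: int | None) -> GeneratorParams:
    """A generative S1 scenario reusing the registry machinery: the only
    live confounder is the binary 'sex' column (age/year coefficients 0)."""
    schema = VariableSchema(
        exposure="x", outcome="y",
        mediators=(Mediator("m1", "risk_factors"),
                   Mediator("m2", "prevention_drugs")),
        confounders=(Confounder("sex", "binary"),))
    return GeneratorParams(
        n=n, seed=seed, schema=schema, sex_prev=0.45,
        year_probs={2012: 1.0},
        beta_x={"const": -0.3, "sex": 0.4},
        beta_m={"m1": {"const": -0.6, "x": np.log(2.0), "sex": 0.3},
                "m2": {"const": -1.0, "x": 0.35, "sex": -0.2, "m1": 0.5}},
        beta_y={"const": -1.5, "x": 0.3, "sex": 0.2, "m1": 0.8, "m2": 0.4})


@pytest.fixture
def s1_params():
    return s1_generator_params


# ---------------------------------------------------------------------------
# small synthetic registries (session-scoped: generated once)
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def riks_data_small():
    from dispmed import generate_population, rikslike_preset
    return generate_population(rikslike_preset(n=4000, seed=42))


@pytest.fixture(scope="session")
def riks_truth():
    from dispmed import rikslike_preset, true_effects
    return true_effects(rikslike_preset(n=1, seed=0))


def make_complete_frame(n: int = 8, seed: int = 0) -> pd.DataFrame:
    """Tiny valid patient frame for data-layer tests."""
    rng = np.random.default_rng(seed)
    from dispmed import riksstroke_schema
    schema = riksstroke_schema()
    frame = pd.DataFrame({c: rng.integers(0, 2, n).astype(float)
                          for c in schema.binary_columns})
    frame["age"] = rng.uniform(40, 95, n).round(1)
    frame["year"] = rng.choice([2012, 2013, 2014, 2015, 2016], n)
    return frame[schema.all_columns]
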