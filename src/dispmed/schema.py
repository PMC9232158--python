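"""Variable-role schema: which column plays which part in the mediation analysis.

A schema names exactly one binary exposure, one binary outcome, an ordered
list of binary mediators partitioned into two named blocks (block A "risk
factors" and block B "prevention drugs"), and a set of confounders typed as
binary, continuous or categorical.  The mediator order is total and is the
order used for the sequential factorization of the joint mediator
distribution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .exceptions import SchemaError

BLOCK_A = "risk_factors"
BLOCK_B = "prevention_drugs"
_VALID_BLOCKS = (BLOCK_A, BLOCK_B)
_VALID_CONF_TYPES = ("binary", "continuous", "categorical")


@dataclass(frozen=True)
class Mediator:
    name: str
    block: str

    def __post_init__(self) -> None:
        if self.block not in _VALID_BLOCKS:
            raise SchemaError(
                f"mediator {self.name!r}: block must be one of {_VALID_BLOCKS}, "
                f"got {self.block!r}"
            )


@dataclass(frozen=True)
class Confounder:
    name: str
    type: str

    def __post_init__(self) -> None:
        if self.type not in _VALID_CONF_TYPES:
            raise SchemaError(
                f"confounder {self.name!r}: type must be one of "
                f"{_VALID_CONF_TYPES}, got {self.type!r}"
            )


@dataclass(frozen=True)
class VariableSchema:
    """Maps column names to analysis roles.

    Parameters
    ----------
    exposure : str
        Binary exposure column; 1 codes the disadvantaged group
        (low education in the stroke application).
    outcome : str
        Binary outcome column; 1 codes the severe outcome
        (lowered consciousness, RLS > 1).
    mediators : tuple of Mediator
        Ordered binary mediators; the order defines the sequential
        factorization used when drawing joint mediator vectors.
    confounders : tuple of Confounder
        Baseline confounders.
    """

    exposure: str
    outcome: str
    mediators: tuple[Mediator, ...]
    confounders: tuple[Confounder, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        names = [self.exposure, self.outcome]
        names += [m.name for m in self.mediators]
        names += [c.name for c in self.confounders]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise SchemaError(f"columns assigned to more than one role: {sorted(dupes)}")
        for block in _VALID_BLOCKS:
            if not any(m.block == block for m in self.mediators):
                raise SchemaError(f"mediator block {block!r} is empty")

    # -- convenience views -------------------------------------------------
    @property
    def mediator_names(self) -> list[str]:
        return [m.name for m in self.mediators]

    def block_names(self, block: str) -> list[str]:
        return [m.name for m in self.mediators if m.block == block]

    @property
    def confounder_names(self) -> list[str]:
        return [c.name for c in self.confounders]

    @property
    def binary_columns(self) -> list[str]:
        cols = [self.exposure, self.outcome] + self.mediator_names
        cols += [c.name for c in self.confounders if c.type == "binary"]
        return cols

    @property
    def all_columns(self) -> list[str]:
        return (
            [self.exposure, self.outcome]
            + self.mediator_names
            + self.confounder_names
        )

    def confounder_type(self, name: str) -> str:
        for c in self.confounders:
            if c.name == name:
                return c.type
        raise SchemaError(f"{name!r} is not a confounder in this schema")

    def swap_blocks(self) -> "VariableSchema":
        """Return a schema with the A/B block labels exchanged."""
        swapped = tuple(
            Mediator(m.name, BLOCK_B if m.block == BLOCK_A else BLOCK_A)
            for m in self.mediators
        )
        return VariableSchema(self.exposure, self.outcome, swapped, self.confounders)

    # -- (de)serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "exposure": self.exposure,
            "outcome": self.outcome,
            "mediators": [{"name": m.name, "block": m.block} for m in self.mediators],
            "confounders": [{"name": c.name, "type": c.type} for c in self.confounders],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VariableSchema":
        try:
            return cls(
                exposure=d["exposure"],
                outcome=d["outcome"],
                mediators=tuple(Mediator(m["name"], m["block"]) for m in d["mediators"]),
                confounders=tuple(
                    Confounder(c["name"], c["type"]) for c in d.get("confounders", [])
                ),
            )
        except KeyError as exc:
            raise SchemaError(f"schema config is missing key {exc}") from exc

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=2)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict(), sort_keys=False)
        )
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "VariableSchema":
        path = Path(path)
        if path.suffix == ".json":
            return cls.from_dict(json.loads(path.read_text()))
        return cls.from_dict(yaml.safe_load(path.read_text()))


def riksstroke_schema() -> VariableSchema:
    """The stroke-registry schema: education exposure, consciousness outcome,
    five risk-factor mediators, four prevention-drug mediators, and the
    baseline confounders sex, age and calendar year."""
    return VariableSchema(
        exposure="low_education",
        outcome="lowered_consciousness",
        mediators=(
            Mediator("smoking", BLOCK_A),
            Mediator("diabetes", BLOCK_A),
            Mediator("atrial_fibrillation", BLOCK_A),
            Mediator("previous_stroke", BLOCK_A),
            Mediator("adl_dependency", BLOCK_A),
            Mediator("antihypertensives", BLOCK_B),
            Mediator("statins", BLOCK_B),
            Mediator("antiplatelets", BLOCK_B),
            Mediator("anticoagulants", BLOCK_B),
        ),
        confounders=(
            Confounder("sex", "binary"),
            Confounder("age", "continuous"),
            Confounder("year", "categorical"),
        ),
    )
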