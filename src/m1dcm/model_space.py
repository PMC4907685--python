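"""Microcircuit architectures for laminar DCM of primary motor cortex.

The model space compared here consists of four-population neural-mass
circuits.  The M1 family has three pyramidal populations — superficial
(layer 2/3), middle (layer 5A) and deep (layer 5B, the Betz-cell layer) —
plus a single pool of inhibitory interneurons, each layer receiving its own
exogenous input (Es, Em, Ed).  A reduced canonical-microcircuit (CMC)
architecture, in which a granular spiny-stellate population replaces the
middle pyramidal one and only the granular layer receives input, serves as
the baseline the M1 variants are compared against.

Connections are directed and signed.  Projections from the inhibitory
population are GABAergic (inhibitory); every population additionally has an
inhibitory self-connection modelling its gain (self-inhibition); all other
inter-population projections are glutamatergic (excitatory).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import Enum

import yaml

from .errors import InvalidArchitectureError

__all__ = [
    "Population",
    "Connection",
    "ModelSpec",
    "ConditionModulationDesign",
    "CONDITIONS",
    "M1_OPTIONAL_EDGES",
    "build_m1_core",
    "enumerate_m1_models",
    "winning_m1_model",
    "build_reduced_cmc",
    "compared_model_space",
    "count_connections",
    "validate_model",
    "default_design",
]

#: Ordered condition labels; ``rest`` is the reference condition.
CONDITIONS: tuple[str, ...] = ("rest", "grip", "post_grip")

EXCITATORY = "excitatory"
INHIBITORY = "inhibitory"


class Population(str, Enum):
    """Neuronal subpopulations of the laminar microcircuit."""

    SP = "superficial_pyramidal"
    MP = "middle_pyramidal"
    DP = "deep_pyramidal"
    II = "inhibitory_interneuron"
    SS = "spiny_stellate"

    @property
    def code(self) -> str:
        return self.name

    @classmethod
    def parse(cls, value: "str | Population") -> "Population":
        if isinstance(value, Population):
            return value
        value = str(value)
        if value in cls.__members__:
            return cls[value]
        return cls(value)


def _expected_sign(source: Population, target: Population) -> str:
    """Sign forced by the circuit's biology: GABAergic interneuron output
    and self-connections (gain terms) are inhibitory, all else excitatory."""
    if source is Population.II or source is target:
        return INHIBITORY
    return EXCITATORY


@dataclass(frozen=True)
class Connection:
    """A directed, signed projection between two populations.

    ``modulated`` flags eligibility for condition-specific changes in
    strength (the beta parameters of the fitted model).
    """

    source: Population
    target: Population
    sign: str = ""
    modulated: bool = True

    def __post_init__(self):
        object.__setattr__(self, "source", Population.parse(self.source))
        object.__setattr__(self, "target", Population.parse(self.target))
        if not self.sign:
            object.__setattr__(self, "sign", _expected_sign(self.source, self.target))

    @property
    def is_self(self) -> bool:
        return self.source is self.target

    @property
    def sign_value(self) -> int:
        return -1 if self.sign == INHIBITORY else 1

    @property
    def label(self) -> str:
        return f"{self.source.code}->{self.target.code}"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.label}:{self.sign}"


@dataclass(frozen=True)
class ModelSpec:
    """A microcircuit architecture: populations, connections and inputs.

    ``inputs`` maps exogenous-input labels (Es/Em/Ed, or Eg for the
    granular input of the reduced CMC) to their target population.
    """

    name: str
    populations: tuple[Population, ...]
    connections: tuple[Connection, ...]
    inputs: dict[str, Population]
    architecture_family: str = "m1"

    def __post_init__(self):
        object.__setattr__(
            self, "populations", tuple(Population.parse(p) for p in self.populations)
        )
        object.__setattr__(self, "connections", tuple(self.connections))
        object.__setattr__(
            self,
            "inputs",
            {str(k): Population.parse(v) for k, v in self.inputs.items()},
        )

    # -- hashable/equality helpers -------------------------------------
    def __eq__(self, other) -> bool:
        if not isinstance(other, ModelSpec):
            return NotImplemented
        return (
            self.populations == other.populations
            and self.connections == other.connections
            and self.inputs == other.inputs
            and self.architecture_family == other.architecture_family
        )

    def __hash__(self) -> int:
        return hash(
            (
                self.populations,
                self.connections,
                tuple(sorted(self.inputs.items())),
                self.architecture_family,
            )
        )

    # -- convenience ----------------------------------------------------
    @property
    def n_populations(self) -> int:
        return len(self.populations)

    @property
    def n_connections(self) -> int:
        return len(self.connections)

    def population_index(self, pop: "Population | str") -> int:
        return self.populations.index(Population.parse(pop))

    def connection_index(self, source, target) -> int:
        source, target = Population.parse(source), Population.parse(target)
        for i, c in enumerate(self.connections):
            if c.source is source and c.target is target:
                return i
        raise KeyError(f"no connection {source.code}->{target.code}")

    def has_connection(self, source, target) -> bool:
        try:
            self.connection_index(source, target)
            return True
        except KeyError:
            return False

    @property
    def inter_connection_indices(self) -> tuple[int, ...]:
        return tuple(i for i, c in enumerate(self.connections) if not c.is_self)

    # -- serialisation ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "architecture_family": self.architecture_family,
            "populations": [p.value for p in self.populations],
            "connections": [
                {"edge": f"{c.source.code}->{c.target.code}", "sign": c.sign,
                 "modulated": bool(c.modulated)}
                for c in self.connections
            ],
            "inputs": {k: v.value for k, v in self.inputs.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        conns = []
        for entry in d["connections"]:
            src, tgt = entry["edge"].split("->")
            conns.append(
                Connection(
                    Population.parse(src),
                    Population.parse(tgt),
                    sign=entry["sign"],
                    modulated=bool(entry.get("modulated", True)),
                )
            )
        return cls(
            name=d["name"],
            populations=tuple(Population.parse(p) for p in d["populations"]),
            connections=tuple(conns),
            inputs=d["inputs"],
            architecture_family=d["architecture_family"],
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ModelSpec":
        return cls.from_dict(yaml.safe_load(text))

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ModelSpec":
        return cls.from_dict(json.loads(text))


@dataclass(frozen=True)
class ConditionModulationDesign:
    """Which model elements carry condition-specific (beta) modulators.

    ``rest`` is the reference condition and carries zero modulation by
    definition; betas are estimated for every other condition.
    """

    conditions: tuple[str, ...] = CONDITIONS
    modulated_connections: tuple[int, ...] = ()
    modulated_inputs: tuple[str, ...] = ()

    def __post_init__(self):
        if not self.conditions or self.conditions[0] != "rest":
            raise InvalidArchitectureError(
                "rest must be the first (reference) condition"
            )

    @property
    def non_rest_conditions(self) -> tuple[str, ...]:
        return tuple(c for c in self.conditions if c != "rest")


def default_design(model: ModelSpec) -> ConditionModulationDesign:
    """Default modulation design: every connection present in the model is
    eligible for condition-specific change, and so is every exogenous input."""
    return ConditionModulationDesign(
        conditions=CONDITIONS,
        modulated_connections=tuple(range(model.n_connections)),
        modulated_inputs=tuple(model.inputs),
    )


# ---------------------------------------------------------------------------
# Architecture constructors
# ---------------------------------------------------------------------------

P = Population

#: Candidate connections resolved by model comparison, in a fixed order.
M1_OPTIONAL_EDGES: tuple[tuple[Population, Population], ...] = (
    (P.DP, P.SP),
    (P.DP, P.MP),
    (P.MP, P.DP),
)

_M1_CORE_INTER: tuple[tuple[Population, Population], ...] = (
    (P.SP, P.MP),
    (P.MP, P.SP),
    (P.SP, P.DP),
    (P.SP, P.II),
    (P.II, P.SP),
    (P.MP, P.II),
    (P.II, P.MP),
    (P.DP, P.II),
    (P.II, P.DP),
)

_M1_POPULATIONS = (P.SP, P.MP, P.DP, P.II)
_M1_INPUTS = {"Es": P.SP, "Em": P.MP, "Ed": P.DP}


def build_m1_core() -> ModelSpec:
    """The anatomically established M1 circuit (solid connections only).

    Nine inter-population projections — reciprocal superficial/middle
    coupling, the dominant superficial-to-deep pathway, and reciprocal
    coupling of the inhibitory population with all three pyramidal layers —
    plus one inhibitory self-connection per population, and distinct
    exogenous inputs to each layer.
    """
    conns = [Connection(s, t) for s, t in _M1_CORE_INTER]
    conns += [Connection(p, p) for p in _M1_POPULATIONS]
    return ModelSpec(
        name="m1_core",
        populations=_M1_POPULATIONS,
        connections=tuple(conns),
        inputs=dict(_M1_INPUTS),
        architecture_family="m1",
    )


def _with_optional(core: ModelSpec, subset: tuple[tuple[Population, Population], ...],
                   name: str) -> ModelSpec:
    inter = [c for c in core.connections if not c.is_self]
    selfs = [c for c in core.connections if c.is_self]
    extra = [Connection(s, t, modulated=True) for s, t in subset]
    return replace(core, name=name, connections=tuple(inter + extra + selfs))


def _subset_name(subset) -> str:
    if not subset:
        return "m1_core"
    tags = "+".join(f"{s.code.lower()}_{t.code.lower()}" for s, t in subset)
    return f"m1_core+{tags}"


def enumerate_m1_models(
    core: ModelSpec | None = None,
    optional_edges: tuple[tuple[Population, Population], ...] | None = None,
) -> list[ModelSpec]:
    """All M1 architectures formed by adding subsets of the candidate edges.

    Subsets are enumerated in binary order over ``optional_edges`` (bit i set
    means edge i is present), so with the three default candidates the list
    has 2**3 = 8 models and element 0 is the core itself.
    """
    core = build_m1_core() if core is None else core
    if core.architecture_family != "m1":
        raise InvalidArchitectureError(
            f"expected an m1-family core, got {core.architecture_family!r}"
        )
    optional = M1_OPTIONAL_EDGES if optional_edges is None else tuple(optional_edges)
    models = []
    for bits in range(2 ** len(optional)):
        subset = tuple(e for i, e in enumerate(optional) if bits >> i & 1)
        models.append(_with_optional(core, subset, _subset_name(subset)))
    return models


def winning_m1_model() -> ModelSpec:
    """The model selected by comparison: the core plus deep-to-superficial
    feedback (DP->SP) and nothing else — 14 connections in total."""
    return enumerate_m1_models()[1]


_CMC_POPULATIONS = (P.SS, P.SP, P.DP, P.II)
_CMC_INTER: tuple[tuple[Population, Population], ...] = (
    (P.SS, P.SP),
    (P.SP, P.DP),
    (P.SS, P.II),
    (P.II, P.SS),
    (P.SP, P.II),
    (P.II, P.SP),
    (P.DP, P.II),
    (P.II, P.DP),
)


def build_reduced_cmc() -> ModelSpec:
    """The reduced canonical-microcircuit baseline.

    Spiny stellate cells occupy the granular layer and receive the only
    exogenous input; forward excitation runs SS->SP->DP; the inhibitory
    population is reciprocally coupled to all three excitatory populations;
    every population keeps an inhibitory self-connection.  This default
    edge set is declared in the package configuration (the architecture
    shares the mathematical framework of the M1 family).
    """
    conns = [Connection(s, t) for s, t in _CMC_INTER]
    conns += [Connection(p, p) for p in _CMC_POPULATIONS]
    return ModelSpec(
        name="reduced_cmc",
        populations=_CMC_POPULATIONS,
        connections=tuple(conns),
        inputs={"Eg": P.SS},
        architecture_family="reduced_cmc",
    )


def compared_model_space() -> list[ModelSpec]:
    """The nine architectures of the comparison in their reporting order:
    model 1 is the winning M1 variant, model 2 the reduced CMC, models 3-9
    the remaining M1 subsets in binary order."""
    m1 = enumerate_m1_models()
    rest = [m for i, m in enumerate(m1) if i != 1]
    return [m1[1], build_reduced_cmc()] + rest


# ---------------------------------------------------------------------------
# Queries and validation
# ---------------------------------------------------------------------------

def count_connections(model: ModelSpec) -> int:
    """Number of directed connections, self-connections included, exogenous
    inputs excluded."""
    return len(model.connections)


def validate_model(model: ModelSpec) -> list[str]:
    """Check every architectural invariant; returns human-readable
    violations (empty list means the model is valid)."""
    violations: list[str] = []
    pops = set(model.populations)

    for c in model.connections:
        if c.source not in pops or c.target not in pops:
            violations.append(
                f"connection {c.label} references a population outside the model"
            )
        expected = _expected_sign(c.source, c.target)
        if c.sign != expected:
            violations.append(
                f"connection {c.label} has sign {c.sign!r} but must be {expected!r}"
                " (inhibitory iff from the interneuron population or a self-connection)"
            )

    seen = set()
    for c in model.connections:
        key = (c.source, c.target)
        if key in seen:
            violations.append(f"duplicate connection {c.label}")
        seen.add(key)

    for label, target in model.inputs.items():
        if target not in pops:
            violations.append(
                f"input {label} targets {target.value}, not a model population"
            )

    if Population.SS in pops and model.architecture_family != "reduced_cmc":
        violations.append(
            "spiny_stellate population is only permitted in the reduced CMC"
        )

    if model.architecture_family == "m1":
        if pops != set(_M1_POPULATIONS):
            violations.append(
                "m1 family requires exactly the four populations SP, MP, DP, II"
            )
        if set(model.inputs) != set(_M1_INPUTS):
            violations.append("m1 family requires all three inputs Es, Em, Ed")
    elif model.architecture_family == "reduced_cmc":
        if pops != set(_CMC_POPULATIONS):
            violations.append(
                "reduced CMC requires exactly the populations SS, SP, DP, II"
            )
    else:
        violations.append(
            f"unknown architecture family {model.architecture_family!r}"
        )

    return violations
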