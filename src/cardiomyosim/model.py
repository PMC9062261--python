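"""Species registry, compartments, parameters: the single source of truth.

The default model (compartment volumes, 63-species registry and every kinetic
constant) is stored in ``data/model.yaml`` and validated on load.  All
concentrations are in mM, time in s, the mitochondrial membrane potential in
mV and free energies in kJ/mol.  ``F/(RT)`` is precomputed once in 1/mV by
:meth:`Model.compiled` so unit conversions never appear inside rate laws.
"""

from __future__ import annotations

import copy as _copy
import importlib.resources
from dataclasses import dataclass, field
from types import SimpleNamespace

import yaml

__all__ = [
    "CompartmentTable",
    "SpeciesSpec",
    "Model",
    "ParameterOverride",
    "ModelValidationError",
    "default_model",
    "apply_overrides",
    "PRESETS",
]

COMPARTMENT_NAMES = ("vessel", "extracellular", "cytosol", "ims", "matrix")
SPECIES_KINDS = ("ode", "assignment", "constant")


class ModelValidationError(ValueError):
    """Raised when the model document violates its schema; lists all problems."""

    def __init__(self, problems):
        self.problems = list(problems)
        super().__init__("invalid model document:\n" + "\n".join(f"  - {p}" for p in self.problems))


@dataclass(frozen=True)
class SpeciesSpec:
    """One chemical species (or the membrane potential) in the registry."""

    name: str
    compartment: str
    unit: str
    initial: float
    kind: str  # "ode" | "assignment" | "constant"


@dataclass(frozen=True)
class CompartmentTable:
    """Relative compartment volumes in liters (cytosol defined as 1 l)."""

    volumes: dict

    def __post_init__(self):
        problems = []
        if tuple(sorted(self.volumes)) != tuple(sorted(COMPARTMENT_NAMES)):
            problems.append(f"compartments must be exactly {COMPARTMENT_NAMES}, got {tuple(self.volumes)}")
        for name, v in self.volumes.items():
            if not (isinstance(v, (int, float)) and v > 0):
                problems.append(f"compartment {name!r} volume must be positive, got {v!r}")
        if problems:
            raise ModelValidationError(problems)

    def __getitem__(self, name):
        return self.volumes[name]

    @property
    def total(self):
        return sum(self.volumes.values())


@dataclass(frozen=True)
class ParameterOverride:
    """A single replacement of a kinetic parameter or an initial value.

    ``path`` is dotted: ``"c1.X"`` addresses a kinetic constant,
    ``"species.O2_v.initial"`` an initial value.  With ``multiplicative=True``
    the stored value scales the base value instead of replacing it.
    """

    path: str
    value: float
    multiplicative: bool = False


def _ns(d):
    """Recursively convert nested dicts to attribute namespaces."""
    if isinstance(d, dict):
        return SimpleNamespace(**{k: _ns(v) for k, v in d.items()})
    return d


@dataclass
class Model:
    """Compartments + species registry + kinetic parameters."""

    compartments: CompartmentTable
    species: list = field(default_factory=list)
    params: dict = field(default_factory=dict)
    physical: dict = field(default_factory=dict)
    structural: dict = field(default_factory=dict)

    # -- lookups ---------------------------------------------------------
    def species_by_name(self, name: str) -> SpeciesSpec:
        try:
            return self._index[name]
        except AttributeError:
            self._index = {s.name: s for s in self.species}
            return self._index[name]

    @property
    def species_names(self):
        return [s.name for s in self.species]

    def names_of_kind(self, kind: str):
        return [s.name for s in self.species if s.kind == kind]

    def initial(self, name: str) -> float:
        return self.species_by_name(name).initial

    # -- mutation (always copy-on-write) ---------------------------------
    def copy(self) -> "Model":
        return Model(
            compartments=CompartmentTable(dict(self.compartments.volumes)),
            species=list(self.species),
            params=_copy.deepcopy(self.params),
            physical=dict(self.physical),
            structural=dict(self.structural),
        )

    def _set_species_initial(self, name: str, value: float):
        idx = next((i for i, s in enumerate(self.species) if s.name == name), None)
        if idx is None:
            raise KeyError(f"override path does not resolve: unknown species {name!r}")
        s = self.species[idx]
        self.species[idx] = SpeciesSpec(s.name, s.compartment, s.unit, float(value), s.kind)
        self.__dict__.pop("_index", None)

    def get_param(self, path: str) -> float:
        node = {"physical": self.physical, "structural": self.structural, **self.params}
        for part in path.split("."):
            try:
                node = node[part]
            except (KeyError, TypeError):
                raise KeyError(f"override path does not resolve: {path!r}")
        if isinstance(node, dict):
            raise KeyError(f"override path does not resolve to a leaf value: {path!r}")
        return node

    def _set_param(self, path: str, value: float):
        parts = path.split(".")
        root = {"physical": self.physical, "structural": self.structural}.get(parts[0], None)
        node = root if root is not None else self.params
        walk = parts[1:] if root is not None else parts
        for part in walk[:-1]:
            try:
                node = node[part]
            except (KeyError, TypeError):
                raise KeyError(f"override path does not resolve: {path!r}")
        if not isinstance(node, dict) or walk[-1] not in node:
            raise KeyError(f"override path does not resolve: {path!r}")
        node[walk[-1]] = float(value)

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "version": 1,
            "compartments": dict(self.compartments.volumes),
            "physical": dict(self.physical),
            "structural": dict(self.structural),
            "species": [
                {"name": s.name, "compartment": s.compartment, "kind": s.kind,
                 "unit": s.unit, "initial": s.initial}
                for s in self.species
            ],
            "parameters": _copy.deepcopy(self.params),
        }

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True, default_flow_style=False)

    @classmethod
    def from_dict(cls, doc: dict) -> "Model":
        problems = _validate_document(doc)
        if problems:
            raise ModelValidationError(problems)
        species = [
            SpeciesSpec(d["name"], d["compartment"], d["unit"], float(d["initial"]), d["kind"])
            for d in doc["species"]
        ]
        return cls(
            compartments=CompartmentTable({k: float(v) for k, v in doc["compartments"].items()}),
            species=species,
            params=_copy.deepcopy(doc["parameters"]),
            physical={k: float(v) for k, v in doc["physical"].items()},
            structural={k: float(v) for k, v in doc["structural"].items()},
        )

    @classmethod
    def from_yaml(cls, text: str) -> "Model":
        return cls.from_dict(yaml.safe_load(text))

    def __eq__(self, other):
        return isinstance(other, Model) and self.to_dict() == other.to_dict()

    # -- runtime compilation --------------------------------------------
    def compiled(self) -> SimpleNamespace:
        """Flatten the model into an attribute namespace for the rate kernel.

        Precomputes RT (kJ/mol), F/RT (1/mV) and the phosphate-speciation acid
        constant so the rate laws stay free of unit conversions.
        """
        p = _ns(self.params)
        phys = SimpleNamespace(**self.physical)
        phys.RT = phys.R * phys.T
        phys.F_over_RT = phys.F / phys.RT
        struct = SimpleNamespace(**self.structural)
        struct.Ka_Pi = 10.0 ** (-struct.pKa_Pi) * 1000.0  # mM
        const = SimpleNamespace(
            **{s.name: s.initial for s in self.species if s.kind == "constant"}
        )
        vol = SimpleNamespace(**self.compartments.volumes)
        p.phys, p.struct, p.const, p.vol = phys, struct, const, vol
        return p


def _validate_document(doc) -> list:
    problems = []
    if not isinstance(doc, dict):
        return ["document root must be a mapping"]
    for key in ("compartments", "species", "parameters", "physical", "structural"):
        if key not in doc:
            problems.append(f"missing top-level section {key!r}")
    if problems:
        return problems
    comp = doc["compartments"]
    if sorted(comp) != sorted(COMPARTMENT_NAMES):
        problems.append(f"compartments must be exactly {COMPARTMENT_NAMES}")
    else:
        for k, v in comp.items():
            if not isinstance(v, (int, float)) or v <= 0:
                problems.append(f"compartment {k!r} volume must be a positive number")
    seen = set()
    for i, d in enumerate(doc["species"]):
        name = d.get("name", f"<species #{i}>")
        if name in seen:
            problems.append(f"duplicate species {name!r}")
        seen.add(name)
        if d.get("kind") not in SPECIES_KINDS:
            problems.append(f"species {name!r}: kind must be one of {SPECIES_KINDS}")
        if d.get("compartment") not in COMPARTMENT_NAMES:
            problems.append(f"species {name!r}: unknown compartment {d.get('compartment')!r}")
        if not isinstance(d.get("initial"), (int, float)):
            problems.append(f"species {name!r}: initial value must be numeric")
        elif d.get("unit") != "mV" and d["initial"] < 0:
            problems.append(f"species {name!r}: concentration must be >= 0")
    def _leaves(node, prefix):
        if isinstance(node, dict):
            for k, v in node.items():
                yield from _leaves(v, f"{prefix}.{k}" if prefix else k)
        else:
            yield prefix, node
    for section in ("parameters", "physical", "structural"):
        for path, leaf in _leaves(doc[section], section):
            if not isinstance(leaf, (int, float)):
                problems.append(f"{path}: parameter must be numeric, got {leaf!r}")
    return problems


def default_model() -> Model:
    """Load the complete printed model (volumes, initial values, constants)."""
    text = (
        importlib.resources.files("cardiomyosim") / "data" / "model.yaml"
    ).read_text(encoding="utf-8")
    return Model.from_yaml(text)


def apply_overrides(base: Model, overrides) -> Model:
    """Return a new model with ``overrides`` applied; ``base`` is unchanged.

    Raises ``KeyError`` naming the offending path if it does not resolve.
    """
    model = base.copy()
    for ov in overrides:
        if ov.path.startswith("species."):
            parts = ov.path.split(".")
            if len(parts) != 3 or parts[2] != "initial":
                raise KeyError(f"override path does not resolve: {ov.path!r}")
            name = parts[1]
            old = model.species_by_name(name).initial if any(
                s.name == name for s in model.species
            ) else None
            if old is None:
                raise KeyError(f"override path does not resolve: unknown species {name!r}")
            model._set_species_initial(name, old * ov.value if ov.multiplicative else ov.value)
        else:
            old = model.get_param(ov.path)
            model._set_param(ov.path, old * ov.value if ov.multiplicative else ov.value)
    return model


#: Named override presets.  "f1_table_mg_constants" switches the Mg-nucleotide
#: dissociation constants to the alternative pair printed with the ATP-synthase
#: equation (values there are in M; converted to this model's mM convention).
PRESETS = {
    "f1_table_mg_constants": [
        ParameterOverride("mg_binding.K_MgADP", 0.347),
        ParameterOverride("mg_binding.K_MgATP", 0.0245),
    ],
}
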