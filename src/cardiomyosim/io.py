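"""Run configuration, CSV/JSON writers and structural SBML export."""

from __future__ import annotations

import dataclasses
import json
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import odes, protocols, rates
from .model import Model, ParameterOverride

__all__ = ["RunConfig", "ConfigError", "load_config", "build_protocol",
           "write_timeseries", "read_timeseries", "write_report", "export_sbml"]

_FLOAT_FMT = "%.12g"  # 12 significant digits everywhere we serialize numbers


class ConfigError(ValueError):
    """Invalid run configuration; message lists every offending field."""

    def __init__(self, problems):
        self.problems = list(problems)
        super().__init__("invalid run configuration:\n"
                         + "\n".join(f"  - {p}" for p in self.problems))


@dataclass(frozen=True)
class RunConfig:
    """Validated description of one simulation run (the model is
    deterministic, so there is nothing stochastic to seed)."""

    overrides: tuple = ()
    protocol: dict = field(default_factory=lambda: {"type": "constant"})
    solver: dict = field(default_factory=dict)
    outputs: tuple = ("trajectory",)

    def solver_settings(self) -> protocols.SolverSettings:
        return protocols.SolverSettings(**self.solver)


_PROTOCOL_KEYS = {
    "constant": {"fraction", "t_end"},
    "standard": {"ischemic_fraction", "t_isch_start", "t_rep", "t_end"},
    "two-step": {"ischemic_fraction", "step1_fraction", "t_isch", "t_step1",
                 "t_step2", "t_end"},
}
_OUTPUTS = {"trajectory", "fluxes", "metrics", "sensitivity"}


def load_config(source) -> RunConfig:
    """Load and validate a YAML run configuration (path or mapping)."""
    if isinstance(source, dict):
        doc = source
    else:
        with open(source, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
    problems = []
    if not isinstance(doc, dict):
        raise ConfigError(["configuration root must be a mapping"])
    unknown = set(doc) - {"overrides", "protocol", "solver", "outputs"}
    problems += [f"unknown section {k!r}" for k in sorted(unknown)]

    overrides = []
    for i, ov in enumerate(doc.get("overrides", []) or []):
        if not isinstance(ov, dict) or "path" not in ov or "value" not in ov:
            problems.append(f"overrides[{i}]: needs 'path' and 'value'")
            continue
        overrides.append(ParameterOverride(str(ov["path"]), float(ov["value"]),
                                           bool(ov.get("multiplicative", False))))

    proto = dict(doc.get("protocol", {}) or {})
    kind = proto.pop("type", "constant")
    if kind not in _PROTOCOL_KEYS:
        problems.append(f"protocol.type must be one of {sorted(_PROTOCOL_KEYS)}, got {kind!r}")
    else:
        bad = set(proto) - _PROTOCOL_KEYS[kind]
        problems += [f"protocol.{k}: unknown key for type {kind!r}" for k in sorted(bad)]

    solver = dict(doc.get("solver", {}) or {})
    valid_solver = {f.name for f in dataclasses.fields(protocols.SolverSettings)}
    problems += [f"solver.{k}: unknown setting" for k in sorted(set(solver) - valid_solver)]

    outputs = tuple(doc.get("outputs", ["trajectory"]) or ())
    problems += [f"outputs: unknown output {o!r}" for o in outputs if o not in _OUTPUTS]

    if problems:
        raise ConfigError(problems)
    return RunConfig(overrides=tuple(overrides),
                     protocol={"type": kind, **proto},
                     solver=solver, outputs=outputs)


def build_protocol(config: RunConfig) -> protocols.OxygenProtocol:
    spec = dict(config.protocol)
    kind = spec.pop("type")
    if kind == "constant":
        return protocols.constant_protocol(**spec)
    if kind == "standard":
        return protocols.standard_protocol(**spec)
    return protocols.two_step_protocol(**spec)


# --------------------------------------------------------------------------
# trajectory / report writers
# --------------------------------------------------------------------------

def _unit_of(name, model=None):
    if name == "time":
        return "s"
    if name.startswith("J_"):
        return "mM/s"
    return "mV" if name == "DPSI" else "mM"


def write_timeseries(result, path, include_fluxes=True):
    """CSV trajectory: deterministic column order, unit-annotated header,
    12 significant digits."""
    names = ["time"] + list(odes.ODE_ORDER)
    cols = [result.time] + [result.states[:, i] for i in range(odes.N_ODE)]
    if include_fluxes:
        names += list(rates.FLUX_NAMES)
        cols += [result.fluxes[:, j] for j in range(len(rates.FLUX_NAMES))]
    header = ",".join(f"{n} [{_unit_of(n)}]" for n in names)
    data = np.column_stack(cols)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(header + "\n")
        for row in data:
            fh.write(",".join(_FLOAT_FMT % v for v in row) + "\n")


def read_timeseries(path):
    """Read a trajectory CSV back into a pandas DataFrame (units stripped)."""
    import pandas as pd

    frame = pd.read_csv(path)
    frame.columns = [c.split(" [")[0] for c in frame.columns]
    return frame


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_report(report, path):
    """JSON report for metrics (IRMetrics) or sensitivity results."""
    if hasattr(report, "to_dict"):
        doc = report.to_dict()
    elif hasattr(report, "to_frame"):
        doc = report.to_frame().to_dict(orient="records")
    else:
        doc = report
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(_jsonable(doc), fh, indent=2, sort_keys=True)
        fh.write("\n")


# --------------------------------------------------------------------------
# SBML export (structural)
# --------------------------------------------------------------------------

_SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"


def export_sbml(model: Model) -> str:
    """Structural SBML Level 3 document: compartments, species (with
    constant/boundary flags), global parameters, and the membrane potential
    as a parameter governed by a rate rule.

    The kinetic laws live in :mod:`cardiomyosim.rates`; they are not encoded
    as MathML, so the document describes the model's composition, initial
    state and parameterization for interchange, not an executable copy.
    """
    ET.register_namespace("", _SBML_NS)
    root = ET.Element(f"{{{_SBML_NS}}}sbml", {"level": "3", "version": "2"})
    mdl = ET.SubElement(root, f"{{{_SBML_NS}}}model",
                        {"id": "cardiomyocyte_energy_metabolism",
                         "substanceUnits": "millimole", "timeUnits": "second"})

    lc = ET.SubElement(mdl, f"{{{_SBML_NS}}}listOfCompartments")
    for name, vol in sorted(model.compartments.volumes.items()):
        ET.SubElement(lc, f"{{{_SBML_NS}}}compartment",
                      {"id": name, "size": _FLOAT_FMT % vol,
                       "spatialDimensions": "3", "constant": "true"})

    ls = ET.SubElement(mdl, f"{{{_SBML_NS}}}listOfSpecies")
    for s in model.species:
        if s.name == "DPSI":
            continue  # the membrane potential is not a concentration
        ET.SubElement(ls, f"{{{_SBML_NS}}}species", {
            "id": s.name, "compartment": s.compartment,
            "initialConcentration": _FLOAT_FMT % s.initial,
            "hasOnlySubstanceUnits": "false",
            "boundaryCondition": "true" if s.kind != "ode" else "false",
            "constant": "true" if s.kind == "constant" else "false",
        })

    lp = ET.SubElement(mdl, f"{{{_SBML_NS}}}listOfParameters")
    dpsi = model.species_by_name("DPSI")
    ET.SubElement(lp, f"{{{_SBML_NS}}}parameter",
                  {"id": "DPSI", "value": _FLOAT_FMT % dpsi.initial,
                   "constant": "false", "units": "dimensionless"})

    def emit(prefix, node):
        for key in sorted(node):
            value = node[key]
            if isinstance(value, dict):
                emit(f"{prefix}{key}_", value)
            else:
                ET.SubElement(lp, f"{{{_SBML_NS}}}parameter",
                              {"id": f"{prefix}{key}", "value": _FLOAT_FMT % value,
                               "constant": "true"})
    emit("", model.params)
    emit("phys_", model.physical)
    emit("struct_", model.structural)

    lr = ET.SubElement(mdl, f"{{{_SBML_NS}}}listOfRules")
    ET.SubElement(lr, f"{{{_SBML_NS}}}rateRule", {"variable": "DPSI"})

    ET.indent(root)
    return ET.tostring(root, encoding="unicode", xml_declaration=True)
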