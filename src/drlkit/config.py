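"""YAML experiment configuration for the command-line workflow.

Schema (all concentrations in mol/L; equivalents allowed with host_total):

    composition:
      host_total: 1.0e-5
      equivalents_unlabelled: 100        # or ligand_unlabelled: 1.0e-3
      equivalents_labelled: 100          # or ligand_labelled: 1.0e-3
      t_L: 0.0
      temperature: {value: 24, unit: C}  # C or K
    species:
      - {name: "M(Py)",  mz: 1480.4, group: host1, role: unlabelled, formula: ...}
      - {name: "M(PyL)", mz: 1485.4, group: host1, role: labelled}
    fit: {float_t_L: false, float_f_eq: false, weighting: none, quantitation_limit: 0.5}
    truth: {k_on: 5.0e4, k_off: 5.4e-4}  # simulate command only
    noise: {spray_drift_sd: 0.1, additive_sd: 0.0, shot_scale: 0.0}
    grid:  {dt: 1.0, duration: 9000.0}

Groups partition the species; each group carries exactly one unlabelled and
one labelled partner. Validation failures raise ValidationError (CLI exit 2).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import yaml

from .constants import KELVIN_OFFSET
from .exceptions import ValidationError
from .fitting import FitOptions
from .kinetics import RateConstants, SolutionComposition, TwoSiteRateConstants
from .synthetic import NoiseModel, SpeciesSpec

__all__ = ["ExperimentConfig", "SpeciesEntry", "load_config"]


@dataclass(frozen=True)
class SpeciesEntry:
    name: str
    mz: float
    group: str
    role: str  # "unlabelled" | "labelled"
    formula: str | None = None
    host: str | None = None


@dataclass
class ExperimentConfig:
    composition: SolutionComposition
    species: list[SpeciesEntry]
    fit: FitOptions
    truth: RateConstants | TwoSiteRateConstants | None = None
    noise: NoiseModel = field(default_factory=NoiseModel.quiet)
    dt: float = 1.0
    duration: float | None = None
    raw: dict = field(default_factory=dict)

    @property
    def groups(self) -> dict[str, dict[str, str]]:
        """group -> {'unlabelled': name, 'labelled': name}."""
        out: dict[str, dict[str, str]] = {}
        for sp in self.species:
            out.setdefault(sp.group, {})[sp.role] = sp.name
        return out

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.raw, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def _temperature_kelvin(node) -> float:
    if node is None:
        return 298.15
    if isinstance(node, (int, float)):
        return float(node)  # bare numbers are kelvin
    unit = str(node.get("unit", "K")).upper()
    value = float(node["value"])
    if unit == "K":
        return value
    if unit == "C":
        return value + KELVIN_OFFSET
    raise ValidationError(f"temperature unit must be C or K, got {unit!r}")


def _composition(node: dict) -> SolutionComposition:
    if "host_total" not in node:
        raise ValidationError("composition.host_total is required")
    host = float(node["host_total"])

    def pool(key: str) -> float:
        if f"ligand_{key}" in node:
            return float(node[f"ligand_{key}"])
        if f"equivalents_{key}" in node:
            return float(node[f"equivalents_{key}"]) * host
        raise ValidationError(
            f"composition needs ligand_{key} (mol/L) or equivalents_{key}"
        )

    return SolutionComposition(
        host_total=host,
        ligand_unlabelled=pool("unlabelled"),
        ligand_labelled=pool("labelled"),
        t_L=float(node.get("t_L", 0.0)),
        t_u=float(node["t_u"]) if "t_u" in node else None,
        temperature=_temperature_kelvin(node.get("temperature")),
    )


def _truth(node: dict | None):
    if node is None:
        return None
    if "inner" in node or "outer" in node:
        try:
            return TwoSiteRateConstants(
                inner=RateConstants(**node["inner"]),
                outer=RateConstants(**node["outer"]),
            )
        except (KeyError, TypeError) as exc:
            raise ValidationError(f"invalid two-site truth block: {exc}")
    try:
        return RateConstants(k_on=float(node["k_on"]), k_off=float(node["k_off"]))
    except KeyError as exc:
        raise ValidationError(f"truth block missing field {exc}")


def _species(nodes) -> list[SpeciesEntry]:
    if not nodes:
        raise ValidationError("species table is required and must be non-empty")
    entries = []
    for i, node in enumerate(nodes):
        for req in ("name", "mz", "group", "role"):
            if req not in node:
                raise ValidationError(f"species[{i}] missing required field {req!r}")
        role = str(node["role"])
        if role not in ("unlabelled", "labelled"):
            raise ValidationError(
                f"species[{i}].role must be 'unlabelled' or 'labelled', got {role!r}"
            )
        entries.append(
            SpeciesEntry(
                name=str(node["name"]),
                mz=float(node["mz"]),
                group=str(node["group"]),
                role=role,
                formula=node.get("formula"),
                host=node.get("host"),
            )
        )
    names = [e.name for e in entries]
    if len(set(names)) != len(names):
        raise ValidationError("species names must be unique")
    by_group: dict[str, list[SpeciesEntry]] = {}
    for e in entries:
        by_group.setdefault(e.group, []).append(e)
    for g, members in by_group.items():
        roles = sorted(m.role for m in members)
        if roles != ["labelled", "unlabelled"]:
            raise ValidationError(
                f"group {g!r} must contain exactly one unlabelled and one labelled species"
            )
    return entries


def load_config(path) -> ExperimentConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValidationError("config must be a YAML mapping")
    if "composition" not in raw:
        raise ValidationError("config.composition is required")
    fit_node = raw.get("fit", {}) or {}
    try:
        fit = FitOptions(
            float_t_L=bool(fit_node.get("float_t_L", False)),
            float_f_eq=bool(fit_node.get("float_f_eq", False)),
            weighting=str(fit_node.get("weighting", "none")),
            quantitation_limit=float(fit_node.get("quantitation_limit", 0.5)),
        )
    except TypeError as exc:
        raise ValidationError(f"invalid fit options: {exc}")
    noise_node = raw.get("noise")
    if noise_node:
        noise = NoiseModel(
            spray_drift_sd=float(noise_node.get("spray_drift_sd", 0.0)),
            additive_sd=float(noise_node.get("additive_sd", 0.0)),
            shot_scale=float(noise_node.get("shot_scale", 0.0)),
            seed=int(noise_node.get("seed", 0)),
        )
    else:
        noise = NoiseModel.quiet()
    grid = raw.get("grid", {}) or {}
    return ExperimentConfig(
        composition=_composition(raw["composition"]),
        species=_species(raw.get("species")),
        fit=fit,
        truth=_truth(raw.get("truth")),
        noise=noise,
        dt=float(grid.get("dt", 1.0)),
        duration=float(grid["duration"]) if "duration" in grid else None,
        raw=raw,
    )


def species_specs(config: ExperimentConfig) -> dict[str, SpeciesSpec]:
    """Observable-class -> SpeciesSpec mapping for the simulate command.

    Single-group configs map (unlabelled, labelled) onto the single-site
    observable classes.
    """
    groups = config.groups
    if len(groups) != 1:
        raise ValidationError("simulate expects exactly one species group")
    (pair,) = groups.values()
    by_name = {e.name: e for e in config.species}
    return {
        "bound_unlabelled": _to_spec(by_name[pair["unlabelled"]]),
        "bound_labelled": _to_spec(by_name[pair["labelled"]]),
    }


def _to_spec(entry: SpeciesEntry) -> SpeciesSpec:
    return SpeciesSpec(name=entry.name, mz=entry.mz, formula=entry.formula)
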