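"""Structured run configuration: the reproducibility shell.

One YAML file describes a run: the region (bounds, voxel size, volume
fraction and tortuosity fields), the species (diffusion coefficient, charge,
initial condition, boundary condition), the reactions, the solver settings,
an optional spreading-depression scenario block, and the output settings.
Keyword names mirror the modeling interface (``dx``, ``volume_fraction``,
``tortuosity``, ``d``, ``charge``, ``initial``,
``ecs_boundary_conditions``).  Loading validates every cross-reference and
fills defaults; a loaded configuration serializes back to an identical
document, and the resolved form is logged with every run so any run can be
reproduced from its log alone.

Units are fixed globally: um, ms, mM, mV, mA/cm^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .grid import build_grid, edema_alpha, edema_tortuosity
from .kinetics import RateTerm, Reaction, Species, parse_rate_expression
from .neurons import MembraneParameters
from .sd import SDScenario
from .solver import Simulation

__all__ = ["RunConfig", "load_config", "loads_config", "build_simulation"]

_REGION_KEYS = {"xlo", "ylo", "zlo", "xhi", "yhi", "zhi", "dx",
                "volume_fraction", "tortuosity"}
_SPECIES_KEYS = {"name", "d", "charge", "initial", "ecs_boundary_conditions"}
_REACTION_KEYS = {"lhs", "rhs", "kf", "kb", "mass_action"}
_RATE_KEYS = {"species", "expr"}
_SOLVER_KEYS = {"dt", "t_stop", "splitting", "snapshot_every", "audit"}
_SCENARIO_KEYS = {
    "density", "bolus_radius", "bolus_concentration", "bolus_center",
    "amax", "edema", "edema_alpha0", "edema_tort0", "edema_r0",
    "membrane", "closed_books", "record_every", "front_threshold",
}
_OUTPUT_KEYS = {"directory", "formats", "species"}

_SOLVER_DEFAULTS = {"dt": 0.1, "t_stop": 100.0, "splitting": "lie",
                    "snapshot_every": None, "audit": False}
_OUTPUT_DEFAULTS = {"directory": "out", "formats": ["nrrd"], "species": None}


def _check_keys(block: dict, allowed: set, where: str):
    unknown = set(block) - allowed
    if unknown:
        raise ValueError(f"unknown key(s) {sorted(unknown)} in {where}")


def _field_spec(value, where: str):
    """Interpret a config field value: number, nested list (array), a
    {function: name, ...} mapping over the named built-ins, or a
    {file: path} array reference."""
    if isinstance(value, (int, float)):
        return float(value)
    if isinstance(value, list):
        return np.asarray(value, dtype=float)
    if isinstance(value, str):
        return float(value)
    if isinstance(value, dict):
        if "file" in value:
            path = value["file"]
            return np.loadtxt(path) if str(path).endswith(".txt") else np.load(path)
        name = value.get("function")
        kw = {k: v for k, v in value.items() if k != "function"}
        builtins = {"edema_alpha": edema_alpha, "edema_tortuosity": edema_tortuosity,
                    "sphere": _sphere_field}
        if name not in builtins:
            raise ValueError(
                f"{where}: unknown field function {name!r}; "
                f"available: {sorted(builtins)}"
            )
        if "center" in kw:
            kw["center"] = tuple(kw["center"])
        return builtins[name](**kw)
    raise ValueError(f"{where}: cannot interpret field specification {value!r}")


def _sphere_field(inside, outside, radius, center=(0.0, 0.0, 0.0)):
    cx, cy, cz = center
    r2 = float(radius) ** 2

    def f(x, y, z):
        d2 = (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2
        return np.where(d2 < r2, inside, outside)

    return f


@dataclass
class RunConfig:
    """A validated run description; ``raw`` round-trips to the source YAML
    with defaults made explicit."""

    region: dict
    species: list
    reactions: list = field(default_factory=list)
    rates: list = field(default_factory=list)
    solver: dict = field(default_factory=dict)
    scenario: dict | None = None
    output: dict = field(default_factory=dict)
    seed: int = 0

    def to_dict(self) -> dict:
        d = {
            "seed": self.seed,
            "region": self.region,
            "species": self.species,
            "reactions": self.reactions,
            "rates": self.rates,
            "solver": self.solver,
            "output": self.output,
        }
        if self.scenario is not None:
            d["scenario"] = self.scenario
        return d

    def dumps(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    def dump(self, path):
        Path(path).write_text(self.dumps())


def loads_config(text: str) -> RunConfig:
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise ValueError("configuration must be a mapping")
    _check_keys(doc, {"region", "species", "reactions", "rates", "solver",
                      "scenario", "output", "seed"}, "top level")
    region = doc.get("region")
    if region is None:
        raise ValueError("configuration requires a 'region' block")
    _check_keys(region, _REGION_KEYS, "region")
    for k in ("xlo", "ylo", "zlo", "xhi", "yhi", "zhi", "dx"):
        if k not in region:
            raise ValueError(f"region: missing required key {k!r}")
    region = {**{"volume_fraction": 1.0, "tortuosity": 1.0}, **region}

    species = doc.get("species") or []
    if not species:
        raise ValueError("configuration requires at least one species")
    names = []
    out_species = []
    for i, sp in enumerate(species):
        _check_keys(sp, _SPECIES_KEYS, f"species[{i}]")
        if "name" not in sp:
            raise ValueError(f"species[{i}]: missing 'name'")
        sp = {**{"d": 0.0, "charge": 0, "initial": 0.0,
                 "ecs_boundary_conditions": None}, **sp}
        names.append(sp["name"])
        out_species.append(sp)
    if len(set(names)) != len(names):
        raise ValueError("duplicate species names in configuration")

    out_reactions = []
    for i, rx in enumerate(doc.get("reactions") or []):
        _check_keys(rx, _REACTION_KEYS, f"reactions[{i}]")
        for side in ("lhs", "rhs"):
            if side not in rx:
                raise ValueError(f"reactions[{i}]: missing {side!r}")
        rx = {**{"kf": 0.0, "kb": 0.0, "mass_action": True}, **rx}
        # validation: stoichiometry and rate expressions must resolve
        r = Reaction(rx["lhs"], rx["rhs"], rx["kf"], rx["kb"], rx["mass_action"])
        for nm in {**r.lhs, **r.rhs}:
            if nm not in names:
                raise ValueError(
                    f"reactions[{i}]: undeclared species {nm!r} "
                    f"(declared: {names})"
                )
        parse_rate_expression(rx["kf"], names)
        parse_rate_expression(rx["kb"], names)
        out_reactions.append(rx)

    out_rates = []
    for i, rt in enumerate(doc.get("rates") or []):
        _check_keys(rt, _RATE_KEYS, f"rates[{i}]")
        if rt.get("species") not in names:
            raise ValueError(
                f"rates[{i}]: undeclared species {rt.get('species')!r}"
            )
        parse_rate_expression(rt["expr"], names)
        out_rates.append(dict(rt))

    solver = {**_SOLVER_DEFAULTS, **(doc.get("solver") or {})}
    _check_keys(solver, _SOLVER_KEYS, "solver")
    if solver["splitting"] not in ("lie", "strang"):
        raise ValueError("solver.splitting must be 'lie' or 'strang'")

    scenario = doc.get("scenario")
    if scenario is not None:
        _check_keys(scenario, _SCENARIO_KEYS, "scenario")
        scenario = dict(scenario)

    output = {**_OUTPUT_DEFAULTS, **(doc.get("output") or {})}
    _check_keys(output, _OUTPUT_KEYS, "output")

    return RunConfig(
        region=region,
        species=out_species,
        reactions=out_reactions,
        rates=out_rates,
        solver=solver,
        scenario=scenario,
        output=output,
        seed=int(doc.get("seed", 0)),
    )


def load_config(path) -> RunConfig:
    return loads_config(Path(path).read_text())


def build_simulation(cfg: RunConfig) -> Simulation:
    """Materialize the configured model (region + species + kinetics)."""
    r = cfg.region
    grid = build_grid(
        r["xlo"], r["ylo"], r["zlo"], r["xhi"], r["yhi"], r["zhi"],
        r["dx"],
        _field_spec(r["volume_fraction"], "region.volume_fraction"),
        _field_spec(r["tortuosity"], "region.tortuosity"),
    )
    species = []
    for sp in cfg.species:
        bc = sp["ecs_boundary_conditions"]
        species.append(
            Species(
                sp["name"],
                d=tuple(sp["d"]) if isinstance(sp["d"], list) else sp["d"],
                charge=sp["charge"],
                initial=_field_spec(sp["initial"], f"species {sp['name']}.initial"),
                boundary="neumann" if bc is None else bc,
            )
        )
    reactions = [
        Reaction(rx["lhs"], rx["rhs"], rx["kf"], rx["kb"], rx["mass_action"])
        for rx in cfg.reactions
    ]
    rates = [RateTerm(rt["species"], rt["expr"]) for rt in cfg.rates]
    return Simulation(
        grid, species, reactions=reactions, rate_terms=rates,
        dt=cfg.solver["dt"], splitting=cfg.solver["splitting"],
    )


def scenario_from_config(cfg: RunConfig) -> SDScenario:
    """Build a spreading-depression scenario from the scenario block,
    inheriting region/solver settings from the main configuration."""
    if cfg.scenario is None:
        raise ValueError("configuration has no 'scenario' block")
    r = cfg.region
    sc = cfg.scenario
    membrane = MembraneParameters(**sc["membrane"]) if "membrane" in sc \
        else MembraneParameters()
    kw = dict(
        bounds=(r["xlo"], r["ylo"], r["zlo"], r["xhi"], r["yhi"], r["zhi"]),
        dx=r["dx"],
        dt=cfg.solver["dt"],
        t_stop=cfg.solver["t_stop"],
        membrane=membrane,
        seed=cfg.seed,
    )
    if isinstance(r["volume_fraction"], (int, float)):
        kw["alpha"] = float(r["volume_fraction"])
    if isinstance(r["tortuosity"], (int, float)):
        kw["tortuosity"] = float(r["tortuosity"])
    mapping = {
        "density": "density_per_mm3",
        "bolus_radius": "bolus_radius",
        "bolus_concentration": "bolus_concentration",
        "bolus_center": "bolus_center",
        "amax": "amax",
        "edema": "edema",
        "edema_alpha0": "edema_alpha0",
        "edema_tort0": "edema_tort0",
        "edema_r0": "edema_r0",
        "closed_books": "closed_books",
        "record_every": "record_every",
        "front_threshold": "front_threshold",
    }
    for src, dst in mapping.items():
        if src in sc:
            val = sc[src]
            kw[dst] = tuple(val) if src == "bolus_center" and val else val
    return SDScenario(**kw)
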