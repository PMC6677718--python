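"""Structured run configuration: YAML/JSON parsing, validation, export.

Schema (unknown keys are rejected)::

    domain:    {L, K, h, hy, hz}
    species:   [{name, D}]
    reactions: [{name, stoich: {S: 1}, law: {type: zeroth|first|second,
                 rate, reactants?, profile?, spde_placement?}}]
    init:      {S: [K counts]}
    partition: {alpha, blocks: [[spde, 1, 10], [markov, 11, 20]],
                per_species?: {S2: [[markov, 1, 40]]}}
    scheme:    {name: scheme1|scheme2, dt, transfer_mode?, noise?,
                psi1?, psi2?, edge_guard?, redraw_after_spde?}
    adaptive:  {q_lower, q_upper, n_c, initial_interface?}     # optional
    run:       {t_end, n_realizations, seed, record_times}
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .adaptive import AdaptiveConfig
from .core import (Domain, Partition, ReactionSpec, ReactionDiffusionModel,
                   SpeciesSpec, build_model)
from .hybrid import SchemeConfig
from .spde import EMConfig


class ConfigError(ValueError):
    pass


@dataclass
class RunSpec:
    """A fully validated simulation request."""

    model: ReactionDiffusionModel
    partition: Partition
    scheme: SchemeConfig
    em: EMConfig
    adaptive: AdaptiveConfig | None
    t_end: float
    n_realizations: int
    seed: int
    record_times: list[float]
    raw: dict = field(repr=False, default_factory=dict)

    def manifest(self) -> dict:
        """Reproducibility metadata paired with every output file."""
        from . import __version__
        blob = json.dumps(self.raw, sort_keys=True).encode()
        return {
            "config_sha256": hashlib.sha256(blob).hexdigest(),
            "scheme": self.scheme.scheme,
            "transfer_mode": self.scheme.transfer_mode,
            "dt": self.em.dt,
            "t_end": self.t_end,
            "n_realizations": self.n_realizations,
            "seed": self.seed,
            "adaptive": self.adaptive is not None,
            "hybridrd_version": __version__,
        }


def _require(d: dict, keys: set[str], optional: set[str], where: str) -> None:
    missing = keys - set(d)
    if missing:
        raise ConfigError(f"{where}: missing required field(s) {sorted(missing)}")
    unknown = set(d) - keys - optional
    if unknown:
        raise ConfigError(f"{where}: unknown field(s) {sorted(unknown)}")


def _blocks(raw, where: str) -> tuple:
    out = []
    for b in raw:
        if len(b) != 3:
            raise ConfigError(f"{where}: each block is [kind, first, last]")
        out.append((str(b[0]), int(b[1]), int(b[2])))
    return tuple(out)


def parse_dict(cfg: dict) -> RunSpec:
    if not isinstance(cfg, dict):
        raise ConfigError("top level must be a mapping")
    _require(cfg, {"domain", "species", "init", "partition", "scheme", "run"},
             {"reactions", "adaptive"}, "config")

    d = cfg["domain"]
    _require(d, {"K", "h"}, {"L", "hy", "hz"}, "domain")
    K = int(d["K"])
    h = float(d["h"])
    domain = Domain(L=float(d.get("L", K * h)), K=K, h=h,
                    h_y=float(d.get("hy", 1.0)), h_z=float(d.get("hz", 1.0)))

    species = []
    for s in cfg["species"]:
        _require(s, {"name", "D"}, set(), "species")
        species.append(SpeciesSpec(str(s["name"]), float(s["D"])))

    reactions = []
    for r in cfg.get("reactions", []):
        _require(r, {"name", "stoich", "law"}, set(), f"reaction {r.get('name')}")
        law = r["law"]
        _require(law, {"type", "rate"},
                 {"reactants", "profile", "spde_placement"},
                 f"reaction {r['name']} law")
        typ = law["type"]
        stoich = {str(k): int(v) for k, v in r["stoich"].items()}
        rate = float(law["rate"])
        profile = law.get("profile")
        if typ == "zeroth":
            reactions.append(ReactionSpec.zeroth(
                r["name"], stoich, rate, profile=profile,
                spde_placement=law.get("spde_placement", "uniform")))
        elif typ == "first":
            reactions.append(ReactionSpec.first(
                r["name"], law["reactants"][0], stoich, rate, profile=profile))
        elif typ == "second":
            reactions.append(ReactionSpec.second(
                r["name"], law["reactants"], stoich, rate, profile=profile))
        else:
            raise ConfigError(f"reaction {r['name']}: unknown law type {typ!r}")

    init = {str(k): list(v) for k, v in cfg["init"].items()}
    model = build_model(domain, species, reactions, init)

    p = cfg["partition"]
    _require(p, {"alpha", "blocks"}, {"per_species"}, "partition")
    per_species = {str(k): _blocks(v, f"partition.per_species.{k}")
                   for k, v in p.get("per_species", {}).items()}
    partition = Partition(blocks=_blocks(p["blocks"], "partition.blocks"),
                          alpha=int(p["alpha"]), per_species=per_species)
    for name in model.species_names:   # blocks must tile the domain
        partition.region_array(K, name)
    if abs(partition.dx(h) * partition.alpha - h) > 1e-12 * h:
        raise ConfigError("partition: alpha inconsistent with h (dx = h/alpha)")

    s = cfg["scheme"]
    _require(s, {"name", "dt"},
             {"transfer_mode", "noise", "psi1", "psi2", "edge_guard",
              "redraw_after_spde"},
             "scheme")
    scheme = SchemeConfig(scheme=str(s["name"]),
                          transfer_mode=str(s.get("transfer_mode", "point")),
                          psi1=s.get("psi1"), psi2=s.get("psi2"),
                          edge_guard=float(s.get("edge_guard", 0.0)),
                          redraw_after_spde=bool(s.get("redraw_after_spde", True)))
    em = EMConfig(dt=float(s["dt"]), noise_on=bool(s.get("noise", True)))

    adaptive = None
    if "adaptive" in cfg:
        a = cfg["adaptive"]
        _require(a, {"q_lower", "q_upper", "n_c"}, {"initial_interface"}, "adaptive")
        adaptive = AdaptiveConfig(q_lower=float(a["q_lower"]),
                                  q_upper=float(a["q_upper"]),
                                  n_c=int(a["n_c"]),
                                  initial_interface=float(
                                      a.get("initial_interface", 0.0)))

    r = cfg["run"]
    _require(r, {"t_end"}, {"n_realizations", "seed", "record_times"}, "run")
    t_end = float(r["t_end"])
    record = [float(x) for x in r.get("record_times", [t_end])]

    return RunSpec(model=model, partition=partition, scheme=scheme, em=em,
                   adaptive=adaptive, t_end=t_end,
                   n_realizations=int(r.get("n_realizations", 100)),
                   seed=int(r.get("seed", 0)), record_times=record, raw=cfg)


def parse_config(path: str | Path) -> RunSpec:
    """Load and validate a YAML (or JSON) run configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return parse_dict(cfg)


def export_dict(spec: RunSpec) -> dict:
    """Serialize a RunSpec back to the schema (lossless round trip)."""
    model, partition = spec.model, spec.partition
    dom = model.domain
    reactions = []
    for r in model.reactions:
        law = {"type": {0: "zeroth", 1: "first", 2: "second"}[r.order],
               "rate": r.rate}
        if r.reactants:
            law["reactants"] = list(r.reactants)
        if r.profile is not None:
            law["profile"] = [float(x) for x in r.profile]
        if r.order == 0 and r.spde_placement != "uniform":
            law["spde_placement"] = r.spde_placement
        reactions.append({"name": r.name, "stoich": dict(r.stoich), "law": law})
    out = {
        "domain": {"L": dom.L, "K": dom.K, "h": dom.h,
                   "hy": dom.h_y, "hz": dom.h_z},
        "species": [{"name": s.name, "D": s.D} for s in model.species],
        "reactions": reactions,
        "init": {n: [int(v) for v in model.init[i]]
                 for i, n in enumerate(model.species_names)},
        "partition": {"alpha": partition.alpha,
                      "blocks": [list(b) for b in partition.blocks]},
        "scheme": {"name": spec.scheme.scheme, "dt": spec.em.dt,
                   "transfer_mode": spec.scheme.transfer_mode,
                   "noise": spec.em.noise_on,
                   **({} if spec.scheme.edge_guard == 0.0
                      else {"edge_guard": spec.scheme.edge_guard}),
                   **({} if spec.scheme.redraw_after_spde
                      else {"redraw_after_spde": False})},
        "run": {"t_end": spec.t_end, "n_realizations": spec.n_realizations,
                "seed": spec.seed, "record_times": list(spec.record_times)},
    }
    if partition.per_species:
        out["partition"]["per_species"] = {
            k: [list(b) for b in v] for k, v in partition.per_species.items()}
    if spec.adaptive is not None:
        out["adaptive"] = {"q_lower": spec.adaptive.q_lower,
                           "q_upper": spec.adaptive.q_upper,
                           "n_c": spec.adaptive.n_c,
                           "initial_interface": spec.adaptive.initial_interface}
    return out


def export_config(spec: RunSpec, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(export_dict(spec), fh, sort_keys=False)


def fixture_spec(name: str, **kwargs) -> RunSpec:
    """A packaged model as a RunSpec with its published defaults."""
    from .models import morphogen_model, pom1p_model, two_compartment_model
    if name == "morphogen":
        model, partition = morphogen_model(**kwargs)
        em = EMConfig(dt=5e-4)
        t_end, rec = 50.0, [0.0, 2.0, 5.0, 20.0, 50.0]
    elif name == "two_compartment":
        model, partition = two_compartment_model(**kwargs)
        em = EMConfig(dt=5e-4)
        t_end, rec = 50.0, [50.0]
    elif name == "pom1p":
        model, partition = pom1p_model(**kwargs)
        em = EMConfig(dt=5e-4)
        t_end, rec = 50.0, [50.0]
    else:
        raise ConfigError(f"unknown fixture {name!r}; "
                          "choose from morphogen, two_compartment, pom1p")
    spec = RunSpec(model=model, partition=partition, scheme=SchemeConfig(),
                   em=em, adaptive=None, t_end=t_end, n_realizations=100,
                   seed=0, record_times=rec)
    spec.raw = export_dict(spec)
    return spec
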