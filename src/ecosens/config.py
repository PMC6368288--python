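"""Food-web configuration: domain types, validation, YAML round-trip.

The configuration fully specifies a desk-scale, single-box food web:
components (biomass pools and age-structured vertebrates), per-component
process parameters, the diet/availability matrix with refuge factors, the
initial state, an annually looped primary-producer forcing cycle, and the
simulation settings.  The internal currency is mg N throughout.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import yaml

__all__ = [
    "ConfigError",
    "Component",
    "ProcessParams",
    "DietMatrix",
    "RefugeFactors",
    "InitialState",
    "Forcing",
    "Settings",
    "FoodWebConfig",
    "load_config",
    "save_config",
]

KINDS = ("vertebrate", "biomass_pool", "producer", "detritus")
GUILDS = (
    "phytoplankton",
    "zooplankton",
    "pelagic_fish",
    "demersal_fish",
    "top_predator",
    "detritus",
)
RECRUITMENT_MODES = ("beverton_holt", "constant_per_adult", "none")


class ConfigError(ValueError):
    """Raised when a configuration violates an invariant; names the offending key."""


@dataclass
class Component:
    id: str
    name: str
    kind: str  # vertebrate | biomass_pool | producer | detritus
    guild: str
    n_age_classes: int = 1
    is_key_species: bool = False
    recruitment_mode: str = "none"
    recruitment_lognormal_sigma: float = 0.0


@dataclass
class ProcessParams:
    """Per-component process rates.

    ``mum`` is the maximum growth: mass gain (mg N ind^-1 day^-1) per age
    class for vertebrates, a specific rate (day^-1) for pools.  ``C`` is the
    consumption (clearance) rate, ``E`` the assimilation efficiency.  ``mL``
    is linear mortality (day^-1); quadratic mortality uses ``mQ_juvenile``
    for age classes below ``maturity_age`` and ``mQ_adult`` otherwise (pools
    carry a single coefficient in both slots, applied to biomass).
    Starvation mortality ``mSt_rate`` switches on when the reserve:structural
    weight ratio drops below ``mSt_threshold``.
    """

    mum: np.ndarray = field(default_factory=lambda: np.zeros(1))
    C: np.ndarray = field(default_factory=lambda: np.zeros(1))
    E: float = 0.0
    mL: float = 0.0
    mQ_juvenile: float = 0.0
    mQ_adult: float = 0.0
    mSt_threshold: float = 0.0
    mSt_rate: float = 0.0
    maintenance_rate: float = 0.0  # day^-1 fraction of body mass (vertebrates)
    growth_split_structural: float = 0.5
    maturity_age: int = 1  # 1-based first reproducing age class
    spawn_fraction: float = 0.0  # fraction of reserve weight shed at spawning
    spawn_skip_ratio: float = 0.0  # reserve:structural ratio below which spawning is skipped
    recruit_w_struct: float = 0.0
    recruit_w_reserve: float = 0.0
    KDENR: Optional[float] = None
    BHa: Optional[float] = None
    BHb: Optional[float] = None


@dataclass
class DietMatrix:
    """Availability p[predator][prey] in [0, 1]: the maximum potential
    fraction of the prey's biomass available to the predator."""

    p: dict = field(default_factory=dict)  # {pred_id: {prey_id: float}}

    def get(self, pred: str, prey: str) -> float:
        return float(self.p.get(pred, {}).get(prey, 0.0))


@dataclass
class RefugeFactors:
    """Refuge multipliers delta in [0, 1] applied to availability:
    spatio-temporal overlap, habitat, and per-prey-age gape (size) masks.
    Missing entries default to 1 (no refuge)."""

    overlap: dict = field(default_factory=dict)  # {pred: {prey: float}}
    habitat: dict = field(default_factory=dict)
    size: dict = field(default_factory=dict)  # {pred: {prey: [per prey age]}}

    def get_overlap(self, pred: str, prey: str) -> float:
        return float(self.overlap.get(pred, {}).get(prey, 1.0))

    def get_habitat(self, pred: str, prey: str) -> float:
        return float(self.habitat.get(pred, {}).get(prey, 1.0))

    def get_size(self, pred: str, prey: str, n_prey_ages: int) -> np.ndarray:
        vec = self.size.get(pred, {}).get(prey)
        if vec is None:
            return np.ones(n_prey_ages)
        return np.asarray(vec, dtype=float)


@dataclass
class InitialState:
    pools: dict = field(default_factory=dict)  # {id: biomass mg N}
    vertebrates: dict = field(default_factory=dict)
    # {id: {"numbers": [...], "w_struct": [...], "w_reserve": [...]}}


@dataclass
class Forcing:
    """Annual primary-producer biomass cycle (mg N), looped every simulated
    year so the environment repeats identically (constant climate)."""

    producer_id: str = ""
    cycle: np.ndarray = field(default_factory=lambda: np.ones(365))


@dataclass
class Settings:
    years_total: int = 55
    spin_up_years: int = 25
    averaging_window_years: int = 10
    step_days: int = 1
    seed: int = 0
    spawn_day: int = 90  # day of year for aging + recruitment
    record_interval_days: int = 1


@dataclass
class FoodWebConfig:
    components: list = field(default_factory=list)  # [Component]
    params: dict = field(default_factory=dict)  # {id: ProcessParams}
    diet: DietMatrix = field(default_factory=DietMatrix)
    refuge: RefugeFactors = field(default_factory=RefugeFactors)
    initial: InitialState = field(default_factory=InitialState)
    forcing: Forcing = field(default_factory=Forcing)
    settings: Settings = field(default_factory=Settings)

    # -- helpers ---------------------------------------------------------
    def component(self, cid: str) -> Component:
        for c in self.components:
            if c.id == cid:
                return c
        raise KeyError(f"unknown component {cid!r}")

    @property
    def component_ids(self) -> list:
        return [c.id for c in self.components]

    def copy(self) -> "FoodWebConfig":
        return copy.deepcopy(self)

    def __eq__(self, other) -> bool:
        if not isinstance(other, FoodWebConfig):
            return NotImplemented
        return _to_dict(self) == _to_dict(other)

    def validate(self) -> "FoodWebConfig":
        validate_config(self)
        return self


# ---------------------------------------------------------------------------
# validation

def validate_config(cfg: FoodWebConfig) -> None:
    if not cfg.components:
        raise ConfigError("components: empty component list")
    ids = [c.id for c in cfg.components]
    dup = {i for i in ids if ids.count(i) > 1}
    if dup:
        raise ConfigError(f"components: duplicate ids {sorted(dup)}")
    idset = set(ids)

    for c in cfg.components:
        key = f"components[{c.id}]"
        if c.kind not in KINDS:
            raise ConfigError(f"{key}.kind: {c.kind!r} not in {KINDS}")
        if c.guild not in GUILDS:
            raise ConfigError(f"{key}.guild: {c.guild!r} not in {GUILDS}")
        if c.recruitment_mode not in RECRUITMENT_MODES:
            raise ConfigError(f"{key}.recruitment_mode: {c.recruitment_mode!r}")
        if c.kind == "vertebrate":
            if not (2 <= c.n_age_classes <= 10):
                raise ConfigError(
                    f"{key}.n_age_classes: vertebrates need 2-10 age classes, got {c.n_age_classes}"
                )
            if c.recruitment_mode == "none":
                raise ConfigError(f"{key}.recruitment_mode: vertebrates require a recruitment mode")
        else:
            if c.n_age_classes != 1:
                raise ConfigError(f"{key}.n_age_classes: pools must have 1 age class")
            if c.recruitment_mode != "none":
                raise ConfigError(f"{key}.recruitment_mode: pools must use 'none'")
        if c.recruitment_lognormal_sigma < 0:
            raise ConfigError(f"{key}.recruitment_lognormal_sigma: negative")

        if c.id not in cfg.params:
            raise ConfigError(f"params[{c.id}]: missing")
        p = cfg.params[c.id]
        for name in ("mum", "C"):
            vec = np.asarray(getattr(p, name), dtype=float)
            if vec.shape != (c.n_age_classes,):
                raise ConfigError(
                    f"params[{c.id}].{name}: length {vec.size} != n_age_classes {c.n_age_classes}"
                )
            if np.any(vec < 0):
                raise ConfigError(f"params[{c.id}].{name}: negative rate")
        if not (0.0 <= p.E <= 1.0):
            raise ConfigError(f"params[{c.id}].E: {p.E} outside [0, 1]")
        for name in ("mL", "mQ_juvenile", "mQ_adult", "mSt_rate", "maintenance_rate",
                     "mSt_threshold", "spawn_fraction", "spawn_skip_ratio",
                     "recruit_w_struct", "recruit_w_reserve"):
            if getattr(p, name) < 0:
                raise ConfigError(f"params[{c.id}].{name}: negative")
        if not (0.0 <= p.growth_split_structural <= 1.0):
            raise ConfigError(f"params[{c.id}].growth_split_structural: outside [0, 1]")
        if c.kind == "vertebrate" and not (1 <= p.maturity_age <= c.n_age_classes):
            raise ConfigError(f"params[{c.id}].maturity_age: outside 1..{c.n_age_classes}")
        if c.recruitment_mode == "beverton_holt":
            if p.BHa is None or p.BHb is None:
                raise ConfigError(f"params[{c.id}]: beverton_holt requires BHa and BHb")
            if p.KDENR is not None:
                raise ConfigError(f"params[{c.id}].KDENR: set but mode is beverton_holt")
        elif c.recruitment_mode == "constant_per_adult":
            if p.KDENR is None:
                raise ConfigError(f"params[{c.id}]: constant_per_adult requires KDENR")
            if p.BHa is not None or p.BHb is not None:
                raise ConfigError(f"params[{c.id}].BHa/BHb: set but mode is constant_per_adult")
        else:
            if p.KDENR is not None or p.BHa is not None or p.BHb is not None:
                raise ConfigError(f"params[{c.id}]: recruitment parameters set but mode is none")

    for pred, row in cfg.diet.p.items():
        if pred not in idset:
            raise ConfigError(f"diet[{pred}]: unknown predator id")
        for prey, v in row.items():
            if prey not in idset:
                raise ConfigError(f"diet[{pred}][{prey}]: unknown prey id")
            if not (0.0 <= float(v) <= 1.0):
                raise ConfigError(f"diet[{pred}][{prey}]: {v} outside [0, 1]")

    for attr in ("overlap", "habitat", "size"):
        for pred, row in getattr(cfg.refuge, attr).items():
            if pred not in idset:
                raise ConfigError(f"refuge.{attr}[{pred}]: unknown predator id")
            for prey, v in row.items():
                if prey not in idset:
                    raise ConfigError(f"refuge.{attr}[{pred}][{prey}]: unknown prey id")
                vals = np.atleast_1d(np.asarray(v, dtype=float))
                if np.any(vals < 0) or np.any(vals > 1):
                    raise ConfigError(f"refuge.{attr}[{pred}][{prey}]: outside [0, 1]")
                if attr == "size":
                    n = cfg.component(prey).n_age_classes
                    if vals.size != n:
                        raise ConfigError(
                            f"refuge.size[{pred}][{prey}]: length {vals.size} != prey age classes {n}"
                        )

    for c in cfg.components:
        if c.kind == "vertebrate":
            st = cfg.initial.vertebrates.get(c.id)
            if st is None:
                raise ConfigError(f"initial.vertebrates[{c.id}]: missing")
            for name in ("numbers", "w_struct", "w_reserve"):
                vec = np.asarray(st.get(name, []), dtype=float)
                if vec.shape != (c.n_age_classes,):
                    raise ConfigError(
                        f"initial.vertebrates[{c.id}].{name}: length {vec.size} "
                        f"!= n_age_classes {c.n_age_classes}"
                    )
                if np.any(vec < 0):
                    raise ConfigError(f"initial.vertebrates[{c.id}].{name}: negative")
            num = np.asarray(st["numbers"], dtype=float)
            wr = np.asarray(st["w_reserve"], dtype=float)
            if np.any((num > 0) & (wr <= 0)):
                raise ConfigError(
                    f"initial.vertebrates[{c.id}].w_reserve: must be > 0 where numbers > 0"
                )
        else:
            if c.id not in cfg.initial.pools:
                raise ConfigError(f"initial.pools[{c.id}]: missing")
            if cfg.initial.pools[c.id] < 0:
                raise ConfigError(f"initial.pools[{c.id}]: negative biomass")

    f = cfg.forcing
    if f.producer_id:
        if f.producer_id not in idset:
            raise ConfigError(f"forcing.producer_id: unknown component {f.producer_id!r}")
        if cfg.component(f.producer_id).kind != "producer":
            raise ConfigError(f"forcing.producer_id: {f.producer_id!r} is not a producer")
        cyc = np.asarray(f.cycle, dtype=float)
        if cyc.shape != (365,):
            raise ConfigError(f"forcing.cycle: length {cyc.size} != 365")
        if np.any(cyc <= 0):
            raise ConfigError("forcing.cycle: entries must be strictly positive")

    s = cfg.settings
    for name in ("years_total", "spin_up_years", "averaging_window_years",
                 "step_days", "record_interval_days"):
        if getattr(s, name) < 0 or (name in ("step_days", "record_interval_days")
                                    and getattr(s, name) < 1):
            raise ConfigError(f"settings.{name}: must be positive")
    if s.years_total and s.averaging_window_years > s.years_total - s.spin_up_years:
        raise ConfigError(
            "settings.averaging_window_years: exceeds years_total - spin_up_years"
        )
    if not (1 <= s.spawn_day <= 364):
        raise ConfigError("settings.spawn_day: outside 1..364")


# ---------------------------------------------------------------------------
# YAML (de)serialization

def _arr(x) -> list:
    return [float(v) for v in np.asarray(x, dtype=float).ravel()]


def _to_dict(cfg: FoodWebConfig) -> dict:
    comps = []
    for c in cfg.components:
        p = cfg.params[c.id]
        d = {
            "id": c.id,
            "name": c.name,
            "kind": c.kind,
            "guild": c.guild,
            "n_age_classes": int(c.n_age_classes),
            "is_key_species": bool(c.is_key_species),
            "recruitment_mode": c.recruitment_mode,
            "recruitment_lognormal_sigma": float(c.recruitment_lognormal_sigma),
            "params": {
                "mum": _arr(p.mum),
                "C": _arr(p.C),
                "E": float(p.E),
                "mL": float(p.mL),
                "mQ_juvenile": float(p.mQ_juvenile),
                "mQ_adult": float(p.mQ_adult),
                "mSt_threshold": float(p.mSt_threshold),
                "mSt_rate": float(p.mSt_rate),
                "maintenance_rate": float(p.maintenance_rate),
                "growth_split_structural": float(p.growth_split_structural),
                "maturity_age": int(p.maturity_age),
                "spawn_fraction": float(p.spawn_fraction),
                "spawn_skip_ratio": float(p.spawn_skip_ratio),
                "recruit_w_struct": float(p.recruit_w_struct),
                "recruit_w_reserve": float(p.recruit_w_reserve),
            },
        }
        for name in ("KDENR", "BHa", "BHb"):
            v = getattr(p, name)
            if v is not None:
                d["params"][name] = float(v)
        if c.kind == "vertebrate":
            st = cfg.initial.vertebrates[c.id]
            d["initial"] = {
                "numbers": _arr(st["numbers"]),
                "w_struct": _arr(st["w_struct"]),
                "w_reserve": _arr(st["w_reserve"]),
            }
        else:
            d["initial"] = {"biomass": float(cfg.initial.pools[c.id])}
        comps.append(d)

    def _matrix(m):
        return {pred: {prey: float(v) for prey, v in sorted(row.items())}
                for pred, row in sorted(m.items()) if row}

    out = {
        "settings": {
            "years_total": int(cfg.settings.years_total),
            "spin_up_years": int(cfg.settings.spin_up_years),
            "averaging_window_years": int(cfg.settings.averaging_window_years),
            "step_days": int(cfg.settings.step_days),
            "seed": int(cfg.settings.seed),
            "spawn_day": int(cfg.settings.spawn_day),
            "record_interval_days": int(cfg.settings.record_interval_days),
        },
        "components": comps,
        "diet": _matrix(cfg.diet.p),
        "refuge": {
            "overlap": _matrix(cfg.refuge.overlap),
            "habitat": _matrix(cfg.refuge.habitat),
            "size": {pred: {prey: _arr(v) for prey, v in sorted(row.items())}
                     for pred, row in sorted(cfg.refuge.size.items()) if row},
        },
        "forcing": {},
    }
    if cfg.forcing.producer_id:
        out["forcing"] = {
            "producer_id": cfg.forcing.producer_id,
            "cycle": _arr(cfg.forcing.cycle),
        }
    return out


def _from_dict(doc: dict) -> FoodWebConfig:
    if not isinstance(doc, dict):
        raise ConfigError("top level: expected a mapping")
    cfg = FoodWebConfig()
    s = doc.get("settings", {})
    cfg.settings = Settings(**{k: int(v) for k, v in s.items()})

    for d in doc.get("components", []):
        try:
            comp = Component(
                id=str(d["id"]),
                name=str(d.get("name", d["id"])),
                kind=str(d["kind"]),
                guild=str(d["guild"]),
                n_age_classes=int(d.get("n_age_classes", 1)),
                is_key_species=bool(d.get("is_key_species", False)),
                recruitment_mode=str(d.get("recruitment_mode", "none")),
                recruitment_lognormal_sigma=float(d.get("recruitment_lognormal_sigma", 0.0)),
            )
        except KeyError as e:
            raise ConfigError(f"components: missing field {e}") from e
        cfg.components.append(comp)
        pd_ = dict(d.get("params", {}))
        if "mQ" in pd_:  # pool shorthand: one quadratic coefficient on biomass
            mq = float(pd_.pop("mQ"))
            pd_.setdefault("mQ_juvenile", mq)
            pd_.setdefault("mQ_adult", mq)
        pp = ProcessParams()
        for k, v in pd_.items():
            if not hasattr(pp, k):
                raise ConfigError(f"params[{comp.id}].{k}: unknown parameter")
            if k in ("mum", "C"):
                setattr(pp, k, np.asarray(v, dtype=float))
            elif k == "maturity_age":
                pp.maturity_age = int(v)
            else:
                setattr(pp, k, float(v))
        cfg.params[comp.id] = pp
        init = d.get("initial", {})
        if comp.kind == "vertebrate":
            try:
                cfg.initial.vertebrates[comp.id] = {
                    "numbers": np.asarray(init["numbers"], dtype=float),
                    "w_struct": np.asarray(init["w_struct"], dtype=float),
                    "w_reserve": np.asarray(init["w_reserve"], dtype=float),
                }
            except KeyError as e:
                raise ConfigError(f"initial[{comp.id}]: missing field {e}") from e
        else:
            if "biomass" not in init:
                raise ConfigError(f"initial[{comp.id}]: missing biomass")
            cfg.initial.pools[comp.id] = float(init["biomass"])

    cfg.diet = DietMatrix({p: {q: float(v) for q, v in row.items()}
                           for p, row in doc.get("diet", {}).items()})
    r = doc.get("refuge", {})
    cfg.refuge = RefugeFactors(
        overlap={p: {q: float(v) for q, v in row.items()}
                 for p, row in r.get("overlap", {}).items()},
        habitat={p: {q: float(v) for q, v in row.items()}
                 for p, row in r.get("habitat", {}).items()},
        size={p: {q: [float(x) for x in v] for q, v in row.items()}
              for p, row in r.get("size", {}).items()},
    )
    f = doc.get("forcing", {})
    if f:
        cfg.forcing = Forcing(
            producer_id=str(f.get("producer_id", "")),
            cycle=np.asarray(f.get("cycle", np.ones(365)), dtype=float),
        )
    else:
        cfg.forcing = Forcing(producer_id="")
    return cfg


def load_config(path) -> FoodWebConfig:
    """Read and validate a food-web configuration from a YAML file."""
    with open(path) as fh:
        try:
            doc = yaml.safe_load(fh)
        except yaml.YAMLError as e:
            raise ConfigError(f"{path}: YAML parse failure: {e}") from e
    cfg = _from_dict(doc)
    validate_config(cfg)
    return cfg


def dumps_config(cfg: FoodWebConfig) -> str:
    """Validate and serialize a configuration to its YAML text."""
    validate_config(cfg)
    return yaml.safe_dump(_to_dict(cfg), sort_keys=False, default_flow_style=None)


def save_config(cfg: FoodWebConfig, path) -> None:
    """Validate and write a configuration; load_config(path) returns an equal config."""
    text = dumps_config(cfg)
    with open(path, "w") as fh:
        fh.write(text)
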