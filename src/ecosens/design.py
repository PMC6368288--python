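"""Perturbation experiment design: control, one-at-a-time (OAT) runs,
extreme runs, and impact-paired combination runs.

The default study perturbs four parameter families on the key species:
maximum growth rate (mum), consumption rate (C), quadratic mortality (mQ,
juvenile and adult coefficients scaled together), and recruitment (BHa for
Beverton-Holt species, KDENR for constant-recruitment species; not
applicable to biomass pools).  Every perturbation is multiplicative; the
standard magnitude is +/-25%, applied to all age classes of a vectorized
parameter at once.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import FoodWebConfig

__all__ = [
    "ParameterRef",
    "RunSpec",
    "Manifest",
    "DesignError",
    "enumerate_oat",
    "enumerate_extremes",
    "pair_combinations",
    "apply_edits",
    "default_extremes",
    "default_selected_oat",
    "default_key_species_pairs",
    "build_manifest",
    "save_manifest",
    "load_manifest",
]

PARAM_FAMILIES = ("mum", "C", "recruitment", "mQ")


class DesignError(ValueError):
    pass


@dataclass(frozen=True)
class ParameterRef:
    """A perturbable parameter of one component.  ``parameter`` is one of
    mum, C, mQ (scales juvenile and adult coefficients together) or
    recruitment (resolves to BHa or KDENR by the component's mode)."""

    component: str
    parameter: str

    def __post_init__(self):
        if self.parameter not in PARAM_FAMILIES:
            raise DesignError(f"unknown parameter family {self.parameter!r}")


@dataclass
class RunSpec:
    run_id: str
    label: str
    edits: list = field(default_factory=list)  # [(ParameterRef, multiplier)]
    provenance: str = "oat"  # control | oat | extreme | combination
    parents: list = field(default_factory=list)  # run ids for combinations

    def __post_init__(self):
        for _, m in self.edits:
            if m <= 0:
                raise DesignError(f"{self.run_id}: multiplier must be > 0")
        if self.provenance == "control" and self.edits:
            raise DesignError(f"{self.run_id}: control run must have no edits")
        if self.provenance == "oat" and len(self.edits) != 1:
            raise DesignError(f"{self.run_id}: OAT run must have exactly one edit")
        if self.provenance == "combination" and len(self.parents) != 2:
            raise DesignError(f"{self.run_id}: combination run needs exactly two parents")


@dataclass
class Manifest:
    runs: list = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        ids = [r.run_id for r in self.runs]
        if len(ids) != len(set(ids)):
            raise DesignError("manifest: duplicate run ids")
        idset = set(ids)
        for r in self.runs:
            for p in r.parents:
                if p not in idset:
                    raise DesignError(f"manifest: {r.run_id} parent {p!r} not in manifest")

    def __iter__(self):
        return iter(self.runs)

    def __len__(self):
        return len(self.runs)

    def get(self, run_id: str) -> RunSpec:
        for r in self.runs:
            if r.run_id == run_id:
                return r
        raise KeyError(run_id)

    def by_provenance(self, provenance: str) -> list:
        return [r for r in self.runs if r.provenance == provenance]


# ---------------------------------------------------------------------------

def _applicable_params(cfg: FoodWebConfig, cid: str) -> list:
    c = cfg.component(cid)
    if c.kind == "vertebrate":
        return ["mum", "C", "recruitment", "mQ"]
    return ["mum", "C", "mQ"]


def enumerate_oat(cfg: FoodWebConfig, key_species=None,
                  magnitudes=(1.25, 0.75)) -> list:
    """One run per (key species, applicable parameter family, direction).

    Vertebrates contribute 4 families x 2 directions, pools 3 x 2 (pools
    have no recruitment function).  Per-age vectors are scaled on all age
    classes simultaneously; a mortality edit scales the juvenile and adult
    coefficients together.
    """
    if key_species is None:
        key_species = [c.id for c in cfg.components if c.is_key_species]
    ids = set(cfg.component_ids)
    for cid in key_species:
        if cid not in ids:
            raise DesignError(f"key species {cid!r} not in config")
    runs = []
    i = 1
    for family in PARAM_FAMILIES:
        for cid in key_species:
            if family not in _applicable_params(cfg, cid):
                continue
            for mult in magnitudes:
                direction = "increase" if mult > 1 else "decrease"
                runs.append(RunSpec(
                    run_id=f"run{i:02d}",
                    label=f"{direction} {family} {cid} x{mult:g}",
                    edits=[(ParameterRef(cid, family), float(mult))],
                    provenance="oat",
                ))
                i += 1
    return runs


def default_extremes() -> list:
    """The four extreme perturbations mimicking observed extremes:
    herring-analog recruitment +230% / -90%, cod-analog growth +70% / -39%."""
    return [
        (ParameterRef("SSH", "recruitment"), 3.30),
        (ParameterRef("SSH", "recruitment"), 0.10),
        (ParameterRef("NCO", "mum"), 1.70),
        (ParameterRef("NCO", "mum"), 0.61),
    ]


def enumerate_extremes(spec=None, start_index: int = 65) -> list:
    """One run per (ParameterRef, multiplier) entry; defaults to the four
    observed-extreme runs."""
    if spec is None:
        spec = default_extremes()
    runs = []
    for k, (ref, mult) in enumerate(spec):
        if mult <= 0:
            raise DesignError(f"extreme multiplier must be > 0, got {mult}")
        direction = "increase" if mult > 1 else "decrease"
        runs.append(RunSpec(
            run_id=f"run{start_index + k:02d}",
            label=f"extreme {direction} {ref.parameter} {ref.component} x{mult:g}",
            edits=[(ref, float(mult))],
            provenance="extreme",
        ))
    return runs


def _union_edits(a: RunSpec, b: RunSpec) -> list:
    refs_a = {ref for ref, _ in a.edits}
    refs_b = {ref for ref, _ in b.edits}
    clash = refs_a & refs_b
    if clash:
        r = sorted(clash, key=lambda x: (x.component, x.parameter))[0]
        raise DesignError(
            f"conflicting edits: parents {a.run_id} and {b.run_id} both perturb "
            f"{r.component}:{r.parameter}")
    return list(a.edits) + list(b.edits)


def pair_combinations(oat_runs: list, impact_factors: dict,
                      start_index: int = 69, families=PARAM_FAMILIES) -> list:
    """Algorithmic pairing: per parameter family, select the highest- and
    lowest-impact OAT run (ties broken by run id order), then form every
    unordered pair of the selected runs so high-impact settings meet both
    high- and low-impact settings.  Pairs sharing a ParameterRef are dropped.
    """
    selected = []
    for family in families:
        fam_runs = [r for r in oat_runs if r.edits[0][0].parameter == family]
        if not fam_runs:
            continue
        hi = max(fam_runs, key=lambda r: (impact_factors[r.run_id], [-ord(c) for c in r.run_id]))
        lo = min(fam_runs, key=lambda r: (impact_factors[r.run_id], [ord(c) for c in r.run_id]))
        selected.append(hi)
        if lo.run_id != hi.run_id:
            selected.append(lo)
    runs = []
    i = start_index
    for a, b in itertools.combinations(selected, 2):
        try:
            edits = _union_edits(a, b)
        except DesignError:
            continue
        runs.append(RunSpec(
            run_id=f"run{i:02d}",
            label=f"combination {a.run_id}+{b.run_id}",
            edits=edits,
            provenance="combination",
            parents=[a.run_id, b.run_id],
        ))
        i += 1
    return runs


# -- the reference explicit pairing fixture ------------------------------

def default_selected_oat() -> list:
    """The eight OAT settings (one high-impact and one low-impact per
    parameter family) entering the 28 metric-paired combination runs."""
    return [
        (ParameterRef("ZS", "C"), 1.25),
        (ParameterRef("ZL", "mum"), 0.75),
        (ParameterRef("MWH", "recruitment"), 0.75),
        (ParameterRef("NCO", "mQ"), 1.25),
        (ParameterRef("SSH", "mum"), 0.75),
        (ParameterRef("PCO", "C"), 1.25),
        (ParameterRef("CAP", "recruitment"), 1.25),
        (ParameterRef("PCO", "mQ"), 0.75),
    ]


def default_key_species_pairs() -> list:
    """The eight key-species-response pairings, as (edit-list, edit-list)
    tuples; the last pairs a mortality decrease with a two-edit recruitment
    combination, giving a three-edit run."""
    E = ParameterRef
    return [
        ([(E("NCO", "C"), 0.75)], [(E("NCO", "mQ"), 0.75)]),
        ([(E("NCO", "C"), 0.75)], [(E("CAP", "recruitment"), 0.75)]),
        ([(E("CAP", "recruitment"), 0.75)], [(E("SSH", "recruitment"), 0.75)]),
        ([(E("MWH", "mQ"), 0.75)], [(E("CAP", "mum"), 0.75)]),
        ([(E("CAP", "C"), 0.75)], [(E("NCO", "mQ"), 0.75)]),
        ([(E("PCO", "mum"), 0.75)], [(E("CAP", "mum"), 0.75)]),
        ([(E("MWH", "mum"), 0.75)], [(E("NCO", "C"), 0.75)]),
        ([(E("NCO", "mQ"), 0.75)],
         [(E("CAP", "recruitment"), 0.75), (E("SSH", "recruitment"), 0.75)]),
    ]


def _find_oat(oat_runs: list, edits: list):
    """Locate the run whose edit set equals ``edits`` among OAT/extreme runs."""
    target = set(edits)
    for r in oat_runs:
        if set(r.edits) == target:
            return r
    return None


def build_manifest(cfg: FoodWebConfig, mode: str = "reference",
                   impact_factors: dict | None = None,
                   seed: int | None = None) -> Manifest:
    """Assemble the full run manifest: 1 control + OAT + extremes + combinations.

    ``mode='reference'`` uses the shipped explicit pairing fixture
    (deterministic, no simulation needed): 8 selected OAT settings paired
    all-against-all (28 runs) plus 8 key-species pairings, for 36
    combinations and 105 manifest entries in total.  ``mode='algorithmic'``
    selects the per-family high/low impact runs from ``impact_factors``.
    """
    control = RunSpec("run00", "control", [], "control")
    oat = enumerate_oat(cfg)
    extremes = enumerate_extremes(start_index=len(oat) + 1)
    pool = oat + extremes
    combos = []
    i = len(pool) + 1

    if mode == "reference":
        selected = []
        for ref, mult in default_selected_oat():
            r = _find_oat(pool, [(ref, mult)])
            if r is None:
                raise DesignError(
                    f"reference pairing: no OAT run for {ref.component}:{ref.parameter} x{mult}")
            selected.append(r)
        key_pairs = []
        for e1, e2 in default_key_species_pairs():
            r1 = _find_oat(pool, e1)
            r2 = _find_oat(pool + key_pairs, e2) or _find_oat(key_pairs, e2)
            if r1 is None or r2 is None:
                raise DesignError("reference pairing: key-species parent not found")
            run = RunSpec(f"run{i:02d}", f"combination {r1.run_id}+{r2.run_id}",
                          _union_edits(r1, r2), "combination",
                          parents=[r1.run_id, r2.run_id])
            key_pairs.append(run)
            combos.append(run)
            i += 1
        for a, b in itertools.combinations(selected, 2):
            run = RunSpec(f"run{i:02d}", f"combination {a.run_id}+{b.run_id}",
                          _union_edits(a, b), "combination",
                          parents=[a.run_id, b.run_id])
            combos.append(run)
            i += 1
    elif mode == "algorithmic":
        if impact_factors is None:
            raise DesignError("algorithmic pairing requires OAT impact factors")
        combos = pair_combinations(oat, impact_factors, start_index=i)
    else:
        raise DesignError(f"unknown manifest mode {mode!r}")

    return Manifest(
        runs=[control] + pool + combos,
        metadata={"mode": mode, "magnitudes": [1.25, 0.75],
                  "seed": int(cfg.settings.seed if seed is None else seed)},
    )


# ---------------------------------------------------------------------------

def apply_edits(cfg: FoodWebConfig, runspec: RunSpec) -> FoodWebConfig:
    """Return a copy of ``cfg`` with each referenced parameter multiplied by
    its multiplier; everything else identical, the original untouched."""
    out = cfg.copy()
    for ref, mult in runspec.edits:
        if ref.component not in out.params:
            raise DesignError(f"{runspec.run_id}: unknown component {ref.component!r}")
        p = out.params[ref.component]
        comp = out.component(ref.component)
        if ref.parameter == "mum":
            p.mum = np.asarray(p.mum, dtype=float) * mult
        elif ref.parameter == "C":
            p.C = np.asarray(p.C, dtype=float) * mult
        elif ref.parameter == "mQ":
            p.mQ_juvenile *= mult
            p.mQ_adult *= mult
        elif ref.parameter == "recruitment":
            if comp.kind != "vertebrate":
                raise DesignError(
                    f"{runspec.run_id}: recruitment not applicable to pool {ref.component}")
            if comp.recruitment_mode == "beverton_holt":
                p.BHa *= mult
            else:
                p.KDENR *= mult
    return out


# ---------------------------------------------------------------------------
# manifest persistence (CSV)

def _edits_str(edits: list) -> str:
    return ";".join(f"{r.component}:{r.parameter}:{m!r}" for r, m in edits)


def save_manifest(manifest: Manifest, path) -> None:
    rows = [{
        "run_id": r.run_id,
        "label": r.label,
        "provenance": r.provenance,
        "parent_ids": ";".join(r.parents),
        "edits": _edits_str(r.edits),
    } for r in manifest]
    pd.DataFrame(rows).to_csv(path, index=False)


def load_manifest(path) -> Manifest:
    df = pd.read_csv(path, keep_default_na=False)
    runs = []
    for _, row in df.iterrows():
        edits = []
        if row["edits"]:
            for item in str(row["edits"]).split(";"):
                comp, param, mult = item.split(":")
                edits.append((ParameterRef(comp, param), float(mult)))
        parents = [p for p in str(row["parent_ids"]).split(";") if p]
        runs.append(RunSpec(row["run_id"], row["label"], edits,
                            row["provenance"], parents))
    return Manifest(runs=runs)
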