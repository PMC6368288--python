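"""Impact metrics: biomass changes vs control, impact categories and
weights, per-run impact factor, and additive / synergistic / antagonistic
interaction classification for combination runs.

The per-run score ("impact factor") is the mean over components of the
weight assigned to each component's absolute relative biomass change:
|delta| in [0, 5%) -> no impact (1), [5%, 10%) -> low (2), [10%, 20%) ->
medium (3), >= 20% -> high (4).  A combined-perturbation response is
additive when the combined change matches the sum of the single-run changes
within a +/-1% band on the residual; otherwise it is synergistic when the
combined change exceeds that sum in magnitude, antagonistic when it falls
short.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import TrajectoryTable

__all__ = [
    "BiomassChange",
    "ImpactReport",
    "InteractionClass",
    "biomass_change",
    "impact_category",
    "impact_factor",
    "classify_interaction",
    "tabulate_interactions",
    "response_correlation",
]

CATEGORY_NAMES = {1: "no impact", 2: "low impact", 3: "medium impact", 4: "high impact"}
INTERACTION_LABELS = ("additive", "synergistic", "antagonistic")


@dataclass
class BiomassChange:
    component: str
    delta: float  # signed relative change of last-window mean biomass
    defined: bool = True  # False when the control window mean is zero


@dataclass
class ImpactReport:
    run_id: str
    changes: list = field(default_factory=list)  # [BiomassChange]
    scope: str = "all_components"  # or "key_species"
    excluded: list = field(default_factory=list)  # components with undefined delta

    @property
    def impact_factor(self) -> float:
        return impact_factor([c for c in self.changes if c.defined])

    def delta(self, component: str) -> float:
        for c in self.changes:
            if c.component == component:
                return c.delta
        raise KeyError(component)


@dataclass
class InteractionClass:
    run_id: str
    component: str
    label: str
    residual: float  # dP1P2 - (dP1 + dP2)


# ---------------------------------------------------------------------------

def biomass_change(perturbed: TrajectoryTable, control: TrajectoryTable,
                   window_years: int = 10, components=None) -> list:
    """Signed relative change of mean biomass over the last ``window_years``
    of the run, per component: (mean_perturbed - mean_control) / mean_control.

    Components whose control window mean is zero are flagged undefined and
    later excluded from the impact factor.
    """
    if perturbed.years_total != control.years_total:
        raise ValueError("biomass_change: runs have unequal horizons")
    mp = perturbed.window_mean(window_years)
    mc = control.window_mean(window_years)
    out = []
    for cid in (components if components is not None else control.component_ids):
        c = float(mc[cid])
        if c == 0.0:
            out.append(BiomassChange(cid, float("nan"), defined=False))
        else:
            out.append(BiomassChange(cid, (float(mp[cid]) - c) / c))
    return out


def impact_category(delta: float) -> tuple:
    """Map a signed relative biomass change to its (category, weight).

    Bands on |delta| are half-open upward: [0, 0.05) -> 1, [0.05, 0.10) -> 2,
    [0.10, 0.20) -> 3, >= 0.20 -> 4.
    """
    if not math.isfinite(delta):
        raise ValueError(f"impact_category: non-finite delta {delta}")
    a = abs(delta)
    if a < 0.05:
        w = 1
    elif a < 0.10:
        w = 2
    elif a < 0.20:
        w = 3
    else:
        w = 4
    return CATEGORY_NAMES[w], w


def impact_factor(changes: list) -> float:
    """Mean of the category weights over the given biomass changes (in [1, 4])."""
    deltas = [c.delta if isinstance(c, BiomassChange) else float(c) for c in changes]
    if not deltas:
        raise ValueError("impact_factor: empty change set")
    return float(np.mean([impact_category(d)[1] for d in deltas]))


def classify_interaction(dP1: float, dP2: float, dP12: float,
                         tol: float = 0.01, run_id: str = "",
                         component: str = "") -> InteractionClass:
    """Classify a combined response against the sum of its single responses.

    additive when |dP12 - (dP1 + dP2)| < tol; otherwise synergistic when
    |dP12| > |dP1 + dP2|, antagonistic when smaller.
    """
    for v in (dP1, dP2, dP12):
        if not math.isfinite(v):
            raise ValueError("classify_interaction: non-finite input")
    s = dP1 + dP2
    residual = dP12 - s
    if abs(residual) < tol:
        label = "additive"
    elif abs(dP12) > abs(s):
        label = "synergistic"
    else:
        label = "antagonistic"
    return InteractionClass(run_id, component, label, residual)


def tabulate_interactions(classes: list, grouping: dict) -> pd.DataFrame:
    """Percentage of (run, component) cells per group with each label.

    ``grouping`` maps component id -> group name; rows sum to 100 up to
    rounding.  Returns an empty frame for an empty class list.
    """
    if not classes:
        return pd.DataFrame(columns=list(INTERACTION_LABELS))
    rows = {}
    for ic in classes:
        if ic.component not in grouping:
            raise KeyError(f"tabulate_interactions: no group for component {ic.component!r}")
        g = grouping[ic.component]
        rows.setdefault(g, {lab: 0 for lab in INTERACTION_LABELS})
        rows[g][ic.label] += 1
    table = pd.DataFrame.from_dict(rows, orient="index").loc[:, list(INTERACTION_LABELS)]
    table = table.div(table.sum(axis=1), axis=0) * 100.0
    table.index.name = "group"
    return table.sort_index()


def response_correlation(deltas: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation of per-run biomass-change vectors between
    components.  ``deltas`` is components x runs; zero-variance components
    yield NaN rows/columns (flagged undefined)."""
    if deltas.shape[1] < 2:
        raise ValueError("response_correlation: need at least 2 runs")
    return deltas.T.corr()
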