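"""Hierarchical gating and bead-based absolute quantification.

The gating strategy is a rooted tree of geometric gates; each node's
population is the intersection of its parent population with the gate mask,
so nestedness (child subset of parent) holds by construction. The default
strategy mirrors conventional microglia identification: main cell population
on scatter, doublet exclusion on the FSC-H/FSC-A pulse ratio, dead-cell
exclusion on the viability dye, then CD45+ CD11b/c+ P2y12+ selection.
Counting-bead events convert event counts to absolute cells per mg of tissue.

Conventions (fixed and documented rather than tuned per file): positivity
thresholds use a strict ``>``; rectangle and polygon boundaries are included;
polygons use the even-odd fill rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .flow_io import EventTable, SampleMetadata
from .panels import BEAD_CHANNEL, IDENTIFICATION_MARKERS, VIABILITY_CHANNEL

log = logging.getLogger(__name__)

__all__ = [
    "Gate",
    "GatingStrategy",
    "StrategyResult",
    "AbsoluteCountResult",
    "apply_gate",
    "singlet_mask",
    "viability_mask",
    "find_valley",
    "run_strategy",
    "default_strategy",
    "classify_events",
    "recovery_scores",
    "absolute_count",
    "fold_change_vs_reference",
    "DEFAULT_SETTINGS",
]

GATE_KINDS = ("rectangle", "polygon", "threshold", "ratio_band")

#: Default gate geometry, on the analysis scale (arcsinh fluorescence,
#: linear scatter). Overridable per channel through ``default_strategy``.
DEFAULT_SETTINGS = {
    "cells_fsc": (3.0e4, 4.5e5),
    "cells_ssc": (0.0, 3.5e5),
    "singlet_band": (0.75, 1.10),
    "positivity_threshold": 1.5,
    "viability_fallback": 2.0,
    "bead_threshold": 2.0,
}


@dataclass(frozen=True)
class Gate:
    """One named gate: a geometric region in 1-2 channel dimensions."""

    name: str
    kind: str
    channels: tuple[str, ...]
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in GATE_KINDS:
            raise ValueError(f"unknown gate kind {self.kind!r}")
        object.__setattr__(self, "channels", tuple(self.channels))
        if self.kind == "polygon":
            verts = np.asarray(self.params["vertices"], dtype=float)
            if verts.shape[0] < 3:
                raise ValueError(f"polygon gate {self.name!r} needs >= 3 vertices")
            # collinearity check: the polygon must enclose area
            area = 0.5 * abs(np.sum(
                verts[:, 0] * np.roll(verts[:, 1], -1)
                - np.roll(verts[:, 0], -1) * verts[:, 1]))
            if area == 0:
                raise ValueError(f"polygon gate {self.name!r} vertices are collinear")
        if self.kind == "rectangle":
            (x0, x1), (y0, y1) = self.params["x"], self.params["y"]
            if x0 > x1 or y0 > y1:
                raise ValueError(f"rectangle gate {self.name!r} bounds not ordered")
        if self.kind == "ratio_band":
            lo, hi = self.params["band"]
            if lo >= hi:
                raise ValueError(f"ratio band gate {self.name!r} needs lo < hi")


def _points_in_polygon(x: np.ndarray, y: np.ndarray, verts: np.ndarray) -> np.ndarray:
    """Even-odd ray casting; points on an edge are included."""
    n = verts.shape[0]
    inside = np.zeros(x.shape, dtype=bool)
    on_edge = np.zeros(x.shape, dtype=bool)
    for i in range(n):
        x1, y1 = verts[i]
        x2, y2 = verts[(i + 1) % n]
        # boundary test: point within segment bbox and zero cross product
        cross = (x2 - x1) * (y - y1) - (y2 - y1) * (x - x1)
        within = ((np.minimum(x1, x2) - 1e-12 <= x) & (x <= np.maximum(x1, x2) + 1e-12)
                  & (np.minimum(y1, y2) - 1e-12 <= y) & (y <= np.maximum(y1, y2) + 1e-12))
        on_edge |= within & (np.abs(cross) <= 1e-9 * max(1.0, abs(x2 - x1) + abs(y2 - y1)))
        crosses = ((y1 > y) != (y2 > y))
        with np.errstate(divide="ignore", invalid="ignore"):
            x_at = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
        inside ^= crosses & (x < np.where(crosses, x_at, np.inf))
    return inside | on_edge


def apply_gate(table: EventTable, gate: Gate,
               parent_mask: np.ndarray | None = None) -> np.ndarray:
    """Evaluate one gate; the result is intersected with ``parent_mask``."""
    if parent_mask is None:
        parent_mask = np.ones(table.n_events, dtype=bool)
    parent_mask = np.asarray(parent_mask, dtype=bool)
    if parent_mask.shape != (table.n_events,):
        raise ValueError("parent mask length does not match event count")
    for ch in gate.channels:
        if ch not in table.channels:
            raise KeyError(f"gate {gate.name!r}: channel {ch!r} missing from table")

    if gate.kind == "rectangle":
        x = table.column(gate.channels[0])
        y = table.column(gate.channels[1])
        (x0, x1), (y0, y1) = gate.params["x"], gate.params["y"]
        mask = (x >= x0) & (x <= x1) & (y >= y0) & (y <= y1)
    elif gate.kind == "polygon":
        verts = np.asarray(gate.params["vertices"], dtype=float)
        mask = _points_in_polygon(table.column(gate.channels[0]),
                                  table.column(gate.channels[1]), verts)
    elif gate.kind == "threshold":
        v = table.column(gate.channels[0])
        direction = gate.params.get("direction", ">")
        value = gate.params.get("value")
        if value is None:
            value = _resolve_data_threshold(v[parent_mask], gate)
        mask = (v > value) if direction == ">" else (v < value)
    else:  # ratio_band
        denom = table.column(gate.channels[0])
        num = table.column(gate.channels[1])
        lo, hi = gate.params["band"]
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = num / denom
        mask = (denom > 0) & (ratio >= lo) & (ratio <= hi)
    return mask & parent_mask


def _resolve_data_threshold(values: np.ndarray, gate: Gate) -> float:
    fallback = gate.params.get("fallback")
    try:
        return find_valley(values)
    except ValueError:
        if fallback is None:
            raise
        log.warning("gate %s: valley finding failed, using fallback threshold %.3g",
                    gate.name, fallback)
        return float(fallback)


def find_valley(values: np.ndarray, grid_size: int = 512,
                max_points: int = 5000) -> float:
    """Place a threshold at the density valley between the two largest modes.

    Uses a Gaussian KDE on (a deterministic subsample of) the values. Raises
    ``ValueError`` when the density has fewer than two modes.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size < 20 or np.ptp(values) == 0:
        raise ValueError("not enough spread to locate a valley")
    if values.size > max_points:
        step = values.size // max_points
        values = values[::step]
    lo, hi = np.percentile(values, [0.5, 99.5])
    grid = np.linspace(lo, hi, grid_size)
    dens = gaussian_kde(values)(grid)
    interior = (dens[1:-1] > dens[:-2]) & (dens[1:-1] >= dens[2:])
    peaks = np.where(interior)[0] + 1
    if peaks.size < 2:
        raise ValueError("density is unimodal; no valley to find")
    top2 = peaks[np.argsort(dens[peaks])][-2:]
    a, b = np.sort(top2)
    valley = a + int(np.argmin(dens[a:b + 1]))
    return float(grid[valley])


def singlet_mask(table: EventTable, band: tuple[float, float] = DEFAULT_SETTINGS["singlet_band"]) -> np.ndarray:
    """Keep events whose FSC-H/FSC-A pulse ratio lies in ``band``.

    Aggregates roughly double their pulse area but not their height, so they
    fall below the band. Events with non-positive FSC-A are excluded.
    """
    lo, hi = band
    if lo >= hi:
        raise ValueError(f"ratio band requires lo < hi, got {band}")
    gate = Gate("singlets", "ratio_band", ("FSC-A", "FSC-H"), {"band": (lo, hi)})
    return apply_gate(table, gate)


def viability_mask(table: EventTable, dye_channel: str = VIABILITY_CHANNEL,
                   threshold: float | None = None,
                   fallback: float = DEFAULT_SETTINGS["viability_fallback"]) -> np.ndarray:
    """Live events are dye-negative: dye strictly below the threshold.

    With ``threshold=None`` the threshold is placed at the KDE valley between
    the live and dead modes, falling back to ``fallback`` (logged) when the
    dye distribution is unimodal.
    """
    gate = Gate("live", "threshold", (dye_channel,),
                {"value": threshold, "direction": "<", "fallback": fallback})
    return apply_gate(table, gate)


# ---------------------------------------------------------------------------
# strategy tree


@dataclass(frozen=True)
class GatingStrategy:
    """Rooted tree of gates: list of ``(gate, parent_name)`` with ``None`` as root."""

    nodes: tuple[tuple[Gate, str | None], ...]

    def __post_init__(self):
        names = [g.name for g, _ in self.nodes]
        if len(set(names)) != len(names):
            raise ValueError("gate names must be unique")
        seen = set()
        for gate, parent in self.nodes:
            if parent is not None and parent not in seen:
                raise ValueError(
                    f"node {gate.name!r}: parent {parent!r} undefined or defined later")
            seen.add(gate.name)
        object.__setattr__(self, "nodes", tuple(self.nodes))

    @property
    def names(self) -> list[str]:
        return [g.name for g, _ in self.nodes]

    def to_dict(self) -> list[dict]:
        return [{"name": g.name, "kind": g.kind, "channels": list(g.channels),
                 "params": g.params, "parent": parent}
                for g, parent in self.nodes]

    @classmethod
    def from_dict(cls, nodes: Sequence[Mapping]) -> "GatingStrategy":
        return cls(tuple(
            (Gate(d["name"], d["kind"], tuple(d["channels"]), dict(d.get("params", {}))),
             d.get("parent"))
            for d in nodes))


@dataclass
class StrategyResult:
    """Masks per node plus the population summary table."""

    masks: dict[str, np.ndarray]
    table: pd.DataFrame


def run_strategy(table: EventTable, strategy: GatingStrategy,
                 metadata: SampleMetadata | None = None) -> StrategyResult:
    """Execute the gate tree and tabulate events, % of parent and % of total."""
    masks: dict[str, np.ndarray] = {}
    rows = []
    total = table.n_events
    for gate, parent in strategy.nodes:
        parent_mask = (masks[parent] if parent is not None
                       else np.ones(total, dtype=bool))
        mask = apply_gate(table, gate, parent_mask)
        masks[gate.name] = mask
        n, n_parent = int(mask.sum()), int(parent_mask.sum())
        rows.append({
            "population": gate.name,
            "parent": parent,
            "events": n,
            "pct_of_parent": round(100.0 * n / n_parent, 1) if n_parent else 0.0,
            "pct_of_total": round(100.0 * n / total, 1) if total else 0.0,
        })
    return StrategyResult(masks, pd.DataFrame(rows))


def default_strategy(settings: Mapping | None = None,
                     viability_threshold: float | None = None,
                     positivity: Mapping[str, float] | None = None) -> GatingStrategy:
    """The standard microglia identification tree.

    beads | cells -> singlets -> live -> CD45+ -> CD11b/c+ -> microglia.
    ``positivity`` overrides per-marker thresholds; ``viability_threshold``
    pins the dye threshold instead of valley-finding.
    """
    s = dict(DEFAULT_SETTINGS)
    if settings:
        s.update(settings)
    pos = {m: s["positivity_threshold"] for m in IDENTIFICATION_MARKERS}
    if positivity:
        pos.update(positivity)
    cd45, cd11, p2y12 = IDENTIFICATION_MARKERS
    nodes = [
        (Gate("beads", "threshold", (BEAD_CHANNEL,),
              {"value": s["bead_threshold"], "direction": ">"}), None),
        (Gate("cells", "rectangle", ("FSC-A", "SSC-A"),
              {"x": s["cells_fsc"], "y": s["cells_ssc"]}), None),
        (Gate("singlets", "ratio_band", ("FSC-A", "FSC-H"),
              {"band": s["singlet_band"]}), "cells"),
        (Gate("live", "threshold", (VIABILITY_CHANNEL,),
              {"value": viability_threshold, "direction": "<",
               "fallback": s["viability_fallback"]}), "singlets"),
        (Gate("cd45_pos", "threshold", (cd45,),
              {"value": pos[cd45], "direction": ">"}), "live"),
        (Gate("cd11_pos", "threshold", (cd11,),
              {"value": pos[cd11], "direction": ">"}), "cd45_pos"),
        (Gate("microglia", "threshold", (p2y12,),
              {"value": pos[p2y12], "direction": ">"}), "cd11_pos"),
    ]
    return GatingStrategy(tuple(nodes))


def classify_events(result: StrategyResult) -> np.ndarray:
    """Map default-strategy masks to one predicted population label per event.

    Precedence: bead, then (outside cells) debris, (non-singlet) doublet,
    (dye-positive) dead, then microglia vs other live myeloid (infiltrate).
    """
    m = result.masks
    required = ("beads", "cells", "singlets", "live", "microglia")
    for k in required:
        if k not in m:
            raise KeyError(f"strategy result lacks node {k!r}")
    n = m["cells"].shape[0]
    labels = np.full(n, "infiltrate", dtype=object)
    labels[m["microglia"]] = "microglia"
    labels[m["singlets"] & ~m["live"]] = "dead"
    labels[m["cells"] & ~m["singlets"]] = "doublet"
    labels[~m["cells"] & ~m["beads"]] = "debris"
    labels[m["beads"]] = "bead"
    return labels


def recovery_scores(predicted: np.ndarray, truth: np.ndarray) -> pd.DataFrame:
    """Per-population precision/recall/F1 of predicted vs ground-truth labels."""
    rows = []
    for lab in np.unique(truth):
        tp = int(((predicted == lab) & (truth == lab)).sum())
        fp = int(((predicted == lab) & (truth != lab)).sum())
        fn = int(((predicted != lab) & (truth == lab)).sum())
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        f1 = (2 * precision * recall / (precision + recall)
              if precision + recall else 0.0)
        rows.append({"population": lab, "precision": precision,
                     "recall": recall, "f1": f1, "support": tp + fn})
    return pd.DataFrame(rows).set_index("population")


# ---------------------------------------------------------------------------
# absolute quantification


@dataclass(frozen=True)
class AbsoluteCountResult:
    population: str
    events: int
    cells_per_mg: float
    percent_of_parent: float | None = None


def absolute_count(events: int, bead_events: int, beads_added: int,
                   tissue_mass_mg: float, population: str = "microglia",
                   percent_of_parent: float | None = None) -> AbsoluteCountResult:
    """Bead-ratio absolute count: ``events * (beads_added / bead_events) / mass``."""
    if bead_events <= 0:
        raise ValueError("bead_events must be positive for quantification")
    if tissue_mass_mg <= 0:
        raise ValueError("tissue_mass_mg must be positive")
    if events < 0 or beads_added < 0:
        raise ValueError("counts must be non-negative")
    cells_per_mg = events * (beads_added / bead_events) / tissue_mass_mg
    return AbsoluteCountResult(population, int(events), float(cells_per_mg),
                               percent_of_parent)


def fold_change_vs_reference(counts: Mapping, reference: Sequence,
                             target=("CCI", "ipsilateral")) -> float:
    """Ratio of the target condition's count to the mean over reference conditions."""
    reference = list(reference)
    if not reference:
        raise ValueError("reference condition set must be non-empty")
    missing = [c for c in list(reference) + [target] if c not in counts]
    if missing:
        raise KeyError(f"missing counts for conditions: {missing}")
    ref_mean = float(np.mean([counts[c] for c in reference]))
    if ref_mean == 0:
        raise ZeroDivisionError("reference mean count is zero")
    return float(counts[target]) / ref_mean
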