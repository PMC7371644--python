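"""Synthetic cytometry cohorts with ground truth.

Generates per-sample event mixtures that mimic a CD11b/c-enriched rat brain
single-cell suspension acquired on a conventional cytometer: debris, doublet
aggregates, dead cells, microglia, infiltrating myeloid cells and counting
beads. Fluorescence is modelled as multivariate normal on the arcsinh scale
(a Gaussian copula with normal marginals, so injected inter-marker
correlations are exact) and mapped back to raw intensities; scatter channels
are linear-scale normals. Injury effects enter as a microglia-fraction
multiplier, signed per-channel location shifts, and a condition-specific
inter-marker correlation matrix for the microglia population.

Every sample is emitted together with a :class:`GroundTruthManifest` holding
the per-event population labels and realized counts, which downstream tests
use as the oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .flow_io import EventTable, SampleMetadata, inverse_transform_intensities
from .panels import (
    BEAD_CHANNEL,
    CONDITIONS,
    VIABILITY_CHANNEL,
    panel_channels,
    panel_markers,
)

__all__ = [
    "PopulationSpec",
    "EffectModel",
    "GroundTruthManifest",
    "generate_sample",
    "generate_cohort",
    "default_populations",
    "default_effects",
    "zero_effects",
    "default_cohort",
    "null_cohort",
    "DEFAULT_COFACTOR",
]

POPULATION_LABELS = ("debris", "doublet", "dead", "microglia", "infiltrate", "bead")

DEFAULT_COFACTOR = 150.0

#: FSC pulse height/area ratio of true single cells: N(0.97, 0.02).
SINGLET_RATIO_MEAN = 0.97
SINGLET_RATIO_SD = 0.02

#: Per-animal random intercept on population locations, in arcsinh units for
#: fluorescence (equivalently lognormal multiplicative on raw intensities) and
#: lognormal multiplicative on linear scatter. Kept small enough that the
#: intercept variance stays negligible against event-level sampling error at
#: the pooled event counts the event-unit tests operate on (see methods note);
#: raise it to emulate stronger between-animal biology, at the cost of
#: anticonservative pooled-event tests.
DEFAULT_ANIMAL_SIGMA = 0.005


@dataclass(frozen=True)
class PopulationSpec:
    """Location/scale model of one event population.

    ``channel_locations``/``channel_scales`` are on the generation scale:
    arcsinh units for fluorescence (dye, markers, bead flag), raw linear units
    for scatter. FSC-H is derived from FSC-A through the singlet pulse-ratio
    model and must not be specified directly. The ``doublet`` population is
    constructed from pairwise sums of singlet events and carries no locations.
    """

    name: str
    base_fraction: float
    channel_locations: dict[str, float] = field(default_factory=dict)
    channel_scales: dict[str, float] = field(default_factory=dict)
    is_viable: bool = True
    is_singlet: bool = True

    def __post_init__(self):
        if self.name not in POPULATION_LABELS:
            raise ValueError(
                f"unknown population {self.name!r}; expected one of {POPULATION_LABELS}")
        if not 0.0 <= self.base_fraction <= 1.0:
            raise ValueError(f"base_fraction must be in [0,1], got {self.base_fraction}")
        for ch, sc in self.channel_scales.items():
            if not sc > 0:
                raise ValueError(f"{self.name}: scale for {ch!r} must be > 0, got {sc}")
        if set(self.channel_scales) != set(self.channel_locations):
            raise ValueError(f"{self.name}: locations and scales name different channels")
        if "FSC-H" in self.channel_locations:
            raise ValueError("FSC-H is derived from FSC-A; do not specify it")


@dataclass(frozen=True)
class EffectModel:
    """Condition-dependent injury effect applied to the microglia population.

    ``channel_shifts`` are additive on the generation scale of each channel
    (arcsinh units for fluorescence, raw units for scatter).
    ``correlation_matrix`` is a marker-labelled DataFrame used as the Gaussian
    copula target for the microglia population.
    """

    condition: tuple[str, str]
    microglia_fraction_multiplier: float = 1.0
    channel_shifts: dict[str, float] = field(default_factory=dict)
    correlation_matrix: pd.DataFrame | None = None

    def __post_init__(self):
        if not self.microglia_fraction_multiplier > 0:
            raise ValueError("microglia_fraction_multiplier must be positive")
        if self.correlation_matrix is not None:
            validate_correlation(self.correlation_matrix)
        group = self.condition[0]
        if group == "sham":
            if self.microglia_fraction_multiplier != 1.0 or any(
                    v != 0 for v in self.channel_shifts.values()):
                raise ValueError("sham conditions must have unit multiplier and zero shifts")


def validate_correlation(corr: pd.DataFrame, tol: float = 1e-8) -> None:
    """Reject matrices that are not valid correlation matrices (unit diagonal,
    symmetric, entries in [-1,1], PSD within ``tol``)."""
    m = corr.to_numpy(dtype=float)
    if m.shape[0] != m.shape[1] or list(corr.index) != list(corr.columns):
        raise ValueError("correlation matrix must be square with matching labels")
    if not np.allclose(np.diag(m), 1.0):
        raise ValueError("correlation matrix diagonal must be 1")
    if not np.allclose(m, m.T):
        raise ValueError("correlation matrix must be symmetric")
    if np.any(np.abs(m) > 1 + 1e-12):
        raise ValueError("correlation entries must lie in [-1, 1]")
    w = np.linalg.eigvalsh(m)
    if w.min() < -tol:
        raise ValueError(
            f"correlation matrix is not positive semi-definite (min eigenvalue {w.min():.3g})")


@dataclass(frozen=True)
class GroundTruthManifest:
    """Per-event population labels plus realized counts — the test oracle."""

    labels: np.ndarray
    counts: dict[str, int]
    effect: EffectModel
    seed: int | None

    def __post_init__(self):
        labels = np.asarray(self.labels)
        realized = {lab: int((labels == lab).sum()) for lab in np.unique(labels)}
        for k, v in self.counts.items():
            if realized.get(k, 0) != v:
                raise ValueError(
                    f"manifest count for {k!r} ({v}) does not match labels ({realized.get(k, 0)})")
        if sum(self.counts.values()) != labels.size:
            raise ValueError("manifest counts do not sum to the number of events")
        object.__setattr__(self, "labels", labels)


# ---------------------------------------------------------------------------
# defaults: the study conditions


def _marker_locations(panel: str, overrides: Mapping[str, float]) -> dict[str, float]:
    return {m: overrides[m] for m in panel_markers(panel)}


def default_populations(panel: str) -> list[PopulationSpec]:
    """Default sham-brain population mixture for one staining panel.

    Fractions reflect a CD11b/c-enriched suspension in which resident
    microglia are a small minority at baseline (5%), other live myeloid cells
    dominate, and a realistic burden of debris, aggregates and dead cells
    survives tissue dissociation.
    """
    markers = panel_markers(panel)
    lo = 0.5  # arcsinh location of an unstained/negative channel
    microglia_loc = {"CD45": 2.8, "CD11b/c": 2.8, "P2y12": 3.0,
                     "CD32": 2.0, "CD86": 2.2, "CD200R": 2.0, "RT1B": 2.4, "CD163": 1.8}
    infiltrate_loc = {"CD45": 3.2, "CD11b/c": 2.8, "P2y12": 0.3,
                      "CD32": 1.6, "CD86": 1.8, "CD200R": 1.2, "RT1B": 1.8, "CD163": 1.4}
    # infiltrating myeloid cells are P2y12-negative: unstained-channel spread
    infiltrate_sc = {"P2y12": 0.3}
    dead_loc = {m: 2.0 for m in microglia_loc}

    def spec(name, frac, fsc, ssc, fsc_sc, ssc_sc, dye, marker_locs,
             marker_sc=0.5, marker_scales=None, viable=True):
        locs = {"FSC-A": fsc, "SSC-A": ssc, VIABILITY_CHANNEL: dye,
                BEAD_CHANNEL: 0.0}
        scales = {"FSC-A": fsc_sc, "SSC-A": ssc_sc, VIABILITY_CHANNEL: 0.3,
                  BEAD_CHANNEL: 0.05}
        for m in markers:
            locs[m] = marker_locs[m]
            scales[m] = (marker_scales or {}).get(m, marker_sc)
        return PopulationSpec(name, frac, locs, scales, is_viable=viable)

    return [
        spec("debris", 0.25, 1.2e4, 1.0e4, 4.0e3, 3.0e3, lo, {m: 0.3 for m in markers}),
        PopulationSpec("doublet", 0.06, {}, {}, is_singlet=False),
        spec("dead", 0.14, 0.95e5, 4.5e4, 1.5e4, 1.0e4, 3.5,
             _marker_locations(panel, dead_loc), viable=False),
        spec("microglia", 0.05, 1.0e5, 5.0e4, 1.5e4, 1.0e4, lo,
             _marker_locations(panel, microglia_loc)),
        spec("infiltrate", 0.50, 0.9e5, 5.5e4, 1.5e4, 1.0e4, lo,
             _marker_locations(panel, infiltrate_loc),
             marker_scales={k: v for k, v in infiltrate_sc.items()
                            if k in markers}),
        PopulationSpec(
            "bead", 0.0,
            {"FSC-A": 1.5e4, "SSC-A": 8.0e4, VIABILITY_CHANNEL: 0.5,
             BEAD_CHANNEL: 4.0, **{m: 2.5 for m in markers}},
            {"FSC-A": 1.0e3, "SSC-A": 2.0e3, VIABILITY_CHANNEL: 0.3,
             BEAD_CHANNEL: 0.05, **{m: 0.1 for m in markers}},
        ),
    ]


#: Default injury shifts (arcsinh units for markers, raw units for scatter)
#: for the injured ipsilateral hemisphere. Directions follow the observed
#: activation pattern: size/granularity up, CD45/CD11b/c up, P2y12 down,
#: CD32/CD163 up, CD86/RT1B down, CD200R unchanged. Magnitudes are calibrated
#: so that a linear classifier on panel markers lands in the 0.75-0.90 AUC
#: band (normal-theory Mahalanobis calculation, see docs/methods.md).
DEFAULT_IPSI_SHIFTS = {
    "FSC-A": 3.0e4,
    "SSC-A": 2.0e4,
    "CD45": 0.25,
    "CD11b/c": 0.25,
    "P2y12": -0.30,
    "CD32": 0.40,
    "CD86": -0.25,
    "CD200R": 0.0,
    "RT1B": -0.25,
    "CD163": 0.30,
}

#: Pairwise inter-marker correlation among microglia: modest at baseline,
#: broadly elevated after injury.
DEFAULT_RHO_SHAM = 0.10
DEFAULT_RHO_IPSI = 0.45

#: Microglia enrichment of the injured hemisphere relative to baseline.
DEFAULT_MULTIPLIER = 16.0


def equicorrelation(markers: Sequence[str], rho: float) -> pd.DataFrame:
    """Equicorrelation matrix over ``markers`` (PSD for rho > -1/(m-1))."""
    m = len(markers)
    mat = np.full((m, m), float(rho))
    np.fill_diagonal(mat, 1.0)
    return pd.DataFrame(mat, index=list(markers), columns=list(markers))


def default_effects(panel: str) -> dict[tuple[str, str], EffectModel]:
    """Default condition -> effect mapping for one panel.

    Sham conditions are strict nulls. The injured contralateral hemisphere is
    also modelled as null by default (its real-data changes are mild and a
    null contralateral makes the near-random contralateral discrimination
    reproducible); it is fully configurable.
    """
    markers = panel_markers(panel)
    shifts = {ch: v for ch, v in DEFAULT_IPSI_SHIFTS.items()
              if ch in markers or ch in ("FSC-A", "SSC-A")}
    effects = {}
    for cond in CONDITIONS:
        if cond == ("CCI", "ipsilateral"):
            effects[cond] = EffectModel(
                cond, DEFAULT_MULTIPLIER, shifts,
                equicorrelation(markers, DEFAULT_RHO_IPSI))
        else:
            effects[cond] = EffectModel(
                cond, 1.0, {}, equicorrelation(markers, DEFAULT_RHO_SHAM))
    return effects


def zero_effects(panel: str) -> dict[tuple[str, str], EffectModel]:
    """All-null effects (identical correlation everywhere): the zero-effect cohort."""
    markers = panel_markers(panel)
    return {cond: EffectModel(cond, 1.0, {}, equicorrelation(markers, DEFAULT_RHO_SHAM))
            for cond in CONDITIONS}


# ---------------------------------------------------------------------------
# sample generation


def _effective_fractions(populations: Sequence[PopulationSpec],
                         multiplier: float) -> np.ndarray:
    """Scale the microglia fraction by ``multiplier`` and rescale the other
    populations to keep the total at 1, so the realized microglia event-count
    ratio between conditions equals the multiplier at fixed ``n_events``."""
    fracs = np.array([p.base_fraction for p in populations], dtype=float)
    if abs(fracs.sum() - 1.0) > 1e-9:
        raise ValueError(f"population fractions must sum to 1, got {fracs.sum():.6f}")
    names = [p.name for p in populations]
    i = names.index("microglia")
    f = fracs[i]
    new_f = f * multiplier
    if new_f > 1.0:
        raise ValueError(
            f"microglia fraction {f} x multiplier {multiplier} exceeds 1")
    if f >= 1.0:
        return fracs
    out = fracs * (1.0 - new_f) / (1.0 - f)
    out[i] = new_f
    return out


def _jittered(loc: float, channel: str, jitter: Mapping[str, float] | None) -> float:
    if not jitter or channel not in jitter:
        return loc
    e = jitter[channel]
    if channel in ("FSC-A", "SSC-A"):
        return loc * float(np.exp(e))  # lognormal multiplicative on linear scatter
    return loc + e  # additive on arcsinh scale == lognormal on raw intensity


def _draw_population(spec: PopulationSpec, n: int, channels: Sequence[str],
                     effect: EffectModel | None, rng: np.random.Generator,
                     jitter: Mapping[str, float] | None) -> np.ndarray:
    """Draw ``n`` events of one singlet population on the generation scale
    (columns ordered as ``channels``; FSC-H column left as NaN)."""
    out = np.full((n, len(channels)), np.nan)
    corr = effect.correlation_matrix if effect is not None else None
    corr_markers = list(corr.columns) if corr is not None else []
    shifts = effect.channel_shifts if effect is not None else {}

    if corr_markers and all(m in spec.channel_locations for m in corr_markers):
        locs = np.array([_jittered(spec.channel_locations[m], m, jitter)
                         + shifts.get(m, 0.0) for m in corr_markers])
        scales = np.array([spec.channel_scales[m] for m in corr_markers])
        cov = corr.to_numpy() * np.outer(scales, scales)
        draws = rng.multivariate_normal(locs, cov, size=n, method="svd")
        for j, m in enumerate(corr_markers):
            out[:, channels.index(m)] = draws[:, j]
    else:
        corr_markers = []

    for ch, loc in spec.channel_locations.items():
        if ch in corr_markers:
            continue
        loc = _jittered(loc, ch, jitter) + shifts.get(ch, 0.0)
        out[:, channels.index(ch)] = rng.normal(loc, spec.channel_scales[ch], size=n)
    return out


def _to_raw(gen_scale: np.ndarray, channels: Sequence[str], cofactor: float) -> np.ndarray:
    raw = gen_scale.copy()
    for j, ch in enumerate(channels):
        if ch not in ("FSC-A", "FSC-H", "SSC-A"):
            raw[:, j] = inverse_transform_intensities(gen_scale[:, j], cofactor)
    return raw


def generate_sample(
    populations: Sequence[PopulationSpec],
    effect: EffectModel,
    n_events: int,
    tissue_mass_mg: float = 50.0,
    beads_added: int = 1000,
    seed: int | np.random.Generator = 0,
    cofactor: float = DEFAULT_COFACTOR,
    bead_recovery: float = 1.0,
    _jitter: Mapping[str, float] | None = None,
) -> tuple[EventTable, GroundTruthManifest]:
    """Generate one raw-scale sample plus its ground-truth manifest.

    ``n_events`` cell-stream events are split multinomially across the
    non-bead populations (with the effect's microglia multiplier applied);
    bead events are appended according to the recovery model (all
    ``beads_added`` recovered by default). Identical inputs and seed yield
    bit-identical output.
    """
    if n_events < 100:
        raise ValueError("n_events must be at least 100")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seed_val = None if isinstance(seed, np.random.Generator) else int(seed)

    by_name = {p.name: p for p in populations}
    cell_pops = [p for p in populations if p.name != "bead"]
    fracs = _effective_fractions(cell_pops, effect.microglia_fraction_multiplier)

    # channel order: scatter first, FSC-H derived, then the union of
    # fluorescence channels in spec order
    ref = by_name.get("microglia") or cell_pops[0]
    fluor = [c for c in ref.channel_locations if c not in ("FSC-A", "SSC-A")]
    channels = ["FSC-A", "FSC-H", "SSC-A"] + fluor

    counts = rng.multinomial(n_events, fracs)
    blocks, labels = [], []

    singlet_pool_specs = [p for p in cell_pops if p.name not in ("debris", "doublet")]
    n_doublets = counts[[p.name for p in cell_pops].index("doublet")] \
        if "doublet" in by_name else 0

    for spec, n in zip(cell_pops, counts):
        if n == 0 or spec.name == "doublet":
            continue
        eff = effect if spec.name == "microglia" else None
        gen = _draw_population(spec, int(n), channels, eff, rng, _jitter)
        ratio = rng.normal(SINGLET_RATIO_MEAN, SINGLET_RATIO_SD, size=int(n))
        gen[:, 1] = gen[:, 0] * ratio  # FSC-H from FSC-A
        blocks.append(_to_raw(gen, channels, cofactor))
        labels.append(np.full(int(n), spec.name, dtype=object))

    if n_doublets > 0:
        # doublets: raw-scale sums of two random live singlet events
        # (FSC-A and fluorescence add; FSC-H keeps the larger pulse height)
        weights = np.array([fracs[[p.name for p in cell_pops].index(s.name)]
                            for s in singlet_pool_specs])
        weights = weights / weights.sum()
        members = rng.choice(len(singlet_pool_specs), size=2 * int(n_doublets), p=weights)
        parts = []
        for k, spec in enumerate(singlet_pool_specs):
            n_k = int((members == k).sum())
            if n_k == 0:
                continue
            eff = effect if spec.name == "microglia" else None
            gen = _draw_population(spec, n_k, channels, eff, rng, _jitter)
            ratio = rng.normal(SINGLET_RATIO_MEAN, SINGLET_RATIO_SD, size=n_k)
            gen[:, 1] = gen[:, 0] * ratio
            parts.append(_to_raw(gen, channels, cofactor))
        pool = np.concatenate(parts, axis=0)
        pool = pool[rng.permutation(pool.shape[0])]
        a, b = pool[0::2], pool[1::2]
        doublet = a + b
        doublet[:, 1] = np.maximum(a[:, 1], b[:, 1])
        blocks.append(doublet)
        labels.append(np.full(int(n_doublets), "doublet", dtype=object))

    if beads_added > 0 and "bead" in by_name:
        n_beads = (int(beads_added) if bead_recovery >= 1.0
                   else int(rng.binomial(int(beads_added), bead_recovery)))
        if n_beads > 0:
            gen = _draw_population(by_name["bead"], n_beads, channels, None, rng, _jitter)
            ratio = rng.normal(SINGLET_RATIO_MEAN, SINGLET_RATIO_SD, size=n_beads)
            gen[:, 1] = gen[:, 0] * ratio
            blocks.append(_to_raw(gen, channels, cofactor))
            labels.append(np.full(n_beads, "bead", dtype=object))

    values = np.concatenate(blocks, axis=0)
    all_labels = np.concatenate(labels)
    perm = rng.permutation(values.shape[0])
    values, all_labels = values[perm], all_labels[perm]

    table = EventTable(values, tuple(channels))
    realized = {lab: int((all_labels == lab).sum()) for lab in np.unique(all_labels)}
    manifest = GroundTruthManifest(all_labels, realized, effect, seed_val)
    return table, manifest


# ---------------------------------------------------------------------------
# cohort generation


def generate_cohort(
    design: Mapping[tuple[str, str], tuple[int, int]] | None = None,
    populations: Mapping[str, Sequence[PopulationSpec]] | None = None,
    effects: Mapping[str, Mapping[tuple[str, str], EffectModel]] | None = None,
    panels: Sequence[str] = ("M1", "M2"),
    seed: int = 0,
    tissue_mass_mg: float = 50.0,
    beads_added: int = 1000,
    animal_sigma: float = DEFAULT_ANIMAL_SIGMA,
    cofactor: float = DEFAULT_COFACTOR,
) -> list[tuple[EventTable, SampleMetadata, GroundTruthManifest]]:
    """Generate a full 2x2 cohort: one sample per animal x hemisphere x panel.

    ``design`` maps each (group, hemisphere) condition to
    ``(n_animals, n_events)``; the default is the study design of 3 animals
    per group and 10,000 cell-stream events per sample. Per-animal seeds and
    random intercepts are derived deterministically from the master seed, and
    both hemispheres/panels of an animal share its intercept.
    """
    if design is None:
        design = {cond: (3, 10_000) for cond in CONDITIONS}
    if not design:
        raise ValueError("empty cohort design")
    missing = [c for c in CONDITIONS if c not in design]
    if missing:
        raise ValueError(f"design must cover the 2x2 condition grid; missing {missing}")
    if populations is None:
        populations = {p: default_populations(p) for p in panels}
    if effects is None:
        effects = {p: default_effects(p) for p in panels}

    all_channels = sorted({ch for p in panels for ch in panel_channels(p)})
    ss = np.random.SeedSequence(seed)
    jitter_root, sample_root = ss.spawn(2)

    samples = []
    for group in ("sham", "CCI"):
        n_animals = design[(group, "ipsilateral")][0]
        for a in range(n_animals):
            animal_id = f"{group}-{a + 1}"
            jrng = np.random.default_rng(
                jitter_root.spawn(1)[0]) if animal_sigma > 0 else None
            jitter = ({ch: jrng.normal(0.0, animal_sigma) for ch in all_channels}
                      if jrng is not None else None)
            for hemisphere in ("ipsilateral", "contralateral"):
                cond = (group, hemisphere)
                _, n_events = design[cond]
                for panel in panels:
                    srng = np.random.default_rng(sample_root.spawn(1)[0])
                    table, manifest = generate_sample(
                        populations[panel], effects[panel][cond], n_events,
                        tissue_mass_mg=tissue_mass_mg, beads_added=beads_added,
                        seed=srng, cofactor=cofactor, _jitter=jitter)
                    meta = SampleMetadata(animal_id, group, hemisphere, panel,
                                          tissue_mass_mg, beads_added)
                    samples.append((table, meta, manifest))
    return samples


def default_cohort(seed: int = 0, n_events: int = 10_000, **kwargs):
    """The default injury cohort: the standard 3-animals-per-group study design."""
    design = {cond: (3, n_events) for cond in CONDITIONS}
    return generate_cohort(design=design, seed=seed, **kwargs)


def null_cohort(seed: int = 0, n_events: int = 10_000, panels=("M1", "M2"), **kwargs):
    """Zero-effect cohort: all effects null and no animal intercepts.

    Used for type-I calibration of the event-pooled tests, which assume
    exchangeable events within a condition.
    """
    design = {cond: (3, n_events) for cond in CONDITIONS}
    effects = {p: zero_effects(p) for p in panels}
    return generate_cohort(design=design, effects=effects, panels=panels,
                           seed=seed, animal_sigma=0.0, **kwargs)
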