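"""Shared cohort plumbing: transform each sample, gate it, and pool gated
microglia events per condition for the downstream statistics."""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from .flow_io import EventTable, SampleMetadata, transform_intensities
from .gating import GatingStrategy, default_strategy, run_strategy
from .panels import condition_label, panel_markers

__all__ = ["gate_sample", "pooled_microglia", "screen_parameters"]


def screen_parameters(panel: str) -> list[str]:
    """Parameters screened for a panel: scatter plus all panel markers."""
    return ["FSC-A", "SSC-A", *panel_markers(panel)]


def gate_sample(table: EventTable, metadata: SampleMetadata,
                strategy: GatingStrategy | None = None,
                cofactor: float = 150.0):
    """Arcsinh-transform a raw sample and run the gating strategy on it.

    Returns ``(transformed_table, strategy_result)``. Tables already
    transformed are gated as-is.
    """
    if table.transform_state != "transformed":
        table = transform_intensities(table, "arcsinh", cofactor)
    strategy = strategy or default_strategy()
    return table, run_strategy(table, strategy, metadata)


def pooled_microglia(samples: Sequence, strategy: GatingStrategy | None = None,
                     cofactor: float = 150.0,
                     node: str = "microglia") -> pd.DataFrame:
    """Pool gated microglia events of a cohort into one tidy frame.

    ``samples`` is a sequence of ``(EventTable, SampleMetadata, ...)`` tuples
    (any trailing ground-truth element is ignored). The result has one row per
    gated event with the analysis-scale parameter values plus ``panel``,
    ``group``, ``hemisphere``, ``animal_id`` and ``condition`` columns.
    """
    frames = []
    for sample in samples:
        table, meta = sample[0], sample[1]
        ttable, result = gate_sample(table, meta, strategy, cofactor)
        mask = result.masks[node]
        cols = screen_parameters(meta.panel)
        df = ttable.select(mask).to_dataframe()[cols]
        df["panel"] = meta.panel
        df["group"] = meta.group
        df["hemisphere"] = meta.hemisphere
        df["animal_id"] = meta.animal_id
        df["condition"] = condition_label(meta.group, meta.hemisphere)
        frames.append(df)
    if not frames:
        return pd.DataFrame()
    return pd.concat(frames, ignore_index=True)
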