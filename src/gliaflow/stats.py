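"""Per-marker phenotype statistics: MFI summaries, Mann-Whitney screening
with Benjamini-Hochberg FDR, and QQ distribution-shift curves.

The default statistical unit is the event: measurements of all animals in a
condition are pooled and cells are treated as independent observations,
mirroring common practice in cytometry bioinformatics. This pseudoreplicates
the n=3 biological design, so an animal-level mode (testing per-animal MFIs)
is provided as well; with three animals per group it has very little power
and is clearly labelled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .cohort import pooled_microglia, screen_parameters
from .panels import condition_label

log = logging.getLogger(__name__)

__all__ = [
    "compute_mfi",
    "mann_whitney_u",
    "bh_fdr",
    "marker_panel_screen",
    "animal_mfi_table",
    "qq_curve",
    "QQResult",
    "DEFAULT_COMPARISONS",
]

#: Injury-vs-sham comparisons within each hemisphere, the two test families.
DEFAULT_COMPARISONS = (
    (("CCI", "ipsilateral"), ("sham", "ipsilateral")),
    (("CCI", "contralateral"), ("sham", "contralateral")),
)

P_FLOOR = 1e-300  # underflow floor for reported p-values


def compute_mfi(values, statistic: str = "median") -> float:
    """Fluorescence-intensity summary of a gated population on one channel.

    ``median`` uses the midpoint convention for even n; ``mean`` is the
    arithmetic mean. Empty input is an error.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot summarize an empty intensity vector")
    if statistic == "median":
        return float(np.median(values))
    if statistic == "mean":
        return float(np.mean(values))
    raise ValueError(f"statistic must be 'median' or 'mean', got {statistic!r}")


def mann_whitney_u(x, y, alternative: str = "two-sided") -> tuple[float, float]:
    """Mann-Whitney U test; returns ``(U_x, p)``.

    U is computed via midranks (so ``U_x + U_y = n_x * n_y``). The p-value is
    exact by enumeration when ``min(n) <= 8`` and the pooled data has no
    ties, otherwise a normal approximation with tie and continuity correction
    is used. Constant pooled data yields p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        log.warning("all pooled observations identical; U test degenerate, p = 1")
        return float(x.size * y.size / 2.0), 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(x.size, y.size) <= 8 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative=alternative, method=method,
                           use_continuity=True)
    return float(res.statistic), float(max(res.pvalue, P_FLOOR))


def bh_fdr(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up procedure.

    Returns ``(rejected, adjusted_p)``. NaN p-values are never rejected and
    propagate NaN adjusted values.
    """
    p = np.asarray(p_values, dtype=float)
    if not 0 < q < 1:
        raise ValueError(f"q must be in (0,1), got {q}")
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p < 0) | (p > 1) & ~np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    ok = ~np.isnan(p)
    rejected = np.zeros(p.shape, dtype=bool)
    adjusted = np.full(p.shape, np.nan)
    if ok.any():
        rej, adj, _, _ = multipletests(p[ok], alpha=q, method="fdr_bh")
        rejected[ok], adjusted[ok] = rej, adj
    return rejected, adjusted


def marker_panel_screen(samples, q: float = 0.05, statistic: str = "median",
                        comparisons=DEFAULT_COMPARISONS, strategy=None,
                        cofactor: float = 150.0, unit: str = "events") -> pd.DataFrame:
    """Mann-Whitney marker screen over gated microglia, FDR within comparison.

    One row per (panel, parameter, comparison) with the U statistic, p-value,
    FDR-adjusted p at level ``q``, significance flag and direction (sign of
    the median difference, ``none`` when not significant). ``unit='animals'``
    switches to the per-animal MFI mode.

    All intensities are on the analysis scale: arcsinh for markers, linear
    for scatter (recorded in the ``scale`` column).
    """
    pooled = pooled_microglia(samples, strategy=strategy, cofactor=cofactor)
    rows = []
    for (cond_x, cond_y) in comparisons:
        comparison = f"{condition_label(*cond_x)} vs {condition_label(*cond_y)}"
        for panel in sorted(pooled["panel"].unique()) if len(pooled) else []:
            sub = pooled[pooled["panel"] == panel]
            gx = sub[(sub["group"] == cond_x[0]) & (sub["hemisphere"] == cond_x[1])]
            gy = sub[(sub["group"] == cond_y[0]) & (sub["hemisphere"] == cond_y[1])]
            for param in screen_parameters(panel):
                row = {
                    "panel": panel, "parameter": param, "comparison": comparison,
                    "scale": "linear" if param.startswith(("FSC", "SSC")) else "arcsinh",
                    "n_x": 0, "n_y": 0, "U": np.nan, "p": np.nan,
                    "mfi_x": np.nan, "mfi_y": np.nan,
                }
                if unit == "events":
                    x, y = gx[param].to_numpy(), gy[param].to_numpy()
                elif unit == "animals":
                    x = gx.groupby("animal_id")[param].agg(
                        "median" if statistic == "median" else "mean").to_numpy()
                    y = gy.groupby("animal_id")[param].agg(
                        "median" if statistic == "median" else "mean").to_numpy()
                else:
                    raise ValueError("unit must be 'events' or 'animals'")
                row["n_x"], row["n_y"] = x.size, y.size
                if x.size and y.size:
                    row["mfi_x"] = compute_mfi(x, statistic)
                    row["mfi_y"] = compute_mfi(y, statistic)
                    row["U"], row["p"] = mann_whitney_u(x, y, "two-sided")
                else:
                    log.warning("screen: empty group for %s %s (%s)",
                                panel, param, comparison)
                rows.append(row)
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    flags = np.zeros(len(out), dtype=bool)
    adjusted = np.full(len(out), np.nan)
    for comparison, idx in out.groupby("comparison").groups.items():
        rej, adj = bh_fdr(out.loc[idx, "p"].to_numpy(), q)
        flags[np.asarray(idx)] = rej
        adjusted[np.asarray(idx)] = adj
    out["p_adj"] = adjusted
    out["significant"] = flags
    diff = out["mfi_x"] - out["mfi_y"]
    out["direction"] = np.where(~out["significant"], "none",
                                np.where(diff > 0, "up", "down"))
    return out


def animal_mfi_table(samples, statistic: str = "median", strategy=None,
                     cofactor: float = 150.0) -> pd.DataFrame:
    """Per-animal, per-parameter MFI of gated microglia (for animal-level tests)."""
    pooled = pooled_microglia(samples, strategy=strategy, cofactor=cofactor)
    rows = []
    for (panel, animal, group, hemi), sub in pooled.groupby(
            ["panel", "animal_id", "group", "hemisphere"]):
        for param in screen_parameters(panel):
            rows.append({"panel": panel, "animal_id": animal, "group": group,
                         "hemisphere": hemi, "parameter": param,
                         "statistic": statistic,
                         "mfi": compute_mfi(sub[param].to_numpy(), statistic),
                         "n_events": len(sub)})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class QQResult:
    """Paired quantiles of two samples plus shift summaries.

    ``median_displacement`` is the median vertical distance of the curve from
    the identity line; ``signed_area`` integrates that displacement over the
    probe-probability grid, so matching distributions give 0 and a
    stochastically smaller ``y`` gives a negative area.
    """

    marker: str
    probs: np.ndarray
    x_quantiles: np.ndarray
    y_quantiles: np.ndarray
    median_displacement: float
    signed_area: float


def qq_curve(x, y, n_probes: int = 99, marker: str = "") -> QQResult:
    """Quantile-quantile curve of ``y`` against ``x`` on an even probe grid.

    Quantiles are taken at ``i/(n_probes+1)`` with linear interpolation
    between order statistics. Two samples from the same distribution put the
    curve on y = x.
    """
    if n_probes < 3:
        raise ValueError("n_probes must be at least 3")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    probs = np.arange(1, n_probes + 1) / (n_probes + 1)
    qx = np.quantile(x, probs)
    qy = np.quantile(y, probs)
    disp = qy - qx
    return QQResult(marker, probs, qx, qy,
                    float(np.median(disp)),
                    float(np.trapezoid(disp, probs)))
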