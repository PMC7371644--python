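"""Differential inter-marker correlation between injury and sham microglia.

Pearson correlations are computed across gated events; the injury-vs-sham
contrast for each marker pair is summarized by Cohen's q (the absolute
difference of Fisher-z transformed correlations) and tested with the
standard two-sample Fisher-z normal test for independent correlations,
one-sided for "injury correlation higher", with Benjamini-Hochberg control
across all pairs. The headline summary is the fraction of pairs whose injury
correlation is significantly higher than sham.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .stats import bh_fdr

__all__ = [
    "pearson_matrix",
    "fisher_z",
    "cohens_q",
    "correlation_difference_test",
    "differential_correlation_screen",
    "DifferentialCorrelationResult",
]


def pearson_matrix(events: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation matrix over event columns (markers).

    Requires at least 4 events. Zero-variance markers get NaN rows/columns
    (flagged here, excluded by the screen).
    """
    if len(events) < 4:
        raise ValueError("need at least 4 events for a correlation matrix")
    values = events.to_numpy(dtype=float)
    sd = values.std(axis=0)
    corr = np.full((values.shape[1],) * 2, np.nan)
    ok = sd > 0
    if ok.any():
        sub = np.corrcoef(values[:, ok], rowvar=False)
        corr[np.ix_(ok, ok)] = np.atleast_2d(sub)
    corr[np.diag_indices_from(corr)] = np.where(ok, 1.0, np.nan)
    return pd.DataFrame(np.clip(corr, -1.0, 1.0),
                        index=events.columns, columns=events.columns)


def fisher_z(rho, clamp: bool = False):
    """Fisher z-transform ``atanh(rho)``; |rho| >= 1 is an error unless
    ``clamp`` pulls it to 1 - 1e-12."""
    rho = np.asarray(rho, dtype=float)
    if np.any(np.abs(rho) >= 1):
        if not clamp:
            raise ValueError("fisher_z requires |rho| < 1 (set clamp=True to clip)")
        rho = np.clip(rho, -1 + 1e-12, 1 - 1e-12)
    out = np.arctanh(rho)
    return float(out) if out.ndim == 0 else out


def cohens_q(rho1: float, rho2: float) -> float:
    """Effect size for the difference of two correlations:
    ``|atanh(rho1) - atanh(rho2)|``."""
    return float(abs(fisher_z(rho1) - fisher_z(rho2)))


def correlation_difference_test(rho1: float, n1: int, rho2: float, n2: int,
                                alternative: str = "greater") -> tuple[float, float]:
    """Two-sample Fisher-z test of ``rho1`` (n1 events) vs ``rho2`` (n2 events).

    ``z = (atanh(rho1) - atanh(rho2)) / sqrt(1/(n1-3) + 1/(n2-3))`` referred
    to the standard normal; ``alternative='greater'`` tests rho1 > rho2.
    """
    if n1 <= 3 or n2 <= 3:
        raise ValueError("the Fisher-z test requires more than 3 events per group")
    se = np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    z = (fisher_z(rho1) - fisher_z(rho2)) / se
    if alternative == "greater":
        p = float(norm.sf(z))
    elif alternative == "two-sided":
        p = float(2 * norm.sf(abs(z)))
    else:
        raise ValueError("alternative must be 'greater' or 'two-sided'")
    return float(z), p


@dataclass
class DifferentialCorrelationResult:
    """Per-pair records, the significant-higher fraction, and the Cohen's q
    heat-map matrix (symmetric, zero diagonal)."""

    pairs: pd.DataFrame
    fraction_significantly_higher: float
    q_matrix: pd.DataFrame


def differential_correlation_screen(injury_events: pd.DataFrame,
                                    sham_events: pd.DataFrame,
                                    markers=None, q: float = 0.01,
                                    alternative: str = "greater",
                                    ) -> DifferentialCorrelationResult:
    """Screen all unordered marker pairs for injury correlations exceeding sham.

    Both inputs are event frames gated to microglia (one column per marker).
    BH control at level ``q`` is applied across all pairs of the comparison;
    a pair is flagged only when its injury correlation is higher than sham
    and FDR-significant. Pairs involving a zero-variance marker are excluded.
    """
    markers = list(markers) if markers is not None else list(injury_events.columns)
    if len(markers) < 2:
        raise ValueError("need at least 2 markers")
    if len(injury_events) < 4 or len(sham_events) < 4:
        raise ValueError("need at least 4 events in each condition")
    r_inj = pearson_matrix(injury_events[markers])
    r_sham = pearson_matrix(sham_events[markers])
    n1, n2 = len(injury_events), len(sham_events)

    rows = []
    for i, a in enumerate(markers):
        for b in markers[i + 1:]:
            ri, rs = float(r_inj.loc[a, b]), float(r_sham.loc[a, b])
            if np.isnan(ri) or np.isnan(rs):
                rows.append({"marker_a": a, "marker_b": b, "rho_injury": ri,
                             "rho_sham": rs, "n_injury": n1, "n_sham": n2,
                             "cohens_q": np.nan, "z": np.nan, "p": np.nan})
                continue
            ri_c, rs_c = np.clip([ri, rs], -1 + 1e-12, 1 - 1e-12)
            z, p = correlation_difference_test(ri_c, n1, rs_c, n2, alternative)
            rows.append({"marker_a": a, "marker_b": b, "rho_injury": ri,
                         "rho_sham": rs, "n_injury": n1, "n_sham": n2,
                         "cohens_q": cohens_q(ri_c, rs_c), "z": z, "p": p})
    pairs = pd.DataFrame(rows)
    rejected, adjusted = bh_fdr(pairs["p"].to_numpy(), q)
    pairs["p_adj"] = adjusted
    higher = pairs["rho_injury"] > pairs["rho_sham"]
    pairs["fdr_significant_higher"] = rejected & higher.to_numpy()
    fraction = float(pairs["fdr_significant_higher"].mean()) if len(pairs) else 0.0

    qmat = pd.DataFrame(0.0, index=markers, columns=markers)
    for row in pairs.itertuples():
        val = 0.0 if np.isnan(row.cohens_q) else row.cohens_q
        qmat.loc[row.marker_a, row.marker_b] = val
        qmat.loc[row.marker_b, row.marker_a] = val
    return DifferentialCorrelationResult(pairs, fraction, qmat)
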