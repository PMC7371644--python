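"""End-to-end orchestration under a single validated config.

Stages: ingest or generate samples -> compensate/transform -> gate ->
absolute quantification -> marker screen -> QQ -> differential correlation ->
classifier discrimination -> tSNE maps -> report. Every output carries a
provenance block (config hash, master seed, package version), and a rerun
with the same config and seed reproduces the report.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import pooled_microglia, screen_parameters
from .correlation import differential_correlation_screen
from .discriminate import (crossval_discriminate, downsample_events,
                           propensity_scores, tsne_embed)
from .flow_io import (SampleMetadata, SpilloverMatrix, apply_compensation,
                      read_events)
from .gating import absolute_count, default_strategy, fold_change_vs_reference
from .panels import CONDITIONS, IDENTIFICATION_MARKERS, PANELS, condition_label
from .stats import marker_panel_screen, qq_curve
from .cohort import gate_sample

log = logging.getLogger(__name__)

__all__ = ["DEFAULT_CONFIG", "validate_config", "run_pipeline", "RunReport",
           "load_config"]

DEFAULT_CONFIG: dict = {
    "mode": "synthetic",
    "seed": 0,
    "out_dir": "gliaflow_out",
    "cofactor": 150.0,
    "panels": {p: list(m) for p, m in PANELS.items()},
    "spillover": None,
    "synthetic": {"n_events": 10_000, "n_animals": 3, "beads_added": 1000,
                  "tissue_mass_mg": 50.0},
    "files": [],
    "gating": {},
    "stats": {"mfi_statistic": "median", "fdr_marker": 0.05,
              "fdr_correlation": 0.01, "qq_probes": 99},
    "classify": {"k": 10, "runs": 10, "max_events_per_class": 5000,
                 "classifiers": ["logistic", "random_forest", "rbf_svm"]},
    "tsne": {"enabled": True, "perplexity": 30.0, "n_iter": 1000,
             "n_per_sample": 5000},
}

STAGES = ("gate", "stats", "corr", "classify", "embed")


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        out[k] = _merge(base[k], v) if isinstance(v, dict) and isinstance(base.get(k), dict) else v
    return out


def load_config(path=None) -> dict:
    """Load a YAML/JSON config file merged over the defaults."""
    if path is None:
        return json.loads(json.dumps(DEFAULT_CONFIG))
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    return _merge(DEFAULT_CONFIG, data)


def validate_config(config: dict) -> dict:
    """Validate and default-fill a run config; raises with all errors listed."""
    cfg = _merge(DEFAULT_CONFIG, config or {})
    errors = []
    if cfg["mode"] not in ("synthetic", "files"):
        errors.append(f"mode must be 'synthetic' or 'files', got {cfg['mode']!r}")
    for key in ("fdr_marker", "fdr_correlation"):
        v = cfg["stats"][key]
        if not (isinstance(v, (int, float)) and 0 < v < 1):
            errors.append(f"stats.{key} must be in (0,1), got {v!r}")
    if cfg["stats"]["mfi_statistic"] not in ("median", "mean"):
        errors.append("stats.mfi_statistic must be 'median' or 'mean'")
    for panel, markers in cfg["panels"].items():
        missing = [m for m in IDENTIFICATION_MARKERS if m not in markers]
        if missing:
            errors.append(
                f"panel {panel} lacks identification markers {missing}")
    if cfg["mode"] == "files" and not cfg["files"]:
        errors.append("mode 'files' requires a non-empty files manifest")
    for clf in cfg["classify"]["classifiers"]:
        if clf not in ("logistic", "random_forest", "rbf_svm"):
            errors.append(f"unknown classifier {clf!r}")
    strategy = default_strategy(cfg["gating"] or None)
    known = set(sum(([*m] for m in cfg["panels"].values()), [])) | {
        "FSC-A", "FSC-H", "SSC-A", "Viability", "BeadID"}
    for gate, _parent in strategy.nodes:
        for ch in gate.channels:
            if ch not in known:
                errors.append(f"gate node {gate.name!r} uses unknown channel {ch!r}")
    if errors:
        raise ValueError("invalid config:\n  - " + "\n  - ".join(errors))
    return cfg


def config_hash(cfg: dict) -> str:
    """Hash of the analysis-relevant config (output destination excluded)."""
    payload = {k: v for k, v in cfg.items() if k != "out_dir"}
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:16]


@dataclass
class RunReport:
    provenance: dict
    population_table: pd.DataFrame
    absolute_counts: pd.DataFrame
    fold_change: float | None
    marker_screen: pd.DataFrame
    qq_summaries: pd.DataFrame
    correlation: dict = field(default_factory=dict)
    classifiers: pd.DataFrame | None = None
    propensity_summary: pd.DataFrame | None = None
    embeddings: dict = field(default_factory=dict)

    def summary(self) -> dict:
        out = {"provenance": self.provenance,
               "fold_change_cci_ipsi_vs_reference": self.fold_change,
               "n_samples": int(self.population_table["sample"].nunique())
               if len(self.population_table) else 0}
        if self.correlation:
            out["fraction_significantly_higher"] = {
                k: v.fraction_significantly_higher for k, v in self.correlation.items()}
        if self.classifiers is not None and len(self.classifiers):
            out["auc"] = {
                f"{r.panel}/{r.comparison}/{r.classifier}": r.auc_mean
                for r in self.classifiers.itertuples()}
        return out


def _load_samples(cfg: dict):
    if cfg["mode"] == "synthetic":
        syn = cfg["synthetic"]
        design = {c: (syn["n_animals"], syn["n_events"]) for c in CONDITIONS}
        from .synthetic import generate_cohort
        samples = generate_cohort(
            design=design, seed=cfg["seed"],
            tissue_mass_mg=syn["tissue_mass_mg"], beads_added=syn["beads_added"],
            cofactor=cfg["cofactor"])
        return [(t, m) for t, m, _ in samples]
    samples = []
    for entry in cfg["files"]:
        table, _ = read_events(entry["path"], entry.get("format"))
        meta = SampleMetadata(entry["animal_id"], entry["group"],
                              entry["hemisphere"], entry["panel"],
                              entry["tissue_mass_mg"], entry["beads_added"])
        samples.append((table, meta))
    return samples


def run_pipeline(config: dict | None = None, stages=STAGES,
                 write: bool = True) -> RunReport:
    """Run the configured analysis end to end and (optionally) write outputs."""
    cfg = validate_config(config or {})
    out_dir = Path(cfg["out_dir"])
    provenance = {"config_hash": config_hash(cfg), "seed": cfg["seed"],
                  "gliaflow_version": __version__}
    ss = np.random.SeedSequence(cfg["seed"])
    stage_seeds = {name: int(s.generate_state(1)[0] % (2**31 - 1))
                   for name, s in zip(("classify", "embed"), ss.spawn(2))}

    def _stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - annotate and re-raise
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc

    samples = _stage("ingest", _load_samples, cfg)
    spill = cfg["spillover"]
    if spill:
        matrix = SpilloverMatrix.from_csv(spill)
        samples = [(apply_compensation(t, matrix), m) for t, m in samples]

    # --- gating & quantification -------------------------------------------
    strategy = default_strategy(cfg["gating"] or None)
    pop_rows, count_rows = [], []
    for table, meta in samples:
        _, result = _stage("gate", gate_sample, table, meta, strategy,
                           cfg["cofactor"])
        sample_id = f"{meta.animal_id}/{meta.hemisphere}/{meta.panel}"
        df = result.table.copy()
        df.insert(0, "sample", sample_id)
        df.insert(1, "condition", condition_label(meta.group, meta.hemisphere))
        pop_rows.append(df)
        bead_events = int(result.masks["beads"].sum())
        micro = int(result.masks["microglia"].sum())
        if bead_events > 0:
            res = absolute_count(micro, bead_events, meta.beads_added,
                                 meta.tissue_mass_mg)
            count_rows.append({
                "sample": sample_id,
                "condition": condition_label(meta.group, meta.hemisphere),
                "group": meta.group, "hemisphere": meta.hemisphere,
                "panel": meta.panel, "microglia_events": micro,
                "bead_events": bead_events, "cells_per_mg": res.cells_per_mg})
    population_table = pd.concat(pop_rows, ignore_index=True)
    counts = pd.DataFrame(count_rows)
    fold = None
    if len(counts):
        per_cond = counts.groupby("condition")["cells_per_mg"].mean()
        target = condition_label("CCI", "ipsilateral")
        reference = [c for c in per_cond.index if c != target]
        if target in per_cond.index and reference:
            fold = fold_change_vs_reference(per_cond.to_dict(), reference, target)

    report = RunReport(provenance, population_table, counts, fold,
                       pd.DataFrame(), pd.DataFrame())

    pooled = pooled_microglia(samples, strategy=strategy, cofactor=cfg["cofactor"])

    # --- marker screen + QQ -------------------------------------------------
    if "stats" in stages:
        report.marker_screen = _stage(
            "stats", marker_panel_screen, samples,
            q=cfg["stats"]["fdr_marker"],
            statistic=cfg["stats"]["mfi_statistic"], strategy=strategy,
            cofactor=cfg["cofactor"])
        qq_rows = []
        for panel in sorted(pooled["panel"].unique()):
            sub = pooled[pooled["panel"] == panel]
            x = sub[sub["condition"] == "sham-ipsi"]
            y = sub[sub["condition"] == "CCI-ipsi"]
            if len(x) and len(y):
                for param in screen_parameters(panel):
                    res = qq_curve(x[param], y[param],
                                   cfg["stats"]["qq_probes"], marker=param)
                    qq_rows.append({
                        "panel": panel, "parameter": param,
                        "median_displacement": res.median_displacement,
                        "signed_area": res.signed_area})
        report.qq_summaries = pd.DataFrame(qq_rows)

    # --- differential correlation ------------------------------------------
    if "corr" in stages:
        for panel in sorted(pooled["panel"].unique()):
            markers = cfg["panels"][panel]
            sub = pooled[pooled["panel"] == panel]
            for hemi, short in (("ipsilateral", "ipsi"), ("contralateral", "contra")):
                inj = sub[(sub.group == "CCI") & (sub.hemisphere == hemi)]
                sham = sub[(sub.group == "sham") & (sub.hemisphere == hemi)]
                if len(inj) >= 4 and len(sham) >= 4:
                    res = _stage("corr", differential_correlation_screen,
                                 inj[markers], sham[markers],
                                 q=cfg["stats"]["fdr_correlation"])
                    report.correlation[f"{panel}/{short}"] = res

    # --- discrimination -----------------------------------------------------
    if "classify" in stages:
        clf_rows, prop_rows = [], []
        for panel in sorted(pooled["panel"].unique()):
            markers = cfg["panels"][panel]
            sub = pooled[pooled["panel"] == panel]
            contrasts = {
                "CCI-ipsi vs sham-ipsi":
                    (sub[sub.condition == "CCI-ipsi"], sub[sub.condition == "sham-ipsi"]),
                "CCI-contra vs sham-contra":
                    (sub[sub.condition == "CCI-contra"], sub[sub.condition == "sham-contra"]),
            }
            cap = cfg["classify"].get("max_events_per_class")
            for comparison, (pos, neg) in contrasts.items():
                if len(pos) < 20 or len(neg) < 20:
                    continue
                if cap:
                    # per-class downsampling keeps kernel/forest fits tractable
                    pos = pos.iloc[downsample_events(
                        len(pos), cap, seed=stage_seeds["classify"])]
                    neg = neg.iloc[downsample_events(
                        len(neg), cap, seed=stage_seeds["classify"])]
                X = pd.concat([pos[markers], neg[markers]], ignore_index=True)
                y = np.r_[np.ones(len(pos), dtype=int), np.zeros(len(neg), dtype=int)]
                for clf in cfg["classify"]["classifiers"]:
                    res = _stage("classify", crossval_discriminate, X, y,
                                 classifier=clf, k=cfg["classify"]["k"],
                                 runs=cfg["classify"]["runs"],
                                 seed=stage_seeds["classify"],
                                 comparison=comparison)
                    clf_rows.append({
                        "panel": panel, "comparison": comparison,
                        "classifier": clf, "auc_mean": res.auc_mean,
                        "auc_sd": res.auc_sd,
                        **{f"contrib[{k}]": v
                           for k, v in res.feature_contributions.items()}})
                    if clf == "logistic":
                        scores = propensity_scores(res.model, X)
                        prop_rows.append({
                            "panel": panel, "comparison": comparison,
                            "n_cells": len(scores),
                            "score_mean_injury": float(scores[y == 1].mean()),
                            "score_mean_sham": float(scores[y == 0].mean())})
        report.classifiers = pd.DataFrame(clf_rows)
        report.propensity_summary = pd.DataFrame(prop_rows)

    # --- tSNE ----------------------------------------------------------------
    if "embed" in stages and cfg["tsne"]["enabled"]:
        for panel in sorted(pooled["panel"].unique()):
            markers = cfg["panels"][panel]
            sub = pooled[pooled["panel"] == panel].reset_index(drop=True)
            keep = []
            for cond, grp in sub.groupby("condition"):
                idx = downsample_events(len(grp), cfg["tsne"]["n_per_sample"],
                                        seed=stage_seeds["embed"])
                keep.append(grp.index.to_numpy()[idx])
            keep = np.sort(np.concatenate(keep))
            feats = sub.loc[keep, markers]
            if len(feats) > 3 * cfg["tsne"]["perplexity"]:
                emb = _stage("embed", tsne_embed, feats,
                             perplexity=cfg["tsne"]["perplexity"],
                             n_iter=cfg["tsne"]["n_iter"],
                             seed=stage_seeds["embed"])
                coords = pd.DataFrame(emb.coordinates, columns=["tsne1", "tsne2"])
                coords["condition"] = sub.loc[keep, "condition"].to_numpy()
                report.embeddings[panel] = coords

    if write:
        _write_report(report, out_dir, cfg)
    return report


def _write_report(report: RunReport, out_dir: Path, cfg: dict) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "provenance.json").write_text(
        json.dumps(report.provenance, indent=2))
    (out_dir / "config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))
    report.population_table.to_csv(out_dir / "populations.csv", index=False)
    report.absolute_counts.to_csv(out_dir / "absolute_counts.csv", index=False)
    if len(report.marker_screen):
        report.marker_screen.to_csv(out_dir / "marker_screen.csv", index=False)
    if len(report.qq_summaries):
        report.qq_summaries.to_csv(out_dir / "qq_summaries.csv", index=False)
    for key, res in report.correlation.items():
        tag = key.replace("/", "_")
        res.pairs.to_csv(out_dir / f"correlation_pairs_{tag}.csv", index=False)
        res.q_matrix.to_csv(out_dir / f"cohens_q_matrix_{tag}.csv")
    if report.classifiers is not None and len(report.classifiers):
        report.classifiers.to_csv(out_dir / "classifiers.csv", index=False)
    if report.propensity_summary is not None and len(report.propensity_summary):
        report.propensity_summary.to_csv(out_dir / "propensity_summary.csv",
                                         index=False)
    for panel, coords in report.embeddings.items():
        coords.to_csv(out_dir / f"tsne_{panel}.csv", index=False)
    (out_dir / "summary.json").write_text(
        json.dumps(report.summary(), indent=2, default=float))
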