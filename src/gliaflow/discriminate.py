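"""Classifier-based discrimination of injury vs sham microglia, per-cell
propensity scores, and tSNE density/marker maps.

Three conventional classifiers (L2 logistic regression, random forest,
RBF-SVM) are evaluated with stratified k-fold cross validation, re-split over
several runs; discrimination is summarized as AUC (mean over folds per run,
mean and SD over run means). The logistic model's predicted probability of
the injury class serves as a per-cell propensity score for deviation from
sham. The tSNE embedding uses markers only — scatter channels are excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binned_statistic_2d, rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.linear_model import LogisticRegression
from sklearn.manifold import TSNE
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .panels import SCATTER_CHANNELS

log = logging.getLogger(__name__)

__all__ = [
    "roc_auc",
    "crossval_discriminate",
    "propensity_scores",
    "downsample_events",
    "tsne_embed",
    "embedding_maps",
    "ClassifierResult",
    "EmbeddingResult",
    "CLASSIFIERS",
]

CLASSIFIERS = ("logistic", "random_forest", "rbf_svm")


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve by the rank (Mann-Whitney) formula.

    ``AUC = P(score_pos > score_neg) + 0.5 * P(tie)``; ties get midranks, so
    this equals ``U / (n_pos * n_neg)`` exactly.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute AUC")
    ranks = rankdata(scores)
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _make_estimator(classifier: str, seed: int):
    if classifier == "logistic":
        return Pipeline([
            ("scale", StandardScaler()),
            ("clf", LogisticRegression(C=1.0, max_iter=1000)),  # L2 penalty
        ])
    if classifier == "random_forest":
        return RandomForestClassifier(n_estimators=200, random_state=seed, n_jobs=1)
    if classifier == "rbf_svm":
        return Pipeline([
            ("scale", StandardScaler()),
            ("clf", SVC(kernel="rbf", C=1.0, gamma="scale")),
        ])
    raise ValueError(f"unknown classifier {classifier!r}; expected one of {CLASSIFIERS}")


def _scores(model, X) -> np.ndarray:
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)[:, 1]
    return model.decision_function(X)


@dataclass
class ClassifierResult:
    classifier: str
    comparison: str
    auc_mean: float
    auc_sd: float
    per_run_auc: list[float]
    feature_contributions: dict[str, float]
    model: object = field(repr=False, default=None)


def crossval_discriminate(features, labels, classifier: str = "logistic",
                          k: int = 10, runs: int = 10, seed: int = 0,
                          comparison: str = "") -> ClassifierResult:
    """Stratified k-fold cross-validated AUC, re-split per run.

    ``features`` is an events x markers frame/array on the analysis scale;
    standardization happens inside each training fold (pipeline). Feature
    contributions are mean absolute standardized coefficients for the
    logistic model and permutation importance for the others, computed on a
    full-data fit.
    """
    X = features.to_numpy(dtype=float) if isinstance(features, pd.DataFrame) else np.asarray(features, dtype=float)
    names = (list(features.columns) if isinstance(features, pd.DataFrame)
             else [f"f{i}" for i in range(X.shape[1])])
    y = np.asarray(labels).astype(int)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    min_class = int(min((y == 0).sum(), (y == 1).sum()))
    if min_class < 2:
        raise ValueError("need at least 2 events per class")
    k_eff = min(k, min_class)
    if k_eff < k:
        log.warning("class too small for %d folds; reduced to %d", k, k_eff)

    rng = np.random.default_rng(seed)
    per_run = []
    for _ in range(runs):
        run_seed = int(rng.integers(0, 2**31 - 1))
        skf = StratifiedKFold(n_splits=k_eff, shuffle=True, random_state=run_seed)
        fold_aucs = []
        for train, test in skf.split(X, y):
            est = _make_estimator(classifier, run_seed)
            est.fit(X[train], y[train])
            fold_aucs.append(roc_auc(_scores(est, X[test]), y[test]))
        per_run.append(float(np.mean(fold_aucs)))

    full = _make_estimator(classifier, seed)
    full.fit(X, y)
    if classifier == "logistic":
        coefs = np.abs(full.named_steps["clf"].coef_.ravel())
        contributions = dict(zip(names, map(float, coefs)))
    else:
        imp = permutation_importance(full, X, y, scoring="roc_auc",
                                     n_repeats=5, random_state=seed)
        contributions = dict(zip(names, map(float, imp.importances_mean)))

    return ClassifierResult(
        classifier=classifier, comparison=comparison,
        auc_mean=float(np.mean(per_run)),
        auc_sd=float(np.std(per_run, ddof=1)) if runs > 1 else 0.0,
        per_run_auc=per_run, feature_contributions=contributions, model=full)


def propensity_scores(model, events) -> np.ndarray:
    """Per-cell predicted probability of the injury class from a fitted
    logistic model; monotone in the linear predictor, in [0, 1]."""
    X = events.to_numpy(dtype=float) if isinstance(events, pd.DataFrame) else np.asarray(events, dtype=float)
    n_expected = getattr(model, "n_features_in_", X.shape[1])
    if X.shape[1] != n_expected:
        raise ValueError(
            f"model was trained on {n_expected} channels, got {X.shape[1]}")
    if not hasattr(model, "predict_proba"):
        raise ValueError("propensity scores require a probabilistic classifier")
    return model.predict_proba(X)[:, 1]


def downsample_events(n_events: int, n_per_sample: int, seed: int = 0) -> np.ndarray:
    """Uniform without-replacement downsampling indices (all events if fewer)."""
    if n_per_sample < 1:
        raise ValueError("n_per_sample must be >= 1")
    if n_per_sample >= n_events:
        return np.arange(n_events)
    rng = np.random.default_rng(seed)
    return np.sort(rng.choice(n_events, size=n_per_sample, replace=False))


@dataclass
class EmbeddingResult:
    coordinates: np.ndarray
    indices: np.ndarray
    channels: list[str]
    params: dict


def tsne_embed(features, perplexity: float = 30.0, n_iter: int = 1000,
               seed: int = 0) -> EmbeddingResult:
    """2-D tSNE of marker intensities (scatter channels are dropped).

    Deterministic for a fixed seed and input. Requires more than
    ``3 * perplexity`` events.
    """
    if isinstance(features, pd.DataFrame):
        drop = [c for c in features.columns if c in SCATTER_CHANNELS]
        if drop:
            log.info("tsne: excluding scatter channels %s", drop)
        features = features.drop(columns=drop)
        names = list(features.columns)
        X = features.to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
        names = [f"f{i}" for i in range(X.shape[1])]
    n = X.shape[0]
    if n <= 3 * perplexity:
        raise ValueError(
            f"perplexity {perplexity} infeasible for {n} events (need > 3x)")
    tsne = TSNE(n_components=2, perplexity=perplexity, max_iter=n_iter,
                init="pca", random_state=seed)
    coords = tsne.fit_transform(X)
    return EmbeddingResult(
        coordinates=np.asarray(coords), indices=np.arange(n), channels=names,
        params={"perplexity": perplexity, "n_iter": n_iter, "seed": seed})


def embedding_maps(coordinates: np.ndarray, channel_values: np.ndarray,
                   bins: int = 50):
    """Binned density and mean-intensity maps over the embedding plane.

    Returns ``(density, mean_map, x_edges, y_edges)``; the mean map is a
    masked array, undefined (masked) in empty bins.
    """
    coords = np.asarray(coordinates, dtype=float)
    values = np.asarray(channel_values, dtype=float)
    if coords.shape[0] != values.shape[0]:
        raise ValueError("embedding and channel values are misaligned")
    density, x_edges, y_edges = np.histogram2d(coords[:, 0], coords[:, 1], bins=bins)
    stat, _, _, _ = binned_statistic_2d(coords[:, 0], coords[:, 1], values,
                                        statistic="mean", bins=[x_edges, y_edges])
    mean_map = np.ma.masked_invalid(stat)
    return density, mean_map, x_edges, y_edges
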