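"""Confusion metrics and the cross-validated evaluation harness.

Sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), accuracy =
(TP+TN)/n, with the abnormal class (label 1) as positive.  The harness
runs a stratified k-fold loop in which every data-dependent fitting
step — feature selection, GA search, annealing, Gibbs sampling — is
re-run inside each training fold, so no information leaks from the
validation folds; it reports per-fold metrics and the pooled-counts
aggregate.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .boosted import GABaggingPipeline, TunedTreeEnsemble
from .eegdata import EpochSet, SplitPlan, make_folds
from .ensemble_rank import RankEnsemble, RankEnsembleConfig, AnnealConfig
from .fa_lknn import FALKNNPipeline
from .featurebank import FeatureTable, extract_features
from .hht import hht_features
from .ica_subspace import IICASubspacePipeline
from .selection import GAConfig

__all__ = [
    "ConfusionCounts",
    "EvalReport",
    "confusion",
    "metrics",
    "make_pipeline",
    "evaluate",
    "METHODS",
]

METHODS = ("rank", "ica", "gabag", "hht", "falknn")


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.fp + other.fp,
            self.tn + other.tn,
            self.fn + other.fn,
        )


def confusion(predicted, truth) -> ConfusionCounts:
    """Count TP/FP/TN/FN with label 1 (abnormal) as the positive class."""
    p = np.asarray(predicted, dtype=int)
    t = np.asarray(truth, dtype=int)
    if p.shape != t.shape:
        raise ValueError("predicted and truth must have equal length")
    return ConfusionCounts(
        tp=int(((p == 1) & (t == 1)).sum()),
        fp=int(((p == 1) & (t == 0)).sum()),
        tn=int(((p == 0) & (t == 0)).sum()),
        fn=int(((p == 0) & (t == 1)).sum()),
    )


def metrics(counts: ConfusionCounts) -> tuple[float, float, float]:
    """(sensitivity, specificity, accuracy); an empty denominator yields
    NaN with a warning rather than an error."""
    if counts.n == 0:
        raise ValueError("no evaluated samples")

    def _ratio(num, den, name):
        if den == 0:
            warnings.warn(f"{name} undefined: empty denominator")
            return float("nan")
        return num / den

    sens = _ratio(counts.tp, counts.tp + counts.fn, "sensitivity")
    spec = _ratio(counts.tn, counts.tn + counts.fp, "specificity")
    acc = (counts.tp + counts.tn) / counts.n
    return sens, spec, acc


def make_pipeline(method: str, seed: int = 0, config: dict | None = None):
    """Build an unfitted pipeline for one of the five methods.

    ``config`` entries override the method's defaults; they are passed
    to the pipeline constructor.
    """
    config = dict(config or {})
    if method == "rank":
        rc = RankEnsembleConfig(
            q_features=config.pop("q_features", 40),
            prune_k=config.pop("prune_k", 20),
            anneal=AnnealConfig(
                iterations=config.pop("anneal_iterations", 500)
            ),
        )
        return RankEnsemble(config=rc, seed=seed, **config)
    if method == "ica":
        return IICASubspacePipeline(seed=seed, **config)
    if method == "gabag":
        ga = GAConfig(
            population=config.pop("population", 30),
            generations=config.pop("generations", 20),
            elitism=config.pop("elitism", 4),
        )
        return GABaggingPipeline(ga=ga, seed=seed, **config)
    if method == "hht":
        ga = GAConfig(
            population=config.pop("population", 20),
            generations=config.pop("generations", 15),
            elitism=config.pop("elitism", 3),
        )
        return TunedTreeEnsemble(ga=ga, seed=seed, **config)
    if method == "falknn":
        return FALKNNPipeline(seed=seed, **config)
    raise ValueError(
        f"unknown method {method!r}; valid names: {', '.join(METHODS)}"
    )


@dataclass
class EvalReport:
    """Per-fold and pooled metrics for one method run."""

    method: str
    seed: int
    k_folds: int
    fold_counts: list[ConfusionCounts]
    fold_metrics: list[tuple[float, float, float]]
    pooled: ConfusionCounts
    pooled_metrics: tuple[float, float, float]
    mean_fold_metrics: tuple[float, float, float]
    config: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "method": self.method,
                "seed": self.seed,
                "k_folds": self.k_folds,
                "folds": [
                    {
                        "tp": c.tp,
                        "fp": c.fp,
                        "tn": c.tn,
                        "fn": c.fn,
                        "sensitivity": m[0],
                        "specificity": m[1],
                        "accuracy": m[2],
                    }
                    for c, m in zip(self.fold_counts, self.fold_metrics)
                ],
                "pooled": {
                    "tp": self.pooled.tp,
                    "fp": self.pooled.fp,
                    "tn": self.pooled.tn,
                    "fn": self.pooled.fn,
                    "sensitivity": self.pooled_metrics[0],
                    "specificity": self.pooled_metrics[1],
                    "accuracy": self.pooled_metrics[2],
                },
                "mean_fold": {
                    "sensitivity": self.mean_fold_metrics[0],
                    "specificity": self.mean_fold_metrics[1],
                    "accuracy": self.mean_fold_metrics[2],
                },
                "config": self.config,
            },
            sort_keys=True,
        )


def _as_table(method: str, data) -> FeatureTable:
    if isinstance(data, FeatureTable):
        return data
    if isinstance(data, EpochSet):
        # feature extraction is label-free, so computing it once outside
        # the fold loop cannot leak validation information
        if method == "hht":
            return hht_features(data)
        return extract_features(data)
    raise TypeError("data must be an EpochSet or FeatureTable")


def evaluate(
    method: str,
    data,
    k_folds: int = 10,
    seed: int = 0,
    config: dict | None = None,
) -> EvalReport:
    """Stratified k-fold evaluation of one method.

    All model fitting happens inside each training fold; the report
    carries per-fold metrics, the pooled-counts aggregate, and the mean
    of the fold metrics.
    """
    if method not in METHODS:
        raise ValueError(
            f"unknown method {method!r}; valid names: {', '.join(METHODS)}"
        )
    if k_folds < 2:
        raise ValueError("k_folds must be at least 2")
    table = _as_table(method, data)
    n = table.n_samples
    plan = SplitPlan(train_indices=list(range(n)), test_indices=[], seed=seed)
    plan = make_folds(plan, table.labels, k_folds, seed)

    fold_counts, fold_metrics = [], []
    for f, (tr, va) in enumerate(plan.folds):
        pipe = make_pipeline(method, seed=seed + 1000 * f, config=config)
        pipe.fit(table.subset_rows(tr))
        pred = pipe.predict(table.subset_rows(va))
        counts = confusion(pred, table.labels[va])
        fold_counts.append(counts)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fold_metrics.append(metrics(counts))
    pooled = fold_counts[0]
    for c in fold_counts[1:]:
        pooled = pooled + c
    pooled_metrics = metrics(pooled)
    mean_fold = tuple(
        float(np.nanmean([m[i] for m in fold_metrics])) for i in range(3)
    )
    return EvalReport(
        method=method,
        seed=seed,
        k_folds=k_folds,
        fold_counts=fold_counts,
        fold_metrics=fold_metrics,
        pooled=pooled,
        pooled_metrics=pooled_metrics,
        mean_fold_metrics=mean_fold,
        config=dict(config or {}),
    )
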