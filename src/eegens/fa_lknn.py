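"""Factor-analysis reduction and the layered k-nearest-neighbor classifier.

The factor model x = W f + n (diagonal noise) is fitted by maximum
likelihood EM; posterior-mean factor scores feed the classifier.

The layered KNN (LKNN) works per class: compute the class center and
every member's Euclidean distance to it; find the Tukey-hinge quartiles
of those distances, reject members beyond the upper fence
Q3 + 1.5*IQR as outliers; split the radius up to the largest retained
distance (over all classes) into L concentric layers and weight inner
layers more (weight = L - layer + 1).  A query's k nearest retained
neighbors then vote with weight x inverse distance ("association
rate"); per-class sums ("affiliation degrees") are normalized into
scores and the argmax wins.  A query coinciding with a training member
takes that member's class outright.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import FactorAnalysis

from .featurebank import FeatureTable

logger = logging.getLogger(__name__)

__all__ = [
    "FactorModel",
    "LayeredClassMap",
    "LKNNDecision",
    "fit_factor_model",
    "fa_transform",
    "tukey_quartiles",
    "lknn_fit",
    "lknn_predict",
    "FALKNNPipeline",
    "fit_fa_lknn",
]


@dataclass
class FactorModel:
    """Maximum-likelihood factor-analysis fit."""

    loadings: np.ndarray  # (q, n_factors)
    noise_variance: np.ndarray  # diagonal of the noise covariance
    mean: np.ndarray
    n_factors: int
    feature_names: list[str]
    _sk: FactorAnalysis = None

    def implied_covariance(self) -> np.ndarray:
        return self.loadings @ self.loadings.T + np.diag(self.noise_variance)


def fit_factor_model(
    table: FeatureTable,
    n_factors: int,
    tol: float = 1e-4,
    max_iter: int = 500,
) -> FactorModel:
    """EM maximum-likelihood factor analysis on centered features.

    Zero-variance columns are dropped (with a warning) before the fit;
    a warning is also emitted when there are fewer samples than
    features.
    """
    if n_factors < 1:
        raise ValueError("n_factors must be at least 1")
    x = table.values
    sd = x.std(axis=0)
    keep = sd > 0
    if not keep.all():
        dropped = [n for n, k in zip(table.feature_names, keep) if not k]
        logger.warning("dropping zero-variance columns before fit: %s", dropped)
    names = [n for n, k in zip(table.feature_names, keep) if k]
    x = x[:, keep]
    if n_factors >= x.shape[1]:
        raise ValueError("n_factors must be smaller than the feature count")
    if x.shape[0] < x.shape[1]:
        logger.warning(
            "fewer samples (%d) than features (%d); loadings will be noisy",
            x.shape[0],
            x.shape[1],
        )
    fa = FactorAnalysis(
        n_components=n_factors, tol=tol, max_iter=max_iter, random_state=0
    )
    fa.fit(x)
    return FactorModel(
        loadings=fa.components_.T,
        noise_variance=fa.noise_variance_,
        mean=fa.mean_,
        n_factors=n_factors,
        feature_names=names,
        _sk=fa,
    )


def fa_transform(model: FactorModel, table: FeatureTable) -> FeatureTable:
    """Posterior-mean factor scores, named ``fa.f<i>``."""
    sub = table.select(model.feature_names)
    scores = model._sk.transform(sub.values)
    names = [f"fa.f{i}" for i in range(model.n_factors)]
    return FeatureTable(
        values=scores,
        feature_names=names,
        labels=table.labels,
        provenance={n: "factor_analysis" for n in names},
    )


def tukey_quartiles(values) -> tuple[float, float, float]:
    """Tukey hinges: medians of the lower/upper halves (median included
    in both halves when the count is odd) plus the overall median."""
    v = np.sort(np.asarray(values, dtype=float))
    n = v.size
    if n < 4:
        raise ValueError("quartiles need at least 4 values")
    half = (n + 1) // 2
    q1 = float(np.median(v[:half]))
    q2 = float(np.median(v))
    q3 = float(np.median(v[n - half :]))
    return q1, q2, q3


@dataclass
class ClassLayers:
    """Per-class training state of the LKNN."""

    label: int
    center: np.ndarray
    member_indices: np.ndarray  # into the fitted feature matrix
    distances: np.ndarray
    q1: float
    q2: float
    q3: float
    v_low: float
    v_high: float
    retained: np.ndarray  # boolean over members
    f_far: float


@dataclass
class LayeredClassMap:
    """Fitted LKNN: centers, fences, retained members, layer geometry."""

    classes: list[ClassLayers]
    points: np.ndarray  # retained training points
    labels: np.ndarray
    layer_index: np.ndarray  # 1..L per retained point
    layer_weight: np.ndarray  # L - layer + 1 per retained point
    f_max: float
    n_layers: int

    @property
    def layer_width(self) -> float:
        return self.f_max / self.n_layers if self.n_layers else 0.0


@dataclass
class LKNNDecision:
    """Per-query voting record."""

    neighbor_indices: np.ndarray
    association_rates: np.ndarray
    affiliation: dict[int, float]
    scores: dict[int, float]
    target: int


def lknn_fit(table: FeatureTable, n_layers: int = 4) -> LayeredClassMap:
    """Layers-construction process with IQR outlier rejection."""
    if n_layers < 1:
        raise ValueError("n_layers must be at least 1")
    x, y = table.values, table.labels
    class_states = []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        if idx.size < 4:
            raise ValueError(
                f"class {cls} has {idx.size} members; need at least 4 "
                "for quartiles"
            )
        center = x[idx].mean(axis=0)
        dist = np.linalg.norm(x[idx] - center, axis=1)
        q1, q2, q3 = tukey_quartiles(dist)
        iqr = q3 - q1
        v_low = q1 - 1.5 * iqr
        v_high = q3 + 1.5 * iqr
        retained = dist <= v_high
        class_states.append(
            ClassLayers(
                label=int(cls),
                center=center,
                member_indices=idx,
                distances=dist,
                q1=q1,
                q2=q2,
                q3=q3,
                v_low=v_low,
                v_high=v_high,
                retained=retained,
                f_far=float(dist[retained].max()),
            )
        )
    f_max = max(cs.f_far for cs in class_states)
    width = f_max / n_layers if f_max > 0 else 1.0

    points, labels, layer_idx = [], [], []
    for cs in class_states:
        kept = np.flatnonzero(cs.retained)
        for j in kept:
            points.append(x[cs.member_indices[j]])
            labels.append(cs.label)
            layer = int(np.ceil(cs.distances[j] / width)) if width > 0 else 1
            layer_idx.append(min(max(layer, 1), n_layers))
    layer_idx = np.asarray(layer_idx, dtype=int)
    return LayeredClassMap(
        classes=class_states,
        points=np.asarray(points),
        labels=np.asarray(labels, dtype=int),
        layer_index=layer_idx,
        layer_weight=(n_layers - layer_idx + 1).astype(float),
        f_max=float(f_max),
        n_layers=n_layers,
    )


def lknn_predict(
    cmap: LayeredClassMap, queries, k: int = 5
) -> tuple[np.ndarray, list[LKNNDecision]]:
    """Classify queries by layer-weighted inverse-distance voting.

    Distance ties at the k-boundary break toward the lower retained-
    member index; a zero-distance match short-circuits to that member's
    class; score ties go to the lower class label.
    """
    queries = np.atleast_2d(np.asarray(queries, dtype=float))
    n_train = len(cmap.points)
    if not 1 <= k <= n_train:
        raise ValueError(f"k must be in [1, {n_train}]")
    class_labels = sorted(int(c) for c in np.unique(cmap.labels))
    out = np.empty(len(queries), dtype=int)
    decisions = []
    for qi, q in enumerate(queries):
        d = np.linalg.norm(cmap.points - q, axis=1)
        order = np.lexsort((np.arange(n_train), d))[:k]
        rates = np.empty(k)
        exact = None
        for pos, j in enumerate(order):
            if d[j] == 0:
                exact = j
                break
            rates[pos] = 1.0 / d[j]
        if exact is not None:
            target = int(cmap.labels[exact])
            decisions.append(
                LKNNDecision(
                    neighbor_indices=order,
                    association_rates=np.full(k, np.inf),
                    affiliation={c: float(c == target) for c in class_labels},
                    scores={c: float(c == target) for c in class_labels},
                    target=target,
                )
            )
            out[qi] = target
            continue
        affiliation = {c: 0.0 for c in class_labels}
        for pos, j in enumerate(order):
            affiliation[int(cmap.labels[j])] += (
                rates[pos] * cmap.layer_weight[j]
            )
        total = sum(affiliation.values())
        scores = {c: affiliation[c] / total for c in class_labels}
        target = max(class_labels, key=lambda c: (scores[c], -c))
        decisions.append(
            LKNNDecision(
                neighbor_indices=order,
                association_rates=rates,
                affiliation=affiliation,
                scores=scores,
                target=int(target),
            )
        )
        out[qi] = int(target)
    return out, decisions


class FALKNNPipeline:
    """Factor scores feeding the layered KNN."""

    def __init__(
        self,
        n_factors: int = 8,
        n_layers: int = 4,
        k: int = 5,
        seed: int = 0,
    ):
        self.n_factors = n_factors
        self.n_layers = n_layers
        self.k = k
        self.seed = seed

    def fit(self, table: FeatureTable) -> "FALKNNPipeline":
        self.factor_ = fit_factor_model(table, self.n_factors)
        scores = fa_transform(self.factor_, table)
        self.map_ = lknn_fit(scores, self.n_layers)
        return self

    def predict(self, table: FeatureTable) -> np.ndarray:
        scores = fa_transform(self.factor_, table)
        labels, _ = lknn_predict(self.map_, scores.values, self.k)
        return labels

    def manifest(self) -> str:
        return json.dumps(
            {
                "method": "falknn",
                "seed": self.seed,
                "n_factors": self.n_factors,
                "n_layers": self.n_layers,
                "k": self.k,
                "f_max": self.map_.f_max,
                "retained": int(len(self.map_.points)),
            },
            sort_keys=True,
        )


def fit_fa_lknn(
    table: FeatureTable,
    n_factors: int = 8,
    n_layers: int = 4,
    k: int = 5,
    seed: int = 0,
) -> FALKNNPipeline:
    """Fit the factor-analysis + layered-KNN pipeline."""
    return FALKNNPipeline(
        n_factors=n_factors, n_layers=n_layers, k=k, seed=seed
    ).fit(table)
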