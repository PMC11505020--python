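"""Equidistant assessment, diversity-aware pruning, and ensemble voting.

This is the first and best-performing pipeline: a pool of heterogeneous
base classifiers is tuned over equidistant parameter grids, pruned by
k-means clustering of their validation prediction vectors (keeping the
most accurate member per cluster), trimmed further by a simulated-
annealing search over model-inclusion vectors ("ranking determination"),
and combined by majority voting evaluated with a divide-and-conquer
split that is bit-identical to the plain vote.

The interrater kappa diversity statistic is reported as a diagnostic of
the pool: kappa = 1 - Disav / (2 qbar (1 - qbar)) where qbar is the mean
per-model per-instance correctness and Disav the mean pairwise
disagreement fraction.  Identical members give kappa = 1; members with
complementary errors at qbar = 0.5 give kappa = -1; independent chance-
level members give kappa ~ 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import clone
from sklearn.cluster import KMeans
from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .eegdata import split_train_test
from .featurebank import FeatureTable
from .selection import escd_select

__all__ = [
    "ParamSpec",
    "ModelPool",
    "AnnealConfig",
    "equidistant_grid",
    "assess_model",
    "kappa_diversity",
    "prune_kmeans",
    "ranking_determination",
    "majority_vote",
    "divide_conquer_vote",
    "default_roster",
    "RankEnsemble",
    "fit_rank_ensemble",
]


@dataclass
class ParamSpec:
    """An equidistant parameter grid: `steps` values from start to stop."""

    name: str
    start: float
    stop: float
    steps: int
    integer: bool = False

    def __post_init__(self):
        if self.steps < 1:
            raise ValueError("steps must be at least 1")
        if self.start > self.stop:
            raise ValueError("start must not exceed stop")


def equidistant_grid(spec: ParamSpec) -> list:
    """Equally spaced values inclusive of both endpoints.

    Integer grids are rounded half-up and deduplicated preserving order.
    """
    if spec.steps == 1:
        values = [spec.start]
    else:
        values = np.linspace(spec.start, spec.stop, spec.steps).tolist()
    if spec.integer:
        values = [int(np.floor(v + 0.5)) for v in values]
    out = []
    for v in values:
        if v not in out:
            out.append(v)
    return out


@dataclass
class RosterEntry:
    """A base-model kind with the parameter grid to assess."""

    name: str
    estimator: object
    param: ParamSpec


def default_roster() -> list[RosterEntry]:
    """Eight classical learners with equidistant tuning grids.

    KNN uses the canonical "k, 2, 16, 4" grid; the others get
    four-point grids over their main regularization knob.
    """
    return [
        RosterEntry(
            "knn",
            KNeighborsClassifier(),
            ParamSpec("n_neighbors", 2, 16, 4, integer=True),
        ),
        RosterEntry(
            "svm_rbf",
            SVC(kernel="rbf", gamma="scale", random_state=0),
            ParamSpec("C", 0.5, 8.0, 4),
        ),
        RosterEntry(
            "svm_linear",
            SVC(kernel="linear", random_state=0),
            ParamSpec("C", 0.5, 8.0, 4),
        ),
        RosterEntry(
            "logreg",
            LogisticRegression(max_iter=2000),
            ParamSpec("C", 0.5, 8.0, 4),
        ),
        RosterEntry(
            "rf",
            RandomForestClassifier(random_state=0, n_jobs=1),
            ParamSpec("n_estimators", 25, 100, 4, integer=True),
        ),
        RosterEntry(
            "extra_trees",
            ExtraTreesClassifier(random_state=0, n_jobs=1),
            ParamSpec("n_estimators", 25, 100, 4, integer=True),
        ),
        RosterEntry(
            "naive_bayes",
            GaussianNB(),
            ParamSpec("var_smoothing", 1e-9, 1e-6, 4),
        ),
        RosterEntry(
            "dtree",
            DecisionTreeClassifier(random_state=0),
            ParamSpec("max_depth", 2, 14, 4, integer=True),
        ),
    ]


def assess_model(
    estimator,
    spec: ParamSpec,
    train_x,
    train_y,
    val_x,
    val_y,
):
    """Tune one parameter over its equidistant grid on a validation set.

    Each grid value is evaluated independently, so the selection is
    invariant to evaluation order; ties go to the smaller value.
    Returns ``(fitted best model, best value, {value: accuracy})``.
    """
    train_y = np.asarray(train_y)
    val_y = np.asarray(val_y)
    if len(train_x) == 0 or len(val_x) == 0:
        raise ValueError("train/validation sets must be non-empty")
    if np.unique(train_y).size < 2:
        raise ValueError("training fold contains a single class")
    grid = equidistant_grid(spec)
    accs: dict = {}
    for value in grid:
        model = clone(estimator)
        model.set_params(**{spec.name: value})
        model.fit(train_x, train_y)
        accs[value] = float((model.predict(val_x) == val_y).mean())
    # smaller value wins ties
    best_acc = max(accs.values())
    best_value = min(v for v in grid if accs[v] == best_acc)
    best = clone(estimator)
    best.set_params(**{spec.name: best_value})
    best.fit(train_x, train_y)
    return best, best_value, accs


@dataclass
class ModelPool:
    """Trained base models with validation predictions and metadata."""

    models: list  # fitted estimators
    names: list[str]
    params: list
    votes: np.ndarray  # (t, v) validation predictions in {0, 1}
    accuracies: np.ndarray  # validation accuracy per model
    included: np.ndarray = None  # 0/1 inclusion vector
    clusters: np.ndarray | None = None
    selection_probs: np.ndarray = None

    def __post_init__(self):
        self.votes = np.asarray(self.votes, dtype=int)
        self.accuracies = np.asarray(self.accuracies, dtype=float)
        t = len(self.models)
        if t < 1:
            raise ValueError("pool must contain at least one model")
        if self.votes.shape[0] != t or len(self.names) != t:
            raise ValueError("pool fields must align with models")
        if not np.isin(self.votes, (0, 1)).all():
            raise ValueError("votes must be binary")
        if self.included is None:
            self.included = np.ones(t, dtype=int)
        if self.selection_probs is None:
            self.selection_probs = np.full(t, 0.4)

    @property
    def n_models(self) -> int:
        return len(self.models)

    def subset(self, mask) -> "ModelPool":
        idx = np.flatnonzero(np.asarray(mask).astype(bool))
        return ModelPool(
            models=[self.models[i] for i in idx],
            names=[self.names[i] for i in idx],
            params=[self.params[i] for i in idx],
            votes=self.votes[idx],
            accuracies=self.accuracies[idx],
            selection_probs=self.selection_probs[idx],
        )


def kappa_diversity(votes, truth) -> float:
    """Interrater kappa over a pool's 0/1 predictions.

    Returns 1 when all members agree everywhere (zero disagreement).
    Raises for the degenerate all-right/all-wrong pool that still
    disagrees, where the statistic is undefined.
    """
    votes = np.asarray(votes, dtype=int)
    truth = np.asarray(truth, dtype=int)
    t, v = votes.shape
    if t < 2:
        raise ValueError("diversity needs at least 2 models")
    correct = (votes == truth[None, :]).astype(float)
    qbar = correct.mean()
    # mean pairwise disagreement over the t(t-1) ordered pairs
    agree = votes @ votes.T + (1 - votes) @ (1 - votes).T
    dis = 1.0 - agree / v
    disav = dis.sum() / (t * (t - 1))
    if disav == 0:
        return 1.0
    denom = 2.0 * qbar * (1.0 - qbar)
    if denom == 0:
        raise ValueError(
            "degenerate pool: all predictions right or wrong yet disagreeing"
        )
    return float(1.0 - disav / denom)


def prune_kmeans(pool: ModelPool, k: int, seed: int = 0) -> ModelPool:
    """Cluster models on their validation prediction vectors; keep the
    most accurate member per cluster (ties to the lower model index)."""
    if pool.n_models == 0:
        raise ValueError("empty pool")
    t = pool.n_models
    k_eff = min(k, t)
    if k_eff >= t:
        out = pool.subset(np.ones(t, dtype=bool))
        out.clusters = np.arange(t)
        return out
    km = KMeans(n_clusters=k_eff, n_init=10, random_state=seed)
    assign = km.fit_predict(pool.votes.astype(float))
    keep = np.zeros(t, dtype=bool)
    for c in np.unique(assign):
        members = np.flatnonzero(assign == c)
        best = members[np.argmax(pool.accuracies[members])]
        # argmax returns the first maximum, i.e. the lower index
        keep[best] = True
    out = pool.subset(keep)
    out.clusters = assign[keep]
    return out


@dataclass
class AnnealConfig:
    """Simulated-annealing settings for ranking determination."""

    iterations: int = 500
    t0: float = 1.0
    cooling: float = 0.95
    init_prob: float = 0.4
    prob_boost: float = 1.1
    prob_cap: float = 0.95


def _vote_accuracy(votes, included, truth):
    idx = np.flatnonzero(included)
    if idx.size == 0:
        return -1.0
    pred = majority_vote(votes[idx])
    return float((pred == truth).mean())


def ranking_determination(
    pool: ModelPool,
    truth,
    config: AnnealConfig | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Simulated annealing over model-inclusion vectors.

    Objective: majority-vote validation accuracy of the included
    members, with fewer members breaking ties.  Neighbors flip one model
    chosen proportionally to its selection probability (initialized at
    0.4); probabilities of members present in accepted improving
    solutions are boosted.  Returns the best-ever inclusion vector.
    """
    config = config or AnnealConfig()
    truth = np.asarray(truth, dtype=int)
    t = pool.n_models
    rng = np.random.default_rng(seed)
    if t == 1:
        return np.ones(1, dtype=int)

    probs = np.full(t, config.init_prob)
    current = (rng.random(t) < config.init_prob).astype(int)
    if current.sum() == 0:
        current[int(np.argmax(pool.accuracies))] = 1

    def objective(z):
        return (_vote_accuracy(pool.votes, z, truth), -z.sum())

    cur_obj = objective(current)
    best = current.copy()
    best_obj = cur_obj
    temp = config.t0
    for _ in range(config.iterations):
        flip = rng.choice(t, p=probs / probs.sum())
        cand = current.copy()
        cand[flip] = 1 - cand[flip]
        if cand.sum() == 0:
            cand[int(np.argmax(pool.accuracies))] = 1
        cand_obj = objective(cand)
        delta = cand_obj[0] - cur_obj[0]
        accept = cand_obj >= cur_obj or rng.random() < np.exp(
            min(delta, 0.0) / max(temp, 1e-12)
        )
        if accept:
            improving = cand_obj > cur_obj
            current, cur_obj = cand, cand_obj
            if improving:
                members = current.astype(bool)
                probs[members] = np.minimum(
                    probs[members] * config.prob_boost, config.prob_cap
                )
            if cur_obj > best_obj:
                best, best_obj = current.copy(), cur_obj
        temp *= config.cooling
    return best


def majority_vote(votes, weights=None) -> np.ndarray:
    """Majority vote over a (models x instances) 0/1 matrix.

    Unweighted: class 1 wins when at least half the members vote 1
    (ties go to 1).  Weighted: weights must be non-negative and sum to
    1; class 1 wins when the weighted vote reaches 1/2.
    """
    votes = np.asarray(votes, dtype=float)
    if votes.ndim != 2:
        raise ValueError("votes must be 2-D (models x instances)")
    t = votes.shape[0]
    if weights is None:
        return (votes.sum(axis=0) >= t / 2.0).astype(int)
    w = np.asarray(weights, dtype=float)
    if w.shape != (t,):
        raise ValueError("weights must align with models")
    if (w < 0).any():
        raise ValueError("weights must be non-negative")
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("weights must sum to 1")
    return ((w @ votes) >= 0.5).astype(int)


def divide_conquer_vote(votes, threshold: int = 10_000, weights=None) -> np.ndarray:
    """Majority vote computed by recursively halving the instance set.

    Bit-identical to :func:`majority_vote` for every threshold; the
    split exists as a partition-invariance contract (the original
    design dispatches blocks to a thread pool).
    """
    if threshold < 1:
        raise ValueError("threshold must be at least 1")
    votes = np.asarray(votes)
    if votes.ndim != 2:
        raise ValueError("votes must be 2-D (models x instances)")
    v = votes.shape[1]
    if v == 0:
        return np.zeros(0, dtype=int)
    if v <= threshold:
        return majority_vote(votes, weights)
    mid = v // 2
    left = divide_conquer_vote(votes[:, :mid], threshold, weights)
    right = divide_conquer_vote(votes[:, mid:], threshold, weights)
    return np.concatenate([left, right])


@dataclass
class RankEnsembleConfig:
    q_features: int = 40
    prune_k: int = 20
    validation_fraction: float = 0.9
    anneal: AnnealConfig = field(default_factory=AnnealConfig)
    vote_threshold: int = 10_000


class RankEnsemble:
    """The full pipeline: ESCD selection, equidistant assessment,
    k-means pruning, annealed member selection, divide-and-conquer vote."""

    def __init__(
        self,
        roster: list[RosterEntry] | None = None,
        config: RankEnsembleConfig | None = None,
        seed: int = 0,
    ):
        self.roster = roster if roster is not None else default_roster()
        self.config = config or RankEnsembleConfig()
        self.seed = seed
        self.scaler_: StandardScaler | None = None
        self.selected_: list[str] | None = None
        self.pool_: ModelPool | None = None
        self.kappa_: float | None = None

    def fit(self, table: FeatureTable) -> "RankEnsemble":
        if not self.roster:
            raise ValueError("roster must be non-empty")
        cfg = self.config
        q = min(cfg.q_features, table.n_features)
        _, selected = escd_select(table, q)
        self.selected_ = selected
        sub = table.select(selected)

        self.scaler_ = StandardScaler().fit(sub.values)
        x = self.scaler_.transform(sub.values)
        y = sub.labels

        plan = split_train_test(
            _DataView(y), cfg.validation_fraction, seed=self.seed
        )
        tr, va = plan.train_indices, plan.test_indices
        models, names, params, votes, accs = [], [], [], [], []
        for entry in self.roster:
            model, value, _ = assess_model(
                entry.estimator, entry.param, x[tr], y[tr], x[va], y[va]
            )
            pred = model.predict(x[va]).astype(int)
            models.append(model)
            names.append(entry.name)
            params.append({entry.param.name: value})
            votes.append(pred)
            accs.append(float((pred == y[va]).mean()))
        pool = ModelPool(
            models=models,
            names=names,
            params=params,
            votes=np.asarray(votes),
            accuracies=np.asarray(accs),
        )
        try:
            self.kappa_ = kappa_diversity(pool.votes, y[va])
        except ValueError:
            self.kappa_ = None
        pool = prune_kmeans(pool, cfg.prune_k, seed=self.seed)
        included = ranking_determination(
            pool, y[va], config=cfg.anneal, seed=self.seed
        )
        self.pool_ = pool.subset(included)
        return self

    def predict(self, table: FeatureTable) -> np.ndarray:
        if self.pool_ is None:
            raise RuntimeError("ensemble is not fitted")
        x = self.scaler_.transform(table.select(self.selected_).values)
        votes = np.asarray(
            [m.predict(x).astype(int) for m in self.pool_.models]
        )
        return divide_conquer_vote(votes, self.config.vote_threshold)

    def manifest(self) -> str:
        return json.dumps(
            {
                "method": "rank",
                "seed": self.seed,
                "selected_features": self.selected_,
                "members": self.pool_.names,
                "member_params": self.pool_.params,
                "validation_accuracies": self.pool_.accuracies.tolist(),
                "kappa_diversity": self.kappa_,
                "q_features": self.config.q_features,
                "prune_k": self.config.prune_k,
            },
            sort_keys=True,
        )


class _DataView:
    """Minimal label-bearing view accepted by split_train_test."""

    def __init__(self, labels):
        self.labels = np.asarray(labels, dtype=int)


def fit_rank_ensemble(
    table: FeatureTable,
    roster: list[RosterEntry] | None = None,
    q_features: int = 40,
    config: RankEnsembleConfig | None = None,
    seed: int = 0,
) -> RankEnsemble:
    """Convenience wrapper building and fitting a :class:`RankEnsemble`."""
    cfg = config or RankEnsembleConfig()
    cfg.q_features = q_features
    return RankEnsemble(roster=roster, config=cfg, seed=seed).fit(table)
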