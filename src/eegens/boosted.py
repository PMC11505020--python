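"""GA-driven ensembles: bagged SVMs and GA-tuned tree learners.

The GA-bagging pipeline couples GA wrapper feature selection with a bagging-SVM
committee: R bootstrap resamples, one RBF-kernel SVM per resample,
in-bag error rates recorded per weak classifier, and majority voting.

The HHT tree-trio pipeline runs on HHT features and uses a GA over a mixed
integer/real hyperparameter chromosome to tune three tree ensembles —
random forest, gradient boosting (XGBoost), and histogram gradient
boosting (LightGBM) — whose three predictions are majority-voted (an
odd count, so no ties).  GA fitness is 1 - mean cross-validated error
rate of the voting trio.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from lightgbm import LGBMClassifier
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .ensemble_rank import majority_vote
from .featurebank import FeatureTable
from .selection import Chromosome, GAConfig, ga_optimize_real, ga_select

__all__ = [
    "BaggingPool",
    "BaggingSVM",
    "fit_bagging_svm",
    "GABaggingPipeline",
    "fit_ga_bagging",
    "HyperBounds",
    "default_hyper_bounds",
    "TunedTreeEnsemble",
    "ga_tune_ensemble",
]


@dataclass
class BaggingPool:
    """Bootstrap committee state: members, in-bag error rates, seeds."""

    classifiers: list
    bootstrap_indices: list[np.ndarray]
    error_rates: np.ndarray  # in-bag misclassification fraction per member
    seed: int


class BaggingSVM:
    """Bagged RBF-kernel SVMs combined by majority vote."""

    def __init__(self, r_bags: int = 25, c: float = 1.0, seed: int = 0):
        if r_bags < 1:
            raise ValueError("r_bags must be at least 1")
        self.r_bags = r_bags
        self.c = c
        self.seed = seed

    def fit(self, table: FeatureTable) -> "BaggingSVM":
        rng = np.random.default_rng(self.seed)
        x, y = table.values, table.labels
        n = len(x)
        self.scaler_ = StandardScaler().fit(x)
        xs = self.scaler_.transform(x)
        classifiers, indices, errors = [], [], []
        for _ in range(self.r_bags):
            for attempt in range(10):
                idx = rng.integers(0, n, size=n)
                if np.unique(y[idx]).size == 2:
                    break
            else:
                raise ValueError(
                    "bootstrap resampling produced single-class bags 10 times"
                )
            clf = SVC(kernel="rbf", C=self.c, gamma="scale")
            clf.fit(xs[idx], y[idx])
            in_bag_err = float((clf.predict(xs[idx]) != y[idx]).mean())
            classifiers.append(clf)
            indices.append(idx)
            errors.append(in_bag_err)
        self.pool_ = BaggingPool(
            classifiers=classifiers,
            bootstrap_indices=indices,
            error_rates=np.asarray(errors),
            seed=self.seed,
        )
        return self

    def predict(self, table: FeatureTable) -> np.ndarray:
        xs = self.scaler_.transform(table.values)
        votes = np.asarray(
            [clf.predict(xs).astype(int) for clf in self.pool_.classifiers]
        )
        return majority_vote(votes)

    def manifest(self) -> str:
        return json.dumps(
            {
                "method": "bagging_svm",
                "r_bags": self.r_bags,
                "seed": self.seed,
                "error_rates": self.pool_.error_rates.tolist(),
            },
            sort_keys=True,
        )


def fit_bagging_svm(
    table: FeatureTable, r_bags: int = 25, c: float = 1.0, seed: int = 0
) -> BaggingSVM:
    """Fit a bagged-SVM committee on a feature table."""
    return BaggingSVM(r_bags=r_bags, c=c, seed=seed).fit(table)


def _cv_accuracy(x, y, make_model, folds: int, seed: int) -> float:
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    correct = 0
    for tr, va in skf.split(x, y):
        model = make_model()
        model.fit(x[tr], y[tr])
        correct += int((model.predict(x[va]) == y[va]).sum())
    return correct / len(y)


class GABaggingPipeline:
    """GA mask selection feeding a bagging-SVM committee.

    The GA evaluator scores each mask by the internal cross-validated
    accuracy of a single SVM restricted to the masked features.
    """

    def __init__(
        self,
        ga: GAConfig | None = None,
        r_bags: int = 25,
        cv_folds: int = 3,
        seed: int = 0,
    ):
        self.ga = ga or GAConfig(population=30, generations=20, elitism=4)
        self.r_bags = r_bags
        self.cv_folds = cv_folds
        self.seed = seed

    def fit(self, table: FeatureTable) -> "GABaggingPipeline":
        scaler = StandardScaler().fit(table.values)
        xs = scaler.transform(table.values)
        y = table.labels

        def evaluate(mask) -> float:
            cols = np.flatnonzero(mask)
            return _cv_accuracy(
                xs[:, cols],
                y,
                lambda: SVC(kernel="rbf", gamma="scale"),
                self.cv_folds,
                self.seed,
            )

        ga = GAConfig(**{**self.ga.__dict__, "seed": self.seed})
        if ga.generations > 0:
            self.best_, self.history_ = ga_select(table, ga, evaluate)
        else:
            rng = np.random.default_rng(self.seed)
            bits = rng.integers(0, 2, table.n_features).astype(np.int8)
            if bits.sum() == 0:
                bits[rng.integers(bits.size)] = 1
            self.best_ = Chromosome(bits=bits, fitness=float(evaluate(bits)))
            self.history_ = []
        self.mask_ = self.best_.bits.astype(bool)
        self.feature_names_ = [
            n for n, keep in zip(table.feature_names, self.mask_) if keep
        ]
        self.bagging_ = BaggingSVM(r_bags=self.r_bags, seed=self.seed).fit(
            table.select(self.feature_names_)
        )
        return self

    def predict(self, table: FeatureTable) -> np.ndarray:
        return self.bagging_.predict(table.select(self.feature_names_))

    def manifest(self) -> str:
        return json.dumps(
            {
                "method": "gabag",
                "seed": self.seed,
                "selected_features": self.feature_names_,
                "mask_size": int(self.mask_.sum()),
                "ga_fitness": self.best_.fitness,
                "r_bags": self.r_bags,
            },
            sort_keys=True,
        )


def fit_ga_bagging(
    table: FeatureTable,
    ga: GAConfig | None = None,
    r_bags: int = 25,
    seed: int = 0,
) -> GABaggingPipeline:
    """Fit the GA-selection + bagging-SVM pipeline."""
    return GABaggingPipeline(ga=ga, r_bags=r_bags, seed=seed).fit(table)


# ---------------------------------------------------------------------------
# GA multiparameter tuning of three tree learners


@dataclass
class HyperBounds:
    """Named gene bounds: list of (name, low, high, integer?)."""

    genes: list[tuple[str, float, float, bool]]

    @property
    def names(self) -> list[str]:
        return [g[0] for g in self.genes]

    def as_ga_bounds(self) -> list[tuple[float, float, bool]]:
        return [(lo, hi, isint) for _, lo, hi, isint in self.genes]


def default_hyper_bounds() -> HyperBounds:
    """Search boxes whose midpoints are the study's stated defaults
    (forest: 100 estimators, depth 50, leaf size 15; boosting: eta 0.4,
    depth 4, min child weight 2, gamma 0.2; histogram boosting: 31
    leaves, rate 0.4, depth 4)."""
    return HyperBounds(
        genes=[
            ("rf_n_estimators", 50, 150, True),
            ("rf_max_depth", 10, 90, True),
            ("rf_min_samples_leaf", 5, 25, True),
            ("xgb_eta", 0.1, 0.7, False),
            ("xgb_max_depth", 2, 6, True),
            ("xgb_min_child_weight", 1, 3, False),
            ("xgb_gamma", 0.0, 0.4, False),
            ("lgbm_num_leaves", 8, 54, True),
            ("lgbm_learning_rate", 0.1, 0.7, False),
            ("lgbm_max_depth", 2, 6, True),
        ]
    )


def _build_learners(params: dict, seed: int):
    rf = RandomForestClassifier(
        n_estimators=int(params["rf_n_estimators"]),
        max_depth=int(params["rf_max_depth"]),
        min_samples_split=25,
        min_samples_leaf=int(params["rf_min_samples_leaf"]),
        max_leaf_nodes=10,
        random_state=seed,
        n_jobs=1,
    )
    xgb = XGBClassifier(
        n_estimators=50,
        learning_rate=float(params["xgb_eta"]),
        max_depth=int(params["xgb_max_depth"]),
        min_child_weight=float(params["xgb_min_child_weight"]),
        gamma=float(params["xgb_gamma"]),
        max_delta_step=1.5,
        reg_lambda=1.0,
        reg_alpha=1.0,
        random_state=seed,
        n_jobs=1,
        verbosity=0,
        eval_metric="logloss",
    )
    lgbm = LGBMClassifier(
        n_estimators=50,
        num_leaves=int(params["lgbm_num_leaves"]),
        learning_rate=float(params["lgbm_learning_rate"]),
        max_depth=int(params["lgbm_max_depth"]),
        random_state=seed,
        n_jobs=1,
        verbosity=-1,
    )
    return [("rf", rf), ("xgb", xgb), ("lgbm", lgbm)]


class TunedTreeEnsemble:
    """GA-tuned forest/boosting trio combined by a 3-way vote."""

    def __init__(
        self,
        ga: GAConfig | None = None,
        bounds: HyperBounds | None = None,
        cv_folds: int = 3,
        seed: int = 0,
    ):
        self.ga = ga or GAConfig(population=20, generations=15, elitism=3)
        self.bounds = bounds or default_hyper_bounds()
        self.cv_folds = cv_folds
        self.seed = seed

    def _decode(self, vector) -> dict:
        return dict(zip(self.bounds.names, vector))

    def _trio_votes(self, learners, x) -> np.ndarray:
        return np.asarray([m.predict(x).astype(int) for _, m in learners])

    def fit(self, table: FeatureTable) -> "TunedTreeEnsemble":
        x, y = table.values, table.labels

        def evaluate(vector) -> float:
            params = self._decode(vector)
            skf = StratifiedKFold(
                n_splits=self.cv_folds, shuffle=True, random_state=self.seed
            )
            correct = 0
            for tr, va in skf.split(x, y):
                learners = _build_learners(params, self.seed)
                for _, m in learners:
                    m.fit(x[tr], y[tr])
                pred = majority_vote(self._trio_votes(learners, x[va]))
                correct += int((pred == y[va]).sum())
            return correct / len(y)  # 1 - mean CV error rate

        ga = GAConfig(**{**self.ga.__dict__, "seed": self.seed})
        vec, fit, hist = ga_optimize_real(
            self.bounds.as_ga_bounds(), ga, evaluate
        )
        self.best_params_ = self._decode(vec)
        self.best_fitness_ = fit
        self.history_ = hist
        self.learners_ = _build_learners(self.best_params_, self.seed)
        for _, m in self.learners_:
            m.fit(x, y)
        return self

    def predict(self, table: FeatureTable) -> np.ndarray:
        votes = self._trio_votes(self.learners_, table.values)
        assert votes.shape[0] % 2 == 1, "vote count must stay odd"
        return majority_vote(votes)

    def manifest(self) -> str:
        return json.dumps(
            {
                "method": "hht",
                "seed": self.seed,
                "best_params": {
                    k: float(v) for k, v in self.best_params_.items()
                },
                "cv_fitness": self.best_fitness_,
            },
            sort_keys=True,
        )


def ga_tune_ensemble(
    table: FeatureTable,
    ga: GAConfig | None = None,
    bounds: HyperBounds | None = None,
    seed: int = 0,
) -> TunedTreeEnsemble:
    """Fit the GA-tuned three-learner voting ensemble."""
    return TunedTreeEnsemble(ga=ga, bounds=bounds, seed=seed).fit(table)
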