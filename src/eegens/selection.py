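"""Feature selection: the ESCD filter statistic and GA optimizers.

ESCD ("enhance the sum of connection and distance") is a filter-style
selector scoring each feature by the sum of

* a connection term C_i = \\|Pearson correlation with the label\\| in [0, 1],
  measuring relevance, and
* a distance term D_i = the mean Euclidean distance of the (z-scored)
  feature column to every other column, measuring non-redundancy,
  divided by its maximum so it is bounded by 1 and commensurate with C_i.

Features are ranked by C_i + D_i descending (ties broken by lower column
index) and the top q kept.

The GA half provides a binary-mask optimizer (wrapper feature selection)
and a box-bounded real-vector optimizer (hyperparameter tuning), sharing
the same engine: fitness-proportional roulette selection, single-point
crossover, one-gene mutation, elitism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .featurebank import FeatureTable

__all__ = [
    "ESCDScores",
    "GAConfig",
    "Chromosome",
    "pearson",
    "connection_values",
    "distance_values",
    "escd_select",
    "ga_select",
    "ga_optimize_real",
]


# ---------------------------------------------------------------------------
# ESCD


@dataclass
class ESCDScores:
    """Per-feature connection values, distance values, and ranking."""

    connection: np.ndarray  # C_i in [0, 1]
    distance: np.ndarray  # D_i >= 0 (normalized, <= 1)
    score: np.ndarray  # C_i + D_i
    ranking: np.ndarray  # permutation, best first


def pearson(feature, labels) -> float:
    """Sample Pearson correlation; 0 when either vector is constant."""
    f = np.asarray(feature, dtype=float)
    l = np.asarray(labels, dtype=float)
    if f.shape != l.shape:
        raise ValueError("feature and labels must have equal length")
    if f.size < 2:
        raise ValueError("need at least 2 observations")
    fc = f - f.mean()
    lc = l - l.mean()
    denom = np.sqrt((fc**2).sum() * (lc**2).sum())
    if denom == 0:
        return 0.0
    return float((fc * lc).sum() / denom)


def connection_values(table: FeatureTable) -> np.ndarray:
    """C_i = |PCC(feature_i, labels)| for every feature."""
    y = table.labels.astype(float)
    return np.array(
        [abs(pearson(table.values[:, j], y)) for j in range(table.n_features)]
    )


def distance_values(table: FeatureTable, standardize: bool = True) -> np.ndarray:
    """Mean Euclidean distance of each feature column to all others.

    Columns are z-scored first by default so the statistic measures
    redundancy of shape, not of units.
    """
    if table.n_features < 2:
        raise ValueError("distance values need at least 2 features")
    x = table.values
    if standardize:
        mu = x.mean(axis=0)
        sd = x.std(axis=0, ddof=1)
        sd = np.where(sd > 0, sd, 1.0)
        x = (x - mu) / sd
    g = x.T @ x
    sq = np.diag(g)
    d2 = sq[:, None] + sq[None, :] - 2 * g
    ed = np.sqrt(np.clip(d2, 0.0, None))
    q = table.n_features
    return ed.sum(axis=1) / (q - 1)


def escd_scores(table: FeatureTable, standardize: bool = True) -> ESCDScores:
    """Connection + max-normalized distance score for every feature."""
    c = connection_values(table)
    d = distance_values(table, standardize=standardize)
    dmax = d.max()
    d_norm = d / dmax if dmax > 0 else d
    score = c + d_norm
    # stable descending sort; ties go to the lower feature index
    ranking = np.argsort(-score, kind="stable")
    return ESCDScores(connection=c, distance=d_norm, score=score, ranking=ranking)


def escd_select(
    table: FeatureTable, q: int, standardize: bool = True
) -> tuple[ESCDScores, list[str]]:
    """Return ESCD scores and the names of the top-q features."""
    if not 1 <= q <= table.n_features:
        raise ValueError(f"q must be in [1, {table.n_features}]")
    scores = escd_scores(table, standardize=standardize)
    selected = [table.feature_names[i] for i in scores.ranking[:q]]
    return scores, selected


# ---------------------------------------------------------------------------
# genetic algorithms


@dataclass
class GAConfig:
    """Genetic-algorithm settings.

    Defaults follow the study configuration: population 300, 250
    generations, elitism 10, crossover 0.6, mutation 0.2, iteration cap
    500.  ``feature_penalty`` is the weight on the selected-feature
    fraction subtracted from accuracy in the fitness.
    """

    population: int = 300
    generations: int = 250
    elitism: int = 10
    crossover: float = 0.6
    mutation: float = 0.2
    max_iterations: int = 500
    seed: int = 0
    feature_penalty: float = 0.01
    stagnation: int | None = None  # generations without improvement
    reciprocal_selection: bool = False

    def __post_init__(self):
        if not 0 <= self.crossover <= 1 or not 0 <= self.mutation <= 1:
            raise ValueError("probabilities must lie in [0, 1]")
        if self.population < 2:
            raise ValueError("population must be at least 2")


@dataclass
class Chromosome:
    """A binary feature mask with its evaluated fitness."""

    bits: np.ndarray
    fitness: float = float("nan")
    eval_count: int = 0

    @property
    def n_selected(self) -> int:
        return int(self.bits.sum())


def _roulette_probs(fitness: np.ndarray, reciprocal: bool) -> np.ndarray:
    f = 1.0 / np.maximum(fitness, 1e-12) if reciprocal else fitness.copy()
    if f.min() <= 0:
        f = f - f.min() + 1e-9
    return f / f.sum()


def _repair(bits: np.ndarray, rng) -> np.ndarray:
    if bits.sum() == 0:
        bits = bits.copy()
        bits[rng.integers(bits.size)] = 1
    return bits


def ga_select(
    table: FeatureTable,
    config: GAConfig,
    evaluator,
) -> tuple[Chromosome, list[float]]:
    """Binary-mask GA wrapper feature selection.

    ``evaluator(mask) -> accuracy in [0, 1]``; fitness is
    ``accuracy - feature_penalty * (n_selected / Q)`` so accuracy
    dominates and fewer features break ties.  Returns the best-ever
    chromosome and the per-generation best-fitness history.
    """
    q = table.n_features
    rng = np.random.default_rng(config.seed)
    n = config.population
    evals = 0
    cache: dict[bytes, float] = {}

    def fitness_of(bits):
        nonlocal evals
        key = bits.tobytes()
        if key in cache:
            return cache[key]
        acc = float(evaluator(bits))
        if not np.isfinite(acc):
            raise ValueError(
                f"evaluator returned non-finite accuracy for mask {bits.tolist()}"
            )
        evals += 1
        value = acc - config.feature_penalty * (bits.sum() / q)
        cache[key] = value
        return value

    pop = [_repair(rng.integers(0, 2, q).astype(np.int8), rng) for _ in range(n)]
    fit = np.array([fitness_of(b) for b in pop])
    best = Chromosome(bits=pop[int(np.argmax(fit))].copy(), fitness=float(fit.max()))
    history = []
    stagnant = 0
    for gen in range(config.generations):
        if evals >= config.max_iterations * n:
            break
        order = np.argsort(-fit, kind="stable")
        elite = [pop[i].copy() for i in order[: config.elitism]]
        probs = _roulette_probs(fit, config.reciprocal_selection)
        children = []
        while len(children) < n - len(elite):
            i, j = rng.choice(n, size=2, p=probs)
            child = pop[i].copy()
            if rng.random() < config.crossover:
                point = rng.integers(1, q) if q > 1 else 0
                child = np.concatenate([pop[i][:point], pop[j][point:]])
            if rng.random() < config.mutation:
                flip = rng.integers(q)
                child = child.copy()
                child[flip] = 1 - child[flip]
            children.append(_repair(child, rng))
        pop = elite + children
        fit = np.array([fitness_of(b) for b in pop])
        gen_best = int(np.argmax(fit))
        if fit[gen_best] > best.fitness:
            best = Chromosome(bits=pop[gen_best].copy(), fitness=float(fit[gen_best]))
            stagnant = 0
        else:
            stagnant += 1
        history.append(max(best.fitness, float(fit[gen_best])))
        if config.stagnation is not None and stagnant >= config.stagnation:
            break
    best.eval_count = evals
    return best, history


def ga_optimize_real(
    bounds: list[tuple[float, float, bool]],
    config: GAConfig,
    evaluator,
) -> tuple[np.ndarray, float, list[float]]:
    """Box-bounded real/integer-vector GA.

    ``bounds`` is a list of (low, high, integer?) per gene;
    ``evaluator(vector) -> fitness`` (higher is better).  Returns the
    best vector, its fitness, and the best-fitness history.
    """
    rng = np.random.default_rng(config.seed)
    lo = np.array([b[0] for b in bounds], dtype=float)
    hi = np.array([b[1] for b in bounds], dtype=float)
    is_int = np.array([b[2] for b in bounds], dtype=bool)
    q = len(bounds)
    n = config.population

    def decode(v):
        v = np.clip(v, lo, hi)
        v = np.where(is_int, np.floor(v + 0.5), v)
        return v

    def fitness_of(v):
        f = float(evaluator(decode(v)))
        if not np.isfinite(f):
            raise ValueError(f"evaluator returned non-finite fitness for {v}")
        return f

    pop = [decode(rng.uniform(lo, hi)) for _ in range(n)]
    fit = np.array([fitness_of(v) for v in pop])
    b = int(np.argmax(fit))
    best_vec, best_fit = pop[b].copy(), float(fit[b])
    history = []
    for gen in range(config.generations):
        order = np.argsort(-fit, kind="stable")
        elite = [pop[i].copy() for i in order[: config.elitism]]
        probs = _roulette_probs(fit, config.reciprocal_selection)
        children = []
        while len(children) < n - len(elite):
            i, j = rng.choice(n, size=2, p=probs)
            child = pop[i].copy()
            if rng.random() < config.crossover and q > 1:
                point = rng.integers(1, q)
                child = np.concatenate([pop[i][:point], pop[j][point:]])
            if rng.random() < config.mutation:
                g = rng.integers(q)
                child = child.copy()
                child[g] = rng.uniform(lo[g], hi[g])
            children.append(decode(child))
        pop = elite + children
        fit = np.array([fitness_of(v) for v in pop])
        gb = int(np.argmax(fit))
        if fit[gb] > best_fit:
            best_vec, best_fit = pop[gb].copy(), float(fit[gb])
        history.append(best_fit)
    return best_vec, best_fit, history
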