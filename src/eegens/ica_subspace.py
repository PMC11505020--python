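"""Infinite-ICA latent features and the random-subspace ensemble.

The sparse latent-feature model is Z = H (W ⊙ B) + E: observed rows of Z
are noisy mixtures (mixing matrix H) of latent source rows W, with a
binary mask B switching individual source activations on and off under
a Beta-Bernoulli sparsity prior.  Inference is collapsed Gibbs sampling
on a finite truncation of Q_trunc candidate sources: each mask entry is
sampled with its weight integrated out, then weights, mixing matrix,
activation probabilities and noise variance get conjugate updates.  The
number of rows of B left active is the model's own estimate of how many
independent sources the data carry — the quantity that motivates using
the "infinite" variant instead of fixing the source count a priori.

The classification half trains one RBF-kernel SVM (or an MLP + extended
nearest neighbor + SVM trio in hybrid mode) per random feature subspace
— a disjoint partition or classical overlapping subsets — and
majority-votes all members.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import FastICA
from sklearn.model_selection import GridSearchCV
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .ensemble_rank import majority_vote
from .featurebank import FeatureTable

logger = logging.getLogger(__name__)

__all__ = [
    "IICAModel",
    "SubspacePlan",
    "fit_iica",
    "iica_features",
    "plan_subspaces",
    "plan_random_subspaces",
    "EKNNClassifier",
    "eknn_predict",
    "SubspaceEnsemble",
    "fit_subspace_ensemble",
    "IICASubspacePipeline",
]


@dataclass
class IICAModel:
    """Posterior state of the sparse latent-feature sampler."""

    H: np.ndarray  # (n_obs, q_trunc) mixing matrix
    W: np.ndarray  # (q_trunc, d) source weights
    B: np.ndarray  # (q_trunc, d) binary activation mask
    pi: np.ndarray  # (q_trunc,) activation probabilities
    sigma_e2: float
    error_trace: np.ndarray  # per-sweep mean squared reconstruction error
    seed: int
    # posterior means over the second half of the sweeps; a single final
    # draw carries substantial sampling noise, so downstream encoders
    # should prefer these
    H_mean: np.ndarray | None = None
    sigma_e2_mean: float | None = None

    @property
    def active_counts(self) -> np.ndarray:
        return self.B.sum(axis=1)

    @property
    def n_active_sources(self) -> int:
        return int((self.active_counts > 0).sum())

    def reconstruction(self) -> np.ndarray:
        return self.H @ (self.W * self.B)


def fit_iica(
    z,
    q_trunc: int = 16,
    sweeps: int = 200,
    seed: int = 0,
    alpha: float = 2.0,
    sigma_w2: float = 1.0,
    sigma_h2: float = 1.0,
) -> IICAModel:
    """Gibbs-sample the finite-truncation sparse linear-Gaussian model.

    ``z`` is (n_obs x d): observed rows, d data points.  ``alpha`` is
    the sparsity concentration: activation probabilities get a
    Beta(alpha/q_trunc + m_q, 1 + d - m_q) conjugate update, so with a
    modest alpha most of the q_trunc candidate rows switch off unless
    the data support them.
    """
    z = np.asarray(z, dtype=float)
    if z.ndim != 2:
        raise ValueError("z must be 2-D (observations x data points)")
    if not np.isfinite(z).all():
        raise ValueError("z contains non-finite entries")
    if q_trunc < 1 or sweeps < 1:
        raise ValueError("q_trunc and sweeps must be positive")
    n_obs, d = z.shape
    if q_trunc > n_obs:
        logger.warning(
            "q_trunc=%d exceeds the number of observed rows (%d)", q_trunc, n_obs
        )
    rng = np.random.default_rng(seed)

    # Start from the empty mask with a data-informed mixing matrix: each
    # candidate column sits on a distinct singular direction of Z, so
    # rows whose direction carries only noise-level variance never
    # accumulate activations (a random H instead splits real structure
    # redundantly across rows and the active count loses its meaning).
    # Columns are kept at the prior's natural scale
    # (norm ~ sqrt(n_obs * sigma_h2)); a column scaled down toward zero
    # would make spurious activations on it likelihood-free.
    u, sv, _ = np.linalg.svd(z, full_matrices=False)
    k = min(q_trunc, sv.size)
    H = rng.normal(0, np.sqrt(sigma_h2), size=(n_obs, q_trunc))
    H[:, :k] = u[:, :k] * np.sqrt(n_obs * sigma_h2)
    B = np.zeros((q_trunc, d))
    W = np.zeros((q_trunc, d))
    pi = np.full(q_trunc, (alpha / q_trunc) / (alpha / q_trunc + 1.0))
    # Initialize the noise variance from the SVD tail (the part of the
    # spectrum no truncated model could explain) rather than at an
    # arbitrary hot value: a large initial variance lets junk
    # activations latch on during burn-in and they are slow to die.
    if sv.size > k:
        sigma_e2 = float((sv[k:] ** 2).sum() / ((sv.size - k) * d))
    else:
        sigma_e2 = float(z.var() / 100.0)
    sigma_e2 = max(sigma_e2, 1e-12)

    A = W * B
    errors = np.empty(sweeps)
    burn = sweeps // 2
    h_sum = np.zeros_like(H)
    sig_sum = 0.0
    n_avg = 0
    for sweep in range(sweeps):
        # --- mask and weights, row by row, weight integrated out -------
        R = z - H @ A  # residual with all rows in
        for q in range(q_trunc):
            h = H[:, q]
            hh = float(h @ h)
            # residual with row q removed
            Rq = R + np.outer(h, A[q])
            lam = hh / sigma_e2 + 1.0 / sigma_w2
            m = (h @ Rq) / sigma_e2 / lam
            # collapsed Beta-Bernoulli predictive for the prior odds:
            # (alpha/Q + m_{q,-i}) / (1 + (d-1) - m_{q,-i}); using the
            # predictive instead of a sampled pi_q avoids the ratchet
            # where one lucky draw of pi_q mass-activates a row
            m_minus = B[q].sum() - B[q]
            log_odds = (
                np.log(alpha / q_trunc + m_minus)
                - np.log(d - m_minus)
                - 0.5 * np.log(sigma_w2 * lam)
                + 0.5 * lam * m**2
            )
            p_on = 1.0 / (1.0 + np.exp(-np.clip(log_odds, -500, 500)))
            b = (rng.random(d) < p_on).astype(float)
            w = np.where(
                b > 0,
                rng.normal(m, np.sqrt(1.0 / lam)),
                0.0,
            )
            B[q] = b
            W[q] = w
            A[q] = w * b
            R = Rq - np.outer(h, A[q])

        # --- activation probabilities ---------------------------------
        m_q = B.sum(axis=1)
        pi = rng.beta(alpha / q_trunc + m_q, 1.0 + d - m_q)
        pi = np.clip(pi, 1e-12, 1 - 1e-12)

        # --- mixing matrix, conjugate Gaussian over the active block ---
        # Columns of dead rows (m_q = 0) are left untouched: their
        # conditional is the prior, and redrawing them from it lets a
        # random direction drift onto structure the active rows already
        # explain, inflating the active count.  Skipping the update is a
        # valid Gibbs move and keeps those columns on the noise
        # directions they were initialized to.
        act = np.flatnonzero(m_q > 0)
        if act.size:
            Aa = A[act]
            prec = Aa @ Aa.T / sigma_e2 + np.eye(act.size) / sigma_h2
            cov = np.linalg.inv(prec)
            mean = z @ Aa.T / sigma_e2 @ cov
            chol = np.linalg.cholesky(cov)
            H[:, act] = mean + rng.standard_normal((n_obs, act.size)) @ chol.T

        # --- noise variance, conjugate inverse gamma -------------------
        resid = z - H @ A
        ss = float((resid**2).sum())
        a_post = 1.0 + n_obs * d / 2.0
        b_post = 1.0 + ss / 2.0
        sigma_e2 = float(b_post / rng.gamma(a_post, 1.0))
        errors[sweep] = ss / (n_obs * d)
        if sweep >= burn:
            h_sum += H
            sig_sum += sigma_e2
            n_avg += 1

    return IICAModel(
        H=H,
        W=W,
        B=B,
        pi=pi,
        sigma_e2=sigma_e2,
        error_trace=errors,
        seed=seed,
        H_mean=h_sum / max(n_avg, 1),
        sigma_e2_mean=sig_sum / max(n_avg, 1),
    )


def iica_features(model: IICAModel, table: FeatureTable) -> FeatureTable:
    """Active latent sources as a feature table (samples x sources).

    Falls back to the top-variance raw features when the mask died out
    entirely, with a logged warning.
    """
    active = np.flatnonzero(model.active_counts > 0)
    if active.size == 0:
        logger.warning(
            "no active latent sources; falling back to top-variance features"
        )
        var = table.values.var(axis=0)
        top = np.argsort(-var, kind="stable")[: min(8, table.n_features)]
        names = [table.feature_names[i] for i in top]
        return table.select(names)
    feats = (model.W * model.B)[active].T  # samples x active sources
    names = [f"iica.s{int(q)}" for q in active]
    return FeatureTable(
        values=feats,
        feature_names=names,
        labels=table.labels,
        provenance={n: "iica" for n in names},
    )


@dataclass
class SubspacePlan:
    """Feature-index blocks, one per ensemble member.

    A partition plan (the default) has disjoint blocks covering all
    features; an ``overlapping`` plan holds independent random subsets
    in the classical random-subspace style.
    """

    subspaces: list[list[int]]
    seed: int
    overlapping: bool = False

    def __post_init__(self):
        if any(len(b) == 0 for b in self.subspaces):
            raise ValueError("empty subspace")
        if not self.overlapping:
            flat = [i for block in self.subspaces for i in block]
            if len(flat) != len(set(flat)):
                raise ValueError("subspaces overlap")


def plan_subspaces(q: int, s: int, seed: int = 0) -> SubspacePlan:
    """Uniformly random partition of q features into s near-equal blocks."""
    if not 1 <= s <= q:
        raise ValueError(f"need 1 <= s <= {q}, got s={s}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(q)
    blocks = [sorted(map(int, chunk)) for chunk in np.array_split(perm, s)]
    return SubspacePlan(subspaces=blocks, seed=seed)


def plan_random_subspaces(
    q: int, s: int, subset_size: int | None = None, seed: int = 0
) -> SubspacePlan:
    """Classical random-subspace plan: s independent subsets.

    Each member sees ``subset_size`` features drawn without replacement
    (default: half, at least 1).  Unlike a partition, every informative
    direction reaches roughly half the members, so a compact feature set
    whose class signal lives in few directions still yields a
    majority of better-than-chance voters.
    """
    if not 1 <= s:
        raise ValueError("s must be at least 1")
    if subset_size is None:
        subset_size = max(1, q // 2)
    if not 1 <= subset_size <= q:
        raise ValueError(f"subset_size must be in [1, {q}]")
    rng = np.random.default_rng(seed)
    blocks = [
        sorted(map(int, rng.choice(q, size=subset_size, replace=False)))
        for _ in range(s)
    ]
    return SubspacePlan(subspaces=blocks, seed=seed, overlapping=True)


# ---------------------------------------------------------------------------
# extended nearest neighbor


class EKNNClassifier:
    """Extended nearest-neighbor rule.

    A query is tentatively added to each class in turn, and the class
    maximizing the generalized class-wise coherence — the average, over
    classes, of the fraction of same-class points among each member's k
    nearest neighbors — wins.  Ties go to class 0.
    """

    def __init__(self, k: int = 5):
        if k < 1:
            raise ValueError("k must be at least 1")
        self.k = k

    def fit(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=int)
        self.classes_ = np.unique(y)
        if self.classes_.size < 2:
            raise ValueError("training data contains a single class")
        if self.k > len(x):
            raise ValueError("k exceeds the training-set size")
        self.x_ = x
        self.y_ = y
        return self

    def get_params(self, deep=True):
        return {"k": self.k}

    def set_params(self, **params):
        for key, value in params.items():
            setattr(self, key, value)
        return self

    def _coherence(self, x_all, y_all) -> float:
        # k nearest neighbors of every point within the augmented set
        d = np.linalg.norm(x_all[:, None, :] - x_all[None, :, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        nbrs = np.argsort(d, axis=1, kind="stable")[:, : self.k]
        same = y_all[nbrs] == y_all[:, None]
        total = 0.0
        for c in self.classes_:
            members = y_all == c
            total += same[members].mean()
        return total / self.classes_.size

    def predict(self, queries) -> np.ndarray:
        queries = np.atleast_2d(np.asarray(queries, dtype=float))
        out = np.empty(len(queries), dtype=int)
        for i, q in enumerate(queries):
            x_all = np.vstack([self.x_, q])
            best_c, best_stat = None, -np.inf
            for c in self.classes_:  # ascending: ties stay with class 0
                y_all = np.append(self.y_, c)
                stat = self._coherence(x_all, y_all)
                if stat > best_stat + 1e-12:
                    best_c, best_stat = c, stat
            out[i] = best_c
        return out


def eknn_predict(train: FeatureTable, queries, k: int = 5) -> np.ndarray:
    """Functional wrapper around :class:`EKNNClassifier`."""
    clf = EKNNClassifier(k=k).fit(train.values, train.labels)
    return clf.predict(queries)


# ---------------------------------------------------------------------------
# subspace ensembles


class SubspaceEnsemble:
    """Random-subspace ensemble with SVM-only or hybrid members."""

    def __init__(
        self,
        plan: SubspacePlan,
        mode: str = "svm",
        k: int = 5,
        mlp_hidden: int = 32,
        mlp_epochs: int = 500,
        cv: int = 3,
        seed: int = 0,
    ):
        if mode not in ("svm", "hybrid"):
            raise ValueError("mode must be 'svm' or 'hybrid'")
        self.plan = plan
        self.mode = mode
        self.k = k
        self.mlp_hidden = mlp_hidden
        self.mlp_epochs = mlp_epochs
        self.cv = cv
        self.seed = seed

    def _svm(self, x, y):
        grid = GridSearchCV(
            SVC(kernel="rbf", gamma="scale"),
            {"C": [0.5, 1.0, 4.0, 8.0]},
            cv=min(self.cv, np.bincount(y).min()),
            n_jobs=1,
        )
        grid.fit(x, y)
        return grid.best_estimator_

    def fit(self, table: FeatureTable) -> "SubspaceEnsemble":
        q = table.n_features
        covered = {i for block in self.plan.subspaces for i in block}
        if self.plan.overlapping:
            if covered and max(covered) >= q:
                raise ValueError("plan indexes beyond the table width")
        elif covered != set(range(q)):
            raise ValueError("plan does not match the table width")
        y = table.labels
        self.members_ = []
        self.member_names_ = []
        self.scalers_ = []
        for b, block in enumerate(self.plan.subspaces):
            x = table.values[:, block]
            if np.allclose(x.std(axis=0), 0):
                logger.warning("subspace %d has zero variance; skipped", b)
                continue
            scaler = StandardScaler().fit(x)
            xs = scaler.transform(x)
            if self.mode == "svm":
                models = [("svm", self._svm(xs, y))]
            else:
                mlp = MLPClassifier(
                    hidden_layer_sizes=(self.mlp_hidden,),
                    activation="logistic",
                    max_iter=self.mlp_epochs,
                    random_state=self.seed + b,
                )
                mlp.fit(xs, y)
                eknn = EKNNClassifier(k=min(self.k, len(xs) - 1)).fit(xs, y)
                models = [
                    ("mlp", mlp),
                    ("eknn", eknn),
                    ("svm", self._svm(xs, y)),
                ]
            for name, model in models:
                self.members_.append((b, model))
                self.member_names_.append(f"r{b}.{name}")
                self.scalers_.append((b, scaler))
        if not self.members_:
            raise ValueError("all subspaces degenerate; nothing to train")
        return self

    def _votes(self, table: FeatureTable) -> np.ndarray:
        votes = []
        for (b, model), (_, scaler) in zip(self.members_, self.scalers_):
            x = scaler.transform(table.values[:, self.plan.subspaces[b]])
            votes.append(model.predict(x).astype(int))
        return np.asarray(votes)

    def predict(self, table: FeatureTable) -> np.ndarray:
        return majority_vote(self._votes(table))

    def manifest(self) -> str:
        return json.dumps(
            {
                "method": "ica_subspace",
                "mode": self.mode,
                "seed": self.seed,
                "subspaces": self.plan.subspaces,
                "members": self.member_names_,
            },
            sort_keys=True,
        )


def fit_subspace_ensemble(
    table: FeatureTable,
    plan: SubspacePlan,
    mode: str = "svm",
    seed: int = 0,
    **kwargs,
) -> SubspaceEnsemble:
    """Train a random-subspace ensemble on a feature table."""
    return SubspaceEnsemble(plan, mode=mode, seed=seed, **kwargs).fit(table)


class IICASubspacePipeline:
    """The latent-subspace pipeline end to end: z-score, infinite-ICA features, then the
    random-subspace (hybrid or SVM) voting ensemble.

    Latent features for unseen samples come from the per-sample Bayes
    posterior mean of the masked sources given the posterior-mean mixing
    matrix and noise variance (ridge regression on H restricted to
    active rows).  Because the Gaussian-weight half of the model leaves
    rotations of the latent basis unidentified, the scores are rotated
    to maximal statistical independence (FastICA) before the subspace
    split: without this, class structure can smear across every latent
    and any feature subset destroys it.
    """

    def __init__(
        self,
        q_trunc: int = 16,
        sweeps: int = 100,
        s_subspaces: int = 9,
        subset_fraction: float = 0.8,
        mode: str = "hybrid",
        seed: int = 0,
    ):
        self.q_trunc = q_trunc
        self.sweeps = sweeps
        self.s_subspaces = s_subspaces
        self.subset_fraction = subset_fraction
        self.mode = mode
        self.seed = seed

    def _latent(self, x: np.ndarray) -> np.ndarray:
        h = self.model_.H_mean[:, self.active_]
        s2 = self.model_.sigma_e2_mean
        prec = h.T @ h / s2 + np.eye(h.shape[1])
        proj = np.linalg.solve(prec, h.T / s2)
        scores = (proj @ x.T).T
        if self.rotation_ is not None:
            scores = self.rotation_.transform(scores)
        return scores

    def fit(self, table: FeatureTable) -> "IICASubspacePipeline":
        self.scaler_ = StandardScaler().fit(table.values)
        z = self.scaler_.transform(table.values).T  # rows=features, cols=samples
        self.model_ = fit_iica(
            z, q_trunc=self.q_trunc, sweeps=self.sweeps, seed=self.seed
        )
        self.active_ = np.flatnonzero(self.model_.active_counts > 0)
        self.rotation_ = None
        if self.active_.size == 0:
            feats = iica_features(self.model_, table)
        else:
            x = self.scaler_.transform(table.values)
            if self.active_.size > 1:
                h = self.model_.H_mean[:, self.active_]
                s2 = self.model_.sigma_e2_mean
                prec = h.T @ h / s2 + np.eye(h.shape[1])
                proj = np.linalg.solve(prec, h.T / s2)
                raw_scores = (proj @ x.T).T
                self.rotation_ = FastICA(
                    n_components=self.active_.size,
                    random_state=self.seed,
                    max_iter=2000,
                    whiten="unit-variance",
                )
                self.rotation_.fit(raw_scores)
            feats = FeatureTable(
                values=self._latent(x),
                feature_names=[f"iica.s{int(q)}" for q in self.active_],
                labels=table.labels,
            )
        size = max(1, int(round(self.subset_fraction * feats.n_features)))
        self.plan_ = plan_random_subspaces(
            feats.n_features, self.s_subspaces, subset_size=size, seed=self.seed
        )
        self.feature_names_ = feats.feature_names
        self.ensemble_ = SubspaceEnsemble(
            self.plan_, mode=self.mode, seed=self.seed
        ).fit(feats)
        return self

    def _transform(self, table: FeatureTable) -> FeatureTable:
        if self.active_.size == 0:
            return table.select(self.feature_names_)
        return FeatureTable(
            values=self._latent(self.scaler_.transform(table.values)),
            feature_names=list(self.feature_names_),
            labels=table.labels,
        )

    def predict(self, table: FeatureTable) -> np.ndarray:
        return self.ensemble_.predict(self._transform(table))

    def manifest(self) -> str:
        return json.dumps(
            {
                "method": "ica",
                "seed": self.seed,
                "q_trunc": self.q_trunc,
                "sweeps": self.sweeps,
                "active_sources": self.active_.tolist(),
                "mode": self.mode,
                "subspaces": self.plan_.subspaces,
            },
            sort_keys=True,
        )
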