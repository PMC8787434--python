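"""Microstate discretization and transition-model estimation.

Feature trajectories are clustered into microstates with k-means (the
features are z-scored per column first, since the RMSD axis spans a few
Å while the distance axis spans tens of Å). Transitions are counted with
a sliding window at a chosen lag, trimmed to the largest strongly
connected set, and the transition matrix is estimated either as the
reversible maximum-likelihood estimate (detailed balance enforced via
the standard self-consistent iteration on symmetrized count variables)
or sampled from the conjugate Dirichlet posterior for uncertainty bands.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans

from . import _markov
from .trajectory import DiscreteTrajectorySet, FeatureTrajectory

__all__ = [
    "Discretization",
    "CountMatrix",
    "TransitionModel",
    "BayesianEnsemble",
    "KMeansDiscretizer",
    "MarkovStateModel",
    "kmeans_discretize",
    "count_transitions",
    "largest_connected_set",
    "estimate_reversible_mle",
    "sample_bayesian_posterior",
    "stationary_distribution",
    "implied_timescales_from_model",
]


# ---------------------------------------------------------------------------
# Discretization
# ---------------------------------------------------------------------------

@dataclass
class Discretization:
    """k-means microstate assignment of a set of feature trajectories."""

    centers: np.ndarray  # (k, n_features), original units
    dtrajs: DiscreteTrajectorySet
    inertia: float
    feature_means: np.ndarray
    feature_scales: np.ndarray


class KMeansDiscretizer(BaseEstimator):
    """Microstate discretizer: per-column z-scoring followed by k-means++.

    Cluster centers are reported in original feature units
    (``centers_``); labels and inertia refer to the standardized space.
    """

    def __init__(self, n_clusters: int = 100, seed: int = 0, max_iter: int = 300,
                 tol: float = 1e-6):
        self.n_clusters = n_clusters
        self.seed = seed
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, features: list[FeatureTrajectory] | FeatureTrajectory, y=None):
        if isinstance(features, FeatureTrajectory):
            features = [features]
        X = np.vstack([f.values for f in features])
        if X.shape[0] < self.n_clusters:
            raise ValueError(
                f"k={self.n_clusters} exceeds total frame count {X.shape[0]}"
            )
        self.feature_means_ = X.mean(axis=0)
        scales = X.std(axis=0)
        self.feature_scales_ = np.where(scales > 0, scales, 1.0)
        Z = (X - self.feature_means_) / self.feature_scales_
        km = KMeans(
            n_clusters=self.n_clusters,
            init="k-means++",
            n_init=1,
            max_iter=self.max_iter,
            tol=self.tol,
            random_state=self.seed,
        ).fit(Z)
        self.kmeans_ = km
        self.centers_ = km.cluster_centers_ * self.feature_scales_ + self.feature_means_
        self.inertia_ = float(km.inertia_)
        lengths = [f.n_frames for f in features]
        splits = np.cumsum(lengths)[:-1]
        self.dtrajs_ = [d.astype(int) for d in np.split(km.labels_, splits)]
        self.step_unit_ = features[0].frame_interval
        return self

    def transform(self, features: list[FeatureTrajectory] | FeatureTrajectory):
        if isinstance(features, FeatureTrajectory):
            features = [features]
        out = []
        for f in features:
            Z = (f.values - self.feature_means_) / self.feature_scales_
            out.append(self.kmeans_.predict(Z).astype(int))
        return out


def kmeans_discretize(
    features: list[FeatureTrajectory] | FeatureTrajectory,
    k: int,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-6,
) -> Discretization:
    """Functional wrapper over :class:`KMeansDiscretizer`."""
    est = KMeansDiscretizer(n_clusters=k, seed=seed, max_iter=max_iter, tol=tol).fit(
        features
    )
    return Discretization(
        centers=est.centers_,
        dtrajs=DiscreteTrajectorySet(
            trajectories=est.dtrajs_, n_states=k, step_unit=est.step_unit_
        ),
        inertia=est.inertia_,
        feature_means=est.feature_means_,
        feature_scales=est.feature_scales_,
    )


# ---------------------------------------------------------------------------
# Counting and trimming
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Sliding-window transition counts at a fixed lag."""

    counts: np.ndarray
    lag: int
    step_unit: float = 1.0
    active_set: np.ndarray | None = None
    all_zero: bool = False

    @property
    def lag_time(self) -> float:
        return self.lag * self.step_unit


def _dtraj_list(dtrajs) -> tuple[list[np.ndarray], int, float]:
    if isinstance(dtrajs, Discretization):
        dtrajs = dtrajs.dtrajs
    if isinstance(dtrajs, DiscreteTrajectorySet):
        return dtrajs.trajectories, dtrajs.n_states, dtrajs.step_unit
    trajs = [np.asarray(t, dtype=int) for t in dtrajs]
    n_states = int(max(t.max() for t in trajs)) + 1
    return trajs, n_states, 1.0


def count_transitions(dtrajs, lag: int) -> CountMatrix:
    """Sliding-window counts: C_ij = #{t : s_t = i, s_{t+lag} = j} summed
    over trajectories (never across trajectory boundaries)."""
    if lag < 1:
        raise ValueError("lag must be at least 1")
    trajs, n_states, step_unit = _dtraj_list(dtrajs)
    C = np.zeros((n_states, n_states))
    any_pairs = False
    for t in trajs:
        if t.size > lag:
            np.add.at(C, (t[:-lag], t[lag:]), 1.0)
            any_pairs = True
    if not any_pairs:
        warnings.warn(
            f"lag {lag} is not shorter than any trajectory: all counts are zero",
            stacklevel=2,
        )
    return CountMatrix(counts=C, lag=lag, step_unit=step_unit, all_zero=not any_pairs)


def largest_connected_set(counts: CountMatrix | np.ndarray) -> np.ndarray:
    """States of the largest strongly connected component of the count graph
    (edge i->j iff C_ij > 0); size ties resolved toward the component
    containing the smallest state index."""
    C = counts.counts if isinstance(counts, CountMatrix) else np.asarray(counts)
    return _markov.strongly_connected_sets(C)[0]


# ---------------------------------------------------------------------------
# Transition models
# ---------------------------------------------------------------------------

@dataclass
class TransitionModel:
    """A validated row-stochastic transition matrix at a fixed lag."""

    transition_matrix: np.ndarray
    stationary: np.ndarray
    lag: int = 1
    step_unit: float = 1.0
    reversible: bool = False
    active_set: np.ndarray | None = None
    eigenvalues: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.transition_matrix = _markov.assert_stochastic(self.transition_matrix)
        self.stationary = np.asarray(self.stationary, dtype=float)
        if np.any(self.stationary < -1e-12) or abs(self.stationary.sum() - 1) > 1e-10:
            raise ValueError("stationary distribution must be non-negative and sum to 1")
        if self.reversible and not _markov.is_reversible(
            self.transition_matrix, self.stationary
        ):
            raise ValueError("detailed-balance residual exceeds 1e-8 for reversible model")
        if self.eigenvalues is None:
            self.eigenvalues = _markov.sorted_eigenvalues(self.transition_matrix)
        if self.active_set is None:
            self.active_set = np.arange(self.transition_matrix.shape[0])

    @property
    def n_states(self) -> int:
        return self.transition_matrix.shape[0]

    @property
    def lag_time(self) -> float:
        return self.lag * self.step_unit

    def timescales(self, n_timescales: int) -> np.ndarray:
        return implied_timescales_from_model(self, n_timescales)


def estimate_reversible_mle(
    counts: CountMatrix | np.ndarray,
    tol: float = 1e-12,
    max_iter: int = 100_000,
) -> TransitionModel:
    """Maximum-likelihood reversible transition matrix from counts.

    Standard self-consistent iteration on the symmetrized variables
    x_ij (= pi_i T_ij up to scale):

        x_ij <- (C_ij + C_ji) / (c_i / x_i + c_j / x_j)

    with c_i the count row sums and x_i the current row sums of x. The
    fixed point maximizes the likelihood under detailed balance;
    pi_i = x_i / sum(x), T_ij = x_ij / x_i. Counts must already be
    restricted to a strongly connected active set.
    """
    if isinstance(counts, CountMatrix):
        C = counts.counts
        lag, step_unit = counts.lag, counts.step_unit
        active = counts.active_set
    else:
        C = np.asarray(counts, dtype=float)
        lag, step_unit, active = 1, 1.0, None
    if len(_markov.strongly_connected_sets(C)) != 1:
        raise ValueError(
            "count matrix is not strongly connected; restrict to "
            "largest_connected_set first"
        )
    c = C.sum(axis=1)
    Csym = C + C.T
    x = Csym.copy()
    for it in range(max_iter):
        xi = x.sum(axis=1)
        q = c / xi
        with np.errstate(divide="ignore", invalid="ignore"):
            x_new = np.where(Csym > 0, Csym / (q[:, None] + q[None, :]), 0.0)
        delta = np.max(np.abs(x_new / x_new.sum() - x / x.sum()))
        x = x_new
        if delta < tol:
            break
    else:
        raise RuntimeError(
            f"reversible MLE did not converge in {max_iter} iterations "
            f"(last residual {delta:.3e})"
        )
    xi = x.sum(axis=1)
    T = x / xi[:, None]
    pi = xi / xi.sum()
    return TransitionModel(
        transition_matrix=T,
        stationary=pi,
        lag=lag,
        step_unit=step_unit,
        reversible=True,
        active_set=active,
    )


@dataclass
class BayesianEnsemble:
    """Posterior transition-matrix samples for uncertainty quantification."""

    samples: list[TransitionModel]
    prior_strength: float

    def timescale_samples(self, n_timescales: int) -> np.ndarray:
        return np.array([m.timescales(n_timescales) for m in self.samples])

    def mean_matrix(self) -> np.ndarray:
        return np.mean([m.transition_matrix for m in self.samples], axis=0)


def sample_bayesian_posterior(
    counts: CountMatrix | np.ndarray,
    n_samples: int = 100,
    alpha: float = 0.0,
    seed: int = 0,
) -> BayesianEnsemble:
    """Sample row-stochastic matrices from the conjugate Dirichlet posterior
    Dir(C_i1 + alpha, ..., C_iK + alpha) per row, via gamma variates (a zero
    concentration yields an exact zero entry). Samples are non-reversible;
    they serve for credible bands on scalar functionals such as timescales.
    """
    if isinstance(counts, CountMatrix):
        C = counts.counts
        lag, step_unit, active = counts.lag, counts.step_unit, counts.active_set
    else:
        C = np.asarray(counts, dtype=float)
        lag, step_unit, active = 1, 1.0, None
    conc = C + alpha
    if np.any(conc.sum(axis=1) <= 0):
        raise ValueError("every row needs at least one positive count or alpha > 0")
    rng = np.random.default_rng(seed)
    samples = []
    for _ in range(n_samples):
        G = rng.gamma(np.maximum(conc, 0.0))
        rowsums = G.sum(axis=1)
        bad = rowsums <= 0
        if np.any(bad):  # pathological all-zero gamma draw; retry those rows
            G[bad] = rng.gamma(np.maximum(conc[bad], 1e-8))
            rowsums = G.sum(axis=1)
        T = G / rowsums[:, None]
        pi = _markov.stationary_distribution(T)
        samples.append(
            TransitionModel(
                transition_matrix=T,
                stationary=pi,
                lag=lag,
                step_unit=step_unit,
                reversible=False,
                active_set=active,
            )
        )
    return BayesianEnsemble(samples=samples, prior_strength=alpha)


def stationary_distribution(model: TransitionModel | np.ndarray) -> np.ndarray:
    """Stationary distribution of a transition model or raw stochastic matrix."""
    if isinstance(model, TransitionModel):
        return model.stationary
    return _markov.stationary_distribution(model)


def implied_timescales_from_model(
    model: TransitionModel, n_timescales: int
) -> np.ndarray:
    """t_i = -tau / ln|lambda_{i+1}| in the model's physical time unit.

    Non-reversible models can have complex eigenvalue pairs; their modulus
    is used and a warning is emitted.
    """
    evs = model.eigenvalues[1 : n_timescales + 1]
    if not model.reversible and np.any(np.abs(np.imag(evs)) > 1e-12):
        warnings.warn(
            "complex eigenvalues encountered; timescales use |lambda|",
            stacklevel=2,
        )
    return _markov.implied_timescales(
        model.transition_matrix, n_timescales, lag=model.lag_time
    )


class MarkovStateModel(BaseEstimator):
    """Estimate a validated transition model from discrete trajectories.

    ``fit`` counts sliding-window transitions at ``lag``, trims to the
    largest strongly connected set, and estimates either the reversible
    MLE (default) or the row-normalized nonreversible matrix. Fitted
    attributes: ``counts_``, ``active_set_``, ``transition_matrix_``,
    ``stationary_distribution_``, ``eigenvalues_``, ``model_``.
    """

    def __init__(self, lag: int = 1, reversible: bool = True, mle_tol: float = 1e-12,
                 max_iter: int = 100_000):
        self.lag = lag
        self.reversible = reversible
        self.mle_tol = mle_tol
        self.max_iter = max_iter

    def fit(self, dtrajs, y=None):
        cm = count_transitions(dtrajs, self.lag)
        if cm.all_zero:
            raise ValueError(f"no transition pairs at lag {self.lag}")
        active = largest_connected_set(cm)
        C = cm.counts[np.ix_(active, active)]
        sub = CountMatrix(
            counts=C, lag=cm.lag, step_unit=cm.step_unit, active_set=active
        )
        if self.reversible:
            model = estimate_reversible_mle(sub, tol=self.mle_tol, max_iter=self.max_iter)
        else:
            T = C / C.sum(axis=1, keepdims=True)
            model = TransitionModel(
                transition_matrix=T,
                stationary=_markov.stationary_distribution(T),
                lag=cm.lag,
                step_unit=cm.step_unit,
                reversible=False,
                active_set=active,
            )
        self.counts_ = sub
        self.active_set_ = active
        self.model_ = model
        self.transition_matrix_ = model.transition_matrix
        self.stationary_distribution_ = model.stationary
        self.eigenvalues_ = model.eigenvalues
        return self

    def timescales(self, n_timescales: int) -> np.ndarray:
        return self.model_.timescales(n_timescales)
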