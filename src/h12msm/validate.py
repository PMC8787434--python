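"""Markovianity diagnostics: implied-timescale scans and the
Chapman–Kolmogorov test.

A Markov state model is trustworthy at lag tau when (a) the implied
timescales t_i = -tau/ln|lambda_{i+1}| have converged in tau and (b) the
model propagated to k*tau reproduces transition probabilities
re-estimated directly from the data at lag k*tau (Chapman–Kolmogorov).
Both diagnostics carry uncertainty: Dirichlet-posterior credible bands
for the timescales and binomial standard errors for the CK cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .msm import (
    CountMatrix,
    MarkovStateModel,
    count_transitions,
    largest_connected_set,
    sample_bayesian_posterior,
)

__all__ = ["ImpliedTimescaleScan", "CKTestResult", "its_scan", "ck_test"]


@dataclass
class ImpliedTimescaleScan:
    """Timescales (and optional posterior bands) as a function of lag."""

    lags: np.ndarray
    timescales: np.ndarray  # (n_lags, n_timescales), physical units
    bayes_bands: np.ndarray | None  # (n_lags, n_timescales, 2) 95% CI
    ok: np.ndarray  # per-lag success flag


def its_scan(
    dtrajs,
    lags,
    n_timescales: int = 4,
    bayes_samples: int = 0,
    alpha: float = 0.0,
    seed: int = 0,
    ci: float = 0.95,
    reversible: bool = True,
    effective_counts: bool = True,
) -> ImpliedTimescaleScan:
    """Reversible-MLE implied timescales at each lag, with optional
    Dirichlet-posterior credible bands.

    Sliding-window counts at lag tau overlap tau-fold, so treating them
    as independent makes the posterior too narrow; with
    ``effective_counts`` (default) the posterior concentration uses
    C/tau, the standard effective-count correction. A lag whose count
    matrix cannot support estimation is flagged and the scan continues.
    """
    lags = np.asarray(sorted(int(l) for l in lags))
    if lags.size == 0 or lags[0] < 1:
        raise ValueError("lags must be positive integers")
    ts = np.full((lags.size, n_timescales), np.nan)
    bands = (
        np.full((lags.size, n_timescales, 2), np.nan) if bayes_samples else None
    )
    ok = np.zeros(lags.size, dtype=bool)
    lo_q, hi_q = 100 * (1 - ci) / 2, 100 * (1 + ci) / 2
    for li, lag in enumerate(lags):
        try:
            est = MarkovStateModel(lag=lag, reversible=reversible).fit(dtrajs)
            ts[li] = est.timescales(n_timescales)
            ok[li] = True
        except (ValueError, RuntimeError):
            continue
        if bayes_samples:
            cm = est.counts_
            if effective_counts and lag > 1:
                cm = CountMatrix(
                    counts=cm.counts / lag, lag=cm.lag,
                    step_unit=cm.step_unit, active_set=cm.active_set,
                )
            ens = sample_bayesian_posterior(
                cm, n_samples=bayes_samples, alpha=alpha,
                seed=seed + 7919 * li,
            )
            samples = ens.timescale_samples(n_timescales)
            finite = np.where(np.isfinite(samples), samples, np.nan)
            bands[li, :, 0] = np.nanpercentile(finite, lo_q, axis=0)
            bands[li, :, 1] = np.nanpercentile(finite, hi_q, axis=0)
    return ImpliedTimescaleScan(lags=lags, timescales=ts, bayes_bands=bands, ok=ok)


@dataclass
class CKTestResult:
    """Chapman–Kolmogorov comparison on metastable state groupings.

    ``estimated[k]`` holds the set-to-set transition probabilities
    re-estimated from the data at lag ``factors[k] * base_lag``;
    ``predicted[k]`` the corresponding power of the base model. Both are
    (n_sets, n_sets) with stationary-weighted aggregation.
    """

    sets: list[np.ndarray]
    base_lag: int
    factors: np.ndarray
    estimated: np.ndarray
    predicted: np.ndarray
    deviations: np.ndarray
    std_errors: np.ndarray  # binomial SE of the estimated entries


def _project_to_sets(
    T: np.ndarray, pi: np.ndarray, active: np.ndarray, sets: list[np.ndarray]
) -> np.ndarray:
    """Set-to-set probabilities with microstates weighted by pi within the
    source set. States absent from ``active`` are ignored."""
    pos = {int(s): i for i, s in enumerate(active)}
    out = np.full((len(sets), len(sets)), np.nan)
    idx_sets = [np.array([pos[int(s)] for s in S if int(s) in pos], dtype=int) for S in sets]
    for a, I in enumerate(idx_sets):
        if I.size == 0 or pi[I].sum() == 0:
            continue
        w = pi[I] / pi[I].sum()
        for b, J in enumerate(idx_sets):
            if J.size == 0:
                out[a, b] = 0.0
                continue
            out[a, b] = float(w @ T[np.ix_(I, J)].sum(axis=1))
    return out


def ck_test(
    dtrajs,
    base_lag: int,
    sets: list,
    factors=(1, 2, 3, 4),
    reversible: bool = True,
) -> CKTestResult:
    """Chapman–Kolmogorov test on user-specified state groupings.

    For each factor k the set-projected k-th power of the base model
    (prediction) is compared with a model re-estimated at lag
    ``k * base_lag`` (estimation). Binomial standard errors
    sqrt(p(1-p)/N_source) accompany each estimated cell, with N_source
    the number of counted transitions leaving the source set.
    """
    sets = [np.unique(np.asarray(S, dtype=int)) for S in sets]
    factors = np.asarray(sorted(int(f) for f in factors))
    if factors.size == 0 or factors[0] < 1:
        raise ValueError("factors must be positive integers")
    base = MarkovStateModel(lag=base_lag, reversible=reversible).fit(dtrajs)
    T_base = base.transition_matrix_
    pi_base = base.stationary_distribution_
    active_base = base.active_set_

    n_sets = len(sets)
    est = np.full((factors.size, n_sets, n_sets), np.nan)
    pred = np.full_like(est, np.nan)
    ses = np.full_like(est, np.nan)
    for fi, k in enumerate(factors):
        pred[fi] = _project_to_sets(
            np.linalg.matrix_power(T_base, int(k)), pi_base, active_base, sets
        )
        mk = MarkovStateModel(lag=int(k) * base_lag, reversible=reversible).fit(dtrajs)
        est[fi] = _project_to_sets(
            mk.transition_matrix_, mk.stationary_distribution_, mk.active_set_, sets
        )
        # counts leaving each set at this lag, for binomial standard errors
        cm = count_transitions(dtrajs, int(k) * base_lag)
        active = largest_connected_set(cm)
        row_counts = cm.counts[active].sum(axis=1)
        pos = {int(s): i for i, s in enumerate(active)}
        for a, S in enumerate(sets):
            I = np.array([pos[int(s)] for s in S if int(s) in pos], dtype=int)
            N = row_counts[I].sum() if I.size else 0.0
            if N > 0:
                p = est[fi, a]
                ses[fi, a] = np.sqrt(np.clip(p * (1 - p), 0.0, None) / N)
    return CKTestResult(
        sets=sets,
        base_lag=base_lag,
        factors=factors,
        estimated=est,
        predicted=pred,
        deviations=np.abs(est - pred),
        std_errors=ses,
    )
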