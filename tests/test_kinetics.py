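"""PCCA+ coarse-graining and transition path theory."""

import itertools

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from h12msm import (
    MarkovStateModel,
    coarse_grain_flux,
    committors,
    decompose_pathways,
    make_metastable_chain,
    pcca_coarse_grain,
    reactive_flux,
    sample_discrete_chain,
    select_representatives,
)
from h12msm.kinetics import FluxNetwork, PCCAPlus
from h12msm.msm import Discretization, TransitionModel
from h12msm.trajectory import DiscreteTrajectorySet

from conftest import random_reversible_model


def _reversible_from_weights(W):
    W = 0.5 * (W + W.T)
    T = W / W.sum(axis=1, keepdims=True)
    pi = W.sum(axis=1) / W.sum()
    return TransitionModel(transition_matrix=T, stationary=pi, reversible=True)


class TestPCCA:
    def test_block_diagonal_gives_crisp_blocks(self):
        rng = np.random.default_rng(0)
        blocks = [3, 2, 4]
        n = sum(blocks)
        W = np.zeros((n, n))
        start = 0
        labels = np.empty(n, dtype=int)
        for b, size in enumerate(blocks):
            sl = slice(start, start + size)
            W[sl, sl] = rng.random((size, size)) + 0.2
            labels[sl] = b
            start += size
        model = _reversible_from_weights(W)
        macro = pcca_coarse_grain(model, 3)
        assert adjusted_rand_score(labels, macro.crisp_assignment) == 1.0
        assert np.all((macro.memberships > 1 - 1e-9) | (macro.memberships < 1e-9))

    def test_planted_metastable_chain_recovered(self, planted_chain, planted_model):
        macro = pcca_coarse_grain(planted_model.model_, 5)
        assert adjusted_rand_score(
            planted_chain.block_labels[planted_model.active_set_],
            macro.crisp_assignment,
        ) == 1.0
        np.testing.assert_allclose(macro.memberships.sum(axis=1), 1.0, atol=1e-9)
        assert macro.macro_populations.sum() == pytest.approx(1.0, abs=1e-9)

    def test_matches_bruteforce_partition_oracle_on_small_instance(self):
        # 6 microstates, 2 planted macrostates; oracle enumerates every
        # 2-partition and maximizes the sum of coarse self-transition
        # probabilities (crisp metastability)
        chain = make_metastable_chain(2, 3, intra_p=0.5, inter_p=0.01, seed=12)
        pi = chain.stationary_distribution
        T = chain.transition_matrix
        model = TransitionModel(transition_matrix=T, stationary=pi, reversible=True)
        best, best_score = None, -np.inf
        for assign in itertools.product([0, 1], repeat=6):
            assign = np.array(assign)
            if len(set(assign)) < 2:
                continue
            score = 0.0
            for m in (0, 1):
                I = np.flatnonzero(assign == m)
                w = pi[I] / pi[I].sum()
                score += float(w @ T[np.ix_(I, I)].sum(axis=1))
            if score > best_score:
                best, best_score = assign, score
        macro = pcca_coarse_grain(model, 2)
        assert adjusted_rand_score(best, macro.crisp_assignment) == 1.0

    def test_lifetime_is_geometric_holding_time(self):
        # 2-state model with self-transition 0.9 at lag time 0.2
        T = np.array([[0.9, 0.1], [0.3, 0.7]])
        model = TransitionModel(
            transition_matrix=T, stationary=np.array([0.75, 0.25]),
            lag=1, step_unit=0.2, reversible=True,
        )
        macro = pcca_coarse_grain(model, 2)
        # PCCA on 2 states is the identity coarse-graining
        i = int(macro.crisp_assignment[0])
        assert macro.macro_T[i, i] == pytest.approx(0.9, abs=1e-12)
        assert macro.lifetimes[i] == pytest.approx(0.2 / (1 - 0.9), rel=1e-9)

    def test_membership_invariant_under_state_permutation(self, planted_model):
        model = planted_model.model_
        macro = pcca_coarse_grain(model, 5)
        rng = np.random.default_rng(3)
        perm = rng.permutation(model.n_states)
        T_p = model.transition_matrix[np.ix_(perm, perm)]
        model_p = TransitionModel(
            transition_matrix=T_p, stationary=model.stationary[perm],
            reversible=True,
        )
        macro_p = pcca_coarse_grain(model_p, 5)
        assert adjusted_rand_score(
            macro.crisp_assignment[perm], macro_p.crisp_assignment
        ) == 1.0

    def test_nonreversible_model_rejected(self):
        T = np.array([[0.5, 0.5, 0.0], [0.0, 0.5, 0.5], [0.5, 0.0, 0.5]])
        model = TransitionModel(
            transition_matrix=T, stationary=np.full(3, 1 / 3), reversible=False
        )
        with pytest.raises(ValueError, match="reversible"):
            PCCAPlus(n_metastable=2).fit(model)


class TestSelectRepresentatives:
    def _setup(self):
        chain = make_metastable_chain(2, 3, 0.5, 0.01, seed=5)
        dtrajs = sample_discrete_chain(chain, 4, 300, seed=6)
        est = MarkovStateModel(lag=1).fit(dtrajs)
        macro = pcca_coarse_grain(est.model_, 2)
        disc = Discretization(
            centers=np.zeros((6, 2)), dtrajs=dtrajs, inertia=0.0,
            feature_means=np.zeros(2), feature_scales=np.ones(2),
        )
        return disc, macro, est

    def test_representatives_come_from_own_macrostate(self):
        disc, macro, est = self._setup()
        reps = select_representatives(disc, macro, est.model_, n_per_state=3)
        for m, frames in reps.items():
            states_of_m = set(
                int(est.active_set_[i])
                for i in np.flatnonzero(macro.crisp_assignment == m)
            )
            for ti, fi in frames:
                assert int(disc.dtrajs.trajectories[ti][fi]) in states_of_m

    def test_one_per_state_contract(self):
        disc, macro, est = self._setup()
        reps = select_representatives(disc, macro, est.model_, n_per_state=1)
        assert all(len(v) == 1 for v in reps.values())

    def test_ranking_matches_sort_oracle(self):
        disc, macro, est = self._setup()
        reps = select_representatives(disc, macro, est.model_, n_per_state=1)
        for m, frames in reps.items():
            members = np.flatnonzero(macro.crisp_assignment == m)
            order = sorted(
                members,
                key=lambda i: (-macro.memberships[i, m], -est.model_.stationary[i], i),
            )
            best_state = int(est.active_set_[order[0]])
            ti, fi = frames[0]
            assert int(disc.dtrajs.trajectories[ti][fi]) == best_state


class TestCommittors:
    def test_boundary_conditions(self, three_state_model):
        qp, qm = committors(three_state_model, [0], [2])
        assert qp[0] == 0.0 and qp[2] == 1.0
        assert qm[0] == 1.0 and qm[2] == 0.0

    def test_gamblers_ruin_closed_form(self):
        n = 5
        T = np.zeros((n, n))
        T[0, 0] = T[0, 1] = 0.5
        T[n - 1, n - 1] = T[n - 1, n - 2] = 0.5
        for i in range(1, n - 1):
            T[i, i - 1] = T[i, i + 1] = 0.5
        model = TransitionModel(
            transition_matrix=T, stationary=np.full(n, 1 / n), reversible=True
        )
        qp, _ = committors(model, [0], [4])
        np.testing.assert_allclose(qp, [0, 0.25, 0.5, 0.75, 1.0], atol=1e-12)

    def test_hand_solved_three_state(self, three_state_model):
        qp, qm = committors(three_state_model, [0], [2])
        np.testing.assert_allclose(qp, [0, 0.5, 1.0], atol=1e-10)
        np.testing.assert_allclose(qm, 1 - qp, atol=1e-10)

    def test_monte_carlo_hitting_probabilities(self):
        rng = np.random.default_rng(17)
        model = random_reversible_model(10, rng)
        A, B = [0], [9]
        qp, _ = committors(model, A, B)
        n_walk = 20_000
        cum = np.cumsum(model.transition_matrix, axis=1)
        for start in (3, 6):
            states = np.full(n_walk, start)
            active = np.ones(n_walk, dtype=bool)
            hit_b = np.zeros(n_walk, dtype=bool)
            for _ in range(10_000):
                if not active.any():
                    break
                u = rng.random(active.sum())
                states[active] = (cum[states[active]] > u[:, None]).argmax(1)
                hit_b[active & np.isin(states, B)] = True
                active &= ~np.isin(states, A + B)
            p = hit_b.mean()
            se = np.sqrt(qp[start] * (1 - qp[start]) / n_walk)
            assert abs(p - qp[start]) <= 3 * se

    def test_overlapping_sets_rejected(self, three_state_model):
        with pytest.raises(ValueError, match="disjoint"):
            committors(three_state_model, [0, 1], [1, 2])


class TestReactiveFlux:
    def test_hand_arithmetic_three_state(self, three_state_model):
        fl = reactive_flux(three_state_model, [0], [2])
        assert fl.gross_flux[0, 1] == pytest.approx(0.025, abs=1e-12)
        assert fl.gross_flux[1, 2] == pytest.approx(0.025, abs=1e-12)
        assert fl.total_flux == pytest.approx(0.025, abs=1e-10)

    def test_conservation_on_random_reversible_chains(self):
        rng = np.random.default_rng(23)
        for _ in range(10):
            model = random_reversible_model(8, rng)
            fl = reactive_flux(model, [0, 1], [6, 7])
            assert fl.conservation_residual() < 1e-10

    def test_reversible_backward_committor_complement(self):
        rng = np.random.default_rng(29)
        model = random_reversible_model(7, rng)
        qp, qm = committors(model, [0], [6])
        np.testing.assert_allclose(qm, 1 - qp, atol=1e-10)


class TestCoarseGrainFlux:
    def test_identity_coarse_graining_preserves_flux(self, three_state_model):
        fl = reactive_flux(three_state_model, [0], [2])
        from h12msm.kinetics import MacrostateModel
        macro = MacrostateModel(
            memberships=np.eye(3), crisp_assignment=np.arange(3),
            macro_populations=three_state_model.stationary,
            macro_T=three_state_model.transition_matrix,
            lifetimes=np.ones(3),
        )
        cg = coarse_grain_flux(fl, macro)
        np.testing.assert_allclose(cg.gross_flux, fl.gross_flux, atol=1e-15)
        assert cg.total_flux == pytest.approx(fl.total_flux, abs=1e-12)

    def test_two_macro_lumping_single_edge(self, three_state_model):
        fl = reactive_flux(three_state_model, [0], [2])
        from h12msm.kinetics import MacrostateModel
        chi = np.array([[1.0, 0.0], [0.0, 1.0], [0.0, 1.0]])
        macro = MacrostateModel(
            memberships=chi, crisp_assignment=np.array([0, 1, 1]),
            macro_populations=np.array([0.25, 0.75]),
            macro_T=np.eye(2), lifetimes=np.ones(2),
        )
        cg = coarse_grain_flux(fl, macro)
        assert cg.net_flux[0, 1] == pytest.approx(0.025, abs=1e-12)
        assert cg.total_flux == pytest.approx(0.025, abs=1e-10)

    def test_straddling_source_rejected(self, three_state_model):
        fl = reactive_flux(three_state_model, [0, 1], [2])
        from h12msm.kinetics import MacrostateModel
        macro = MacrostateModel(
            memberships=np.eye(3)[:, :2] * 0 + np.array([[1, 0], [0, 1], [0, 1]]),
            crisp_assignment=np.array([0, 1, 1]),
            macro_populations=np.array([0.25, 0.75]),
            macro_T=np.eye(2), lifetimes=np.ones(2),
        )
        with pytest.raises(ValueError, match="straddle"):
            coarse_grain_flux(fl, macro)


def _network(n, edges, A, B):
    net = np.zeros((n, n))
    for (i, j), f in edges.items():
        net[i, j] = f
    total = sum(f for (i, j), f in edges.items() if i in A)
    return FluxNetwork(
        source_set=np.asarray(A), target_set=np.asarray(B),
        q_plus=np.zeros(n), q_minus=np.zeros(n),
        gross_flux=net, net_flux=net, total_flux=total,
        stationary=np.full(n, 1 / n),
    )


def bruteforce_decomposition(flux, max_paths=50):
    """Oracle: same greedy bottleneck scheme, but each strongest path is
    found by exhaustive enumeration of simple paths (networkx)."""
    import networkx as nx

    F = flux.net_flux.copy()
    total = flux.total_flux
    out = []
    for _ in range(max_paths):
        G = nx.DiGraph()
        for i, j in zip(*np.nonzero(F > 1e-15 * total)):
            G.add_edge(int(i), int(j))
        best = None
        for a in flux.source_set:
            for b in flux.target_set:
                if int(a) not in G or int(b) not in G:
                    continue
                for path in nx.all_simple_paths(G, int(a), int(b)):
                    width = min(F[i, j] for i, j in zip(path[:-1], path[1:]))
                    key = (-width, len(path) - 1, tuple(path))
                    if best is None or key < best:
                        best = key
        if best is None:
            break
        width, path = -best[0], best[2]
        for i, j in zip(path[:-1], path[1:]):
            F[i, j] = max(0.0, F[i, j] - width)
        out.append((path, width))
        if total - sum(w for _, w in out) < 1e-12 * total:
            break
    return out


class TestDecomposePathways:
    def test_single_chain_is_one_full_pathway(self):
        fl = _network(3, {(0, 1): 0.1, (1, 2): 0.1}, [0], [2])
        dec = decompose_pathways(fl)
        assert dec.pathways == [(0, 1, 2)]
        np.testing.assert_allclose(dec.fraction_of_total, [100.0])

    def test_seventy_thirty_split(self):
        fl = _network(
            4, {(0, 1): 0.07, (1, 3): 0.07, (0, 2): 0.03, (2, 3): 0.03}, [0], [3]
        )
        dec = decompose_pathways(fl)
        assert dec.pathways == [(0, 1, 3), (0, 2, 3)]
        np.testing.assert_allclose(dec.fraction_of_total, [70.0, 30.0], atol=1e-9)

    def test_accounting_identity_on_random_networks(self):
        rng = np.random.default_rng(31)
        for _ in range(20):
            model = random_reversible_model(8, rng)
            fl = reactive_flux(model, [0], [7])
            dec = decompose_pathways(fl, max_paths=100)
            frac_sum = dec.fraction_of_total.sum() + 100 * dec.residual_flux / fl.total_flux
            assert frac_sum == pytest.approx(100.0, abs=1e-6)

    def test_matches_exhaustive_enumeration_oracle(self):
        pytest.importorskip("networkx")
        rng = np.random.default_rng(37)
        for _ in range(20):
            model = random_reversible_model(8, rng)
            fl = reactive_flux(model, [0], [7])
            dec = decompose_pathways(fl, max_paths=100)
            oracle = bruteforce_decomposition(fl, max_paths=100)
            assert [p for p, _ in oracle] == dec.pathways
            np.testing.assert_allclose(
                [w for _, w in oracle], dec.pathway_flux, rtol=1e-12
            )

    def test_zero_flux_gives_empty_decomposition(self):
        fl = _network(3, {}, [0], [2])
        dec = decompose_pathways(fl)
        assert dec.pathways == [] and dec.total_flux == 0.0
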