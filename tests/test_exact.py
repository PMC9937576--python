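import itertools
import math

import numpy as np
import pytest

from coopevo import ModelParams
from coopevo.exact import (
    adoption_probability,
    build_transition_matrix,
    death_probability,
    stationary_distribution,
    steady_state_summary,
    sweep_exact,
)
from coopevo.states import enumerate_states


# ---------------------------------------------------------------------------
# death / adoption


def test_death_probability_examples():
    homog = np.array([[0, 0, 4], [0, 0, 4]])
    assert death_probability(homog, 0, 2) == pytest.approx(0.5)
    state = np.array([[1, 1, 2], [0, 0, 4]])
    assert death_probability(state, 0, 0) == pytest.approx(0.125)


def test_death_probability_normalizes(rng):
    for _ in range(20):
        counts = rng.multinomial(4, [1 / 3] * 3, size=2)
        total = sum(
            death_probability(counts, g, t) for g in range(2) for t in range(3)
        )
        assert total == pytest.approx(1.0)


def test_adoption_probability_trivial(baseline_params):
    homog = np.array([[0, 0, 4], [0, 0, 4]])
    assert adoption_probability(baseline_params, homog, 2) == pytest.approx(1.0)
    # two types, equal counts, identical payoffs by symmetry (U vs F at b_h=c_h)
    params = baseline_params.replace(b_h=1.0, p=0.5)
    state = np.array([[2, 0, 2], [2, 0, 2]])
    pU = adoption_probability(params, state, 0)
    pF = adoption_probability(params, state, 2)
    assert pU + pF == pytest.approx(1.0)


def test_adoption_probability_matches_symbolic_oracle(baseline_params):
    """The imitation ratio evaluated in exact arithmetic (sympy)."""
    import sympy

    from coopevo.model_core import expected_payoff_table

    state = np.array([[2, 1, 1], [0, 0, 4]])
    table = expected_payoff_table(baseline_params, state[None, ...])[0]
    weights = [
        sum(
            sympy.Integer(int(state[g, t])) * sympy.exp(sympy.Float(table[g, t], 30))
            for g in range(2)
        )
        for t in range(3)
    ]
    total = sum(weights)
    for t in range(3):
        exact = float((weights[t] / total).evalf(30))
        assert adoption_probability(baseline_params, state, t) == pytest.approx(
            exact, rel=1e-12
        )


# ---------------------------------------------------------------------------
# transition matrix


def _brute_force_matrix(params, T=3):
    """Naive independent construction: scalar loops, printed formulas only."""
    n, k, mu = params.n, params.k, params.mu
    N = n * k
    per_group = [
        c
        for c in itertools.product(range(n + 1), repeat=T)
        if sum(c) == n
    ]
    states = [s for s in itertools.product(per_group, repeat=k)]
    index = {s: i for i, s in enumerate(states)}

    def payoff(state, g, t):
        nU = sum(row[0] for row in state)
        common = 2 * params.e + nU * params.b_PG / N + state[g][1] * params.b_CG / n
        if t == 2:
            return common
        net = params.b_h - params.c_h
        if t == 1:
            meet = params.p * (state[g][1] - 1) / (n - 1) if n > 1 else 0.0
        else:
            meet = (params.p * (state[g][0] - 1) / (n - 1) if n > 1 else 0.0) + (
                (1 - params.p) * (nU - state[g][0]) / (N - n) if N > n else 0.0
            )
        return common - params.c_c + meet * net

    M = np.zeros((len(states), len(states)))
    for s, state in enumerate(states):
        weights = [
            sum(state[g][t] * math.exp(payoff(state, g, t)) for g in range(k))
            for t in range(T)
        ]
        total = sum(weights)
        for i in range(k):
            for j in range(T):
                death = (1 / k) * state[i][j] / n
                if death == 0:
                    continue
                for y in range(T):
                    prob = death * (mu / T + (1 - mu) * weights[y] / total)
                    if y == j:
                        M[s, s] += prob
                    else:
                        new = [list(row) for row in state]
                        new[i][j] -= 1
                        new[i][y] += 1
                        M[s, index[tuple(tuple(r) for r in new)]] += prob
    return M, states


def test_transition_matrix_matches_brute_force():
    params = ModelParams(n=2, b_CG=1.5, b_h=7.0, p=0.5)
    M, space = build_transition_matrix(params)
    B, states = _brute_force_matrix(params)
    # align the (possibly different) enumeration orders
    perm = [space.index(np.array(s)) for s in states]
    np.testing.assert_allclose(M[np.ix_(perm, perm)], B, atol=1e-12)


def test_row_stochastic_over_many_random_parameter_draws(rng):
    for _ in range(1000):
        params = ModelParams(
            n=2,
            b_CG=1.5,
            b_h=float(rng.uniform(0, 9)),
            p=float(rng.uniform(0, 1)),
            mu=float(10 ** rng.uniform(-5, -1)),
        )
        M, _ = build_transition_matrix(params)
        assert np.all(M >= 0)
        assert np.max(np.abs(M.sum(axis=1) - 1.0)) < 1e-12


def test_one_step_reachability_bound(baseline_params):
    """At most k*T*(T-1) + 1 states are reachable in one Moran event."""
    M, _ = build_transition_matrix(baseline_params.replace(b_h=7.0))
    reachable = (M > 0).sum(axis=1)
    assert np.all(reachable <= 2 * 3 * 2 + 1)


def test_mutation_free_chain_absorbs_in_homogeneous_states():
    params = ModelParams(mu=0.0, b_h=3.0)
    M, space = build_transition_matrix(params)
    homogeneous = [
        s
        for s in range(len(space))
        if (space.counts[s].sum(axis=0) == params.N).any()
    ]
    assert len(homogeneous) == 3  # one per type (both groups same type)
    for s in homogeneous:
        assert M[s, s] == pytest.approx(1.0)
    with pytest.raises(ValueError, match="reducible"):
        stationary_distribution(M, backend="eig")


def test_pure_mutation_limit_ignores_payoffs(baseline_params):
    params = baseline_params.replace(mu=1.0)
    M, space = build_transition_matrix(params)
    s = space.index(np.array([[1, 1, 2], [0, 0, 4]]))
    # moving one of two F agents in group 1 to U: death 2/8 * 1/2, mutation 1/3
    t = space.index(np.array([[2, 1, 1], [0, 0, 4]]))
    assert M[s, t] == pytest.approx((1 / 2) * (2 / 4) * (1 / 3))


# ---------------------------------------------------------------------------
# stationary distribution


def test_two_state_toy_chain_closed_form():
    a, b = 0.3, 0.1
    M = np.array([[1 - a, a], [b, 1 - b]])
    expected = np.array([b / (a + b), a / (a + b)])
    for backend in ("solve", "eig", "power"):
        w = stationary_distribution(M, backend=backend)
        np.testing.assert_allclose(w, expected, atol=1e-10)


@pytest.mark.parametrize("n, k", [(2, 2), (3, 2), (4, 1), (12, 1)])
def test_stationary_backends_agree_on_small_systems(n, k, rng):
    """All systems with <= 100 states: three backends within 1e-8."""
    for _ in range(3):
        params = ModelParams(
            n=n,
            k=k,
            b_CG=1.5,
            b_h=float(rng.uniform(0, 9)),
            p=float(rng.uniform(0, 1)),
            mu=float(10 ** rng.uniform(-4, -1)),
        )
        M, _ = build_transition_matrix(params)
        assert M.shape[0] <= 100
        sols = [
            stationary_distribution(M, backend=b) for b in ("solve", "eig", "power")
        ]
        for w in sols:
            assert abs(w.sum() - 1) < 1e-10
            assert np.max(np.abs(w @ M - w)) < 1e-8
        assert np.max(np.abs(sols[0] - sols[1])) < 1e-8
        assert np.max(np.abs(sols[0] - sols[2])) < 1e-8


# ---------------------------------------------------------------------------
# summaries and sweeps


def test_steady_state_proportions_normalize(baseline_params):
    s = steady_state_summary(baseline_params.replace(b_h=5.0, p=0.75))
    assert s.prop_U + s.prop_P + s.prop_F == pytest.approx(1.0, abs=1e-10)
    assert s.state_count == 225


def test_free_riding_dominates_without_net_helping_benefit(baseline_params):
    s = steady_state_summary(baseline_params.replace(b_h=1.0))
    assert s.prop_F > 0.95


def test_universalist_steady_state_creates_more_welfare(baseline_params):
    """b_CG < b_PG: a universalist population out-earns a parochialist one."""
    universal = steady_state_summary(baseline_params.replace(b_h=7.0, p=0.5))
    parochial = steady_state_summary(baseline_params.replace(b_h=7.0, p=1.0))
    assert universal.prop_U > 0.9 and parochial.prop_P > 0.9
    assert universal.welfare > parochial.welfare


def test_single_cell_sweep_equals_summary(baseline_params):
    df = sweep_exact(baseline_params, p_grid=[0.75], bh_grid=[5.0])
    assert len(df) == 1
    s = steady_state_summary(baseline_params.replace(p=0.75, b_h=5.0))
    assert df.loc[0, "prop_U"] == pytest.approx(s.prop_U)
    assert df.loc[0, "welfare"] == pytest.approx(s.welfare)


def test_sweep_grid_shape(baseline_params):
    df = sweep_exact(baseline_params, p_grid=[0.5, 1.0], bh_grid=[1.0, 4.0, 7.0])
    assert len(df) == 6
    assert set(df.columns) >= {
        "p", "b_h", "prop_U", "prop_P", "prop_F", "welfare", "n", "k", "mu",
        "state_count",
    }


def test_steady_state_refuses_mu_zero(baseline_params):
    with pytest.raises(ValueError, match="absorb"):
        steady_state_summary(baseline_params.replace(mu=0.0))


def test_enumerate_states_helper_reexported():
    assert len(enumerate_states(4, 2, 3)) == 225
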