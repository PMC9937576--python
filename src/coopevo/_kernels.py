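"""Numba-compiled inner loop for the core three-type agent-based model.

The kernel replicates one evolutionary iteration — realized stage-1
earnings, realized stage-2 pairing and helping, one Moran event — for the
canonical (U, P, F) strategy space with equal contiguous groups.  It exists
to make multi-million-iteration time averages and large sweeps cheap; the
general (extended-strategy) path lives in :mod:`coopevo.abm` in plain
NumPy, and the two are cross-validated statistically in the test suite.

Strategy codes: 0 = universalist, 1 = parochialist, 2 = free-rider.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["core3_kernel"]


@njit(cache=False)
def core3_kernel(
    strat,  # int64[N], initial strategies; agent a is in group a // n
    k,
    n,
    e,
    c_c,
    c_h,
    b_CG,
    b_PG,
    b_h,
    p,
    mu,
    seed,
    max_iter,
    stop_on_homog,  # bool: stop once all agents share one type
    tail_window,  # average composition over the last `tail_window` iterations
    burn_in,  # iterations discarded before batch accumulation
    n_batches,  # 0: no batch means
    payoff_blind,  # bool: constant imitation weights (neutral drift)
    expected_fitness,  # bool: imitation weights from expected, not realized, payoffs
    mutation_includes_current,  # bool: mutation target uniform over all 3 types
):
    """Run up to ``max_iter`` iterations; returns
    ``(converged_iter, comp, batch_means)`` where ``converged_iter`` is -1
    if the cap was reached, ``comp`` the final composition (homogeneous
    one-hot, else the tail-window mean of type shares) and ``batch_means``
    the per-batch mean type shares over the post-burn-in iterations.
    """
    np.random.seed(seed)
    N = k * n
    T = 3

    cnt = np.zeros(T, dtype=np.int64)
    gcnt = np.zeros((k, T), dtype=np.int64)
    for a in range(N):
        cnt[strat[a]] += 1
        gcnt[a // n, strat[a]] += 1

    pay = np.zeros(N)
    weights = np.zeros(N)
    pi = np.zeros((k, T))
    helps = np.zeros(N, dtype=np.bool_)
    recv = np.zeros(N, dtype=np.int64)

    tail_sum = np.zeros(T)
    tail_count = 0
    batch_means = np.zeros((max(n_batches, 1), T))
    batch_len = 0
    if n_batches > 0:
        batch_len = (max_iter - burn_in) // n_batches

    converged_iter = -1
    for it in range(max_iter):
        if stop_on_homog:
            homog = False
            for t in range(T):
                if cnt[t] == N:
                    homog = True
            if homog:
                converged_iter = it
                break

        # stage 1: realized earnings from the two pools + stage-2 endowment
        pub_total = cnt[0]
        for a in range(N):
            g = a // n
            s = strat[a]
            base = e - c_c if s != 2 else e
            pay[a] = base + pub_total * b_PG / N + gcnt[g, 1] * b_CG / n + e

        # stage 2: realized pairing and helping
        for a in range(N):
            g = a // n
            if np.random.random() < p:
                off = a - g * n
                j = np.random.randint(0, n - 1)
                if j >= off:
                    j += 1
                recv[a] = g * n + j
            else:
                j = np.random.randint(0, N - n)
                if j >= g * n:
                    j += n
                recv[a] = j
        for a in range(N):
            r = recv[a]
            s = strat[a]
            if s == 0:
                helps[a] = strat[r] == 0
            elif s == 1:
                helps[a] = strat[r] == 1 and (r // n) == (a // n)
            else:
                helps[a] = False
            if helps[a]:
                pay[a] -= c_h
                pay[r] += b_h

        # Moran event: uniform death, mutation or fitness-proportional imitation
        die = np.random.randint(0, N)
        if np.random.random() < mu:
            if mutation_includes_current:
                new = np.random.randint(0, T)
            else:
                new = np.random.randint(0, T - 1)
                if new >= strat[die]:
                    new += 1
        else:
            if payoff_blind:
                for a in range(N):
                    weights[a] = 1.0
            elif expected_fitness:
                nU = cnt[0]
                for g in range(k):
                    common = 2.0 * e + nU * b_PG / N + gcnt[g, 1] * b_CG / n
                    meet_u = 0.0
                    meet_p = 0.0
                    if n > 1:
                        meet_u += p * (gcnt[g, 0] - 1) / (n - 1)
                        meet_p += p * (gcnt[g, 1] - 1) / (n - 1)
                    if N > n:
                        meet_u += (1.0 - p) * (nU - gcnt[g, 0]) / (N - n)
                    pi[g, 0] = common - c_c + meet_u * (b_h - c_h)
                    pi[g, 1] = common - c_c + meet_p * (b_h - c_h)
                    pi[g, 2] = common
                mx = pi[0, strat[0]]
                for a in range(N):
                    v = pi[a // n, strat[a]]
                    if v > mx:
                        mx = v
                for a in range(N):
                    weights[a] = np.exp(pi[a // n, strat[a]] - mx)
            else:
                mx = pay[0]
                for a in range(N):
                    if pay[a] > mx:
                        mx = pay[a]
                for a in range(N):
                    weights[a] = np.exp(pay[a] - mx)
            total = 0.0
            for a in range(N):
                total += weights[a]
            u = np.random.random() * total
            acc = 0.0
            m = N - 1
            for a in range(N):
                acc += weights[a]
                if u < acc:
                    m = a
                    break
            new = strat[m]

        old = strat[die]
        if new != old:
            strat[die] = new
            cnt[old] -= 1
            cnt[new] += 1
            g = die // n
            gcnt[g, old] -= 1
            gcnt[g, new] += 1

        # bookkeeping (composition measured after the Moran event)
        if it >= max_iter - tail_window:
            for t in range(T):
                tail_sum[t] += cnt[t]
            tail_count += 1
        if n_batches > 0 and it >= burn_in:
            b = (it - burn_in) // batch_len
            if b >= n_batches:
                b = n_batches - 1
            for t in range(T):
                batch_means[b, t] += cnt[t]

    comp = np.zeros(T)
    if converged_iter >= 0:
        for t in range(T):
            comp[t] = cnt[t] / N
    elif tail_count > 0:
        for t in range(T):
            comp[t] = tail_sum[t] / (tail_count * N)
    else:
        for t in range(T):
            comp[t] = cnt[t] / N

    if n_batches > 0 and batch_len > 0:
        for b in range(n_batches):
            length = batch_len
            if b == n_batches - 1:
                length = (max_iter - burn_in) - batch_len * (n_batches - 1)
            for t in range(T):
                batch_means[b, t] /= length * N
    return converged_iter, comp, batch_means
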