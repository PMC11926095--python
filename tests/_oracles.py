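"""Independent brute-force oracles used to check the package's fast paths.

Everything here is deliberately naive (explicit Python loops, full
enumeration) and shares no code with the implementation it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def bf_score_probability(theta_u, eta_t, p, s) -> float:
    """Explicit double sum over (k, l) of θ_uk η_tl p_kl(s)."""
    K = len(theta_u)
    L = len(eta_t)
    total = 0.0
    for k in range(K):
        for l in range(L):
            total += theta_u[k] * eta_t[l] * p[k][l][s - 1]
    return total


def bf_log_likelihood(theta, eta, p, links) -> float:
    """Term-by-term log of the mixed-membership categorical law."""
    total = 0.0
    for (u, t, s) in links:
        total += math.log(bf_score_probability(theta[u], eta[t], p, s))
    return total


def bf_e_step(theta, eta, p, links):
    """Per-link K×L responsibility arrays by direct normalization."""
    K = theta.shape[1]
    L = eta.shape[1]
    out = []
    for (u, t, s) in links:
        num = np.empty((K, L))
        for k in range(K):
            for l in range(L):
                num[k, l] = theta[u, k] * eta[t, l] * p[k, l, s - 1]
        out.append(num / num.sum())
    return out


def bf_m_step(omega_per_link, links, U, T, K, L, n_scores=5):
    """Direct evaluation of the membership and score-law update sums."""
    theta = np.zeros((U, K))
    eta = np.zeros((T, L))
    p_num = np.zeros((K, L, n_scores))
    p_den = np.zeros((K, L))
    d_u = np.zeros(U)
    d_t = np.zeros(T)
    for om, (u, t, s) in zip(omega_per_link, links):
        d_u[u] += 1
        d_t[t] += 1
        for k in range(K):
            for l in range(L):
                theta[u, k] += om[k, l]
                eta[t, l] += om[k, l]
                p_num[k, l, s - 1] += om[k, l]
                p_den[k, l] += om[k, l]
    theta = theta / d_u[:, None]
    eta = eta / d_t[:, None]
    p = p_num / p_den[:, :, None]
    return theta, eta, p


def bf_pagerank(nodes, edges, damping=0.85, n_iter=500):
    """Power iteration with uniform teleport; dangling mass redistributed."""
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    out_nbrs = {i: [] for i in range(n)}
    for a, b in edges:
        out_nbrs[idx[a]].append(idx[b])
    r = np.full(n, 1.0 / n)
    for _ in range(n_iter):
        new = np.full(n, (1.0 - damping) / n)
        for i in range(n):
            if out_nbrs[i]:
                share = damping * r[i] / len(out_nbrs[i])
                for j in out_nbrs[i]:
                    new[j] += share
            else:
                new += damping * r[i] / n
        r = new
    return {v: r[idx[v]] for v in nodes}


def bf_mwu_exact_p(x, y) -> float:
    """Two-sided Mann-Whitney p by full enumeration of group labelings.

    Tie-free samples only; counts labelings whose U statistic is at least
    as extreme (min(U, mn - U) <= observed min) as the observed one.
    """
    x = list(x)
    y = list(y)
    pooled = x + y
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    m, n = len(x), len(y)

    def u_stat(xs, ys):
        return sum(1 for a in xs for b in ys if a > b)

    u_obs = u_stat(x, y)
    extreme_obs = min(u_obs, m * n - u_obs)
    count = 0
    total = 0
    for combo in itertools.combinations(range(m + n), m):
        xs = [pooled[i] for i in combo]
        ys = [pooled[i] for i in range(m + n) if i not in set(combo)]
        u = u_stat(xs, ys)
        if min(u, m * n - u) <= extreme_obs:
            count += 1
        total += 1
    return count / total


def bf_spearman(a, b) -> float:
    """Spearman rho via average ranks and the Pearson formula."""

    def avg_ranks(v):
        v = list(v)
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            mean_rank = (i + j) / 2 + 1
            for k in range(i, j + 1):
                ranks[order[k]] = mean_rank
            i = j + 1
        return ranks

    ra, rb = avg_ranks(a), avg_ranks(b)
    ra = np.asarray(ra)
    rb = np.asarray(rb)
    ra -= ra.mean()
    rb -= rb.mean()
    return float((ra * rb).sum() / np.sqrt((ra**2).sum() * (rb**2).sum()))
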