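"""Mixed-membership stochastic block model for bipartite ordinal scores.

The model assumes K latent groups of students and L latent groups of tasks.
Student u holds a membership simplex vector θ_u (their cognitive profile),
task t a membership vector η_t (its cognitive demands), and each group pair
(k, l) a categorical score law p_kl(s) over the quintiles s ∈ {1,...,5}. The
probability that student u scores s on task t is

    Pr[s_ut = s] = Σ_{k,l} θ_uk η_tl p_kl(s),

so score patterns depend on group structure only, with nodes allowed to mix
groups. Parameters are estimated by maximum likelihood via an
expectation-maximization scheme: the E-step computes per-link responsibilities
ω_ut(k, l) ∝ θ_uk η_tl p_kl(s_ut), and the M-step re-estimates θ, η and p
from responsibility sums (the closed-form stationary conditions of the
Lagrangian with simplex constraints). The log-likelihood is non-decreasing
across iterations, which the fitter verifies.

The estimator class :class:`MixedMembershipSBM` wraps the functional core in
the scikit-learn fit/predict idiom; the module-level functions (``e_step``,
``m_step``, ``fit_em``, ...) remain the primitive surface and are what the
estimator delegates to.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from ._rng import rng_for
from .ratings import N_SCORES, RatingsTable

__all__ = [
    "MMSBMParams",
    "FitResult",
    "DegenerateParameterError",
    "DegenerateRowWarning",
    "init_params",
    "score_probability",
    "log_likelihood",
    "e_step",
    "m_step",
    "fit_em",
    "align_labels",
    "order_achievement_groups",
    "predict",
    "MixedMembershipSBM",
]

_SIMPLEX_ATOL = 1e-12


class DegenerateParameterError(ValueError):
    """Raised when some observed link has zero probability under the params."""


class DegenerateRowWarning(UserWarning):
    """A zero-degree user/task or empty (k, l) cell was reset to uniform."""


@dataclass
class MMSBMParams:
    """Model parameters: θ (U×K), η (T×L) and the score tensor p (K×L×5)."""

    theta: np.ndarray
    eta: np.ndarray
    p: np.ndarray

    @property
    def K(self) -> int:
        return self.theta.shape[1]

    @property
    def L(self) -> int:
        return self.eta.shape[1]

    def validate(self, atol: float = _SIMPLEX_ATOL) -> None:
        if self.p.shape != (self.K, self.L, N_SCORES):
            raise ValueError(
                f"p has shape {self.p.shape}, expected {(self.K, self.L, N_SCORES)}"
            )
        for name, arr, axis in (("theta", self.theta, 1), ("eta", self.eta, 1)):
            if (arr < 0).any():
                raise ValueError(f"{name} has negative entries")
            if not np.allclose(arr.sum(axis=axis), 1.0, atol=atol, rtol=0):
                raise ValueError(f"{name} rows do not sum to 1 within {atol}")
        if (self.p < 0).any():
            raise ValueError("p has negative entries")
        if not np.allclose(self.p.sum(axis=2), 1.0, atol=atol, rtol=0):
            raise ValueError(f"p score rows do not sum to 1 within {atol}")

    def copy(self) -> "MMSBMParams":
        return MMSBMParams(self.theta.copy(), self.eta.copy(), self.p.copy())


@dataclass
class FitResult:
    """Outcome of an EM fit: best-restart parameters plus diagnostics."""

    params: MMSBMParams
    loglik_trace: np.ndarray
    n_iter: int
    converged: bool
    seed: int
    restart: int
    n_degenerate_rows: int = 0
    restart_logliks: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def loglik(self) -> float:
        return float(self.loglik_trace[-1])


def init_params(U: int, T: int, K: int, L: int, seed: int) -> MMSBMParams:
    """Random strictly-positive simplex rows, reproducible from ``seed``.

    Entries are drawn uniform on [0.1, 1] before row normalization, so no
    component starts zero-locked (zeros are absorbing under the M-step).
    """
    if min(U, T, K, L) < 1:
        raise ValueError("all dimensions must be >= 1")
    rng = np.random.default_rng(seed)
    theta = rng.uniform(0.1, 1.0, size=(U, K))
    theta /= theta.sum(axis=1, keepdims=True)
    eta = rng.uniform(0.1, 1.0, size=(T, L))
    eta /= eta.sum(axis=1, keepdims=True)
    p = rng.uniform(0.1, 1.0, size=(K, L, N_SCORES))
    p /= p.sum(axis=2, keepdims=True)
    return MMSBMParams(theta, eta, p)


def _link_numerators(params: MMSBMParams, ratings: RatingsTable) -> np.ndarray:
    """Per-link K×L array θ_uk η_tl p_kl(s_ut); shape (n_links, K, L)."""
    th = params.theta[ratings.u]                    # (n, K)
    et = params.eta[ratings.t]                      # (n, L)
    ps = params.p[:, :, ratings.s - 1]              # (K, L, n)
    return th[:, :, None] * et[:, None, :] * np.moveaxis(ps, 2, 0)


def score_probability(params: MMSBMParams, u: int, t: int, s: int | None = None):
    """Pr[s_ut = s] = Σ_{k,l} θ_uk η_tl p_kl(s) for user/task *positions* u, t.

    With ``s=None`` the full length-5 distribution over scores is returned.
    """
    dist = np.einsum("k,l,kls->s", params.theta[u], params.eta[t], params.p)
    if s is None:
        return dist
    if s not in range(1, N_SCORES + 1):
        raise ValueError(f"score must be in 1..5, got {s}")
    return float(dist[s - 1])


def log_likelihood(params: MMSBMParams, ratings: RatingsTable) -> float:
    """Σ over observed links of log Pr[s_ut]; 0 on an empty table.

    Returns -inf if any observed link has zero probability.
    """
    if ratings.n_links == 0:
        return 0.0
    z = _link_numerators(params, ratings).sum(axis=(1, 2))
    with np.errstate(divide="ignore"):
        return float(np.log(z).sum())


def e_step(params: MMSBMParams, ratings: RatingsTable) -> np.ndarray:
    """Responsibilities ω_ut(k,l) ∝ θ_uk η_tl p_kl(s_ut), one K×L slab per link."""
    num = _link_numerators(params, ratings)
    z = num.sum(axis=(1, 2))
    if (z <= 0).any():
        bad = int(np.flatnonzero(z <= 0)[0])
        raise DegenerateParameterError(
            f"link {bad} (user {ratings.users[ratings.u[bad]]!r}, "
            f"task {ratings.tasks[ratings.t[bad]]!r}) has zero probability"
        )
    return num / z[:, None, None]


def m_step(
    omega: np.ndarray,
    ratings: RatingsTable,
    U: int,
    T: int,
    K: int | None = None,
    L: int | None = None,
) -> MMSBMParams:
    """Closed-form parameter updates from responsibility sums.

    θ_uk = Σ_{t∈∂u} Σ_l ω_ut(k,l) / d_u, η_tl = Σ_{u∈∂t} Σ_k ω_ut(k,l) / d_t,
    p_kl(s) = Σ_{links: s_ut=s} ω_ut(k,l) / Σ_{all links} ω_ut(k,l).

    Zero-degree users/tasks and empty (k,l) cells get uniform rows, with a
    :class:`DegenerateRowWarning`.
    """
    if K is None:
        K = omega.shape[1]
    if L is None:
        L = omega.shape[2]

    theta = np.zeros((U, K))
    np.add.at(theta, ratings.u, omega.sum(axis=2))
    d_u = np.bincount(ratings.u, minlength=U).astype(float)
    zero_u = d_u == 0
    if zero_u.any():
        warnings.warn(
            f"{int(zero_u.sum())} user(s) have no links; memberships set uniform",
            DegenerateRowWarning,
            stacklevel=2,
        )
        theta[zero_u] = 1.0 / K
        d_u[zero_u] = 1.0
    theta /= d_u[:, None]

    eta = np.zeros((T, L))
    np.add.at(eta, ratings.t, omega.sum(axis=1))
    d_t = np.bincount(ratings.t, minlength=T).astype(float)
    zero_t = d_t == 0
    if zero_t.any():
        warnings.warn(
            f"{int(zero_t.sum())} task(s) have no links; memberships set uniform",
            DegenerateRowWarning,
            stacklevel=2,
        )
        eta[zero_t] = 1.0 / L
        d_t[zero_t] = 1.0
    eta /= d_t[:, None]

    p_acc = np.zeros((N_SCORES, K, L))
    np.add.at(p_acc, ratings.s - 1, omega)
    p = np.moveaxis(p_acc, 0, 2)                    # (K, L, S)
    denom = p.sum(axis=2)
    empty = denom == 0
    if empty.any():
        warnings.warn(
            f"{int(empty.sum())} (k,l) cell(s) received no responsibility; "
            "score law set uniform",
            DegenerateRowWarning,
            stacklevel=2,
        )
        p[empty] = 1.0 / N_SCORES
        denom[empty] = 1.0
    p /= denom[:, :, None]
    return MMSBMParams(theta, eta, p)


def _param_delta(a: MMSBMParams, b: MMSBMParams) -> float:
    return max(
        float(np.abs(a.theta - b.theta).max()),
        float(np.abs(a.eta - b.eta).max()),
        float(np.abs(a.p - b.p).max()),
    )


def fit_em(
    ratings: RatingsTable,
    K: int,
    L: int,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
    n_restarts: int = 10,
) -> FitResult:
    """EM driver: alternate E and M steps until the maximum absolute parameter
    change falls below ``tol`` (or ``max_iter``), over ``n_restarts`` random
    initializations; the restart with the highest final log-likelihood wins.
    """
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    if tol <= 0:
        raise ValueError("tol must be > 0")
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    if ratings.n_links == 0:
        raise ValueError("cannot fit on an empty ratings table")

    U, T = ratings.n_users, ratings.n_tasks
    best: FitResult | None = None
    final_lls = np.empty(n_restarts)
    for r in range(n_restarts):
        params = init_params(U, T, K, L, rng_for(seed, "restart", r).integers(2**31))
        trace = []
        converged = False
        n_degenerate = 0
        n_iter = 0
        for it in range(max_iter):
            num = _link_numerators(params, ratings)
            z = num.sum(axis=(1, 2))
            if (z <= 0).any():
                raise DegenerateParameterError(
                    "a link reached zero probability during EM"
                )
            trace.append(float(np.log(z).sum()))
            omega = num / z[:, None, None]
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always", DegenerateRowWarning)
                new_params = m_step(omega, ratings, U, T, K, L)
            n_degenerate += len(caught)
            delta = _param_delta(params, new_params)
            params = new_params
            n_iter = it + 1
            if delta < tol:
                converged = True
                break
        trace.append(log_likelihood(params, ratings))
        final_lls[r] = trace[-1]
        if best is None or trace[-1] > best.loglik:
            best = FitResult(
                params=params,
                loglik_trace=np.asarray(trace),
                n_iter=n_iter,
                converged=converged,
                seed=seed,
                restart=r,
                n_degenerate_rows=n_degenerate,
            )
    assert best is not None
    best.restart_logliks = final_lls
    return best


def _permute(params: MMSBMParams, kperm: tuple, lperm: tuple) -> MMSBMParams:
    kp = np.asarray(kperm)
    lp = np.asarray(lperm)
    return MMSBMParams(
        theta=params.theta[:, kp],
        eta=params.eta[:, lp],
        p=params.p[np.ix_(kp, lp)],
    )


def align_labels(reference: MMSBMParams, candidate: MMSBMParams) -> MMSBMParams:
    """Permute candidate's group labels to best match the reference.

    The MMSBM is identifiable only up to relabeling of user groups and task
    groups; this searches the permutation pair minimizing the total L1
    distance between the score tensors (exhaustive for K, L <= 5, greedy row
    matching on p otherwise).
    """
    if reference.K != candidate.K or reference.L != candidate.L:
        raise ValueError("reference and candidate dimensions differ")
    K, L = reference.K, reference.L

    if K <= 5 and L <= 5:
        best_cost = np.inf
        best = (tuple(range(K)), tuple(range(L)))
        for kperm in itertools.permutations(range(K)):
            for lperm in itertools.permutations(range(L)):
                cost = float(
                    np.abs(
                        reference.p - candidate.p[np.ix_(kperm, lperm)]
                    ).sum()
                )
                if cost < best_cost - 1e-15:
                    best_cost = cost
                    best = (kperm, lperm)
        return _permute(candidate, *best)

    # greedy: match user groups by L1 distance of p slabs, then task groups
    kperm, used = [], set()
    for k in range(K):
        costs = [
            np.inf if j in used else float(np.abs(reference.p[k] - candidate.p[j]).sum())
            for j in range(K)
        ]
        j = int(np.argmin(costs))
        kperm.append(j)
        used.add(j)
    lperm, used = [], set()
    for l in range(L):
        costs = [
            np.inf
            if j in used
            else float(np.abs(reference.p[kperm][:, l] - candidate.p[kperm][:, j]).sum())
            for j in range(L)
        ]
        j = int(np.argmin(costs))
        lperm.append(j)
        used.add(j)
    return _permute(candidate, tuple(kperm), tuple(lperm))


def order_achievement_groups(params: MMSBMParams) -> MMSBMParams:
    """Permute user groups into the canonical achievement order.

    Group labels are arbitrary after fitting; this fixes the convention the
    profile analyses rely on: column 0 = highest-achieving group, column 1 =
    lowest, column 2 = intermediate (for K = 3; for other K, columns are
    sorted by decreasing expected score). Achievement is measured as the
    expected quintile Σ_s s · p_kl(s), averaged over task groups.
    """
    scores = np.arange(1, N_SCORES + 1)
    expected = (params.p * scores).sum(axis=2).mean(axis=1)   # (K,)
    desc = np.argsort(-expected)
    if params.K == 3:
        kperm = (int(desc[0]), int(desc[2]), int(desc[1]))    # high, low, average
    else:
        kperm = tuple(int(k) for k in desc)
    return _permute(params, kperm, tuple(range(params.L)))


def predict(
    params: MMSBMParams, u_idx: np.ndarray, t_idx: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Score distribution and modal score for user/task position pairs.

    Returns (proba, modal) with proba of shape (n, 5) and modal scores in
    1..5; ties in the argmax break toward the lower score.
    """
    u_idx = np.asarray(u_idx, dtype=np.intp)
    t_idx = np.asarray(t_idx, dtype=np.intp)
    proba = np.einsum(
        "nk,nl,kls->ns", params.theta[u_idx], params.eta[t_idx], params.p
    )
    modal = np.argmax(proba, axis=1) + 1            # argmax takes first (lowest) tie
    return proba, modal


class MixedMembershipSBM(BaseEstimator):
    """Mixed-membership stochastic block model for student×task quintile scores.

    scikit-learn-style estimator. ``fit`` takes the observed links as a
    DataFrame with columns ``user_id``, ``task_id``, ``score`` (or an (n, 3)
    array, or a :class:`RatingsTable`) and estimates memberships by
    expectation-maximization with random restarts. ``predict`` returns the
    modal quintile for (user_id, task_id) pairs; ``predict_proba`` the full
    score distributions; ``score`` the mean per-link log-likelihood.

    Parameters
    ----------
    n_user_groups, n_task_groups : int, default 3
        Number of latent student groups K and task groups L. Three of each
        suffices to express a single low/average/high achievement axis.
    tol : float, default 1e-6
        Convergence threshold on the maximum absolute parameter change.
    max_iter : int, default 500
    n_restarts : int, default 10
        Independent random initializations; the highest-likelihood run wins.
    random_state : int, default 0

    Attributes
    ----------
    theta_ : ndarray (U, K)
        Student membership vectors (cognitive profiles).
    eta_ : ndarray (T, L)
        Task membership vectors.
    p_ : ndarray (K, L, 5)
        Score-probability tensor.
    users_, tasks_ : ndarray
        Id universe, aligned with the rows of ``theta_``/``eta_``.
    loglik_trace_ : ndarray
        Per-iteration log-likelihood of the winning restart (non-decreasing).
    """

    def __init__(
        self,
        n_user_groups: int = 3,
        n_task_groups: int = 3,
        *,
        tol: float = 1e-6,
        max_iter: int = 500,
        n_restarts: int = 10,
        random_state: int = 0,
    ):
        self.n_user_groups = n_user_groups
        self.n_task_groups = n_task_groups
        self.tol = tol
        self.max_iter = max_iter
        self.n_restarts = n_restarts
        self.random_state = random_state

    @staticmethod
    def _as_table(X) -> RatingsTable:
        if isinstance(X, RatingsTable):
            return X
        if isinstance(X, pd.DataFrame):
            return RatingsTable.from_frame(X)
        X = np.asarray(X)
        if X.ndim != 2 or X.shape[1] != 3:
            raise ValueError(
                "expected a RatingsTable, a (user_id, task_id, score) frame, "
                f"or an (n, 3) array; got shape {X.shape}"
            )
        return RatingsTable.from_links([tuple(row) for row in X])

    def fit(self, X, y=None) -> "MixedMembershipSBM":
        table = self._as_table(X)
        result = fit_em(
            table,
            K=self.n_user_groups,
            L=self.n_task_groups,
            seed=self.random_state,
            tol=self.tol,
            max_iter=self.max_iter,
            n_restarts=self.n_restarts,
        )
        result.params = order_achievement_groups(result.params)
        self.result_ = result
        self.params_ = result.params
        self.theta_ = result.params.theta
        self.eta_ = result.params.eta
        self.p_ = result.params.p
        self.users_ = table.users
        self.tasks_ = table.tasks
        self.table_ = table
        self.loglik_trace_ = result.loglik_trace
        self.n_iter_ = result.n_iter
        self.converged_ = result.converged
        return self

    def _pair_positions(self, X) -> tuple[np.ndarray, np.ndarray]:
        if isinstance(X, RatingsTable):
            return X.u, X.t
        if isinstance(X, pd.DataFrame):
            pairs = list(zip(X["user_id"], X["task_id"]))
        else:
            pairs = [tuple(row[:2]) for row in np.asarray(X, dtype=object)]
        u = np.array([self.table_.user_position(a) for a, _ in pairs], dtype=np.intp)
        t = np.array([self.table_.task_position(b) for _, b in pairs], dtype=np.intp)
        return u, t

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "params_")
        u, t = self._pair_positions(X)
        proba, _ = predict(self.params_, u, t)
        return proba

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "params_")
        u, t = self._pair_positions(X)
        _, modal = predict(self.params_, u, t)
        return modal

    def score(self, X, y=None) -> float:
        """Mean per-link log-likelihood of held-out links."""
        check_is_fitted(self, "params_")
        table = X if isinstance(X, RatingsTable) else self._as_table(X)
        if not isinstance(X, RatingsTable):
            table = RatingsTable.from_frame(
                table.to_frame(), users=self.users_, tasks=self.tasks_
            )
        return log_likelihood(self.params_, table) / max(table.n_links, 1)

    def profiles(self) -> pd.DataFrame:
        """Student cognitive profiles as a DataFrame indexed by user id."""
        check_is_fitted(self, "params_")
        cols = [f"group_{i}" for i in range(self.theta_.shape[1])]
        return pd.DataFrame(self.theta_, index=pd.Index(self.users_, name="user_id"),
                            columns=cols)
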