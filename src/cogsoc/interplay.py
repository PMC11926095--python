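"""Joining cognitive profiles to sociograms: assortativity and status.

Two families of statistics, each with its permutation null:

* **Cognitive-distance assortativity.** For a layer, compare the mean
  profile distance over connected pairs (d_connected) to the mean over all
  within-class pairs (d_all) via log(d_connected / d_all). Negative values
  mean connected students are more cognitively similar than chance
  (assortative); positive values mean disassortative. The null shuffles the
  profile vectors among the classroom's students, keeping edges fixed.
* **Status-achievement correlation.** Social status is the PageRank index on
  the directed nomination graph (nominator → nominee, so being nominated
  raises status); the statistic is the Spearman rank correlation between
  PageRank and the membership to the high- (or low-) achievement group. The
  null shuffles membership vectors among students.

Per-classroom statistics are aggregated by averaging over classrooms within
each age; undefined classrooms (empty layers, constant inputs) are excluded
and counted, never silently dropped.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

from .sociogram import Classroom, SociogramLayer

__all__ = [
    "GROUP_INDEX",
    "cognitive_distance",
    "pairwise_distances",
    "assortativity_log_ratio",
    "assortativity_null",
    "pagerank_status",
    "status_profile_correlation",
    "status_null",
    "aggregate_by_age",
]

#: membership-vector column convention for the three achievement groups:
#: group I (high) first, group II (low) second, group III (average) third
GROUP_INDEX = {"high": 0, "low": 1, "average": 2}

_METRICS = ("euclidean", "l1", "cosine")


def cognitive_distance(theta_u, theta_v, metric: str = "euclidean") -> float:
    """Distance between two membership (cognitive profile) vectors.

    Euclidean by default; "l1" and "cosine" are exposed as alternatives
    since any symmetric profile dissimilarity supports the same analysis.
    """
    a = np.asarray(theta_u, dtype=float)
    b = np.asarray(theta_v, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"profile lengths differ: {a.shape} vs {b.shape}")
    if metric == "euclidean":
        return float(np.linalg.norm(a - b))
    if metric == "l1":
        return float(np.abs(a - b).sum())
    if metric == "cosine":
        na, nb = np.linalg.norm(a), np.linalg.norm(b)
        if na == 0 or nb == 0:
            raise ValueError("cosine distance undefined for a zero vector")
        return float(1.0 - np.dot(a, b) / (na * nb))
    raise ValueError(f"unknown metric {metric!r}; choose from {_METRICS}")


def _profile_matrix(
    students: Sequence, profiles: Mapping
) -> np.ndarray:
    try:
        return np.asarray([profiles[s] for s in students], dtype=float)
    except KeyError as e:
        raise KeyError(f"student {e} has no profile") from None


def pairwise_distances(theta: np.ndarray, metric: str = "euclidean") -> np.ndarray:
    """Full n×n profile distance matrix."""
    from scipy.spatial.distance import pdist, squareform

    scipy_metric = {"euclidean": "euclidean", "l1": "cityblock", "cosine": "cosine"}
    if metric not in scipy_metric:
        raise ValueError(f"unknown metric {metric!r}; choose from {_METRICS}")
    n = theta.shape[0]
    if n < 2:
        return np.zeros((n, n))
    return squareform(pdist(theta, metric=scipy_metric[metric]))


def assortativity_log_ratio(
    layer: SociogramLayer,
    profiles: Mapping,
    metric: str = "euclidean",
) -> float:
    """log(d_connected / d_all) for one classroom layer.

    d_connected is the mean profile distance over directed edges; d_all the
    mean over all unordered distinct student pairs (connected ones
    included). Negative values indicate assortativity. Returns -inf when
    d_connected is exactly 0 in a heterogeneous class, and NaN (with a
    warning) when the statistic is undefined (empty layer, < 2 students, or
    d_all = 0).
    """
    students = list(layer.roster)
    if layer.n_edges == 0 or len(students) < 2:
        warnings.warn(
            f"assortativity undefined for layer {layer.label} "
            "(empty layer or single-student class)",
            stacklevel=2,
        )
        return np.nan
    theta = _profile_matrix(students, profiles)
    dmat = pairwise_distances(theta, metric)
    pos = {s: i for i, s in enumerate(students)}
    src = np.array([pos[a] for a, _ in layer.edges], dtype=np.intp)
    dst = np.array([pos[b] for _, b in layer.edges], dtype=np.intp)
    d_connected = float(dmat[src, dst].mean())
    iu = np.triu_indices(len(students), k=1)
    d_all = float(dmat[iu].mean())
    if d_all == 0.0:
        warnings.warn(
            f"all profiles identical in layer {layer.label}; log-ratio undefined",
            stacklevel=2,
        )
        return np.nan
    if d_connected == 0.0:
        return -np.inf
    return float(np.log(d_connected / d_all))


def assortativity_null(
    layer: SociogramLayer,
    profiles: Mapping,
    n_shuffles: int = 1000,
    seed: int = 0,
    metric: str = "euclidean",
) -> tuple[float, float]:
    """Null (mean, sd) of the log-ratio under profile shuffling.

    Profiles are permuted uniformly among the classroom's students in each
    shuffle; the edge structure (and hence d_all) is untouched.
    """
    if n_shuffles < 2:
        raise ValueError("n_shuffles must be >= 2")
    students = list(layer.roster)
    if layer.n_edges == 0 or len(students) < 2:
        warnings.warn("null undefined on an empty layer", stacklevel=2)
        return (np.nan, np.nan)
    theta = _profile_matrix(students, profiles)
    dmat = pairwise_distances(theta, metric)
    pos = {s: i for i, s in enumerate(students)}
    src = np.array([pos[a] for a, _ in layer.edges], dtype=np.intp)
    dst = np.array([pos[b] for _, b in layer.edges], dtype=np.intp)
    iu = np.triu_indices(len(students), k=1)
    d_all = float(dmat[iu].mean())
    if d_all == 0.0:
        warnings.warn("all profiles identical; null undefined", stacklevel=2)
        return (np.nan, np.nan)

    rng = np.random.default_rng(seed)
    vals = np.empty(n_shuffles)
    n = len(students)
    for i in range(n_shuffles):
        perm = rng.permutation(n)
        d_conn = dmat[perm[src], perm[dst]].mean()
        vals[i] = np.log(d_conn / d_all) if d_conn > 0 else -np.inf
    finite = vals[np.isfinite(vals)]
    if finite.size < 2:
        return (np.nan, np.nan)
    return (float(finite.mean()), float(finite.std(ddof=1)))


def pagerank_status(layer: SociogramLayer, damping: float = 0.85) -> dict:
    """PageRank social status on the directed nomination graph.

    Edges point nominator → nominee, so receiving nominations raises
    status. All roster students are included (isolates get teleport mass);
    scores sum to 1 over the roster.
    """
    if not layer.roster:
        raise ValueError("empty roster")
    if not 0 < damping < 1:
        raise ValueError("damping must be in (0, 1)")
    g = nx.DiGraph()
    g.add_nodes_from(layer.roster)
    g.add_edges_from(layer.edges)
    return nx.pagerank(g, alpha=damping, tol=1e-14, max_iter=2000)


def status_profile_correlation(
    layer: SociogramLayer,
    profiles: Mapping,
    group: str = "high",
    damping: float = 0.85,
) -> float:
    """Spearman correlation between PageRank status and achievement membership.

    ``group`` selects which membership coordinate is correlated ("high" or
    "low" achievement; "average" is also accepted). Returns NaN with a
    warning when either variable is constant across the classroom.
    """
    if group not in GROUP_INDEX:
        raise ValueError(f"group must be one of {sorted(GROUP_INDEX)}")
    students = list(layer.roster)
    if len(students) < 4:
        warnings.warn("correlation unreliable below 4 students", stacklevel=2)
    pr = pagerank_status(layer, damping)
    x = np.array([pr[s] for s in students])
    theta = _profile_matrix(students, profiles)
    y = theta[:, GROUP_INDEX[group]]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn(
            "constant PageRank or membership; correlation undefined", stacklevel=2
        )
        return np.nan
    rho, _ = sps.spearmanr(x, y)
    return float(rho)


def status_null(
    layer: SociogramLayer,
    profiles: Mapping,
    group: str = "high",
    n_shuffles: int = 1000,
    seed: int = 0,
    damping: float = 0.85,
) -> tuple[float, float]:
    """Null (mean, sd) of the status correlation under membership shuffling."""
    if n_shuffles < 2:
        raise ValueError("n_shuffles must be >= 2")
    if group not in GROUP_INDEX:
        raise ValueError(f"group must be one of {sorted(GROUP_INDEX)}")
    students = list(layer.roster)
    pr = pagerank_status(layer, damping)
    x = np.array([pr[s] for s in students])
    theta = _profile_matrix(students, profiles)
    y = theta[:, GROUP_INDEX[group]]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant inputs; null undefined", stacklevel=2)
        return (np.nan, np.nan)
    rng = np.random.default_rng(seed)
    vals = np.empty(n_shuffles)
    for i in range(n_shuffles):
        rho, _ = sps.spearmanr(x, y[rng.permutation(len(students))])
        vals[i] = rho
    finite = vals[np.isfinite(vals)]
    if finite.size < 2:
        return (np.nan, np.nan)
    return (float(finite.mean()), float(finite.std(ddof=1)))


def aggregate_by_age(
    per_classroom_values: Mapping,
    ages: Mapping,
) -> pd.DataFrame:
    """Average per-classroom statistics within each age.

    Non-finite (undefined/flagged) classroom values are excluded from the
    average and reported in ``n_excluded``. Returns a DataFrame with columns
    age, mean, sem, n, n_excluded.
    """
    per_age: dict = {}
    for cid, value in per_classroom_values.items():
        if cid not in ages:
            raise KeyError(f"classroom {cid!r} has no age")
        per_age.setdefault(ages[cid], []).append(value)
    rows = []
    for age in sorted(per_age):
        vals = np.asarray(per_age[age], dtype=float)
        finite = vals[np.isfinite(vals)]
        rows.append(
            {
                "age": age,
                "mean": float(finite.mean()) if finite.size else np.nan,
                "sem": float(finite.std(ddof=1) / np.sqrt(finite.size))
                if finite.size > 1
                else np.nan,
                "n": int(finite.size),
                "n_excluded": int(vals.size - finite.size),
            }
        )
    return pd.DataFrame(rows)
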