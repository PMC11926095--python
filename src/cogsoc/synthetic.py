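"""Planted-truth synthetic populations and classroom sociograms.

School cognitive/sociometric data cannot be redistributed, so this module
generates populations with known ground truth that mimic the statistical
structure of such a study: classrooms of 20-30 students aged 6-15, 8-10
cognitive tasks scored in quintiles 1-5 from a planted K = L = 3 block
structure, and five directed nomination layers per classroom with tunable
cognitive homophily, gender homophily and preference for high-achievers.

The planted membership pattern places students either almost purely in the
low-achievement group or on one of two simplex edges — mixing low with
average achievement, or high with average — and never mixing high and low.
The score tensor is stochastically ordered so the high group outperforms the
average group, which outperforms the low group, in every task group.

Nomination layers draw, for each student, 1-3 distinct nominees without
replacement with selection weight

    w(u → v) ∝ exp(-λ · d_cog(u, v) + γ · 1[same gender] + β · θ_v,high),

an exponential (softmax) link chosen as the simplest monotone map from
planted effect sizes (λ cognitive homophily, γ gender homophily, β status
preference) to the estimands the analysis pipeline measures. Negative
layers ("would NOT work/play with") flip the sign of λ, making them
cognitively disassortative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from ._rng import rng_for
from .interplay import pairwise_distances
from .ratings import N_SCORES, RatingsTable
from .sociogram import (
    Classroom,
    MultilayerSociogram,
    SociogramLayer,
)

__all__ = [
    "PlantedPopulation",
    "SociogramSpec",
    "AgeConfig",
    "AgeSeriesConfig",
    "make_planted_params",
    "sample_ratings",
    "sample_sociogram_layer",
    "make_age_series",
    "population_from_series",
    "default_age_series_config",
]

#: self-reported gender frequencies observed in large school samples
GENDER_PROBS = {"boy": 0.46, "girl": 0.40, "no-answer": 0.13, "other": 0.01}

#: achievement centers of the three student groups on the quintile scale:
#: group I (high), group II (low), group III (average). The spread and the
#: score-law concentration below are set so each group's scores sit on a
#: couple of adjacent quintiles (clearly defined groups), which also makes
#: the planted memberships identifiable from ~10 tasks per student.
_GROUP_CENTERS_3 = (4.6, 1.4, 3.0)
#: per-task-group shift of the achievement center; makes task groups
#: genuinely distinct so L is identifiable
_TASK_SHIFTS_3 = (-0.4, 0.0, 0.4)
_SCORE_SD = 0.30
_ETA_DOMINANCE = 0.95


@dataclass(frozen=True)
class PlantedPopulation:
    """Ground-truth parameters plus a classroom roster.

    theta_true rows are student membership simplex vectors (group I = high
    achievement first, group II = low second, group III = average third);
    eta_true rows are task memberships; p_true is the K×L×5 score tensor.
    """

    theta_true: np.ndarray
    eta_true: np.ndarray
    p_true: np.ndarray
    roster: tuple
    student_ids: tuple
    task_ids: tuple

    @property
    def n_students(self) -> int:
        return len(self.student_ids)

    @property
    def n_tasks(self) -> int:
        return len(self.task_ids)

    def profiles(self) -> dict:
        return {sid: self.theta_true[i] for i, sid in enumerate(self.student_ids)}


@dataclass(frozen=True)
class SociogramSpec:
    """Planted effect sizes for one nomination layer.

    lambda_cog >= 0 attracts cognitively similar nominees (< 0 repels);
    gamma_gender weights same-gender nominees; beta_status weights the
    nominee's high-achievement membership. ``sign`` marks positive versus
    negative ("would NOT ...") layers: negative layers flip lambda_cog.
    """

    lambda_cog: float = 0.0
    gamma_gender: float = 0.0
    beta_status: float = 0.0
    sign: str = "positive"
    max_nominations: int = 3

    def __post_init__(self):
        if self.max_nominations < 1:
            raise ValueError("max_nominations must be >= 1")
        if self.sign not in ("positive", "negative"):
            raise ValueError("sign must be 'positive' or 'negative'")

    @property
    def effective_lambda(self) -> float:
        return self.lambda_cog if self.sign == "positive" else -self.lambda_cog


def _score_tensor(K: int, L: int) -> np.ndarray:
    """Discretized-Gaussian score laws, stochastically ordered across groups."""
    if K == 3:
        centers = np.asarray(_GROUP_CENTERS_3)
    else:
        centers = np.linspace(4.6, 1.4, K)
    if L == 3:
        shifts = np.asarray(_TASK_SHIFTS_3)
    else:
        shifts = np.linspace(-0.6, 0.6, L) if L > 1 else np.zeros(1)
    scores = np.arange(1, N_SCORES + 1)
    mu = centers[:, None] + shifts[None, :]                 # (K, L)
    p = np.exp(-((scores[None, None, :] - mu[:, :, None]) ** 2) / (2 * _SCORE_SD**2))
    return p / p.sum(axis=2, keepdims=True)


def _make_roster(
    n_students: int,
    rng: np.random.Generator,
    class_size_range: tuple = (20, 30),
    ages: Sequence = tuple(range(6, 16)),
) -> tuple:
    """Chunk students into classrooms of uniform-random size with cycled ages."""
    lo, hi = class_size_range
    ids = [f"s{i:05d}" for i in range(n_students)]
    genders = rng.choice(
        list(GENDER_PROBS), size=n_students, p=list(GENDER_PROBS.values())
    )
    classrooms = []
    start, c = 0, 0
    while start < n_students:
        size = int(rng.integers(lo, hi + 1))
        members = ids[start : start + size]
        if not members:
            break
        classrooms.append(
            Classroom(
                classroom_id=f"c{c:03d}",
                age=int(ages[c % len(ages)]),
                students=tuple(members),
                gender={m: genders[start + j] for j, m in enumerate(members)},
            )
        )
        start += size
        c += 1
    return tuple(classrooms), tuple(ids)


def make_planted_params(
    n_students: int,
    n_tasks: int = 10,
    K: int = 3,
    L: int = 3,
    pattern: str = "empirical",
    seed: int = 0,
    class_size_range: tuple = (20, 30),
) -> PlantedPopulation:
    """Generate ground-truth memberships, score tensor and roster.

    Patterns
    --------
    "empirical" (requires K = L = 3)
        Students sit on the high-average or low-average simplex edge
        (mixing weight uniform) or purely in the low group; high and low
        achievement are never mixed. Tasks are dominated by one group each
        (dominance 0.95). The score tensor orders group I above III above
        II in every task group.
    "pure"
        One-hot memberships, groups assigned uniformly at random.
    "uniform"
        Dirichlet(1, ..., 1) membership rows.
    """
    if K < 1 or L < 1:
        raise ValueError("K and L must be >= 1")
    if pattern not in ("empirical", "pure", "uniform"):
        raise ValueError(f"unknown pattern {pattern!r}")
    if pattern == "empirical" and (K != 3 or L != 3):
        raise ValueError('pattern "empirical" requires K = L = 3')

    rng = rng_for(seed, "planted")
    if pattern == "empirical":
        theta = np.zeros((n_students, 3))
        kind = rng.choice(3, size=n_students)            # 0 pure-low, 1 low-avg, 2 high-avg
        w = rng.uniform(size=n_students)
        for i in range(n_students):
            if kind[i] == 0:
                theta[i] = (0.0, 1.0, 0.0)
            elif kind[i] == 1:                           # II-III edge (low/average)
                theta[i] = (0.0, w[i], 1.0 - w[i])
            else:                                        # I-III edge (high/average)
                theta[i] = (w[i], 0.0, 1.0 - w[i])
        eta = np.full((n_tasks, 3), (1.0 - _ETA_DOMINANCE) / 2)
        for t in range(n_tasks):
            eta[t, t % 3] = _ETA_DOMINANCE
    elif pattern == "pure":
        theta = np.zeros((n_students, K))
        theta[np.arange(n_students), rng.integers(0, K, size=n_students)] = 1.0
        eta = np.zeros((n_tasks, L))
        eta[np.arange(n_tasks), rng.integers(0, L, size=n_tasks)] = 1.0
    else:
        theta = rng.dirichlet(np.ones(K), size=n_students)
        eta = rng.dirichlet(np.ones(L), size=n_tasks)

    p = _score_tensor(K, L)
    roster, ids = _make_roster(n_students, rng, class_size_range)
    task_ids = tuple(f"t{j:02d}" for j in range(n_tasks))
    return PlantedPopulation(
        theta_true=theta,
        eta_true=eta,
        p_true=p,
        roster=roster,
        student_ids=ids,
        task_ids=task_ids,
    )


def sample_ratings(
    population: PlantedPopulation, coverage: float = 1.0, seed: int = 0
) -> RatingsTable:
    """Sample observed (student, task, score) links from the planted model.

    Each (student, task) pair is observed independently with probability
    ``coverage``; observed scores are drawn from the mixed-membership
    categorical law Σ_{k,l} θ_uk η_tl p_kl(s).
    """
    if not 0 < coverage <= 1:
        raise ValueError("coverage must be in (0, 1]")
    rng = rng_for(seed, "ratings")
    U, T = population.n_students, population.n_tasks
    probs = np.einsum(
        "uk,tl,kls->uts", population.theta_true, population.eta_true, population.p_true
    )
    observed = rng.random((U, T)) <= coverage if coverage < 1 else np.ones((U, T), bool)
    cdf = probs.cumsum(axis=2)
    draws = rng.random((U, T))
    scores = (draws[:, :, None] > cdf).sum(axis=2) + 1   # categorical inverse-cdf
    uu, tt = np.nonzero(observed)
    links = [
        (population.student_ids[u], population.task_ids[t], int(scores[u, t]))
        for u, t in zip(uu, tt)
    ]
    return RatingsTable.from_links(
        links, users=population.student_ids, tasks=population.task_ids
    )


def _weighted_sample_without_replacement(
    weights: np.ndarray, k: int, rng: np.random.Generator
) -> np.ndarray:
    """Sequential weighted draws without replacement (k small)."""
    weights = weights.astype(float).copy()
    chosen = []
    for _ in range(k):
        total = weights.sum()
        if total <= 0:
            break
        idx = int(rng.choice(weights.size, p=weights / total))
        chosen.append(idx)
        weights[idx] = 0.0
    return np.asarray(chosen, dtype=np.intp)


def sample_sociogram_layer(
    classroom: Classroom,
    thetas: Mapping,
    genders: Mapping | None,
    spec: SociogramSpec,
    seed: int = 0,
    label: str = "friend",
    forced_nominations: Mapping | None = None,
) -> SociogramLayer:
    """Generate one directed nomination layer for a classroom.

    Each student draws ``n ~ Uniform{1..max_nominations}`` distinct nominees
    (self excluded) with weight exp(-λ·d_cog + γ·same_gender + β·θ_v,high).
    ``forced_nominations`` optionally pre-seeds some of a student's
    nominations (used to plant cross-layer edge overlap); forced picks count
    toward the student's nomination budget.
    """
    students = list(classroom.students)
    n = len(students)
    if n == 0:
        raise ValueError("empty classroom")
    if n < spec.max_nominations + 1:
        raise ValueError(
            f"classroom {classroom.classroom_id} needs at least "
            f"{spec.max_nominations + 1} students"
        )
    if genders is None:
        genders = classroom.gender
    theta = np.asarray([thetas[s] for s in students], dtype=float)
    dmat = pairwise_distances(theta, "euclidean")
    g = np.array([genders.get(s, "no-answer") for s in students])
    same_gender = (g[:, None] == g[None, :]).astype(float)
    status = theta[:, 0]                                  # membership to high group

    logw = (
        -spec.effective_lambda * dmat
        + spec.gamma_gender * same_gender
        + spec.beta_status * status[None, :]
    )
    rng = rng_for(seed, "layer", label, classroom.classroom_id)
    edges = []
    for i in range(n):
        n_nom = int(rng.integers(1, spec.max_nominations + 1))
        w = np.exp(logw[i] - logw[i].max())
        w[i] = 0.0
        picked: list = []
        if forced_nominations and students[i] in forced_nominations:
            for tgt in forced_nominations[students[i]][:n_nom]:
                j = students.index(tgt)
                if j != i and j not in picked:
                    picked.append(j)
                    w[j] = 0.0
        remaining = n_nom - len(picked)
        if remaining > 0:
            picked.extend(_weighted_sample_without_replacement(w, remaining, rng))
        edges.extend((students[i], students[j]) for j in picked)
    return SociogramLayer(label=label, roster=tuple(students), edges=tuple(edges))


@dataclass(frozen=True)
class AgeConfig:
    """Generation parameters for all classrooms of one age."""

    age: int
    n_classrooms: int
    specs: Mapping = field(default_factory=dict)          # layer label -> SociogramSpec
    work_play_overlap: float = 0.3    # prob. a work+ nomination is copied into play+
    neg_overlap: float = 0.3          # same for work- into play-
    class_size_range: tuple = (20, 30)


@dataclass(frozen=True)
class AgeSeriesConfig:
    ages: tuple


def default_age_series_config(
    n_classrooms_per_age: int = 3,
    ages: Sequence = tuple(range(6, 16)),
) -> AgeSeriesConfig:
    """A population emulating the study's age trends.

    Positive layers are cognitively homophilous (λ = 2) and gender
    homophilous, with gender homophily weakening in adolescence; the work+
    layer prefers high-achievers with a preference that grows with age;
    negative layers are cognitively disassortative. The planted work/play
    edge-sharing probability declines linearly with age, so the work+/play+
    Jaccard overlap decreases across the series, while the negative-layer
    overlap stays flat.
    """
    age_cfgs = []
    ages = list(ages)
    for age in ages:
        frac = (age - ages[0]) / max(ages[-1] - ages[0], 1)
        gamma = 1.5 if age < 12 else 0.8
        beta_work = 1.5 + 3.0 * frac
        specs = {
            "work+": SociogramSpec(2.0, gamma, beta_work, "positive"),
            "work-": SociogramSpec(2.0, -0.5, -beta_work / 2, "negative"),
            "play+": SociogramSpec(2.0, gamma, 1.0 * (1 - frac), "positive"),
            "play-": SociogramSpec(2.0, -0.5, 0.0, "negative"),
            "friend": SociogramSpec(2.0, gamma, 0.5, "positive"),
        }
        age_cfgs.append(
            AgeConfig(
                age=age,
                n_classrooms=n_classrooms_per_age,
                specs=specs,
                work_play_overlap=0.6 - 0.4 * frac,
                neg_overlap=0.3,
            )
        )
    return AgeSeriesConfig(ages=tuple(age_cfgs))


def population_from_series(series, n_tasks: int = 10) -> PlantedPopulation:
    """Wrap an age-series roster and its planted profiles as a population.

    Lets the cognitive side of the pipeline (ratings, model fitting) run on
    the same students that populate the generated sociograms. Task
    memberships follow the standard near-pure pattern and the score tensor
    is the ordered three-group law.
    """
    ids, thetas, roster = [], [], []
    for classroom, _, profiles in series:
        roster.append(classroom)
        for s in classroom.students:
            ids.append(s)
            thetas.append(profiles[s])
    eta = np.full((n_tasks, 3), (1.0 - _ETA_DOMINANCE) / 2)
    for t in range(n_tasks):
        eta[t, t % 3] = _ETA_DOMINANCE
    return PlantedPopulation(
        theta_true=np.asarray(thetas),
        eta_true=eta,
        p_true=_score_tensor(3, 3),
        roster=tuple(roster),
        student_ids=tuple(ids),
        task_ids=tuple(f"t{j:02d}" for j in range(n_tasks)),
    )


def _planted_classroom_profiles(n: int, rng: np.random.Generator) -> np.ndarray:
    """Per-classroom student profiles drawn from the planted membership pattern."""
    theta = np.zeros((n, 3))
    kind = rng.choice(3, size=n)
    w = rng.uniform(size=n)
    for i in range(n):
        if kind[i] == 0:
            theta[i] = (0.0, 1.0, 0.0)
        elif kind[i] == 1:
            theta[i] = (0.0, w[i], 1.0 - w[i])
        else:
            theta[i] = (w[i], 0.0, 1.0 - w[i])
    return theta


def make_age_series(
    config: AgeSeriesConfig, seed: int = 0
) -> list:
    """Generate (Classroom, MultilayerSociogram, profiles) tuples per config.

    Deterministic given ``seed``. Cross-layer overlap between the work and
    play layers of the same sign is planted by copying each work nomination
    into the play layer with the configured probability before the play
    layer fills its remaining nominations from the weighted law.
    """
    if not config.ages:
        raise ValueError("config lists no ages")
    out = []
    for acfg in config.ages:
        for c in range(acfg.n_classrooms):
            rng = rng_for(seed, "class", acfg.age, c)
            lo, hi = acfg.class_size_range
            size = int(rng.integers(lo, hi + 1))
            ids = tuple(f"a{acfg.age:02d}c{c:02d}s{i:02d}" for i in range(size))
            genders = {
                s: rng.choice(list(GENDER_PROBS), p=list(GENDER_PROBS.values()))
                for s in ids
            }
            classroom = Classroom(
                classroom_id=f"a{acfg.age:02d}c{c:02d}",
                age=acfg.age,
                students=ids,
                gender=genders,
            )
            theta = _planted_classroom_profiles(size, rng)
            profiles = {s: theta[i] for i, s in enumerate(ids)}

            layers = {}
            for label in ("work+", "work-"):
                layers[label] = sample_sociogram_layer(
                    classroom,
                    profiles,
                    genders,
                    acfg.specs[label],
                    seed=rng_for(seed, "seed", acfg.age, c, label).integers(2**31),
                    label=label,
                )
            for src_label, tgt_label, rho in (
                ("work+", "play+", acfg.work_play_overlap),
                ("work-", "play-", acfg.neg_overlap),
            ):
                copy_rng = rng_for(seed, "copy", acfg.age, c, tgt_label)
                forced: dict = {}
                for a, b in layers[src_label].edges:
                    if copy_rng.random() < rho:
                        forced.setdefault(a, []).append(b)
                layers[tgt_label] = sample_sociogram_layer(
                    classroom,
                    profiles,
                    genders,
                    acfg.specs[tgt_label],
                    seed=rng_for(seed, "seed", acfg.age, c, tgt_label).integers(2**31),
                    label=tgt_label,
                    forced_nominations=forced,
                )
            layers["friend"] = sample_sociogram_layer(
                classroom,
                profiles,
                genders,
                acfg.specs["friend"],
                seed=rng_for(seed, "seed", acfg.age, c, "friend").integers(2**31),
                label="friend",
            )
            out.append(
                (classroom, MultilayerSociogram(classroom=classroom, layers=layers),
                 profiles)
            )
    return out
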