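"""Multilayer classroom sociograms and their overlap/homophily statistics.

A sociogram layer is the directed nomination network a classroom produces in
answer to one question ("who would you like to work with?", "...play
with?", positive and negative, plus friendship). Each child names up to
three classmates, so out-degree is capped at 3 per layer. The five layers
over one roster form a multilayer network.

Statistics here:

* Jaccard edge overlap between two layers, |A∩B| / |A∪B| over directed
  edge sets, with a null model that independently rewires both layers by
  degree-preserving double-edge swaps.
* Same-gender edge fraction with a gender-label-shuffling null.
* Per-age aggregation (classrooms averaged within age, SEM reported).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._rng import rng_for

__all__ = [
    "LAYER_LABELS",
    "GENDERS",
    "Classroom",
    "SociogramLayer",
    "MultilayerSociogram",
    "NullOverlap",
    "GenderHomophilyResult",
    "jaccard_overlap",
    "rewire_preserving_degrees",
    "null_overlap",
    "overlap_by_age",
    "gender_homophily",
]

#: the five nomination questions, sign-coded
LAYER_LABELS = ("work+", "work-", "play+", "play-", "friend")

GENDERS = ("boy", "girl", "no-answer", "other")

MAX_NOMINATIONS = 3


@dataclass(frozen=True)
class Classroom:
    """A classroom roster: ids, age in years and self-reported genders."""

    classroom_id: str
    age: int
    students: tuple
    gender: Mapping = field(default_factory=dict)

    def __post_init__(self):
        if len(set(self.students)) != len(self.students):
            raise ValueError(f"duplicate student ids in {self.classroom_id}")

    @property
    def n_students(self) -> int:
        return len(self.students)


@dataclass(frozen=True)
class SociogramLayer:
    """One directed nomination layer within a classroom.

    Edges are (nominator, nominee) ordered pairs; nominations are analyzed
    in their directed form throughout.
    """

    label: str
    roster: tuple
    edges: tuple

    def __post_init__(self):
        roster = set(self.roster)
        seen = set()
        out_deg: dict = {}
        for e in self.edges:
            src, dst = e
            if src == dst:
                raise ValueError(f"self-loop {e} in layer {self.label}")
            if e in seen:
                raise ValueError(f"duplicate edge {e} in layer {self.label}")
            seen.add(e)
            if src not in roster or dst not in roster:
                raise ValueError(f"edge {e} references a non-roster student")
            out_deg[src] = out_deg.get(src, 0) + 1
            if out_deg[src] > MAX_NOMINATIONS:
                raise ValueError(
                    f"student {src!r} has more than {MAX_NOMINATIONS} "
                    f"nominations in layer {self.label}"
                )

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_set(self) -> frozenset:
        return frozenset(self.edges)


@dataclass(frozen=True)
class MultilayerSociogram:
    """The five nomination layers of one classroom, sharing a roster."""

    classroom: Classroom
    layers: Mapping

    def __post_init__(self):
        roster = tuple(self.classroom.students)
        for label, layer in self.layers.items():
            if tuple(layer.roster) != roster:
                raise ValueError(
                    f"layer {label} roster differs from classroom roster"
                )

    def __getitem__(self, label: str) -> SociogramLayer:
        return self.layers[label]


def jaccard_overlap(A: SociogramLayer, B: SociogramLayer) -> float:
    """Edge overlap |A∩B| / |A∪B| over directed edge sets; 0 if both empty."""
    if tuple(A.roster) != tuple(B.roster):
        raise ValueError("layers are over different rosters")
    ea, eb = A.edge_set(), B.edge_set()
    union = ea | eb
    if not union:
        return 0.0
    return len(ea & eb) / len(union)


def rewire_preserving_degrees(
    layer: SociogramLayer, n_swap_multiplier: int = 10, seed: int = 0
) -> SociogramLayer:
    """Randomize a layer by directed double-edge swaps.

    Each attempted swap picks two edges (a, b), (c, d) and rewires them to
    (a, d), (c, b), rejecting candidates that would create a self-loop or a
    duplicate edge; this preserves every node's in- and out-degree exactly.
    ``n_swap_multiplier * n_edges`` swaps are attempted. Layers admitting no
    feasible swap are returned unchanged with a warning.
    """
    edges = list(layer.edges)
    m = len(edges)
    if m < 2:
        warnings.warn(
            f"layer {layer.label} has < 2 edges; returned unchanged", stacklevel=2
        )
        return layer
    rng = np.random.default_rng(seed)
    edge_set = set(edges)
    n_applied = 0
    for _ in range(n_swap_multiplier * m):
        i, j = rng.integers(0, m, size=2)
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if a == d or c == b:
            continue
        e1, e2 = (a, d), (c, b)
        if e1 in edge_set or e2 in edge_set:
            continue
        edge_set.discard((a, b))
        edge_set.discard((c, d))
        edge_set.add(e1)
        edge_set.add(e2)
        edges[i] = e1
        edges[j] = e2
        n_applied += 1
    if n_applied == 0:
        warnings.warn(
            f"layer {layer.label} admitted no feasible swap; returned unchanged",
            stacklevel=2,
        )
        return layer
    return SociogramLayer(label=layer.label, roster=layer.roster, edges=tuple(edges))


@dataclass(frozen=True)
class NullOverlap:
    """Monte-Carlo summary of the chance edge overlap between two layers."""

    mean: float
    sd: float
    samples: np.ndarray


def null_overlap(
    A: SociogramLayer,
    B: SociogramLayer,
    n_samples: int = 1000,
    seed: int = 0,
    n_swap_multiplier: int = 10,
) -> NullOverlap:
    """Chance overlap under independent degree-preserving rewiring.

    Both layers are rewired independently in each sample and the Jaccard
    index recorded; the null asks how much overlap degrees alone produce.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    samples = np.empty(n_samples)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(n_samples):
            ra = rewire_preserving_degrees(
                A, n_swap_multiplier, seed=rng_for(seed, "A", i).integers(2**31)
            )
            rb = rewire_preserving_degrees(
                B, n_swap_multiplier, seed=rng_for(seed, "B", i).integers(2**31)
            )
            samples[i] = jaccard_overlap(ra, rb)
    return NullOverlap(float(samples.mean()), float(samples.std(ddof=1)), samples)


def overlap_by_age(
    dataset: Iterable[MultilayerSociogram],
    layer_pair: tuple,
    n_null_samples: int = 200,
    seed: int = 0,
    n_swap_multiplier: int = 10,
) -> pd.DataFrame:
    """Observed vs null edge overlap of a layer pair, averaged within age.

    For each classroom the observed Jaccard index and ``n_null_samples``
    rewired null samples are computed; classrooms are then averaged within
    each age (SEM = sd/sqrt(n), NaN for single-classroom ages). The age-level
    null mean/sd summarize the distribution of the age average across null
    samples (classroom null draws paired by sample index).

    Returns a DataFrame with columns age, mean, sem, n_classrooms,
    null_mean, null_sd.
    """
    la, lb = layer_pair
    per_age: dict = {}
    for i, ml in enumerate(dataset):
        age = ml.classroom.age
        obs = jaccard_overlap(ml[la], ml[lb])
        null = null_overlap(
            ml[la],
            ml[lb],
            n_samples=n_null_samples,
            seed=rng_for(seed, "null", ml.classroom.classroom_id).integers(2**31),
            n_swap_multiplier=n_swap_multiplier,
        )
        per_age.setdefault(age, []).append((obs, null.samples))

    rows = []
    for age in sorted(per_age):
        entries = per_age[age]
        obs = np.array([o for o, _ in entries])
        null_matrix = np.stack([s for _, s in entries])   # (n_class, n_samples)
        age_null = null_matrix.mean(axis=0)
        rows.append(
            {
                "age": age,
                "mean": float(obs.mean()),
                "sem": float(obs.std(ddof=1) / np.sqrt(obs.size))
                if obs.size > 1
                else np.nan,
                "n_classrooms": int(obs.size),
                "null_mean": float(age_null.mean()),
                "null_sd": float(age_null.std(ddof=1)),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class GenderHomophilyResult:
    """Same-gender edge fraction against a label-shuffling null."""

    fraction: float
    null_mean: float
    null_sd: float
    n_edges: int

    @property
    def defined(self) -> bool:
        return not np.isnan(self.fraction)


def gender_homophily(
    layer: SociogramLayer,
    classroom: Classroom,
    n_shuffles: int = 1000,
    seed: int = 0,
) -> GenderHomophilyResult:
    """Fraction of same-gender edges, with a gender-shuffling null.

    Students whose gender is undisclosed ("no-answer"/"other") make
    same-gender undefined, so edges touching them are excluded from both
    numerator and denominator. The null shuffles the classroom's gender
    labels uniformly (``n_shuffles`` permutations), keeping edges fixed;
    eligibility is re-evaluated under each shuffle.
    """
    students = list(classroom.students)
    genders = np.array([classroom.gender.get(s, "no-answer") for s in students])
    pos = {s: i for i, s in enumerate(students)}
    src = np.array([pos[a] for a, _ in layer.edges], dtype=np.intp)
    dst = np.array([pos[b] for _, b in layer.edges], dtype=np.intp)

    def frac(g: np.ndarray) -> float:
        disclosed = np.isin(g, ("boy", "girl"))
        ok = disclosed[src] & disclosed[dst] if src.size else np.array([], bool)
        if not ok.any():
            return np.nan
        return float((g[src[ok]] == g[dst[ok]]).mean())

    observed = frac(genders)
    n_eligible = 0
    if src.size:
        disclosed = np.isin(genders, ("boy", "girl"))
        n_eligible = int((disclosed[src] & disclosed[dst]).sum())
    if np.isnan(observed):
        warnings.warn(
            f"layer {layer.label} has no eligible edges; homophily undefined",
            stacklevel=2,
        )
        return GenderHomophilyResult(np.nan, np.nan, np.nan, 0)

    rng = np.random.default_rng(seed)
    null = np.array([frac(rng.permutation(genders)) for _ in range(n_shuffles)])
    null = null[~np.isnan(null)]
    return GenderHomophilyResult(
        observed,
        float(null.mean()) if null.size else np.nan,
        float(null.std(ddof=1)) if null.size > 1 else np.nan,
        n_eligible,
    )
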