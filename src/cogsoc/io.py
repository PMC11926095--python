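"""File formats and configuration.

Everything on disk is plain text: ratings, rosters and edge lists are CSV,
fitted models are JSON, run configuration is YAML. Readers validate the
domain invariants (quintile range, no duplicate links, nomination cap,
no self-loops, within-classroom edges) and report violations with the
offending row number.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .mmsbm import MMSBMParams
from .ratings import RatingsTable
from .sociogram import (
    Classroom,
    GENDERS,
    LAYER_LABELS,
    MAX_NOMINATIONS,
    MultilayerSociogram,
    SociogramLayer,
)

__all__ = [
    "RunConfig",
    "read_ratings",
    "write_ratings",
    "scores_to_quintiles",
    "read_sociograms",
    "write_sociograms",
    "write_roster",
    "save_model",
    "load_model",
    "load_config",
]


@dataclass
class RunConfig:
    """Top-level run configuration; one seed drives every stochastic stage."""

    seed: int = 0
    ratings_path: str | None = None
    roster_path: str | None = None
    edges_path: str | None = None
    output_dir: str = "runs"
    K: int = 3
    L: int = 3
    tol: float = 1e-6
    max_iter: int = 500
    n_restarts: int = 10
    n_shuffles: int = 1000
    n_rewire_samples: int = 1000
    swap_multiplier: int = 10
    distance_metric: str = "euclidean"
    alpha: float = 0.05
    extras: dict = field(default_factory=dict)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f for f in RunConfig.__dataclass_fields__ if f != "extras"}
    kwargs = {k: v for k, v in raw.items() if k in known}
    extras = {k: v for k, v in raw.items() if k not in known}
    return RunConfig(**kwargs, extras=extras)


def read_ratings(path) -> RatingsTable:
    """Read a ratings CSV (user_id, task_id, score) with validation.

    Scores outside 1..5, duplicate (user, task) pairs and malformed rows
    are rejected with the offending row number (0-based data row).
    """
    df = pd.read_csv(path, dtype={"user_id": str, "task_id": str})
    required = {"user_id", "task_id", "score"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    scores = pd.to_numeric(df["score"], errors="coerce")
    bad = scores.isna() | (scores % 1 != 0)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(f"{path}: non-integer score at row {row}")
    df["score"] = scores.astype(int)
    try:
        return RatingsTable.from_frame(df)
    except ValueError as e:
        raise ValueError(f"{path}: {e}") from None


def write_ratings(table: RatingsTable, path) -> None:
    table.to_frame().to_csv(path, index=False)


def scores_to_quintiles(raw: pd.DataFrame) -> pd.DataFrame:
    """Convert raw per-task performance values to quintile scores 1..5.

    Input columns: user_id, task_id, value. For each task, values are
    percentile-ranked over the full sample (ties get the average rank) and
    binned by cut points at the 20/40/60/80 percentiles; values landing
    exactly on a boundary go to the lower quintile. Tasks with fewer than 5
    distinct values cannot spread over the quintiles and are flagged.
    """
    required = {"user_id", "task_id", "value"}
    missing = required - set(raw.columns)
    if missing:
        raise ValueError(f"raw scores frame missing columns: {sorted(missing)}")
    out = raw.reset_index(drop=True).copy()
    degenerate = []
    scores = np.empty(len(out), dtype=int)
    for tid, grp in out.groupby("task_id", sort=False):
        vals = grp["value"].astype(float)
        if vals.nunique() < 5:
            degenerate.append(tid)
        pct = vals.rank(method="average") / len(vals) * 100.0
        q = np.ceil(pct.to_numpy() / 20.0).astype(int)
        scores[grp.index.to_numpy()] = np.clip(q, 1, 5)
    if degenerate:
        import warnings

        warnings.warn(
            f"tasks with fewer than 5 distinct values: {degenerate}", stacklevel=2
        )
    out["score"] = scores
    return out[["user_id", "task_id", "score"]]


def write_roster(classrooms, path) -> None:
    rows = []
    for c in classrooms:
        for s in c.students:
            rows.append(
                {
                    "classroom_id": c.classroom_id,
                    "student_id": s,
                    "age": c.age,
                    "gender": c.gender.get(s, "no-answer"),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_sociograms(sociograms, path) -> None:
    rows = []
    for ml in sociograms:
        cid = ml.classroom.classroom_id
        for label, layer in ml.layers.items():
            for src, dst in layer.edges:
                rows.append(
                    {
                        "classroom_id": cid,
                        "layer": label,
                        "source_id": src,
                        "target_id": dst,
                    }
                )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_sociograms(edges_path, roster_path) -> list:
    """Read roster and edge-list CSVs into per-classroom multilayer objects.

    Violations — self-loops, cross-classroom edges, unknown layers, more
    than three nominations per student per layer — are rejected with the
    offending row number.
    """
    roster_df = pd.read_csv(
        roster_path, dtype={"classroom_id": str, "student_id": str, "gender": str}
    )
    req = {"classroom_id", "student_id", "age", "gender"}
    missing = req - set(roster_df.columns)
    if missing:
        raise ValueError(f"{roster_path}: missing columns {sorted(missing)}")
    bad_gender = ~roster_df["gender"].isin(GENDERS)
    if bad_gender.any():
        row = int(np.flatnonzero(bad_gender.to_numpy())[0])
        raise ValueError(f"{roster_path}: unknown gender at row {row}")

    classrooms = {}
    for cid, grp in roster_df.groupby("classroom_id", sort=False):
        ages = grp["age"].unique()
        if len(ages) != 1:
            raise ValueError(f"{roster_path}: classroom {cid} has multiple ages")
        classrooms[cid] = Classroom(
            classroom_id=cid,
            age=int(ages[0]),
            students=tuple(grp["student_id"]),
            gender=dict(zip(grp["student_id"], grp["gender"])),
        )

    edges_df = pd.read_csv(
        edges_path,
        dtype={"classroom_id": str, "layer": str, "source_id": str, "target_id": str},
    )
    req = {"classroom_id", "layer", "source_id", "target_id"}
    missing = req - set(edges_df.columns)
    if missing:
        raise ValueError(f"{edges_path}: missing columns {sorted(missing)}")

    per_class: dict = {cid: {lbl: [] for lbl in LAYER_LABELS} for cid in classrooms}
    out_deg: dict = {}
    for row_idx, row in enumerate(edges_df.itertuples(index=False)):
        cid, layer, src, dst = row.classroom_id, row.layer, row.source_id, row.target_id
        if cid not in classrooms:
            raise ValueError(f"{edges_path}: unknown classroom at row {row_idx}")
        if layer not in LAYER_LABELS:
            raise ValueError(f"{edges_path}: unknown layer {layer!r} at row {row_idx}")
        members = set(classrooms[cid].students)
        if src not in members or dst not in members:
            raise ValueError(
                f"{edges_path}: cross-classroom or unknown student at row {row_idx}"
            )
        if src == dst:
            raise ValueError(f"{edges_path}: self-loop at row {row_idx}")
        if (src, dst) in per_class[cid][layer]:
            raise ValueError(f"{edges_path}: duplicate edge at row {row_idx}")
        key = (cid, layer, src)
        out_deg[key] = out_deg.get(key, 0) + 1
        if out_deg[key] > MAX_NOMINATIONS:
            raise ValueError(
                f"{edges_path}: student {src!r} exceeds {MAX_NOMINATIONS} "
                f"nominations in layer {layer!r} at row {row_idx}"
            )
        per_class[cid][layer].append((src, dst))

    sociograms = []
    for cid, classroom in classrooms.items():
        layers = {
            lbl: SociogramLayer(
                label=lbl,
                roster=tuple(classroom.students),
                edges=tuple(per_class[cid][lbl]),
            )
            for lbl in LAYER_LABELS
        }
        sociograms.append(MultilayerSociogram(classroom=classroom, layers=layers))
    return sociograms


def save_model(params: MMSBMParams, users, tasks, path, metadata: dict | None = None):
    """Serialize fitted parameters (θ, η, p) plus id indices as JSON."""
    payload = {
        "theta": params.theta.tolist(),
        "eta": params.eta.tolist(),
        "p": params.p.tolist(),
        "users": [str(u) for u in users],
        "tasks": [str(t) for t in tasks],
        "metadata": metadata or {},
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path) -> tuple[MMSBMParams, list, list, dict]:
    payload = json.loads(Path(path).read_text())
    params = MMSBMParams(
        theta=np.asarray(payload["theta"]),
        eta=np.asarray(payload["eta"]),
        p=np.asarray(payload["p"]),
    )
    params.validate(atol=1e-9)
    return params, payload["users"], payload["tasks"], payload.get("metadata", {})
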