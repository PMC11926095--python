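"""The bipartite ratings table: observed (student, task, quintile score) links."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: admissible quintile scores
SCORES = (1, 2, 3, 4, 5)
N_SCORES = 5


@dataclass(frozen=True)
class RatingsTable:
    """Observed links of the bipartite student-by-task graph.

    Each link is a (user, task, score) triple with the score a quintile in
    1..5. Users and tasks are kept in explicit index arrays so that a subset
    (e.g. the train half of a holdout split) can retain the full id universe
    of its parent table; users or tasks that end up with zero links are then
    handled by the model's degenerate-row rule instead of disappearing.

    Attributes
    ----------
    users, tasks : ndarray
        Unique ids, in first-appearance order; positions define the integer
        coding used by ``u`` and ``t``.
    u, t : ndarray of int
        Per-link user/task index into ``users``/``tasks``.
    s : ndarray of int
        Per-link quintile score in 1..5.
    """

    users: np.ndarray
    tasks: np.ndarray
    u: np.ndarray
    t: np.ndarray
    s: np.ndarray
    _user_pos: dict = field(repr=False, compare=False, default_factory=dict)
    _task_pos: dict = field(repr=False, compare=False, default_factory=dict)

    def __post_init__(self):
        object.__setattr__(
            self, "_user_pos", {uid: i for i, uid in enumerate(self.users)}
        )
        object.__setattr__(
            self, "_task_pos", {tid: i for i, tid in enumerate(self.tasks)}
        )

    @property
    def n_links(self) -> int:
        return int(self.u.size)

    @property
    def n_users(self) -> int:
        return int(self.users.size)

    @property
    def n_tasks(self) -> int:
        return int(self.tasks.size)

    def user_position(self, user_id) -> int:
        try:
            return self._user_pos[user_id]
        except KeyError:
            raise KeyError(f"unknown user id: {user_id!r}") from None

    def task_position(self, task_id) -> int:
        try:
            return self._task_pos[task_id]
        except KeyError:
            raise KeyError(f"unknown task id: {task_id!r}") from None

    @classmethod
    def from_links(
        cls,
        links: Iterable[tuple],
        users: Sequence | None = None,
        tasks: Sequence | None = None,
    ) -> "RatingsTable":
        """Build a table from (user_id, task_id, score) triples.

        ``users``/``tasks`` optionally fix the id universe (useful for splits
        that must share their parent's index); ids appearing in links but not
        listed are rejected.
        """
        rows = list(links)
        df = pd.DataFrame(rows, columns=["user_id", "task_id", "score"])
        return cls.from_frame(df, users=users, tasks=tasks)

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        users: Sequence | None = None,
        tasks: Sequence | None = None,
    ) -> "RatingsTable":
        required = {"user_id", "task_id", "score"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"ratings frame missing columns: {sorted(missing)}")
        scores = df["score"].to_numpy()
        bad = ~np.isin(scores, SCORES)
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"score out of range 1..5 at row {row}: {scores[row]!r}"
            )
        dup = df.duplicated(subset=["user_id", "task_id"])
        if dup.any():
            row = int(np.flatnonzero(dup.to_numpy())[0])
            raise ValueError(f"duplicate (user, task) pair at row {row}")

        if users is None:
            users = df["user_id"].drop_duplicates().to_numpy()
        else:
            users = np.asarray(list(users))
        if tasks is None:
            tasks = df["task_id"].drop_duplicates().to_numpy()
        else:
            tasks = np.asarray(list(tasks))

        upos = {uid: i for i, uid in enumerate(users)}
        tpos = {tid: i for i, tid in enumerate(tasks)}
        try:
            u = np.array([upos[x] for x in df["user_id"]], dtype=np.intp)
        except KeyError as e:
            raise ValueError(f"link references user absent from index: {e}") from None
        try:
            t = np.array([tpos[x] for x in df["task_id"]], dtype=np.intp)
        except KeyError as e:
            raise ValueError(f"link references task absent from index: {e}") from None
        return cls(
            users=np.asarray(users),
            tasks=np.asarray(tasks),
            u=u,
            t=t,
            s=scores.astype(np.intp),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "user_id": self.users[self.u],
                "task_id": self.tasks[self.t],
                "score": self.s,
            }
        )

    def subset(self, mask: np.ndarray) -> "RatingsTable":
        """Link subset sharing this table's full user/task index."""
        mask = np.asarray(mask, dtype=bool)
        return RatingsTable(
            users=self.users,
            tasks=self.tasks,
            u=self.u[mask],
            t=self.t[mask],
            s=self.s[mask],
        )

    def user_degrees(self) -> np.ndarray:
        return np.bincount(self.u, minlength=self.n_users)

    def task_degrees(self) -> np.ndarray:
        return np.bincount(self.t, minlength=self.n_tasks)
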