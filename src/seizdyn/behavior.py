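"""Racine behavioral score series and group curve comparison.

Behavioral seizure severity is rated on the ordinal Racine scale (0-5) in
contiguous 30 s epochs anchored to the pilocarpine injection.  Group curves
are per-epoch means with SEM across subjects, with missing epochs (shorter
records, or epochs after pentobarbital) excluded pairwise.  Group curves
are compared with the cluster-based permutation test using the rank-sum
pointwise statistic, which respects the ordinal scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AlignmentError, FormatError, PreconditionError
from .group_stats import ClusterResult, cluster_permutation_test

EPOCH_S = 30.0
SCORE_RANGE = (0, 5)


@dataclass
class RacineSeries:
    """One animal's Racine ratings: integer scores 0-5 in 30 s epochs."""

    epoch_starts: np.ndarray  # seconds, relative to injection
    scores: np.ndarray  # int, 0-5
    subject_id: str = ""
    group: str | None = None

    def __post_init__(self) -> None:
        self.epoch_starts = np.asarray(self.epoch_starts, dtype=float)
        self.scores = np.asarray(self.scores)
        if self.epoch_starts.shape != self.scores.shape:
            raise FormatError("epoch_starts and scores must align")
        if self.scores.size and not np.all(
            (self.scores >= SCORE_RANGE[0]) & (self.scores <= SCORE_RANGE[1])
        ):
            raise FormatError("Racine scores must lie in 0..5")
        if self.epoch_starts.size > 1:
            steps = np.diff(self.epoch_starts)
            if not np.allclose(steps, EPOCH_S):
                raise FormatError("epochs must be contiguous at 30 s spacing")

    def truncated_at(self, t: float) -> "RacineSeries":
        """Drop epochs starting at or after ``t`` (e.g. pentobarbital)."""
        keep = self.epoch_starts < t
        return RacineSeries(
            self.epoch_starts[keep], self.scores[keep], self.subject_id, self.group
        )


def load_racine(
    path, subject_id: str = "", group: str | None = None
) -> RacineSeries:
    """Read a Racine series from CSV with columns ``epoch_start_s,score``."""
    df = pd.read_csv(path)
    if not {"epoch_start_s", "score"} <= set(df.columns):
        raise FormatError("racine CSV needs columns epoch_start_s,score")
    scores = df["score"].to_numpy()
    if not np.all(scores == scores.astype(int)):
        raise FormatError("Racine scores must be integers")
    return RacineSeries(
        df["epoch_start_s"].to_numpy(float), scores.astype(int), subject_id, group
    )


@dataclass
class GroupCurves:
    """Per-group Racine score matrices on a common epoch grid."""

    epoch_starts: np.ndarray
    matrices: dict[str, np.ndarray]  # group -> (subjects x epochs), NaN-padded

    def mean(self, group: str) -> np.ndarray:
        return np.nanmean(self.matrices[group], axis=0)

    def sem(self, group: str) -> np.ndarray:
        m = self.matrices[group]
        count = np.sum(~np.isnan(m), axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            sd = np.nanstd(m, axis=0, ddof=1)
        sem = np.where(count > 1, sd / np.sqrt(np.maximum(count, 1)), 0.0)
        return np.nan_to_num(sem)


def group_racine_curves(series_set: list[RacineSeries]) -> GroupCurves:
    """Assemble per-group score matrices on the union epoch grid.

    Epochs beyond an animal's record are NaN and are excluded pairwise by
    the mean/SEM accessors.
    """
    if not series_set:
        raise PreconditionError("empty series collection")
    t0 = min(s.epoch_starts[0] for s in series_set if s.epoch_starts.size)
    t1 = max(s.epoch_starts[-1] for s in series_set if s.epoch_starts.size)
    grid = np.arange(t0, t1 + EPOCH_S / 2, EPOCH_S)
    groups: dict[str, list[np.ndarray]] = {}
    for s in series_set:
        row = np.full(grid.size, np.nan)
        j = np.round((s.epoch_starts - t0) / EPOCH_S).astype(int)
        row[j] = s.scores
        groups.setdefault(s.group or "", []).append(row)
    return GroupCurves(grid, {g: np.vstack(rows) for g, rows in groups.items()})


def compare_racine(
    groupA: np.ndarray,
    groupB: np.ndarray,
    alpha_point: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
    times: np.ndarray | None = None,
) -> ClusterResult:
    """Cluster-based permutation comparison of two Racine score matrices.

    Columns containing any NaN (epochs not rated for every animal) are
    dropped from both groups before testing.
    """
    A = np.atleast_2d(np.asarray(groupA, dtype=float))
    B = np.atleast_2d(np.asarray(groupB, dtype=float))
    if min(A.shape[0], B.shape[0]) < 3:
        raise PreconditionError("each group needs >= 3 subjects")
    if A.shape[1] != B.shape[1]:
        raise AlignmentError("group score matrices must share one epoch grid")
    complete = ~np.isnan(A).any(axis=0) & ~np.isnan(B).any(axis=0)
    t = np.asarray(times)[complete] if times is not None else None
    return cluster_permutation_test(
        A[:, complete],
        B[:, complete],
        stat="ranksum",
        alpha_point=alpha_point,
        n_perm=n_perm,
        seed=seed,
        times=t,
    )
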