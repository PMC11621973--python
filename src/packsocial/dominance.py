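"""Dominance matrix construction and (normalised) David's scores.

Three coded behaviours feed the dominance matrix. An aggression event adds
one win to the aggressor over the recipient. A submission event adds one
win to the *recipient* of the display over the displayer (the submissive
signal acknowledges the other animal's dominance). A scent-marking event
adds one win to the marker over every other adult that is a group member at
the time of the event. Each win is worth exactly one point.

From the win matrix s, the dyadic win proportion is P_ij = s_ij / n_ij
with n_ij = s_ij + s_ji (P_ij = 0 for unobserved dyads). David's score
combines direct and opponent-weighted win/loss proportions,

    DS_i = w_i + w2_i - l_i - l2_i,
    w_i = sum_j P_ij,      w2_i = sum_j w_j P_ij,
    l_i = sum_j P_ji,      l2_i = sum_j l_j P_ji,

and the normalised score NormDS_i = (DS_i + N(N-1)/2) / N maps onto
[0, N-1] so that scores are comparable across group sizes. Optionally the
dyadic proportions can be replaced by the sample-size-corrected index
Dij = P_ij - (P_ij - 0.5)/(n_ij + 1) (de Vries et al. 2006).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .obs_model import UNIDENTIFIED, ObservationLog

__all__ = [
    "DominanceMatrix",
    "DavidsScoreTable",
    "build_dominance_matrix",
    "dyadic_proportions",
    "davids_scores",
    "rank_hierarchy",
]

Correction = Literal["none", "dij"]


@dataclass
class DominanceMatrix:
    """Win counts between adults: ``wins[i, j]`` = wins of i over j."""

    ids: tuple[str, ...]
    wins: np.ndarray
    skipped_unidentified: int = 0

    def __post_init__(self) -> None:
        self.ids = tuple(self.ids)
        wins = np.asarray(self.wins, dtype=float)
        n = len(self.ids)
        if wins.shape != (n, n):
            raise ValueError(f"wins shape {wins.shape} != ({n}, {n})")
        if (wins < 0).any():
            raise ValueError("negative win count")
        if np.diagonal(wins).any():
            raise ValueError("diagonal of the win matrix must be zero")
        self.wins = wins

    def index(self, code: str) -> int:
        return self.ids.index(code)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.wins, index=list(self.ids), columns=list(self.ids))

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index_label="id")

    @classmethod
    def read_csv(cls, path: str | Path) -> "DominanceMatrix":
        frame = pd.read_csv(path, index_col=0)
        return cls(ids=tuple(frame.columns), wins=frame.to_numpy())


@dataclass
class DavidsScoreTable:
    """Per-individual David's score components and normalised scores.

    ``rank`` and ``tie_break`` are filled by :func:`rank_hierarchy`;
    ``tie_break`` records which criterion separated each individual from
    the one ranked immediately above it.
    """

    ids: tuple[str, ...]
    w: np.ndarray
    w2: np.ndarray
    l: np.ndarray
    l2: np.ndarray
    ds: np.ndarray
    norm_ds: np.ndarray
    total_wins: np.ndarray
    total_losses: np.ndarray
    rank: np.ndarray | None = None
    tie_break: tuple[str, ...] | None = None

    @property
    def n(self) -> int:
        return len(self.ids)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            {
                "id": list(self.ids),
                "w": self.w,
                "w2": self.w2,
                "l": self.l,
                "l2": self.l2,
                "DS": self.ds,
                "NormDS": self.norm_ds,
                "total_wins": self.total_wins,
                "total_losses": self.total_losses,
            }
        )
        if self.rank is not None:
            frame["rank"] = self.rank
            frame["tie_break"] = list(self.tie_break or ())
            frame = frame.sort_values("rank").reset_index(drop=True)
        return frame


def build_dominance_matrix(
    log: ObservationLog,
    adults: Sequence[str] | None = None,
    scent_mark_fanout: bool = True,
) -> DominanceMatrix:
    """Tally wins from aggression, submission and scent-marking events.

    Parameters
    ----------
    log:
        Observation log; its roster supplies tenure dates, which determine
        who counts as "the rest of the group" for a scent mark.
    adults:
        Ids to include (default: all roster adults). Events whose actor or
        recipient is outside this set contribute nothing.
    scent_mark_fanout:
        If True (default), a scent mark scores one win against *each* other
        adult in the group at the event's time. If False, the mark is worth
        a single aggregate point, spread as 1/k of a win against each of
        the k other adults then present.
    """
    if adults is None:
        adults = [ind.id for ind in log.roster if ind.life_stage == "adult"]
    adults = list(adults)
    if len(adults) < 2:
        raise ValueError("need at least two adults to build a dominance matrix")
    roster_ids = set(log.roster_ids())
    missing = set(adults) - roster_ids
    if missing:
        raise ValueError(f"adults not in roster: {sorted(missing)}")

    idx = {code: i for i, code in enumerate(adults)}
    wins = np.zeros((len(adults), len(adults)), dtype=float)
    skipped = 0
    tenure = {ind.id: ind for ind in log.roster}

    for ev in log.events:
        if ev.behaviour in ("aggression", "submission"):
            if ev.actor == UNIDENTIFIED or ev.recipient == UNIDENTIFIED:
                skipped += 1
                continue
            if ev.actor not in idx or ev.recipient not in idx:
                continue
            if ev.behaviour == "aggression":
                wins[idx[ev.actor], idx[ev.recipient]] += 1
            else:  # submission: the displayed-to individual gains the win
                wins[idx[ev.recipient], idx[ev.actor]] += 1
        elif ev.behaviour == "scent marking":
            if ev.actor == UNIDENTIFIED:
                skipped += 1
                continue
            if ev.actor not in idx:
                continue
            day = ev.timestamp.date()
            others = [
                code
                for code in adults
                if code != ev.actor and tenure[code].present_on(day)
            ]
            if not others:
                continue
            credit = 1.0 if scent_mark_fanout else 1.0 / len(others)
            for code in others:
                wins[idx[ev.actor], idx[code]] += credit

    return DominanceMatrix(
        ids=tuple(adults), wins=wins, skipped_unidentified=skipped
    )


def dyadic_proportions(
    matrix: DominanceMatrix, correction: Correction = "none"
) -> np.ndarray:
    """Dyadic win proportions P_ij (or the corrected index Dij).

    Unobserved dyads (n_ij = 0) get 0 in both directions; the diagonal is 0.
    """
    s = matrix.wins.astype(float)
    n_ij = s + s.T
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_ij > 0, s / np.where(n_ij > 0, n_ij, 1.0), 0.0)
    if correction == "dij":
        p = np.where(n_ij > 0, p - (p - 0.5) / (n_ij + 1.0), 0.0)
    elif correction != "none":
        raise ValueError(f"unknown correction {correction!r}")
    np.fill_diagonal(p, 0.0)
    return p


def davids_scores(
    matrix: DominanceMatrix, correction: Correction = "none"
) -> DavidsScoreTable:
    """David's scores and normalised David's scores for the matrix's adults."""
    n = len(matrix.ids)
    if n < 2:
        raise ValueError("David's scores require at least two individuals")
    p = dyadic_proportions(matrix, correction=correction)
    w = p.sum(axis=1)
    l = p.sum(axis=0)
    w2 = p @ w
    l2 = p.T @ l
    ds = w + w2 - l - l2
    norm_ds = (ds + n * (n - 1) / 2.0) / n
    return DavidsScoreTable(
        ids=matrix.ids,
        w=w,
        w2=w2,
        l=l,
        l2=l2,
        ds=ds,
        norm_ds=norm_ds,
        total_wins=matrix.wins.sum(axis=1),
        total_losses=matrix.wins.sum(axis=0),
    )


def rank_hierarchy(table: DavidsScoreTable) -> DavidsScoreTable:
    """Assign hierarchy ranks 1..N by NormDS (descending).

    Ties are broken by (1) more total raw wins, (2) fewer total raw losses,
    (3) lexicographic id; the criterion that separated each individual from
    its predecessor is recorded in ``tie_break``.
    """
    order = sorted(
        range(table.n),
        key=lambda i: (
            -table.norm_ds[i],
            -table.total_wins[i],
            table.total_losses[i],
            table.ids[i],
        ),
    )
    rank = np.empty(table.n, dtype=np.int64)
    tie_break: list[str] = [""] * table.n
    prev: int | None = None
    for pos, i in enumerate(order, start=1):
        rank[i] = pos
        if prev is None:
            tie_break[i] = "top"
        elif not np.isclose(table.norm_ds[prev], table.norm_ds[i]):
            tie_break[i] = "norm_ds"
        elif table.total_wins[prev] != table.total_wins[i]:
            tie_break[i] = "wins"
        elif table.total_losses[prev] != table.total_losses[i]:
            tie_break[i] = "losses"
        else:
            tie_break[i] = "id"
        prev = i
    return DavidsScoreTable(
        ids=table.ids,
        w=table.w,
        w2=table.w2,
        l=table.l,
        l2=table.l2,
        ds=table.ds,
        norm_ds=table.norm_ds,
        total_wins=table.total_wins,
        total_losses=table.total_losses,
        rank=rank,
        tie_break=tuple(tie_break),
    )
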