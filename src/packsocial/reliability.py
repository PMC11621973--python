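"""Reliability and temporal-independence diagnostics.

Individual identification from camera-trap footage is observer work, so a
study of this kind checks itself twice: intra-observer reliability, by
re-identifying a sample of detections and scoring agreement between the two
rounds with Cohen's kappa; and temporal independence of the recordings, by
autocorrelating the per-bin detection counts (short clips triggered by the
same passing animal would show up as positive short-lag autocorrelation).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .obs_model import ObservationLog

__all__ = [
    "ConfusionTable",
    "KappaResult",
    "AcfResult",
    "UndefinedKappaError",
    "ZeroVarianceError",
    "cohens_kappa",
    "detection_series",
    "acf",
]


class UndefinedKappaError(ValueError):
    """All mass in one row-column pair: chance agreement is 1, kappa undefined."""


class ZeroVarianceError(ValueError):
    """Autocorrelation of a constant series is undefined."""


@dataclass(frozen=True)
class ConfusionTable:
    """Square round-1 x round-2 identification count table."""

    labels: tuple[str, ...]
    counts: np.ndarray  # shape (k, k), non-negative integers

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", counts)
        k = len(self.labels)
        if counts.shape != (k, k):
            raise ValueError(f"counts shape {counts.shape} != ({k}, {k})")
        if (counts < 0).any():
            raise ValueError("negative cell count")
        if counts.sum() < 1:
            raise ValueError("confusion table must contain at least one count")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @classmethod
    def from_pairs(
        cls, pairs: list[tuple[str, str]], labels: tuple[str, ...] | None = None
    ) -> "ConfusionTable":
        """Build a table from (round-1 label, round-2 label) pairs."""
        if labels is None:
            labels = tuple(sorted({l for pair in pairs for l in pair}))
        index = {l: i for i, l in enumerate(labels)}
        counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
        for a, b in pairs:
            counts[index[a], index[b]] += 1
        return cls(labels=labels, counts=counts)

    @classmethod
    def read_csv(cls, path: str | Path) -> "ConfusionTable":
        """Read a labelled square matrix CSV (first column = round-1 labels)."""
        import csv

        with open(path, newline="", encoding="utf-8") as fh:
            rows = list(csv.reader(fh))
        header = rows[0][1:]
        labels = tuple(header)
        counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
        for row in rows[1:]:
            i = labels.index(row[0])
            counts[i, :] = [int(v) for v in row[1:]]
        return cls(labels=labels, counts=counts)

    def write_csv(self, path: str | Path) -> None:
        import csv

        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow([""] + list(self.labels))
            for label, row in zip(self.labels, self.counts):
                writer.writerow([label] + [int(v) for v in row])


@dataclass(frozen=True)
class KappaResult:
    p_o: float
    p_e: float
    kappa: float


@dataclass(frozen=True)
class AcfResult:
    n: int
    lags: tuple[int, ...]
    r: tuple[float, ...]

    def max_abs(self) -> float:
        return max(abs(v) for v in self.r)


def cohens_kappa(table: ConfusionTable) -> KappaResult:
    """Chance-corrected agreement between two labelling rounds.

    p_o is the observed agreement (diagonal fraction), p_e the agreement
    expected from the marginal label frequencies alone, and
    kappa = (p_o - p_e) / (1 - p_e).
    """
    counts = table.counts.astype(float)
    n = counts.sum()
    p_o = float(np.trace(counts) / n)
    p_e = float((counts.sum(axis=1) * counts.sum(axis=0)).sum() / n**2)
    if p_e >= 1.0:
        raise UndefinedKappaError(
            "all identifications fall in a single row-column pair (p_e = 1)"
        )
    return KappaResult(p_o=p_o, p_e=p_e, kappa=(p_o - p_e) / (1.0 - p_e))


def detection_series(
    log: ObservationLog, bin_width: dt.timedelta = dt.timedelta(days=1)
) -> np.ndarray:
    """Per-bin counts of recordings, from the first to the last event.

    A recording is assigned to the bin containing its start (the timestamp
    of its earliest event). Bins are contiguous, so quiet spells appear as
    zeros rather than gaps.
    """
    if not log.events:
        raise ValueError("cannot build a detection series from an empty log")
    if bin_width <= dt.timedelta(0):
        raise ValueError("bin_width must be positive")
    starts = [min(ev.timestamp for ev in evs) for evs in log.recordings().values()]
    t0 = min(starts)
    offsets = np.array([(s - t0) / bin_width for s in starts])
    idx = np.floor(offsets).astype(int)
    counts = np.bincount(idx, minlength=int(idx.max()) + 1)
    return counts.astype(np.int64)


def acf(series: np.ndarray, max_lag: int | None = None) -> AcfResult:
    """Sample autocorrelation r_k of a series at lags 1..max_lag.

    r_k = sum_{t}(x_t - xbar)(x_{t+k} - xbar) / sum_t (x_t - xbar)^2, the
    standard biased estimator whose denominator runs over the full series.
    Default max_lag = min(30, n // 4).
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if max_lag is None:
        max_lag = min(30, n // 4)
    if max_lag < 1 or n < max_lag + 2:
        raise ValueError(f"series of length {n} too short for max_lag={max_lag}")
    d = x - x.mean()
    denom = float(d @ d)
    if denom == 0.0:
        raise ZeroVarianceError("constant series has no autocorrelation")
    r = tuple(float(d[:-k] @ d[k:]) / denom for k in range(1, max_lag + 1))
    return AcfResult(n=n, lags=tuple(range(1, max_lag + 1)), r=r)
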