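"""Synthetic camera-trap event logs with known latent social structure.

The generator emulates what a year of camera trapping over one canid
group's territory yields: short recordings triggered by passing animals,
coded into behavioural events against the ethogram. Latent structure is
planted so every pipeline stage has a recoverable ground truth:

* a linear dominance hierarchy — each adult i has a latent strength s_i,
  and in an agonistic encounter between i and j, i wins with probability
  sigma(beta * (s_i - s_j)), a logistic curve in the strength difference;
* association clusters — each recording picks an anchor individual and
  co-detects others with probability p_in (same cluster) or p_out
  (different cluster), so within-cluster dyads co-occur more often;
* a composition timeline — a dispersal event removes subordinates partway
  through the study and a pup cohort enters as juveniles afterwards;
* identification noise — a re-identification round relabels each sampled
  detection correctly with probability q, otherwise uniformly to another
  roster id, feeding the kappa diagnostics.

All randomness flows from the single config seed through one named
generator; identical configs give byte-identical logs.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .obs_model import Individual, ObservationEvent, ObservationLog, UNIDENTIFIED
from .reliability import ConfusionTable
from .socialnet import SightingSummary

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "simulate_event_log",
    "simulate_reidentification",
    "planted_association_network",
]

_BASE_DATE = dt.date(2023, 1, 1)


def _default_strengths(n: int) -> tuple[float, ...]:
    """Dominant pair well above a run of homogeneous subordinates."""
    if n < 2:
        raise ValueError("need at least two adults")
    subs = tuple(0.6 - 0.1 * k for k in range(n - 2))
    return (2.0, 1.8) + subs


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator parameters; defaults describe a seven-adult group with a
    dominant pair, weak two-cluster association structure, a mid-study
    dispersal of three subordinates and a six-pup cohort."""

    n_adults: int = 7
    latent_strengths: tuple[float, ...] | None = None
    beta: float = 1.5
    dyadic_rate: float = 0.05          # agonistic events per dyad per day
    scent_mark_rates: tuple[float, ...] | None = None  # per adult per day
    cluster_assignment: tuple[int, ...] | None = None
    p_in: float = 0.5
    p_out: float = 0.35
    recordings_per_day: int = 5
    n_days: int = 290
    dispersal_ids: tuple[int, ...] = (2, 3, 6)   # adult indices that leave
    dispersal_day: int = 140
    pup_count: int = 6
    pup_day: int = 170
    submission_fraction: float = 0.3   # agonistic events coded from the loser's side
    misid_accuracy: float = 0.9
    seed: int = 0

    def strengths(self) -> tuple[float, ...]:
        s = self.latent_strengths or _default_strengths(self.n_adults)
        if len(s) != self.n_adults:
            raise ValueError("latent_strengths length must equal n_adults")
        return tuple(float(v) for v in s)

    def scent_rates(self) -> tuple[float, ...]:
        if self.scent_mark_rates is not None:
            if len(self.scent_mark_rates) != self.n_adults:
                raise ValueError("scent_mark_rates length must equal n_adults")
            return tuple(float(v) for v in self.scent_mark_rates)
        # dominants mark an order of magnitude more often than subordinates
        return tuple(0.1 if k < 2 else 0.02 for k in range(self.n_adults))

    def clusters(self) -> tuple[int, ...]:
        if self.cluster_assignment is not None:
            if len(self.cluster_assignment) != self.n_adults:
                raise ValueError("cluster_assignment length must equal n_adults")
            return tuple(int(c) for c in self.cluster_assignment)
        return tuple(0 if k < 2 else 1 for k in range(self.n_adults))

    def validate(self) -> None:
        if self.n_adults < 2:
            raise ValueError("n_adults must be >= 2")
        for name, p in (("p_in", self.p_in), ("p_out", self.p_out)):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.dyadic_rate < 0 or any(r < 0 for r in self.scent_rates()):
            raise ValueError("rates must be non-negative")
        if not 0.0 < self.misid_accuracy <= 1.0:
            raise ValueError("misid_accuracy must lie in (0, 1]")
        if not 0.0 <= self.submission_fraction <= 1.0:
            raise ValueError("submission_fraction must lie in [0, 1]")
        if self.n_days < 1 or self.recordings_per_day < 0:
            raise ValueError("n_days >= 1 and recordings_per_day >= 0 required")
        for day in (self.dispersal_day, self.pup_day):
            if not 1 <= day <= self.n_days:
                raise ValueError("dispersal/pup days must lie within [1, n_days]")
        if any(not 0 <= i < self.n_adults for i in self.dispersal_ids):
            raise ValueError("dispersal_ids must index adults")
        self.strengths()
        self.clusters()


@dataclass(frozen=True)
class GroundTruth:
    """Latent parameters behind a generated log, for recovery assertions."""

    ids: tuple[str, ...]
    strengths: tuple[float, ...]
    strength_order: tuple[str, ...]          # strongest first
    cluster_labels: dict[str, int]
    win_prob: np.ndarray                     # P(i beats j) per adult dyad
    p_in: float
    p_out: float


def adult_ids(n: int) -> tuple[str, ...]:
    """Two-letter codes AA, AB, AC, ... for the adults."""
    out = []
    for k in range(n):
        out.append("A" + chr(ord("A") + k) if n <= 26 else f"A{k:02d}")
    return tuple(out)


def _win_probabilities(strengths: Sequence[float], beta: float) -> np.ndarray:
    s = np.asarray(strengths, dtype=float)
    diff = np.subtract.outer(s, s)
    p = 1.0 / (1.0 + np.exp(-beta * diff))
    np.fill_diagonal(p, 0.0)
    return p


def _ground_truth(config: SyntheticConfig) -> GroundTruth:
    ids = adult_ids(config.n_adults)
    strengths = config.strengths()
    order = tuple(
        ids[i]
        for i in sorted(range(len(ids)), key=lambda i: (-strengths[i], ids[i]))
    )
    return GroundTruth(
        ids=ids,
        strengths=strengths,
        strength_order=order,
        cluster_labels=dict(zip(ids, config.clusters())),
        win_prob=_win_probabilities(strengths, config.beta),
        p_in=config.p_in,
        p_out=config.p_out,
    )


def simulate_event_log(config: SyntheticConfig) -> tuple[ObservationLog, GroundTruth]:
    """Generate a full observation log plus the latent truth behind it.

    Per day: agonistic encounter counts per present adult dyad are Poisson
    with rate ``dyadic_rate``; the encounter's winner follows the logistic
    win model, and the event is coded either as aggression by the winner
    or (with probability ``submission_fraction``) as submission by the
    loser — both add the same win to the dominance matrix. Scent marks are
    Poisson per adult. Detection recordings use the anchor/cluster
    co-detection model; pups join detection recordings as juveniles after
    ``pup_day``; dispersed adults emit nothing after ``dispersal_day``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    truth = _ground_truth(config)
    ids = list(truth.ids)
    strengths = truth.strengths
    clusters = config.clusters()
    scent = config.scent_rates()

    pup_ids = [f"P{k + 1}" for k in range(config.pup_count)]
    pup_entry = _BASE_DATE + dt.timedelta(days=config.pup_day - 1)
    roster = [
        Individual(
            id=ids[i],
            sex=("female", "male")[i % 2] if i < 2 else "unknown",
            life_stage="adult",
            entry_date=_BASE_DATE,
            exit_date=(
                _BASE_DATE + dt.timedelta(days=config.dispersal_day - 1)
                if i in config.dispersal_ids
                else None
            ),
        )
        for i in range(config.n_adults)
    ] + [
        Individual(
            id=p, sex="unknown", life_stage="juvenile", entry_date=pup_entry
        )
        for p in pup_ids
    ]
    tenure = {ind.id: ind for ind in roster}

    events: list[ObservationEvent] = []
    rec_counter = 0

    def new_recording(day: int) -> tuple[str, dt.datetime, str]:
        nonlocal rec_counter
        rec_counter += 1
        seconds = int(rng.integers(0, 86400))
        ts = dt.datetime.combine(
            _BASE_DATE + dt.timedelta(days=day - 1), dt.time()
        ) + dt.timedelta(seconds=seconds)
        camera = f"C{int(rng.integers(1, 12)):02d}"
        return f"R{rec_counter:06d}", ts, camera

    for day in range(1, config.n_days + 1):
        date = _BASE_DATE + dt.timedelta(days=day - 1)
        present_adults = [
            i for i in range(config.n_adults) if tenure[ids[i]].present_on(date)
        ]
        present_all = [code for code in tenure if tenure[code].present_on(date)]

        # agonistic encounters per present dyad
        for ai in range(len(present_adults)):
            for aj in range(ai + 1, len(present_adults)):
                i, j = present_adults[ai], present_adults[aj]
                for _ in range(int(rng.poisson(config.dyadic_rate))):
                    p_i = truth.win_prob[i, j]
                    winner, loser = (i, j) if rng.random() < p_i else (j, i)
                    rec, ts, cam = new_recording(day)
                    if rng.random() < config.submission_fraction:
                        behaviour, actor, recipient = (
                            "submission", ids[loser], ids[winner],
                        )
                    else:
                        behaviour, actor, recipient = (
                            "aggression", ids[winner], ids[loser],
                        )
                    events.append(
                        ObservationEvent(
                            recording_id=rec,
                            timestamp=ts,
                            camera_id=cam,
                            behaviour=behaviour,
                            actor=actor,
                            recipient=recipient,
                            present=frozenset({ids[i], ids[j]}),
                        )
                    )

        # scent marks per present adult
        for i in present_adults:
            for _ in range(int(rng.poisson(scent[i]))):
                rec, ts, cam = new_recording(day)
                events.append(
                    ObservationEvent(
                        recording_id=rec,
                        timestamp=ts,
                        camera_id=cam,
                        behaviour="scent marking",
                        actor=ids[i],
                        present=frozenset({ids[i]}),
                    )
                )

        # detection recordings with cluster-coupled co-detection
        cluster_of = {ids[i]: clusters[i] for i in range(config.n_adults)}
        for p in pup_ids:
            cluster_of[p] = 0  # pups travel with the dominant pair's cluster
        for _ in range(config.recordings_per_day):
            anchor = present_all[int(rng.integers(len(present_all)))]
            occupants = {anchor}
            for code in present_all:
                if code == anchor:
                    continue
                p = config.p_in if cluster_of[code] == cluster_of[anchor] else config.p_out
                if rng.random() < p:
                    occupants.add(code)
            rec, ts, cam = new_recording(day)
            behaviour = "social resting" if len(occupants) > 1 else "solitary resting"
            events.append(
                ObservationEvent(
                    recording_id=rec,
                    timestamp=ts,
                    camera_id=cam,
                    behaviour=behaviour,
                    actor=min(occupants),
                    present=frozenset(occupants),
                )
            )

    return ObservationLog(roster=roster, events=events), truth


def simulate_reidentification(
    log: ObservationLog,
    q: float,
    seed: int,
    n_samples: int = 120,
) -> ConfusionTable:
    """Simulate a second identification round over sampled detections.

    Each sampled detection keeps its true id with probability ``q`` and is
    otherwise relabelled uniformly to one of the other roster ids; the
    result is the round-1 x round-2 confusion table the kappa diagnostic
    consumes.
    """
    if not 0.0 < q <= 1.0:
        raise ValueError("q must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    labels = tuple(log.roster_ids())
    if len(labels) < 2:
        raise ValueError("re-identification needs at least two roster ids")
    detections = [
        code
        for events in log.recordings().values()
        for code in sorted(set().union(*(ev.present for ev in events)))
        if code != UNIDENTIFIED
    ]
    if not detections:
        raise ValueError("log contains no identified detections")
    picks = rng.integers(0, len(detections), size=n_samples)
    pairs = []
    for k in picks:
        true = detections[int(k)]
        if rng.random() < q:
            second = true
        else:
            others = [l for l in labels if l != true]
            second = others[int(rng.integers(len(others)))]
        pairs.append((true, second))
    return ConfusionTable.from_pairs(pairs, labels=labels)


def planted_association_network(
    config: SyntheticConfig,
) -> tuple[SightingSummary, GroundTruth]:
    """Sighting tallies from the pure cluster co-detection model.

    Recordings are drawn exactly as the detection recordings of
    :func:`simulate_event_log` (anchor plus p_in/p_out co-detections of the
    adults only), with ``recordings_per_day * n_days`` recordings. Requires
    planted structure, i.e. at least two clusters and p_in > p_out.
    """
    config.validate()
    clusters = config.clusters()
    if len(set(clusters)) < 2:
        raise ValueError("planted network needs at least two clusters")
    if config.p_in <= config.p_out:
        raise ValueError("planted structure requires p_in > p_out")
    rng = np.random.default_rng(config.seed)
    truth = _ground_truth(config)
    n = config.n_adults
    n_recordings = config.recordings_per_day * config.n_days
    x = np.zeros((n, n), dtype=np.int64)
    for _ in range(n_recordings):
        anchor = int(rng.integers(n))
        occupants = [anchor]
        for j in range(n):
            if j == anchor:
                continue
            p = config.p_in if clusters[j] == clusters[anchor] else config.p_out
            if rng.random() < p:
                occupants.append(j)
        for a in occupants:
            x[a, a] += 1
        for ai in range(len(occupants)):
            for bj in range(ai + 1, len(occupants)):
                a, b = occupants[ai], occupants[bj]
                x[a, b] += 1
                x[b, a] += 1
    return SightingSummary(ids=truth.ids, x=x), truth
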