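import datetime as dt

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from packsocial.obs_model import Individual, ObservationEvent, ObservationLog

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

BASE = dt.datetime(2023, 1, 1, 12, 0)


def make_individual(code, life_stage="adult", sex="unknown", entry=None, exit=None):
    return Individual(
        id=code,
        sex=sex,
        life_stage=life_stage,
        entry_date=entry or dt.date(2023, 1, 1),
        exit_date=exit,
    )


def make_event(
    rec,
    behaviour,
    actor,
    recipient=None,
    present=None,
    when=None,
    camera="C01",
):
    if present is None:
        present = {actor} | ({recipient} if recipient else set())
        present.discard("UNIDENTIFIED")
    return ObservationEvent(
        recording_id=rec,
        timestamp=when or BASE,
        camera_id=camera,
        behaviour=behaviour,
        actor=actor,
        recipient=recipient,
        present=frozenset(present),
    )


@pytest.fixture
def trio_roster():
    return [make_individual(c) for c in ("A", "B", "C")]


@pytest.fixture
def trio_log(trio_roster):
    events = [
        make_event("R1", "aggression", "A", "B", when=BASE),
        make_event("R2", "social resting", "A", present={"A", "B"},
                   when=BASE + dt.timedelta(hours=1)),
        make_event("R3", "scent marking", "C", when=BASE + dt.timedelta(hours=2)),
    ]
    return ObservationLog(roster=trio_roster, events=events)


@pytest.fixture
def rng():
    return np.random.default_rng(20230101)
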