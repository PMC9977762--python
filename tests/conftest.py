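import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from flocknet.simulate import SimConfig, generate_dataset
from flocknet.types import BirdRecord, SightingSession, Subgroup

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_roster(ids, first_days=None, **attrs):
    first_days = first_days or {}
    return [
        BirdRecord(
            bird_id=b,
            sex=attrs.get("sex", "unknown"),
            origin=attrs.get("origin", "captive"),
            age=attrs.get("age", 10.0),
            first_day_present=first_days.get(b, 0),
        )
        for b in ids
    ]


def make_session(day, slot, groups, n_unid=None):
    """groups: iterable of member-id iterables; n_unid: per-group counts."""
    n_unid = n_unid or {}
    return SightingSession(
        day=day,
        slot=slot,
        subgroups=tuple(
            Subgroup(frozenset(g), n_unid.get(i, 0)) for i, g in enumerate(groups)
        ),
    )


def random_sessions(rng, ids, n_sessions, max_days=None):
    """Random partitions of a random subset of ids into subgroups."""
    sessions = []
    n_days = max_days or max(2, n_sessions // 2)
    for s in range(n_sessions):
        day = int(rng.integers(0, n_days))
        present = [b for b in ids if rng.random() < 0.8]
        rng.shuffle(present)
        groups = []
        i = 0
        while i < len(present):
            size = int(rng.integers(1, 4))
            groups.append(present[i : i + size])
            i += size
        if not groups:
            continue
        sessions.append(make_session(day, f"s{s}", groups))
    return sessions


@pytest.fixture(scope="session")
def small_dataset():
    return generate_dataset(SimConfig.small(seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
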