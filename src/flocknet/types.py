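"""Shared domain types for the flock social-network pipeline.

The central objects mirror how gambit-of-the-group association data are
collected in the field: photographic samples (sessions) are partitions of the
sighted birds into subgroups, possibly with unidentified members; pairwise
sighting tallies feed the half-weight association index; behavioural and
agonistic event logs carry the personality and social-support data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

#: Marker used in event logs for a participant whose leg ring could not be read.
UNIDENTIFIED = "UNIDENTIFIED"

SEXES = ("male", "female", "unknown")
ORIGINS = ("wild", "captive")
TRAITS = ("aggressive", "exploratory", "submissive")
OUTCOMES = ("win", "loss", "draw")
#: Personality categories in ascending score order; ordinal ranks are 1-based.
CATEGORIES = ("A", "B", "C", "D")


class IntegrityError(ValueError):
    """Raised when data violate a structural invariant (duplicates, bounds...)."""


class ParseError(ValueError):
    """Raised when an input file is malformed; names the offending line."""


@dataclass(frozen=True)
class BirdRecord:
    """Roster entry for one individually identifiable bird."""

    bird_id: str
    sex: str = "unknown"
    origin: str = "captive"
    age: float = 0.0
    first_day_present: int = 0

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise IntegrityError(f"unknown sex {self.sex!r} for bird {self.bird_id}")
        if self.origin not in ORIGINS:
            raise IntegrityError(
                f"unknown origin {self.origin!r} for bird {self.bird_id}"
            )
        if self.age < 0:
            raise IntegrityError(f"negative age for bird {self.bird_id}")


@dataclass(frozen=True)
class Subgroup:
    """One spatial subgroup within a photographic sample.

    ``member_ids`` holds the identified birds; unidentified birds are carried
    only as a count so that the identification-exclusion rules can be applied
    deterministically.
    """

    member_ids: frozenset[str]
    n_unidentified: int = 0

    def __post_init__(self) -> None:
        if self.n_unidentified < 0:
            raise IntegrityError("n_unidentified must be >= 0")
        if not self.member_ids and self.n_unidentified == 0:
            raise IntegrityError("empty subgroup")

    @property
    def total_size(self) -> int:
        return len(self.member_ids) + self.n_unidentified


@dataclass(frozen=True)
class SightingSession:
    """All subgroups recorded in one photographic sample (one day/slot)."""

    day: int
    slot: str
    subgroups: tuple[Subgroup, ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g in self.subgroups:
            dup = seen & g.member_ids
            if dup:
                raise IntegrityError(
                    f"bird(s) {sorted(dup)} appear in two subgroups of session "
                    f"day={self.day} slot={self.slot!r}"
                )
            seen |= g.member_ids

    @property
    def identified_ids(self) -> frozenset[str]:
        out: set[str] = set()
        for g in self.subgroups:
            out |= g.member_ids
        return frozenset(out)


@dataclass(frozen=True)
class ProximityRecord:
    """Raw one-neck-length proximity edges for one sample, before the chain rule.

    ``sighted_ids`` lists every identified bird in the sample (a superset of the
    edge endpoints) so that birds sighted alone become singleton subgroups.
    """

    day: int
    slot: str
    edges: frozenset[frozenset[str]]
    sighted_ids: frozenset[str]

    def __post_init__(self) -> None:
        for e in self.edges:
            if len(e) != 2:
                raise IntegrityError(f"proximity edge {set(e)} is not a pair")
            if not e <= self.sighted_ids:
                raise IntegrityError(f"edge {set(e)} references unsighted birds")


@dataclass
class PairCounts:
    """Dyadic sighting tallies underlying the half-weight index.

    For birds i, j (matrix indices into ``ids``):

    * ``x[i, j]``      — samples with both identified and in the same subgroup.
    * ``y_ab[i, j]``   — samples with both identified but in different subgroups.
    * ``y_only[i, j]`` — samples with i identified and j not (``y_A`` from i's
      perspective; ``y_only.T`` gives ``y_B``).

    Samples before either bird's ``first_day_present`` are excluded for that
    dyad, so denominators are dyad specific.
    """

    ids: list[str]
    x: np.ndarray
    y_ab: np.ndarray
    y_only: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        for name in ("x", "y_ab", "y_only"):
            a = getattr(self, name)
            if a.shape != (n, n):
                raise IntegrityError(f"{name} has shape {a.shape}, expected {(n, n)}")
            if (a < 0).any():
                raise IntegrityError(f"negative counts in {name}")
        if not np.array_equal(self.x, self.x.T) or not np.array_equal(
            self.y_ab, self.y_ab.T
        ):
            raise IntegrityError("x and y_ab must be symmetric")


@dataclass
class AssociationMatrix:
    """Symmetric matrix of association indices in [0, 1] with zero diagonal."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if len(set(self.ids)) != n:
            raise IntegrityError("duplicate bird ids in association matrix")
        if self.values.shape != (n, n):
            raise IntegrityError(
                f"matrix shape {self.values.shape} does not match {n} ids"
            )
        if not np.allclose(self.values, self.values.T, atol=0.0, rtol=0.0):
            raise IntegrityError("association matrix is not symmetric")
        if (self.values < 0).any() or (self.values > 1).any():
            raise IntegrityError("association indices must lie in [0, 1]")
        if np.diagonal(self.values).any():
            raise IntegrityError("association matrix diagonal must be zero")

    @property
    def n(self) -> int:
        return len(self.ids)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AssociationMatrix):
            return NotImplemented
        return self.ids == other.ids and np.array_equal(self.values, other.values)


@dataclass(frozen=True)
class BehaviourEvent:
    """One observed instance of a trait-linked behaviour."""

    bird_id: str
    day: int
    trait: str

    def __post_init__(self) -> None:
        if self.trait not in TRAITS:
            raise IntegrityError(f"unknown trait {self.trait!r}")


@dataclass(frozen=True)
class Participant:
    """One bird's involvement in an agonistic event."""

    bird_id: str  # may be UNIDENTIFIED
    side: str
    outcome: str

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOMES:
            raise IntegrityError(f"unknown fight outcome {self.outcome!r}")


@dataclass(frozen=True)
class SupportRecord:
    """A claimed act of social support within a fight.

    Whether it *counts* (supporter did not instigate, shares the supported
    bird's side, and the supported bird was not subsequently displaced) is
    adjudicated by :func:`flocknet.agonistic.count_social_support`.
    """

    supporter_id: str
    supported_id: str
    focal_displaced_after: bool


@dataclass(frozen=True)
class AgonisticEvent:
    """One fight: two or more participants on at least two sides."""

    event_id: str
    day: int
    participants: tuple[Participant, ...]
    instigator_id: str = UNIDENTIFIED
    supports: tuple[SupportRecord, ...] = ()

    def __post_init__(self) -> None:
        if len(self.participants) < 2:
            raise IntegrityError(f"event {self.event_id}: fewer than 2 participants")
        if len({p.side for p in self.participants}) < 2:
            raise IntegrityError(f"event {self.event_id}: fewer than 2 sides")


@dataclass(frozen=True)
class DailyAssociationSet:
    """Day-pooled association data: who was identified, which dyads associated."""

    day: int
    identified_ids: frozenset[str]
    associated_pairs: frozenset[frozenset[str]]

    def __post_init__(self) -> None:
        for pair in self.associated_pairs:
            if not pair <= self.identified_ids:
                raise IntegrityError(
                    f"day {self.day}: associated pair {set(pair)} not identified"
                )


def make_pair(a: str, b: str) -> frozenset[str]:
    if a == b:
        raise IntegrityError(f"self-pair {a!r}")
    return frozenset((a, b))


def roster_index(roster: Sequence[BirdRecord]) -> dict[str, BirdRecord]:
    """Map bird_id -> record, enforcing id uniqueness."""
    out: dict[str, BirdRecord] = {}
    for rec in roster:
        if rec.bird_id in out:
            raise IntegrityError(f"duplicate bird_id {rec.bird_id!r} in roster")
        out[rec.bird_id] = rec
    return out
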