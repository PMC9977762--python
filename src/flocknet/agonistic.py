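"""Per-bird fight participation, outcomes and social-support frequencies.

A fight is an interaction between two or more birds within association
distance in which every participant shows aggressive behaviour; the observer
records each identified participant's outcome (win / loss / draw) and flags
the instigator. Social support means joining an associate's fight on their
side against a common opponent without having instigated it; a support act
only counts if the supported (focal) bird was not displaced or forced to
retreat afterwards. Unidentified participants are carried in the log but
accrue no counts.
"""

from __future__ import annotations

import logging
from typing import Sequence

import pandas as pd

from .types import (
    UNIDENTIFIED,
    AgonisticEvent,
    BirdRecord,
    IntegrityError,
    roster_index,
)

logger = logging.getLogger(__name__)

__all__ = ["summarise_fights", "count_social_support", "agonistic_summary"]

_COLUMNS = [
    "total_fights",
    "fights_won",
    "fights_lost",
    "fights_drawn",
    "support_given",
    "support_received",
]


def _empty_summary(roster: Sequence[BirdRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        0,
        index=pd.Index([r.bird_id for r in roster], name="bird_id"),
        columns=_COLUMNS,
    )


def summarise_fights(
    events: Sequence[AgonisticEvent], roster: Sequence[BirdRecord]
) -> pd.DataFrame:
    """Tally total fights, wins, losses and draws per identified bird."""
    by_id = roster_index(roster)
    out = _empty_summary(roster)
    for ev in events:
        for p in ev.participants:
            if p.bird_id == UNIDENTIFIED:
                continue
            if p.bird_id not in by_id:
                raise IntegrityError(
                    f"event {ev.event_id}: participant {p.bird_id!r} not in roster"
                )
            out.loc[p.bird_id, "total_fights"] += 1
            col = {"win": "fights_won", "loss": "fights_lost", "draw": "fights_drawn"}[
                p.outcome
            ]
            out.loc[p.bird_id, col] += 1
    return out[["total_fights", "fights_won", "fights_lost", "fights_drawn"]]


def count_social_support(
    events: Sequence[AgonisticEvent], roster: Sequence[BirdRecord]
) -> pd.DataFrame:
    """Count valid social-support acts given and received per bird.

    A record counts iff the supporter did not instigate the fight, supporter
    and supported stand on the same side, both are identified, and the focal
    (supported) bird was not displaced after receiving support. Invalid
    records are rejected with a warning.
    """
    by_id = roster_index(roster)
    out = _empty_summary(roster)[["support_given", "support_received"]].copy()
    for ev in events:
        sides = {p.bird_id: p.side for p in ev.participants if p.bird_id != UNIDENTIFIED}
        for s in ev.supports:
            if s.supporter_id == UNIDENTIFIED or s.supported_id == UNIDENTIFIED:
                continue
            if s.supporter_id == ev.instigator_id:
                logger.warning(
                    "event %s: supporter %s instigated the fight; record rejected",
                    ev.event_id,
                    s.supporter_id,
                )
                continue
            if s.supporter_id not in sides or s.supported_id not in sides:
                logger.warning(
                    "event %s: support record references non-participants; rejected",
                    ev.event_id,
                )
                continue
            if sides[s.supporter_id] != sides[s.supported_id]:
                logger.warning(
                    "event %s: supporter %s and supported %s on different sides; "
                    "record rejected",
                    ev.event_id,
                    s.supporter_id,
                    s.supported_id,
                )
                continue
            if s.focal_displaced_after:
                continue  # support did not hold: focal bird displaced
            if s.supporter_id not in by_id or s.supported_id not in by_id:
                raise IntegrityError(
                    f"event {ev.event_id}: support involves unknown bird"
                )
            out.loc[s.supporter_id, "support_given"] += 1
            out.loc[s.supported_id, "support_received"] += 1
    return out


def agonistic_summary(
    events: Sequence[AgonisticEvent], roster: Sequence[BirdRecord]
) -> pd.DataFrame:
    """Combined per-bird fight and social-support summary.

    "Social support frequency" as modelled downstream is ``support_given``;
    ``support_received`` is kept for completeness.
    """
    fights = summarise_fights(events, roster)
    support = count_social_support(events, roster)
    return fights.join(support)
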