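"""Readers and writers for the tabular input formats and matrix/graph export.

All formats are plain CSV so that archived field data can be dropped in
directly:

* sightings            — ``day,slot,subgroup,bird_id,n_unidentified`` (one row
  per identified bird; a row with an empty ``bird_id`` denotes a subgroup whose
  members were all unidentified)
* proximity edges      — ``day,slot,bird_a,bird_b`` (empty ``bird_b`` marks a
  bird sighted alone)
* roster               — ``bird_id,sex,origin,age,first_day_present``
* behaviour events     — ``day,bird_id,trait``
* agonistic events     — ``event_id,day,bird_id,side,outcome,is_instigator``
  plus a companion support CSV
  ``event_id,supporter_id,supported_id,focal_displaced``
* association matrices — square CSV with a header row and column of bird ids

Matrices are written in full (not as triangles) so that file corruption is
detectable through the symmetry check on read. Floats use ``repr`` precision,
making write→read an exact round trip.
"""

from __future__ import annotations

import csv
from collections import defaultdict
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .types import (
    UNIDENTIFIED,
    AgonisticEvent,
    AssociationMatrix,
    BehaviourEvent,
    BirdRecord,
    IntegrityError,
    ParseError,
    Participant,
    ProximityRecord,
    SightingSession,
    Subgroup,
    SupportRecord,
    make_pair,
    roster_index,
)

__all__ = [
    "read_sightings",
    "write_sightings",
    "read_proximity",
    "write_proximity",
    "read_roster",
    "write_roster",
    "read_behaviour_events",
    "write_behaviour_events",
    "read_agonistic_events",
    "write_agonistic_events",
    "read_association_matrix",
    "write_association_matrix",
    "export_graph",
]


def _open_rows(path: str | Path, expected_header: list[str]):
    """Yield (line_number, row) after validating the header row."""
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            return
        if [h.strip() for h in header] != expected_header:
            raise ParseError(
                f"{path}: line 1: expected header {','.join(expected_header)!r}, "
                f"got {','.join(header)!r}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            yield lineno, [c.strip() for c in row]


def _int(value: str, path, lineno: int, what: str) -> int:
    try:
        return int(value)
    except ValueError:
        raise ParseError(f"{path}: line {lineno}: bad {what} {value!r}") from None


def _float(value: str, path, lineno: int, what: str) -> float:
    try:
        return float(value)
    except ValueError:
        raise ParseError(f"{path}: line {lineno}: bad {what} {value!r}") from None


# ---------------------------------------------------------------------------
# sightings


def read_sightings(path: str | Path) -> list[SightingSession]:
    """Read long-format sighting data into sessions sorted by (day, slot).

    Rejects duplicate (day, slot, subgroup, bird) rows and birds appearing in
    two subgroups of the same session; checks that ``n_unidentified`` is
    reported consistently within each subgroup.
    """
    header = ["day", "slot", "subgroup", "bird_id", "n_unidentified"]
    members: dict[tuple[int, str], dict[str, set[str]]] = defaultdict(
        lambda: defaultdict(set)
    )
    n_unid: dict[tuple[int, str], dict[str, int]] = defaultdict(dict)
    for lineno, row in _open_rows(path, header):
        if len(row) != 5:
            raise ParseError(f"{path}: line {lineno}: expected 5 fields, got {len(row)}")
        day = _int(row[0], path, lineno, "day")
        slot, subgroup, bird = row[1], row[2], row[3]
        k = _int(row[4], path, lineno, "n_unidentified") if row[4] else 0
        if k < 0:
            raise ParseError(f"{path}: line {lineno}: negative n_unidentified")
        key = (day, slot)
        prev = n_unid[key].get(subgroup)
        if prev is not None and prev != k:
            raise IntegrityError(
                f"{path}: line {lineno}: inconsistent n_unidentified for subgroup "
                f"{subgroup!r} in session day={day} slot={slot!r} ({prev} vs {k})"
            )
        n_unid[key][subgroup] = k
        if bird:
            if bird in members[key][subgroup]:
                raise IntegrityError(
                    f"{path}: line {lineno}: duplicate row for bird {bird!r} in "
                    f"subgroup {subgroup!r}, session day={day} slot={slot!r}"
                )
            members[key][subgroup].add(bird)
        else:
            members[key].setdefault(subgroup, set())

    sessions = []
    for (day, slot) in sorted(members, key=lambda k: (k[0], k[1])):
        subgroups = tuple(
            Subgroup(frozenset(members[(day, slot)][g]), n_unid[(day, slot)][g])
            for g in sorted(members[(day, slot)])
        )
        sessions.append(SightingSession(day=day, slot=slot, subgroups=subgroups))
    return sessions


def write_sightings(sessions: Iterable[SightingSession], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["day", "slot", "subgroup", "bird_id", "n_unidentified"])
        for s in sessions:
            for gi, g in enumerate(s.subgroups):
                if g.member_ids:
                    for b in sorted(g.member_ids):
                        w.writerow([s.day, s.slot, f"g{gi}", b, g.n_unidentified])
                else:
                    w.writerow([s.day, s.slot, f"g{gi}", "", g.n_unidentified])


# ---------------------------------------------------------------------------
# proximity edges


def read_proximity(path: str | Path) -> list[ProximityRecord]:
    """Read raw one-neck-length proximity edges, one record per (day, slot)."""
    header = ["day", "slot", "bird_a", "bird_b"]
    edges: dict[tuple[int, str], set[frozenset[str]]] = defaultdict(set)
    sighted: dict[tuple[int, str], set[str]] = defaultdict(set)
    for lineno, row in _open_rows(path, header):
        if len(row) != 4:
            raise ParseError(f"{path}: line {lineno}: expected 4 fields, got {len(row)}")
        day = _int(row[0], path, lineno, "day")
        key = (day, row[1])
        a, b = row[2], row[3]
        if not a:
            raise ParseError(f"{path}: line {lineno}: empty bird_a")
        sighted[key].add(a)
        if b:
            if a == b:
                raise IntegrityError(f"{path}: line {lineno}: self-pair {a!r}")
            sighted[key].add(b)
            edges[key].add(make_pair(a, b))
        else:
            edges[key]  # touch so singleton-only records still appear
    return [
        ProximityRecord(
            day=day,
            slot=slot,
            edges=frozenset(edges[(day, slot)]),
            sighted_ids=frozenset(sighted[(day, slot)]),
        )
        for (day, slot) in sorted(sighted, key=lambda k: (k[0], k[1]))
    ]


def write_proximity(records: Iterable[ProximityRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["day", "slot", "bird_a", "bird_b"])
        for r in records:
            in_edges: set[str] = set()
            for e in sorted(tuple(sorted(e)) for e in r.edges):
                w.writerow([r.day, r.slot, e[0], e[1]])
                in_edges |= set(e)
            for b in sorted(r.sighted_ids - in_edges):
                w.writerow([r.day, r.slot, b, ""])


# ---------------------------------------------------------------------------
# roster


def read_roster(path: str | Path) -> list[BirdRecord]:
    header = ["bird_id", "sex", "origin", "age", "first_day_present"]
    roster: list[BirdRecord] = []
    for lineno, row in _open_rows(path, header):
        if len(row) != 5:
            raise ParseError(f"{path}: line {lineno}: expected 5 fields, got {len(row)}")
        roster.append(
            BirdRecord(
                bird_id=row[0],
                sex=row[1],
                origin=row[2],
                age=_float(row[3], path, lineno, "age"),
                first_day_present=_int(row[4], path, lineno, "first_day_present")
                if row[4]
                else 0,
            )
        )
    roster_index(roster)  # uniqueness check
    return roster


def write_roster(roster: Iterable[BirdRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["bird_id", "sex", "origin", "age", "first_day_present"])
        for r in roster:
            w.writerow([r.bird_id, r.sex, r.origin, repr(float(r.age)), r.first_day_present])


# ---------------------------------------------------------------------------
# behaviour events


def read_behaviour_events(path: str | Path) -> list[BehaviourEvent]:
    header = ["day", "bird_id", "trait"]
    events = []
    for lineno, row in _open_rows(path, header):
        if len(row) != 3:
            raise ParseError(f"{path}: line {lineno}: expected 3 fields, got {len(row)}")
        try:
            events.append(
                BehaviourEvent(
                    day=_int(row[0], path, lineno, "day"), bird_id=row[1], trait=row[2]
                )
            )
        except IntegrityError as exc:
            raise IntegrityError(f"{path}: line {lineno}: {exc}") from None
    return events


def write_behaviour_events(events: Iterable[BehaviourEvent], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["day", "bird_id", "trait"])
        for e in events:
            w.writerow([e.day, e.bird_id, e.trait])


# ---------------------------------------------------------------------------
# agonistic events


def read_agonistic_events(
    events_path: str | Path, supports_path: str | Path | None = None
) -> list[AgonisticEvent]:
    """Read fights and (optionally) their companion support records."""
    header = ["event_id", "day", "bird_id", "side", "outcome", "is_instigator"]
    parts: dict[str, list[Participant]] = defaultdict(list)
    days: dict[str, int] = {}
    instigators: dict[str, str] = {}
    order: list[str] = []
    for lineno, row in _open_rows(events_path, header):
        if len(row) != 6:
            raise ParseError(
                f"{events_path}: line {lineno}: expected 6 fields, got {len(row)}"
            )
        eid, day = row[0], _int(row[1], events_path, lineno, "day")
        if eid not in days:
            order.append(eid)
            days[eid] = day
        elif days[eid] != day:
            raise IntegrityError(
                f"{events_path}: line {lineno}: event {eid!r} spans two days"
            )
        try:
            parts[eid].append(Participant(bird_id=row[2], side=row[3], outcome=row[4]))
        except IntegrityError as exc:
            raise IntegrityError(f"{events_path}: line {lineno}: {exc}") from None
        if row[5].lower() in ("1", "true", "yes"):
            if eid in instigators and instigators[eid] != row[2]:
                raise IntegrityError(
                    f"{events_path}: line {lineno}: event {eid!r} has two instigators"
                )
            instigators[eid] = row[2]

    supports: dict[str, list[SupportRecord]] = defaultdict(list)
    if supports_path is not None:
        sheader = ["event_id", "supporter_id", "supported_id", "focal_displaced"]
        for lineno, row in _open_rows(supports_path, sheader):
            if len(row) != 4:
                raise ParseError(
                    f"{supports_path}: line {lineno}: expected 4 fields, got {len(row)}"
                )
            if row[0] not in days:
                raise IntegrityError(
                    f"{supports_path}: line {lineno}: unknown event_id {row[0]!r}"
                )
            supports[row[0]].append(
                SupportRecord(
                    supporter_id=row[1],
                    supported_id=row[2],
                    focal_displaced_after=row[3].lower() in ("1", "true", "yes"),
                )
            )

    return [
        AgonisticEvent(
            event_id=eid,
            day=days[eid],
            participants=tuple(parts[eid]),
            instigator_id=instigators.get(eid, UNIDENTIFIED),
            supports=tuple(supports.get(eid, ())),
        )
        for eid in order
    ]


def write_agonistic_events(
    events: Iterable[AgonisticEvent],
    events_path: str | Path,
    supports_path: str | Path,
) -> None:
    with open(events_path, "w", newline="") as fe, open(
        supports_path, "w", newline=""
    ) as fs:
        we = csv.writer(fe)
        ws = csv.writer(fs)
        we.writerow(["event_id", "day", "bird_id", "side", "outcome", "is_instigator"])
        ws.writerow(["event_id", "supporter_id", "supported_id", "focal_displaced"])
        for ev in events:
            for p in ev.participants:
                we.writerow(
                    [
                        ev.event_id,
                        ev.day,
                        p.bird_id,
                        p.side,
                        p.outcome,
                        int(p.bird_id == ev.instigator_id and p.bird_id != UNIDENTIFIED),
                    ]
                )
            for s in ev.supports:
                ws.writerow(
                    [
                        ev.event_id,
                        s.supporter_id,
                        s.supported_id,
                        int(s.focal_displaced_after),
                    ]
                )


# ---------------------------------------------------------------------------
# association matrices


def write_association_matrix(m: AssociationMatrix, path: str | Path) -> None:
    """Write the full symmetric matrix with an id header row and column."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["bird_id", *m.ids])
        for i, bid in enumerate(m.ids):
            w.writerow([bid, *(repr(float(v)) for v in m.values[i])])


def read_association_matrix(path: str | Path) -> AssociationMatrix:
    """Read a matrix CSV; symmetry, range and diagonal checks are applied."""
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty matrix file") from None
        ids = [h.strip() for h in header[1:]]
        rows = []
        row_ids = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(ids) + 1:
                raise ParseError(
                    f"{path}: line {lineno}: expected {len(ids) + 1} fields, "
                    f"got {len(row)}"
                )
            row_ids.append(row[0].strip())
            rows.append([_float(v, path, lineno, "matrix entry") for v in row[1:]])
    if row_ids != ids:
        raise IntegrityError(f"{path}: row ids do not match column ids")
    return AssociationMatrix(ids=ids, values=np.array(rows, dtype=float))


# ---------------------------------------------------------------------------
# graph export


def export_graph(
    m: AssociationMatrix,
    roster: Sequence[BirdRecord],
    path: str | Path,
    personality: dict[str, float] | None = None,
    categories: dict[str, str] | None = None,
) -> nx.Graph:
    """Export the weighted association network as GraphML.

    One node per bird (annotated with sex, origin, age and — when supplied —
    personality score/category), one weighted edge per strictly positive dyad.
    """
    by_id = roster_index(roster)
    missing = [b for b in m.ids if b not in by_id]
    if missing:
        raise IntegrityError(f"matrix ids missing from roster: {missing}")
    g = nx.Graph()
    for b in m.ids:
        rec = by_id[b]
        attrs = {"sex": rec.sex, "origin": rec.origin, "age": float(rec.age)}
        if personality is not None and b in personality:
            attrs["personality_score"] = float(personality[b])
        if categories is not None and b in categories:
            attrs["personality_category"] = categories[b]
        g.add_node(b, **attrs)
    n = m.n
    for i in range(n):
        for j in range(i + 1, n):
            w = m.values[i, j]
            if w > 0:
                g.add_edge(m.ids[i], m.ids[j], weight=float(w))
    nx.write_graphml(g, path)
    return g
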