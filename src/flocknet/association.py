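"""From sighting sessions to pairwise counts and the half-weight association matrix.

The pipeline follows the gambit of the group: every pair of identified birds in
the same subgroup of a photographic sample counts as associating in that
sample. The chain rule first merges one-neck-length proximity edges into
subgroups (connected components), then partial-identifiability exclusions are
applied, and finally per-dyad tallies feed the half-weight index

    HWI(i, j) = x / (x + y_AB + (y_A + y_B) / 2)

where x counts samples with the dyad together, y_AB samples with both
identified but apart, and y_A / y_B samples where only one of the two was
identified. The half-weight form is the standard choice when universal
identification within a sample is impossible.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .types import (
    AssociationMatrix,
    BirdRecord,
    IntegrityError,
    PairCounts,
    ProximityRecord,
    SightingSession,
    Subgroup,
    roster_index,
)

logger = logging.getLogger(__name__)

__all__ = [
    "chain_rule_groups",
    "apply_identification_exclusions",
    "tally_pair_counts",
    "half_weight_matrix",
    "build_association_matrix",
]


def chain_rule_groups(
    p: ProximityRecord, n_unidentified: int = 0
) -> SightingSession:
    """Merge proximity edges into subgroups by the chain rule.

    Subgroups are the connected components of the one-neck-length proximity
    graph: birds beyond the threshold distance still associate when linked
    through intermediate subgroup members. Birds sighted with no neighbour
    become singleton subgroups. ``n_unidentified`` (unplaceable unidentified
    birds) is attached to the session as its own subgroup so downstream
    exclusion rules can discard it.
    """
    g = nx.Graph()
    g.add_nodes_from(p.sighted_ids)
    g.add_edges_from(tuple(e) for e in p.edges)
    subgroups = [Subgroup(frozenset(comp)) for comp in nx.connected_components(g)]
    if n_unidentified > 0:
        subgroups.append(Subgroup(frozenset(), n_unidentified))
    # deterministic order: by sorted member list
    subgroups.sort(key=lambda s: sorted(s.member_ids))
    return SightingSession(day=p.day, slot=p.slot, subgroups=tuple(subgroups))


def apply_identification_exclusions(s: SightingSession) -> SightingSession:
    """Apply the partial-identifiability exclusion rules to one session.

    * A pair (total size 2) containing an unidentified bird is discounted
      entirely — the identified partner contributes nothing in this sample.
    * In subgroups of more than two birds, unidentified members are dropped
      while associations among the identified members are kept.
    * Subgroups whose members are all unidentified are removed.
    """
    kept: list[Subgroup] = []
    for g in s.subgroups:
        if not g.member_ids:
            continue  # wholly unidentified
        if g.total_size == 2 and g.n_unidentified == 1:
            continue  # unidentified bird standing in a pair: partner discounted
        if g.n_unidentified and g.total_size > 2:
            kept.append(Subgroup(g.member_ids, 0))
        else:
            kept.append(g)
    return SightingSession(day=s.day, slot=s.slot, subgroups=tuple(kept))


def tally_pair_counts(
    sessions: Iterable[SightingSession],
    roster: Sequence[BirdRecord],
    count_singletons: bool = True,
) -> PairCounts:
    """Accumulate per-dyad sighting tallies over exclusion-filtered sessions.

    The sampling unit is the photographic session. For each dyad, only
    sessions on or after both birds' ``first_day_present`` contribute, so
    birds added mid-study get dyad-specific denominators.

    ``count_singletons`` controls whether a bird photographed alone counts as
    "identified but not associated" for its dyads (the default) or is treated
    as present only for the one-sided counts. This is a sensitivity switch for
    an ambiguity in how lone birds enter the index denominator.
    """
    by_id = roster_index(roster)
    ids = [r.bird_id for r in roster]
    idx = {b: i for i, b in enumerate(ids)}
    n = len(ids)
    fdp = np.array([by_id[b].first_day_present for b in ids])

    x = np.zeros((n, n), dtype=np.int64)
    y_ab = np.zeros((n, n), dtype=np.int64)
    y_only = np.zeros((n, n), dtype=np.int64)

    for s in sessions:
        eligible = fdp <= s.day
        present = np.zeros(n, dtype=bool)
        group_of = np.full(n, -1, dtype=np.int64)
        alone = np.zeros(n, dtype=bool)
        for gi, g in enumerate(s.subgroups):
            for b in g.member_ids:
                if b not in idx:
                    raise IntegrityError(f"bird {b!r} in sightings but not in roster")
                i = idx[b]
                present[i] = True
                group_of[i] = gi
                alone[i] = len(g.member_ids) == 1
        if not count_singletons:
            # a lone bird is treated as unsampled in this session altogether
            present = present & ~alone
        pe = present & eligible
        same = (group_of[:, None] == group_of[None, :]) & pe[:, None] & pe[None, :]
        both = pe[:, None] & pe[None, :]
        x += same
        y_ab += both & ~same
        y_only += pe[:, None] & (~pe[None, :]) & eligible[None, :]

    np.fill_diagonal(x, 0)
    np.fill_diagonal(y_ab, 0)
    np.fill_diagonal(y_only, 0)
    return PairCounts(ids=ids, x=x, y_ab=y_ab, y_only=y_only)


def half_weight_matrix(c: PairCounts) -> AssociationMatrix:
    """Compute the half-weight association index matrix from dyadic tallies.

    Dyads never observed (zero denominator, i.e. the pair was co-absent in
    every eligible sample) score 0 and are logged, keeping the matrix dense
    for downstream matrix regression.
    """
    denom = c.x + c.y_ab + (c.y_only + c.y_only.T) / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        h = np.where(denom > 0, c.x / np.where(denom > 0, denom, 1.0), 0.0)
    np.fill_diagonal(h, 0.0)
    unobserved = (denom == 0).sum() - len(c.ids)  # exclude the diagonal
    if unobserved > 0:
        logger.warning(
            "%d dyads were never jointly observable; their HWI is set to 0",
            unobserved // 2,
        )
    return AssociationMatrix(ids=list(c.ids), values=h)


def build_association_matrix(
    sessions: Iterable[SightingSession],
    roster: Sequence[BirdRecord],
    count_singletons: bool = True,
) -> AssociationMatrix:
    """Exclusion-filter sessions, tally dyads and return the HWI matrix."""
    filtered = [apply_identification_exclusions(s) for s in sessions]
    return half_weight_matrix(
        tally_pair_counts(filtered, roster, count_singletons=count_singletons)
    )
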