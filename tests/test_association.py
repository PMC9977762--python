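import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import oracles
from conftest import make_roster, make_session, random_sessions
from flocknet.association import (
    apply_identification_exclusions,
    chain_rule_groups,
    half_weight_matrix,
    tally_pair_counts,
)
from flocknet.types import (
    IntegrityError,
    PairCounts,
    ProximityRecord,
    SightingSession,
    Subgroup,
)


def prox(edges, sighted, day=0, slot="s"):
    return ProximityRecord(
        day=day,
        slot=slot,
        edges=frozenset(frozenset(e) for e in edges),
        sighted_ids=frozenset(sighted),
    )


class TestChainRule:
    def test_chain_links_transitively(self):
        s = chain_rule_groups(prox([("A", "B"), ("B", "C")], "ABC"))
        assert {g.member_ids for g in s.subgroups} == {frozenset("ABC")}

    def test_no_edges_gives_singletons(self):
        s = chain_rule_groups(prox([], "AB"))
        assert {g.member_ids for g in s.subgroups} == {
            frozenset("A"),
            frozenset("B"),
        }

    def test_two_separate_pairs(self):
        s = chain_rule_groups(prox([("A", "B"), ("C", "D")], "ABCD"))
        expected = oracles.components_by_transitive_closure(
            "ABCD", [("A", "B"), ("C", "D")]
        )
        assert {g.member_ids for g in s.subgroups} == expected

    @given(st.data())
    def test_matches_transitive_closure_oracle(self, data):
        ids = [f"b{i}" for i in range(data.draw(st.integers(2, 7)))]
        pairs = [
            (a, b) for i, a in enumerate(ids) for b in ids[i + 1 :]
        ]
        edges = data.draw(st.lists(st.sampled_from(pairs), unique=True)) if pairs else []
        s = chain_rule_groups(prox(edges, ids))
        assert {g.member_ids for g in s.subgroups} == oracles.components_by_transitive_closure(ids, edges)

    def test_idempotent_under_rederived_proximity(self):
        s = chain_rule_groups(prox([("A", "B"), ("C", "D"), ("B", "E")], "ABCDEF"))
        # re-derive proximity edges from the output subgroups (clique edges)
        edges = set()
        for g in s.subgroups:
            ms = sorted(g.member_ids)
            edges |= {(a, b) for i, a in enumerate(ms) for b in ms[i + 1 :]}
        s2 = chain_rule_groups(prox(edges, [b for g in s.subgroups for b in g.member_ids]))
        assert {g.member_ids for g in s.subgroups} == {
            g.member_ids for g in s2.subgroups
        }


class TestIdentificationExclusions:
    def test_unidentified_in_pair_discounts_partner(self):
        s = make_session(0, "s", [["A"]], {0: 1})
        assert apply_identification_exclusions(s).subgroups == ()

    def test_trio_with_one_unidentified_keeps_pair(self):
        s = make_session(0, "s", [["A", "B"]], {0: 1})
        out = apply_identification_exclusions(s)
        assert [g.member_ids for g in out.subgroups] == [frozenset({"A", "B"})]
        assert out.subgroups[0].n_unidentified == 0

    def test_fully_identified_subgroup_unchanged(self):
        s = make_session(0, "s", [["A", "B"]])
        assert apply_identification_exclusions(s) == s

    def test_wholly_unidentified_subgroup_removed(self):
        s = SightingSession(0, "s", (Subgroup(frozenset(), 3),))
        assert apply_identification_exclusions(s).subgroups == ()

    def test_lone_identified_singleton_kept(self):
        s = make_session(0, "s", [["A"]])
        assert apply_identification_exclusions(s) == s


class TestPairCounts:
    def test_together_twice_apart_once(self):
        roster = make_roster(["A", "B"])
        sessions = [
            make_session(0, "a", [["A", "B"]]),
            make_session(0, "b", [["A", "B"]]),
            make_session(1, "a", [["A"], ["B"]]),
        ]
        c = tally_pair_counts(sessions, roster)
        assert c.x[0, 1] == 2
        assert c.y_ab[0, 1] == 1
        assert c.y_only[0, 1] == 0 and c.y_only[1, 0] == 0

    def test_one_bird_never_sighted(self):
        roster = make_roster(["A", "B"])
        sessions = [make_session(d, "a", [["A"]]) for d in range(4)]
        c = tally_pair_counts(sessions, roster)
        assert c.x[0, 1] == 0 and c.y_ab[0, 1] == 0
        assert c.y_only[0, 1] == 4 and c.y_only[1, 0] == 0

    def test_first_day_present_excludes_earlier_sessions(self):
        roster = make_roster(["A", "B"], first_days={"B": 5})
        sessions = [
            make_session(0, "a", [["A"]]),
            make_session(5, "a", [["A", "B"]]),
        ]
        c = tally_pair_counts(sessions, roster)
        # day 0 predates B's arrival, so it contributes nothing to the dyad
        assert c.x[0, 1] == 1
        assert c.y_only[0, 1] == 0

    def test_unknown_bird_rejected(self):
        with pytest.raises(IntegrityError, match="roster"):
            tally_pair_counts([make_session(0, "a", [["Z"]])], make_roster(["A"]))

    def test_matches_brute_force_recount(self, rng):
        ids = [f"b{i}" for i in range(6)]
        roster = make_roster(ids)
        sessions = random_sessions(rng, ids, 20)
        c = tally_pair_counts(sessions, roster)
        ox, oyab, oya, oyb = oracles.recount_pair_counts(
            [(s.day, [g.member_ids for g in s.subgroups]) for s in sessions],
            {b: 0 for b in ids},
        )
        for i, a in enumerate(ids):
            for j in range(i + 1, len(ids)):
                b = ids[j]
                assert c.x[i, j] == ox[(a, b)]
                assert c.y_ab[i, j] == oyab[(a, b)]
                assert c.y_only[i, j] == oya[(a, b)]
                assert c.y_only[j, i] == oyb[(a, b)]

    def test_session_order_invariance(self, rng):
        ids = [f"b{i}" for i in range(5)]
        roster = make_roster(ids)
        sessions = random_sessions(rng, ids, 12)
        c1 = tally_pair_counts(sessions, roster)
        c2 = tally_pair_counts(sessions[::-1], roster)
        assert np.array_equal(c1.x, c2.x)
        assert np.array_equal(c1.y_ab, c2.y_ab)
        assert np.array_equal(c1.y_only, c2.y_only)


def counts(ids, x, y_ab, y_a, y_b):
    """PairCounts for a single dyad (2 birds)."""
    return PairCounts(
        ids=list(ids),
        x=np.array([[0, x], [x, 0]]),
        y_ab=np.array([[0, y_ab], [y_ab, 0]]),
        y_only=np.array([[0, y_a], [y_b, 0]]),
    )


class TestHalfWeightIndex:
    @pytest.mark.parametrize(
        "x,y_ab,y_a,y_b,expected",
        [
            (3, 1, 1, 1, 0.6),  # 3 / (3 + 1 + 1)
            (5, 0, 0, 0, 1.0),  # always together
            (0, 4, 2, 0, 0.0),  # never together
            (2, 2, 0, 0, 0.5),  # full identifiability: x / (x + y_ab)
        ],
    )
    def test_worked_values(self, x, y_ab, y_a, y_b, expected):
        m = half_weight_matrix(counts("AB", x, y_ab, y_a, y_b))
        assert m.values[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_zero_denominator_scores_zero(self):
        m = half_weight_matrix(counts("AB", 0, 0, 0, 0))
        assert m.values[0, 1] == 0.0

    def test_negative_counts_rejected(self):
        with pytest.raises(IntegrityError, match="negative"):
            counts("AB", -1, 0, 0, 0)

    @given(
        x=st.integers(0, 30),
        y_ab=st.integers(0, 30),
        y_a=st.integers(0, 30),
        y_b=st.integers(0, 30),
    )
    def test_bounds_and_extremes(self, x, y_ab, y_a, y_b):
        v = half_weight_matrix(counts("AB", x, y_ab, y_a, y_b)).values[0, 1]
        assert 0.0 <= v <= 1.0
        if v == 1.0:
            assert x > 0 and y_ab == y_a == y_b == 0
        expected = oracles.hwi_from_counts(x, y_ab, y_a, y_b)
        assert v == pytest.approx(expected, abs=1e-12)

    @given(
        x=st.integers(0, 10),
        y_ab=st.integers(0, 10),
        y_a=st.integers(0, 10),
        y_b=st.integers(1, 10),
    )
    def test_monotone_in_x(self, x, y_ab, y_a, y_b):
        lo = half_weight_matrix(counts("AB", x, y_ab, y_a, y_b)).values[0, 1]
        hi = half_weight_matrix(counts("AB", x + 1, y_ab, y_a, y_b)).values[0, 1]
        assert hi >= lo
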