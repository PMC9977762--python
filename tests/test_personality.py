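import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import make_roster
from flocknet.personality import (
    bray_curtis_similarity,
    categorise,
    category_rank,
    pca_score,
    tally_traits,
)
from flocknet.types import BehaviourEvent, IntegrityError, TRAITS


def tallies_frame(rows):
    return pd.DataFrame(
        rows, columns=TRAITS, index=pd.Index([f"b{i}" for i in range(len(rows))])
    ).astype(float)


class TestTallyTraits:
    def test_simple_counts(self):
        roster = make_roster(["A", "B"])
        events = [BehaviourEvent("A", 0, "aggressive")] * 3 + [
            BehaviourEvent("A", 1, "submissive")
        ]
        t = tally_traits(events, roster)
        assert t.loc["A"].tolist() == [3, 0, 1]
        assert t.loc["B"].tolist() == [0, 0, 0]

    def test_no_events_gives_zero_tallies(self):
        t = tally_traits([], make_roster(["A", "B"]))
        assert (t == 0).all().all()

    def test_unknown_bird_rejected(self):
        with pytest.raises(IntegrityError, match="unknown"):
            tally_traits([BehaviourEvent("Z", 0, "aggressive")], make_roster(["A"]))

    def test_matches_hash_count_oracle(self, rng):
        ids = [f"b{i}" for i in range(10)]
        roster = make_roster(ids)
        events = [
            BehaviourEvent(
                bird_id=str(rng.choice(ids)),
                day=int(rng.integers(0, 30)),
                trait=str(rng.choice(TRAITS)),
            )
            for _ in range(500)
        ]
        t = tally_traits(events, roster)
        expected = {}
        for e in events:
            expected[(e.bird_id, e.trait)] = expected.get((e.bird_id, e.trait), 0) + 1
        for b in ids:
            for trait in TRAITS:
                assert t.loc[b, trait] == expected.get((b, trait), 0)


class TestBrayCurtis:
    def test_identical_tallies_similarity_one(self):
        t = tallies_frame([[2, 3, 4], [2, 3, 4]])
        assert bray_curtis_similarity(t).iloc[0, 1] == pytest.approx(1.0)

    def test_disjoint_tallies_similarity_zero(self):
        t = tallies_frame([[5, 0, 0], [0, 3, 0]])
        assert bray_curtis_similarity(t).iloc[0, 1] == pytest.approx(0.0)

    def test_worked_value_two_thirds(self):
        t = tallies_frame([[2, 1, 0], [1, 1, 1]])
        assert bray_curtis_similarity(t).iloc[0, 1] == pytest.approx(2 / 3)

    def test_all_zero_pair_flagged_nan(self):
        t = tallies_frame([[0, 0, 0], [0, 0, 0]])
        assert np.isnan(bray_curtis_similarity(t).iloc[0, 1])

    @given(st.data())
    def test_symmetric_bounded_and_one_iff_identical(self, data):
        n = data.draw(st.integers(2, 5))
        rows = data.draw(
            st.lists(
                st.tuples(*(st.integers(0, 20) for _ in range(3))),
                min_size=n,
                max_size=n,
            ).filter(lambda r: all(sum(row) > 0 for row in r))
        )
        sim = bray_curtis_similarity(tallies_frame(rows)).to_numpy()
        assert np.allclose(sim, sim.T)
        assert ((sim >= -1e-12) & (sim <= 1 + 1e-12)).all()
        for i in range(n):
            for j in range(i + 1, n):
                if sim[i, j] == pytest.approx(1.0, abs=1e-12):
                    assert rows[i] == rows[j]


class TestPcaScore:
    def test_perfectly_correlated_traits(self):
        base = np.array([1.0, 4.0, 2.0, 8.0, 5.0])
        t = tallies_frame(np.column_stack([base, 2 * base, 3 * base]))
        res = pca_score(t)
        assert res.eigenvalue == pytest.approx(3.0, abs=1e-10)
        assert res.pct_variance == pytest.approx(100.0, abs=1e-8)

    def test_uncorrelated_traits_large_n(self):
        rng = np.random.default_rng(5)
        t = tallies_frame(rng.poisson(20, size=(4000, 3)))
        res = pca_score(t)
        assert res.eigenvalue == pytest.approx(1.0, abs=0.1)
        assert res.pct_variance == pytest.approx(100 / 3, abs=3)

    def test_matches_independent_eigendecomposition(self):
        rows = [
            [3, 1, 2],
            [8, 5, 7],
            [1, 0, 1],
            [6, 6, 4],
            [2, 2, 3],
            [9, 4, 8],
        ]
        t = tallies_frame(rows)
        res = pca_score(t)
        x = np.array(rows, dtype=float)
        z = (x - x.mean(0)) / x.std(0, ddof=1)
        corr = (z.T @ z) / (len(rows) - 1)
        w, v = np.linalg.eigh(corr)
        vec = v[:, np.argmax(w)]
        if vec.sum() < 0:
            vec = -vec
        assert res.eigenvalue == pytest.approx(w.max(), abs=1e-10)
        assert np.allclose(res.scores.to_numpy(), z @ vec, atol=1e-10)
        assert np.allclose(res.loadings.to_numpy(), vec, atol=1e-10)

    def test_matches_sklearn_cross_check(self):
        sklearn = pytest.importorskip("sklearn")
        from sklearn.decomposition import PCA

        rng = np.random.default_rng(17)
        shared = rng.normal(size=60)
        x = np.column_stack(
            [np.round(20 + 4 * shared + rng.normal(size=60)) for _ in range(3)]
        )
        t = tallies_frame(x)
        res = pca_score(t)
        z = (x - x.mean(0)) / x.std(0, ddof=1)
        p = PCA(n_components=1).fit(z)
        # eigenvalue convention: sklearn uses ddof=1 sample covariance of z
        assert res.eigenvalue == pytest.approx(p.explained_variance_[0], rel=1e-9)
        sk_scores = p.transform(z).ravel()
        if np.corrcoef(sk_scores, res.scores)[0, 1] < 0:
            sk_scores = -sk_scores
        assert np.allclose(res.scores, sk_scores, atol=1e-8)

    def test_loading_orientation_positive(self, small_dataset):
        from flocknet.personality import tally_traits as tt

        t = tt(small_dataset.behaviour_events, small_dataset.roster)
        res = pca_score(t)
        assert res.loadings.sum() > 0
        assert np.allclose(np.linalg.norm(res.loadings), 1.0)

    def test_zero_variance_trait_names_trait(self):
        t = tallies_frame([[1, 5, 0], [2, 6, 0], [3, 7, 0], [4, 8, 0]])
        with pytest.raises(ValueError, match="submissive"):
            pca_score(t)

    def test_too_few_birds_rejected(self):
        with pytest.raises(ValueError, match="4 birds"):
            pca_score(tallies_frame([[1, 2, 3], [4, 5, 6], [7, 8, 9]]))

    def test_scale_invariance_of_scores(self):
        rows = np.array([[3, 1, 2], [8, 5, 7], [1, 0, 1], [6, 6, 4], [2, 2, 3]])
        r1 = pca_score(tallies_frame(rows))
        scaled = rows.astype(float)
        scaled[:, 0] *= 7.0
        r2 = pca_score(tallies_frame(scaled))
        assert np.allclose(r1.scores, r2.scores, atol=1e-10)
        assert r1.eigenvalue == pytest.approx(r2.eigenvalue, abs=1e-12)


class TestCategorise:
    @pytest.mark.parametrize(
        "score,expected",
        [
            (-1.5, "A"),
            (-0.95, "A"),
            (-0.9, "B"),
            (0.0, "B"),
            (0.5, "C"),
            (1.0, "C"),
            (1.05, "D"),
            (2.0, "D"),
        ],
    )
    def test_gap_closed_bins(self, score, expected):
        s = pd.Series([score], index=["A1"])
        assert categorise(s).iloc[0] == expected

    def test_strict_mode_rejects_gap_scores(self):
        with pytest.raises(ValueError, match="gap"):
            categorise(pd.Series([0.05], index=["A1"]), strict=True)

    def test_strict_mode_accepts_printed_bounds(self):
        s = pd.Series([-1.0, -0.5, 0.5, 1.5], index=list("wxyz"))
        assert categorise(s, strict=True).tolist() == ["A", "B", "C", "D"]

    def test_ordinal_ranks(self):
        s = pd.Series([-2.0, -0.5, 0.5, 2.0], index=list("wxyz"))
        assert category_rank(categorise(s)).tolist() == [1, 2, 3, 4]

    def test_non_finite_scores_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            categorise(pd.Series([np.nan], index=["A1"]))
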