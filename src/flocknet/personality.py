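"""Behavioural trait tallies, similarity, and the single-score personality PCA.

Each bird accrues counts of aggressive, exploratory and submissive behaviours.
Pairwise behavioural similarity is Bray-Curtis on the raw three-trait count
vectors. Because the three tallies are positively correlated, they are
condensed into one personality score: the first principal component of the
standardised tallies (a direct eigendecomposition of the 3x3 trait correlation
matrix), oriented so that larger scores mean more frequent aggressive,
exploratory and submissive behaviour. Scores are then binned into ordinal
categories A-D for use as a dyadic similarity predictor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .types import BehaviourEvent, BirdRecord, IntegrityError, TRAITS, roster_index

logger = logging.getLogger(__name__)

__all__ = [
    "PersonalityResult",
    "tally_traits",
    "bray_curtis_similarity",
    "pca_score",
    "categorise",
    "category_rank",
]

#: Score bin edges: A < -0.9; B (-0.9, 0]; C (0, 1.0]; D > 1.0. The printed
#: field protocol gives rounded, slightly gapped bounds (B from -0.89, C from
#: 0.1, D from 1.1); the default reading closes the gaps into contiguous
#: half-open bins, while ``strict`` mode enforces the printed bounds verbatim
#: and rejects scores falling in the gaps.
_EDGES = (-0.9, 0.0, 1.0)


@dataclass
class PersonalityResult:
    """Single-component PCA extraction of the three trait tallies."""

    scores: pd.Series  # per bird: PC1 score
    categories: pd.Series  # per bird: A/B/C/D
    eigenvalue: float
    pct_variance: float
    loadings: pd.Series  # unit-norm eigenvector entries per trait
    component_correlations: pd.Series  # trait-PC1 correlations (loading * sqrt(eig))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "score": self.scores,
                "category": self.categories,
                "rank": category_rank(self.categories),
            }
        )


def tally_traits(
    events: list[BehaviourEvent], roster: list[BirdRecord]
) -> pd.DataFrame:
    """Per-bird counts of each trait-linked behaviour; unseen birds get zeros."""
    by_id = roster_index(roster)
    counts = pd.DataFrame(
        0, index=pd.Index([r.bird_id for r in roster], name="bird_id"), columns=TRAITS
    )
    for e in events:
        if e.bird_id not in by_id:
            raise IntegrityError(f"behaviour event for unknown bird {e.bird_id!r}")
        counts.loc[e.bird_id, e.trait] += 1
    return counts


def bray_curtis_similarity(tallies: pd.DataFrame) -> pd.DataFrame:
    """Bray-Curtis similarity 1 - sum|x_i - x_j| / sum(x_i + x_j) per pair.

    A pair in which both birds have all-zero tallies has no defined
    similarity; such entries are NaN and logged.
    """
    if len(tallies) < 2:
        raise ValueError("similarity needs at least 2 birds")
    x = tallies.to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = squareform(pdist(x, metric="braycurtis"))
    sim = 1.0 - dist
    np.fill_diagonal(sim, 1.0)
    n_undef = int(np.isnan(sim).sum()) // 2
    if n_undef:
        logger.warning("%d all-zero pairs have undefined similarity (NaN)", n_undef)
    return pd.DataFrame(sim, index=tallies.index, columns=tallies.index)


def pca_score(tallies: pd.DataFrame, strict_categories: bool = False) -> PersonalityResult:
    """First principal component of the standardised trait tallies.

    The three columns are z-scored and the leading eigenvector of their
    correlation matrix taken; the component is sign-oriented so the loading
    sum is positive, making high scores mean behaviourally busy birds. The
    eigenvalue and the percentage of total variance (eigenvalue / 3 * 100)
    are reported, with loadings given both as raw unit-norm eigenvector
    entries and as trait-component correlations.
    """
    if len(tallies) < 4:
        raise ValueError("PCA needs at least 4 birds")
    x = tallies.to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=1)
    for trait, s in zip(tallies.columns, sd):
        if s == 0:
            raise ValueError(f"trait {trait!r} has zero variance; PCA undefined")
    z = (x - x.mean(axis=0)) / sd
    corr = np.corrcoef(x, rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(corr)
    ev = float(eigvals[-1])
    vec = eigvecs[:, -1]
    if vec.sum() < 0:
        vec = -vec
    scores = pd.Series(z @ vec, index=tallies.index, name="score")
    cats = categorise(scores, strict=strict_categories)
    return PersonalityResult(
        scores=scores,
        categories=cats,
        eigenvalue=ev,
        pct_variance=ev / corr.shape[0] * 100.0,
        loadings=pd.Series(vec, index=tallies.columns, name="loading"),
        component_correlations=pd.Series(
            vec * np.sqrt(ev), index=tallies.columns, name="correlation"
        ),
    )


def categorise(scores: pd.Series, strict: bool = False) -> pd.Series:
    """Bin personality scores into ordinal categories A < B < C < D.

    Default bins are contiguous: A (-inf, -0.9), B [-0.9, 0], C (0, 1.0],
    D (1.0, inf). With ``strict=True`` the printed protocol bounds are used
    verbatim (B starts at -0.89, C at 0.1, D above 1.1) and a score falling
    in one of the uncovered gaps raises a ValueError.
    """
    s = np.asarray(scores, dtype=float)
    if not np.isfinite(s).all():
        raise ValueError("personality scores must be finite")
    if strict:
        gaps = (
            ((s >= -0.9) & (s < -0.89))
            | ((s > 0) & (s < 0.1))
            | ((s > 1.0) & (s <= 1.1))
        )
        if gaps.any():
            bad = scores.index[gaps].tolist()
            raise ValueError(
                f"scores for {bad} fall in a gap of the printed category bounds"
            )
        cond = [s < -0.9, s <= 0, s <= 1.0]
    else:
        cond = [s < _EDGES[0], s <= _EDGES[1], s <= _EDGES[2]]
    cats = np.select(cond, ["A", "B", "C"], default="D")
    return pd.Series(cats, index=scores.index, name="category")


def category_rank(categories: pd.Series) -> pd.Series:
    """Ordinal rank 1-4 of the A-D categories."""
    rank = categories.map({"A": 1, "B": 2, "C": 3, "D": 4})
    if rank.isna().any():
        raise ValueError("unknown personality category")
    return rank.astype(int).rename("rank")
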