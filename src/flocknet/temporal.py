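"""Temporal test of non-random association: lagged vs. null association rates.

The sampling unit is the day: a dyad "associates on day d" if it shares a
subgroup in at least one photographic sample that day. The lagged association
rate at lag tau is the probability that a dyad associating on day d is
associating again on day d + tau, given both members were identified on day
d + tau. The null rate is the same quantity after daily identities are
shuffled uniformly among each day's identified positions (preserving subgroup
sizes and the identified set), i.e. the rate expected were birds associating
at random. Observed and null rates are compared with a paired-sample t-test
across lags.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .types import DailyAssociationSet, SightingSession, make_pair

logger = logging.getLogger(__name__)

__all__ = [
    "LagRateSeries",
    "PairedComparison",
    "pool_days",
    "lagged_association_rate",
    "null_association_rate",
    "compare_lag_null",
    "lag_null_series",
    "plot_lag_rates",
]


@dataclass
class LagRateSeries:
    """Lag-indexed observed and null association rates.

    ``n_pairs`` is the support of each lag: the number of (dyad, day) pairs in
    the rate's denominator.
    """

    lags: np.ndarray
    lag_rate: np.ndarray
    null_rate: np.ndarray | None = None
    n_pairs: np.ndarray | None = None
    n_perm: int | None = None
    seed: int | None = None
    #: optional (n_perm, n_lags) per-replicate null rates for diagnostics
    null_replicates: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        data = {"lag": self.lags, "lag_rate": self.lag_rate}
        if self.null_rate is not None:
            data["null_rate"] = self.null_rate
        if self.n_pairs is not None:
            data["n_pairs"] = self.n_pairs
        return pd.DataFrame(data)


@dataclass
class PairedComparison:
    """Paired t-test of observed vs. null rates across lags."""

    t_statistic: float
    df: int
    p_value: float
    mean_lag: float
    sd_lag: float
    mean_null: float
    sd_null: float
    zero_variance: bool = False


def pool_days(sessions: list[SightingSession]) -> list[DailyAssociationSet]:
    """Pool exclusion-filtered sessions into per-day association sets."""
    by_day: dict[int, list[SightingSession]] = {}
    for s in sessions:
        by_day.setdefault(s.day, []).append(s)
    out = []
    for day in sorted(by_day):
        identified: set[str] = set()
        pairs: set[frozenset[str]] = set()
        for s in by_day[day]:
            identified |= s.identified_ids
            for g in s.subgroups:
                members = sorted(g.member_ids)
                for i in range(len(members)):
                    for j in range(i + 1, len(members)):
                        pairs.add(make_pair(members[i], members[j]))
        out.append(
            DailyAssociationSet(
                day=day,
                identified_ids=frozenset(identified),
                associated_pairs=frozenset(pairs),
            )
        )
    return out


def _day_arrays(days: list[DailyAssociationSet]):
    """Dense boolean per-day adjacency and identified-indicator arrays."""
    ids = sorted(set().union(*(d.identified_ids for d in days)) if days else set())
    idx = {b: i for i, b in enumerate(ids)}
    n = len(ids)
    adj = np.zeros((len(days), n, n), dtype=bool)
    ident = np.zeros((len(days), n), dtype=bool)
    day_index = np.array([d.day for d in days])
    for k, d in enumerate(days):
        for b in d.identified_ids:
            ident[k, idx[b]] = True
        for pair in d.associated_pairs:
            a, b = tuple(pair)
            adj[k, idx[a], idx[b]] = True
            adj[k, idx[b], idx[a]] = True
    return day_index, adj, ident


def _rate_dicts(day_index, adj, ident):
    """Per-lag numerator/denominator dicts from dense day arrays."""
    num: dict[int, int] = {}
    den: dict[int, int] = {}
    k = len(day_index)
    for i in range(k):
        for j in range(i + 1, k):
            tau = int(day_index[j] - day_index[i])
            both_ident = ident[j][:, None] & ident[j][None, :]
            d = int((adj[i] & both_ident).sum()) // 2
            if d == 0:
                continue
            n = int((adj[i] & adj[j]).sum()) // 2
            num[tau] = num.get(tau, 0) + n
            den[tau] = den.get(tau, 0) + d
    return num, den


def _rates_from_arrays(day_index, adj, ident):
    """Lags, rates and supports per lag; zero-support lags omitted."""
    num, den = _rate_dicts(day_index, adj, ident)
    lags = np.array(sorted(den), dtype=int)
    n_pairs = np.array([den[t] for t in lags], dtype=int)
    rate = np.array([num.get(t, 0) / den[t] for t in lags], dtype=float)
    return lags, rate, n_pairs


def lagged_association_rate(days: list[DailyAssociationSet]) -> LagRateSeries:
    """Observed lagged association rate per lag; zero-support lags are omitted."""
    if len(days) < 2:
        raise ValueError("lagged association rates need at least 2 days")
    day_index, adj, ident = _day_arrays(days)
    lags, rate, n_pairs = _rates_from_arrays(day_index, adj, ident)
    return LagRateSeries(lags=lags, lag_rate=rate, n_pairs=n_pairs)


def null_association_rate(
    days: list[DailyAssociationSet],
    n_perm: int = 100,
    seed: int | None = None,
    keep_replicates: bool = False,
) -> LagRateSeries:
    """Monte-Carlo null: shuffle identities within each day's identified set.

    Each replicate draws an independent uniform permutation of identities per
    day over that day's identified positions, preserving subgroup sizes and
    the identified set exactly, then recomputes the lagged rate; the null rate
    at each lag is the mean over replicates. Denominators are unaffected by
    the shuffles, so lags are the observed ones.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    day_index, adj, ident = _day_arrays(days)
    rng = np.random.default_rng(seed)
    lags, obs_rate, n_pairs = _rates_from_arrays(day_index, adj, ident)
    n = adj.shape[1]
    # shuffling can move association off birds identified at the later day, so
    # a lag may lose support in some replicates; the null at each lag is the
    # mean ratio over the replicates in which it retains support
    reps = np.full((n_perm, len(lags)), np.nan)
    for r in range(n_perm):
        padj = np.empty_like(adj)
        for k in range(len(days)):
            perm = np.arange(n)
            members = np.flatnonzero(ident[k])
            perm[members] = rng.permutation(members)
            padj[k] = adj[k][np.ix_(perm, perm)]
        pnum, pden = _rate_dicts(day_index, padj, ident)
        for c, tau in enumerate(lags):
            t = int(tau)
            if pden.get(t, 0) > 0:
                reps[r, c] = pnum.get(t, 0) / pden[t]
    with np.errstate(invalid="ignore"):
        null_rate = np.nanmean(reps, axis=0)
    return LagRateSeries(
        lags=lags,
        lag_rate=obs_rate,
        null_rate=null_rate,
        n_pairs=n_pairs,
        n_perm=n_perm,
        seed=seed,
        null_replicates=reps if keep_replicates else None,
    )


def compare_lag_null(
    series: LagRateSeries, min_support: int = 10
) -> PairedComparison:
    """Paired-sample t-test of lag vs. null rate, paired by lag.

    Lags supported by fewer than ``min_support`` dyad-days are dropped (and
    logged) to avoid noise from nearly empty denominators.
    """
    if series.null_rate is None:
        raise ValueError("series has no null rates; run null_association_rate first")
    keep = (
        series.n_pairs >= min_support
        if series.n_pairs is not None
        else np.ones(len(series.lags), dtype=bool)
    )
    dropped = int((~keep).sum())
    if dropped:
        logger.info("%d low-support lags dropped from the paired test", dropped)
    lag = np.asarray(series.lag_rate)[keep]
    null = np.asarray(series.null_rate)[keep]
    if len(lag) < 2:
        raise ValueError("paired comparison needs at least 2 supported lags")
    diff = lag - null
    df = len(diff) - 1
    if np.allclose(diff, 0.0):
        # observed and null agree at every lag: no evidence either way
        return PairedComparison(
            t_statistic=0.0,
            df=df,
            p_value=1.0,
            mean_lag=float(lag.mean()),
            sd_lag=float(lag.std(ddof=1)),
            mean_null=float(null.mean()),
            sd_null=float(null.std(ddof=1)),
        )
    if np.allclose(diff.std(ddof=1), 0.0):
        logger.warning("zero variance of lag-null differences; p undefined")
        return PairedComparison(
            t_statistic=float("nan"),
            df=df,
            p_value=float("nan"),
            mean_lag=float(lag.mean()),
            sd_lag=float(lag.std(ddof=1)),
            mean_null=float(null.mean()),
            sd_null=float(null.std(ddof=1)),
            zero_variance=True,
        )
    t, p = stats.ttest_rel(lag, null)
    return PairedComparison(
        t_statistic=float(t),
        df=df,
        p_value=float(p),
        mean_lag=float(lag.mean()),
        sd_lag=float(lag.std(ddof=1)),
        mean_null=float(null.mean()),
        sd_null=float(null.std(ddof=1)),
    )


def lag_null_series(
    sessions: list[SightingSession], n_perm: int = 100, seed: int | None = None
) -> LagRateSeries:
    """Convenience: pool days and compute observed + null rates in one call."""
    return null_association_rate(pool_days(sessions), n_perm=n_perm, seed=seed)


def plot_lag_rates(series: LagRateSeries, path) -> None:
    """Plot observed vs. null association rates against lag."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(series.lags, series.lag_rate, "o-", color="tab:blue", label="lag rate")
    if series.null_rate is not None:
        ax.plot(
            series.lags, series.null_rate, "s--", color="tab:green", label="null rate"
        )
    ax.set_xlabel("lag (days)")
    ax.set_ylabel("association rate")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
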