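"""Independent brute-force oracles for cross-checking the pipeline.

Everything here is deliberately naive — exhaustive recounts, transitive
closures, path enumerations and closed forms — and shares no code with the
package implementation it checks.
"""

from __future__ import annotations

import itertools
from collections import defaultdict

import numpy as np


# ---------------------------------------------------------------------------
# grouping / association


def components_by_transitive_closure(nodes, edges):
    """Connected components via repeated relation closure (no graph library)."""
    nodes = list(nodes)
    reach = {a: {a} for a in nodes}
    for a, b in edges:
        reach[a].add(b)
        reach[b].add(a)
    changed = True
    while changed:
        changed = False
        for a in nodes:
            new = set()
            for b in reach[a]:
                new |= reach[b]
            if not new <= reach[a]:
                reach[a] |= new
                changed = True
    comps = set()
    for a in nodes:
        comps.add(frozenset(reach[a]))
    return comps


def recount_pair_counts(sessions, roster):
    """Per-session dyadic recount: (x, y_ab, y_a, y_b) dicts keyed by (i, j).

    ``sessions`` are (day, subgroup-member-set list) tuples of identified
    birds only (already exclusion-filtered); ``roster`` maps bird -> first day.
    Pairs are ordered tuples (i, j) with i < j; y_a counts samples with only i
    present.
    """
    ids = sorted(roster)
    x = defaultdict(int)
    y_ab = defaultdict(int)
    y_a = defaultdict(int)
    y_b = defaultdict(int)
    for day, groups in sessions:
        where = {}
        for gi, g in enumerate(groups):
            for b in g:
                where[b] = gi
        for i, j in itertools.combinations(ids, 2):
            if day < roster[i] or day < roster[j]:
                continue
            pi, pj = i in where, j in where
            if pi and pj:
                if where[i] == where[j]:
                    x[(i, j)] += 1
                else:
                    y_ab[(i, j)] += 1
            elif pi:
                y_a[(i, j)] += 1
            elif pj:
                y_b[(i, j)] += 1
    return x, y_ab, y_a, y_b


def hwi_from_counts(x, y_ab, y_a, y_b):
    den = x + y_ab + (y_a + y_b) / 2
    return 0.0 if den == 0 else x / den


# ---------------------------------------------------------------------------
# graph metrics (exhaustive, for <= ~8 nodes)


def _all_shortest_paths(adj, s, t):
    """All shortest s-t paths by breadth-limited exhaustive path enumeration."""
    n = len(adj)
    best = None
    paths = []
    stack = [(s, [s])]
    while stack:
        node, path = stack.pop()
        if best is not None and len(path) - 1 > best:
            continue
        if node == t:
            d = len(path) - 1
            if best is None or d < best:
                best = d
                paths = [path]
            elif d == best:
                paths.append(path)
            continue
        for nxt in range(n):
            if adj[node][nxt] and nxt not in path:
                stack.append((nxt, path + [nxt]))
    return best, paths


def betweenness_exhaustive(adj):
    """Raw betweenness with fractional credit among tied geodesics."""
    n = len(adj)
    bet = [0.0] * n
    for s, t in itertools.combinations(range(n), 2):
        d, paths = _all_shortest_paths(adj, s, t)
        if not paths:
            continue
        for p in paths:
            for v in p[1:-1]:
                bet[v] += 1.0 / len(paths)
    return bet


def clustering_exhaustive(adj):
    """Mean local clustering over nodes of degree >= 2 (triangle count by hand)."""
    n = len(adj)
    vals = []
    for v in range(n):
        nbrs = [u for u in range(n) if adj[v][u]]
        k = len(nbrs)
        if k < 2:
            continue
        tri = sum(
            1 for a, b in itertools.combinations(nbrs, 2) if adj[a][b]
        )
        vals.append(2.0 * tri / (k * (k - 1)))
    return float(np.mean(vals)) if vals else float("nan")


def path_length_exhaustive(adj):
    """Mean geodesic over connected unordered pairs, via Floyd-Warshall."""
    n = len(adj)
    inf = float("inf")
    d = [[0 if i == j else (1 if adj[i][j] else inf) for j in range(n)] for i in range(n)]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i][k] + d[k][j] < d[i][j]:
                    d[i][j] = d[i][k] + d[k][j]
    vals = [d[i][j] for i, j in itertools.combinations(range(n), 2) if d[i][j] < inf]
    return float(np.mean(vals)) if vals else float("nan")


# ---------------------------------------------------------------------------
# temporal rates


def lar_double_loop(day_sets):
    """Lagged association rate by brute-force double loop over day pairs.

    ``day_sets``: list of (day, identified set, associated pair-set) tuples.
    Returns {tau: (numerator, denominator)}.
    """
    out = {}
    for (d1, id1, as1), (d2, id2, as2) in itertools.combinations(day_sets, 2):
        tau = d2 - d1
        num = den = 0
        for pair in as1:
            a, b = tuple(pair)
            if a in id2 and b in id2:
                den += 1
                if pair in as2:
                    num += 1
        if den:
            n0, d0 = out.get(tau, (0, 0))
            out[tau] = (n0 + num, d0 + den)
    return out


def null_rate_enumerated(day_sets):
    """Exact expected null rate by enumerating joint per-day identity shuffles.

    Every combination of one permutation per day (each over that day's
    identified set) is enumerated; for each combination the full lagged rate
    is recomputed naively and the result averaged. Feasible only for a few
    days of a few birds.
    """
    per_day_perms = []
    for day, ids, pairs in day_sets:
        ids = sorted(ids)
        relabels = [dict(zip(ids, p)) for p in itertools.permutations(ids)]
        per_day_perms.append(relabels)
    acc = defaultdict(float)
    support = defaultdict(int)
    combos = list(itertools.product(*per_day_perms))
    for combo in combos:
        shuffled = []
        for (day, ids, pairs), relabel in zip(day_sets, combo):
            new_pairs = {
                frozenset((relabel[a], relabel[b])) for a, b in (tuple(p) for p in pairs)
            }
            shuffled.append((day, ids, new_pairs))
        rates = lar_double_loop(shuffled)
        for tau, (num, den) in rates.items():
            acc[tau] += num / den
            support[tau] += 1
    return {t: acc[t] / support[t] for t in acc}


def paired_t_closed_form(diffs):
    """t = mean / (sd / sqrt(n)) with sample sd."""
    diffs = np.asarray(diffs, dtype=float)
    n = len(diffs)
    sd = diffs.std(ddof=1)
    return diffs.mean() / (sd / np.sqrt(n))


# ---------------------------------------------------------------------------
# regression / permutation


def ols_normal_equations(x, y):
    """OLS coefficients (intercept first) by explicitly solving X'X b = X'y."""
    x = np.column_stack([np.ones(len(y)), np.atleast_2d(np.asarray(x, float).T).T])
    return np.linalg.solve(x.T @ x, x.T @ np.asarray(y, float))


def node_regression_enumerated_p_upper(y, x):
    """Exact upper-tail p of the slope under all n! response permutations."""
    y = np.asarray(y, float)
    x = np.asarray(x, float)
    xc = x - x.mean()

    def slope(v):
        return float(xc @ (v - v.mean()) / (xc @ xc))

    obs = slope(y)
    count = 0
    perms = list(itertools.permutations(range(len(y))))
    for p in perms:
        if slope(y[list(p)]) >= obs - 1e-12:
            count += 1
    return count / len(perms)


def mrqap_enumerated_p(y_mat, pred_mats, k):
    """Exact two-sided DSP tail for predictor k over all node permutations.

    Residualisation is done with explicit normal equations; the statistic is
    the correlation of the permuted residual matrix's dyads with the
    residualised response.
    """
    n = y_mat.shape[0]
    dyads = [(i, j) for i in range(n) for j in range(i + 1, n)]
    y = np.array([y_mat[i, j] for i, j in dyads])
    cols = [np.array([m[i, j] for i, j in dyads]) for m in pred_mats]
    others = np.column_stack([np.ones(len(y))] + [c for idx, c in enumerate(cols) if idx != k])

    def resid(v):
        b = np.linalg.solve(others.T @ others, others.T @ v)
        return v - others @ b

    def corr(a, b):
        na, nb = np.linalg.norm(a), np.linalg.norm(b)
        return 0.0 if na == 0 or nb == 0 else float(a @ b / (na * nb))

    e_y = resid(y)
    e_k = resid(cols[k])
    obs = corr(e_y, e_k)
    emat = np.zeros((n, n))
    for (i, j), v in zip(dyads, e_k):
        emat[i, j] = emat[j, i] = v
    count = 0
    perms = list(itertools.permutations(range(n)))
    for p in perms:
        pm = emat[np.ix_(p, p)]
        v = np.array([pm[i, j] for i, j in dyads])
        if abs(corr(e_y, resid(v))) >= abs(obs) - 1e-12:
            count += 1
    return count / len(perms)
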