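"""Permutation inference for dyadic and node-level regressions.

Two engines, both designed for the non-independence of social-network data:

* :func:`mrqap_dsp` — multiple regression quadratic assignment procedure with
  Dekker's double semi-partialing (DSP). The association matrix is regressed
  on dyadic predictor matrices; each predictor's significance comes from
  permuting the rows and columns of its *residual* matrix (the predictor with
  the other predictors partialled out) by a common node permutation and
  recomputing its partial correlation with the residualised response.

* :func:`node_permutation_regression` — OLS of an individual-level response
  (degree, fight totals, ...) on node attributes, with p-values from a
  sampling distribution built by shuffling the response labels across nodes.

Coefficient estimates are exactly the OLS estimates; permutation affects
inference only. All p-values use the add-one rule p = (1 + #extreme) /
(1 + n_perm), so a p of exactly 0 is impossible; exact enumeration over all
node permutations is available for small problems.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .personality import PersonalityResult, category_rank
from .types import AssociationMatrix, BirdRecord, IntegrityError, roster_index

logger = logging.getLogger(__name__)

__all__ = [
    "DyadicPredictor",
    "MrqapResult",
    "NodeRegressionResult",
    "build_dyadic_predictors",
    "mrqap_dsp",
    "mrqap_stability",
    "node_permutation_regression",
]

#: Tie tolerance when comparing permuted to observed statistics.
_TIE_TOL = 1e-12

#: Condition number above which the dyadic design is declared collinear.
_COND_LIMIT = 1e8


@dataclass
class DyadicPredictor:
    """A named dyadic predictor matrix (dissimilarity or mismatch coding).

    Larger entries always mean *less* similar, so homophily on the attribute
    shows up as a negative partial correlation with the association matrix.
    """

    name: str
    kind: str  # "absolute_difference" | "mismatch"
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise IntegrityError(f"predictor {self.name!r}: matrix not square")
        if not np.allclose(m, m.T):
            raise IntegrityError(f"predictor {self.name!r}: matrix not symmetric")
        if np.diagonal(m).any():
            raise IntegrityError(f"predictor {self.name!r}: nonzero diagonal")
        if self.kind == "mismatch" and not np.isin(m, (0.0, 1.0)).all():
            raise IntegrityError(f"predictor {self.name!r}: mismatch entries not 0/1")
        self.matrix = m


@dataclass
class MrqapResult:
    table: pd.DataFrame  # per predictor: coefficient, std_coefficient,
    # partial_correlation, p_value
    r_squared: float
    n_dyads: int
    n_permutations: int
    seed: int | None
    method: str = "dsp"


@dataclass
class NodeRegressionResult:
    table: pd.DataFrame  # per predictor: b, p_upper, p_lower, p_two_sided
    r_squared: float
    f_statistic: float
    model_p: float
    df_model: int
    df_resid: int
    n_permutations: int
    seed: int | None
    constant_response: bool = False


def build_dyadic_predictors(
    roster: Sequence[BirdRecord],
    personality: PersonalityResult,
    ids: Sequence[str] | None = None,
    personality_coding: str = "category",
) -> list[DyadicPredictor]:
    """Build the standard dyadic predictor set for the association MRQAP.

    * personality — absolute difference of ordinal category ranks (A=1..D=4);
      ``personality_coding="score"`` uses |raw score difference| instead.
    * age — absolute age difference in years.
    * sex, origin — mismatch (0 same level, 1 different; unknown sex is its
      own level, so unknown-vs-male counts as a mismatch).
    """
    by_id = roster_index(roster)
    if ids is None:
        ids = [r.bird_id for r in roster]
    missing = [b for b in ids if b not in by_id]
    if missing:
        raise IntegrityError(f"ids missing from roster: {missing}")
    for b in ids:
        if b not in personality.scores.index:
            raise IntegrityError(f"bird {b!r} has no personality score")

    if personality_coding == "category":
        pers = category_rank(personality.categories).loc[list(ids)].to_numpy(float)
    elif personality_coding == "score":
        pers = personality.scores.loc[list(ids)].to_numpy(float)
    else:
        raise ValueError(f"unknown personality_coding {personality_coding!r}")
    age = np.array([by_id[b].age for b in ids], dtype=float)
    sex = np.array([by_id[b].sex for b in ids])
    origin = np.array([by_id[b].origin for b in ids])

    def absdiff(v):
        m = np.abs(v[:, None] - v[None, :])
        np.fill_diagonal(m, 0.0)
        return m

    def mismatch(v):
        m = (v[:, None] != v[None, :]).astype(float)
        np.fill_diagonal(m, 0.0)
        return m

    return [
        DyadicPredictor("personality", "absolute_difference", absdiff(pers)),
        DyadicPredictor("age", "absolute_difference", absdiff(age)),
        DyadicPredictor("sex", "mismatch", mismatch(sex)),
        DyadicPredictor("origin", "mismatch", mismatch(origin)),
    ]


def _check_collinearity(xmat: np.ndarray, names: list[str]) -> None:
    cond = np.linalg.cond(np.column_stack([np.ones(len(xmat)), xmat]))
    if cond > _COND_LIMIT:
        corr = np.corrcoef(xmat, rowvar=False)
        offenders = [
            f"{names[i]}~{names[j]}"
            for i in range(len(names))
            for j in range(i + 1, len(names))
            if abs(corr[i, j]) > 0.99
        ]
        raise ValueError(
            "collinear dyadic predictors (condition number "
            f"{cond:.3g}): {offenders or names}"
        )


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


def mrqap_dsp(
    response: AssociationMatrix,
    predictors: Sequence[DyadicPredictor],
    n_perm: int = 1000,
    seed: int | None = None,
    method: str = "dsp",
    exact: bool = False,
) -> MrqapResult:
    """MRQAP of the association matrix on dyadic predictors.

    Coefficients and R^2 come from OLS over the n(n-1)/2 unique dyads.
    With ``method="dsp"`` each predictor's p-value is from double
    semi-partialing node permutations of its residual matrix; with
    ``method="y"`` the response matrix itself is permuted (simple QAP,
    retained as a cross-check). ``exact=True`` enumerates all n! node
    permutations (small n only) and reports the exact tail probability
    #{|stat_perm| >= |stat_obs|} / n!.
    """
    n = response.n
    if not exact and n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    if method not in ("dsp", "y"):
        raise ValueError(f"unknown method {method!r}")
    for p in predictors:
        if p.matrix.shape != (n, n):
            raise IntegrityError(
                f"predictor {p.name!r} shape {p.matrix.shape} does not match "
                f"response ({n}, {n})"
            )
    iu = np.triu_indices(n, k=1)
    y = response.values[iu]
    names = [p.name for p in predictors]
    xmat = np.column_stack([p.matrix[iu] for p in predictors])
    _check_collinearity(xmat, names)

    design = np.column_stack([np.ones(len(y)), xmat])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    fitted = design @ beta
    sst = float(((y - y.mean()) ** 2).sum())
    sse = float(((y - fitted) ** 2).sum())
    r_squared = 1.0 - sse / sst if sst > 0 else float("nan")
    xsd = xmat.std(axis=0, ddof=1)
    ysd = y.std(ddof=1)
    std_coef = beta[1:] * np.where(xsd > 0, xsd, np.nan) / (ysd if ysd > 0 else np.nan)

    if exact:
        perms = [np.array(p) for p in itertools.permutations(range(n))]
        if n > 8:
            raise ValueError("exact enumeration is limited to n <= 8 nodes")
    else:
        rng = np.random.default_rng(seed)
        perms = [rng.permutation(n) for _ in range(n_perm)]

    partials = np.empty(len(predictors))
    pvals = np.empty(len(predictors))
    for k in range(len(predictors)):
        others = np.column_stack(
            [np.ones(len(y))] + [xmat[:, j] for j in range(xmat.shape[1]) if j != k]
        )
        q, _ = np.linalg.qr(others)
        e_y = y - q @ (q.T @ y)
        e_k = xmat[:, k] - q @ (q.T @ xmat[:, k])
        obs = _corr(e_y, e_k)
        partials[k] = obs

        if method == "dsp":
            resid_mat = np.zeros((n, n))
            resid_mat[iu] = e_k
            resid_mat += resid_mat.T
            count = 0
            for perm in perms:
                v = resid_mat[np.ix_(perm, perm)][iu]
                v_r = v - q @ (q.T @ v)
                if abs(_corr(e_y, v_r)) >= abs(obs) - _TIE_TOL:
                    count += 1
        else:
            count = 0
            for perm in perms:
                yp = response.values[np.ix_(perm, perm)][iu]
                e_yp = yp - q @ (q.T @ yp)
                if abs(_corr(e_yp, e_k)) >= abs(obs) - _TIE_TOL:
                    count += 1
        if exact:
            pvals[k] = count / len(perms)
        else:
            pvals[k] = (1 + count) / (1 + len(perms))

    table = pd.DataFrame(
        {
            "coefficient": beta[1:],
            "std_coefficient": std_coef,
            "partial_correlation": partials,
            "p_value": pvals,
        },
        index=pd.Index(names, name="predictor"),
    )
    return MrqapResult(
        table=table,
        r_squared=r_squared,
        n_dyads=len(y),
        n_permutations=len(perms),
        seed=seed,
        method=method,
    )


def mrqap_stability(
    response: AssociationMatrix,
    predictors: Sequence[DyadicPredictor],
    n_perms: Sequence[int] = (1000, 5000, 10000),
    seed: int | None = None,
) -> pd.DataFrame:
    """Re-run the MRQAP at increasing permutation counts to check p stability."""
    frames = []
    for i, np_ in enumerate(n_perms):
        res = mrqap_dsp(
            response, predictors, n_perm=np_, seed=None if seed is None else seed + i
        )
        t = res.table[["partial_correlation", "p_value"]].copy()
        t["n_permutations"] = np_
        frames.append(t.reset_index())
    return pd.concat(frames, ignore_index=True)


def node_permutation_regression(
    y: pd.Series | np.ndarray,
    x: pd.DataFrame | np.ndarray,
    n_perm: int = 1000,
    seed: int | None = None,
    exact: bool = False,
) -> NodeRegressionResult:
    """OLS of a node-level response with node-label permutation inference.

    The response is shuffled across nodes ``n_perm`` times; per-predictor
    one-tailed p-values count permuted coefficients at least as large
    (``p_upper``) or as small (``p_lower``) as observed, a two-tailed p uses
    |b|, and the model p comes from the permutation distribution of F. Ties
    are included in both tails, so p_upper + p_lower >= 1. ``exact=True``
    enumerates all n! label permutations (small n only).
    """
    if isinstance(x, pd.DataFrame):
        names = list(x.columns)
        xmat = x.to_numpy(dtype=float)
        if isinstance(y, pd.Series) and not y.index.equals(x.index):
            y = y.loc[x.index]
    else:
        xmat = np.atleast_2d(np.asarray(x, dtype=float))
        if xmat.shape[0] != len(np.asarray(y)):
            xmat = xmat.T
        names = [f"x{i}" for i in range(xmat.shape[1])]
    yv = np.asarray(y, dtype=float)
    n, p = xmat.shape
    if n < p + 2:
        raise ValueError(f"need at least p + 2 = {p + 2} birds, got {n}")
    if np.isnan(yv).any() or np.isnan(xmat).any():
        raise ValueError("missing values in regression inputs")
    if not exact and n_perm < 99:
        raise ValueError("n_perm must be >= 99")

    df_model, df_resid = p, n - p - 1
    if np.allclose(yv, yv[0]):
        logger.warning("constant response: coefficients 0, p undefined")
        table = pd.DataFrame(
            {
                "b": np.zeros(p),
                "p_upper": np.nan,
                "p_lower": np.nan,
                "p_two_sided": np.nan,
            },
            index=pd.Index(names, name="predictor"),
        )
        return NodeRegressionResult(
            table=table,
            r_squared=float("nan"),
            f_statistic=float("nan"),
            model_p=float("nan"),
            df_model=df_model,
            df_resid=df_resid,
            n_permutations=0,
            seed=seed,
            constant_response=True,
        )

    design = np.column_stack([np.ones(n), xmat])
    pinv = np.linalg.pinv(design)  # (p+1, n)
    sst = float(((yv - yv.mean()) ** 2).sum())

    def fit(resp: np.ndarray):
        """Vectorised OLS for a stack of responses (rows)."""
        b = resp @ pinv.T  # (m, p+1)
        fitted = b @ design.T
        sse = ((resp - fitted) ** 2).sum(axis=1)
        r2 = 1.0 - sse / sst
        with np.errstate(invalid="ignore", divide="ignore"):
            f = (r2 / df_model) / ((1.0 - r2) / df_resid)
        return b, r2, f

    b_obs, r2_obs, f_obs = (v[0] for v in fit(yv[None, :]))

    if exact:
        if n > 8:
            raise ValueError("exact enumeration is limited to n <= 8 nodes")
        perm_stack = np.array(
            [yv[list(pi)] for pi in itertools.permutations(range(n))]
        )
    else:
        rng = np.random.default_rng(seed)
        perm_stack = np.array([yv[rng.permutation(n)] for _ in range(n_perm)])
    b_perm, _, f_perm = fit(perm_stack)
    coefs = b_perm[:, 1:]
    obs = b_obs[1:]

    upper = (coefs >= obs[None, :] - _TIE_TOL).sum(axis=0)
    lower = (coefs <= obs[None, :] + _TIE_TOL).sum(axis=0)
    two = (np.abs(coefs) >= np.abs(obs)[None, :] - _TIE_TOL).sum(axis=0)
    f_count = (f_perm >= f_obs - _TIE_TOL).sum()
    m = len(perm_stack)
    if exact:
        p_upper, p_lower, p_two = upper / m, lower / m, two / m
        model_p = f_count / m
    else:
        p_upper = (1 + upper) / (1 + m)
        p_lower = (1 + lower) / (1 + m)
        p_two = (1 + two) / (1 + m)
        model_p = (1 + f_count) / (1 + m)

    table = pd.DataFrame(
        {"b": obs, "p_upper": p_upper, "p_lower": p_lower, "p_two_sided": p_two},
        index=pd.Index(names, name="predictor"),
    )
    return NodeRegressionResult(
        table=table,
        r_squared=float(r2_obs),
        f_statistic=float(f_obs),
        model_p=float(model_p),
        df_model=df_model,
        df_resid=df_resid,
        n_permutations=m,
        seed=seed,
    )
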