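"""Single-config orchestration of the full analysis for one flock.

Stage order: ingest -> association matrix -> network metrics -> temporal
lag/null test -> personality PCA -> MRQAP -> node-permutation regressions ->
agonistic summary -> report files. Each stage is also independently
invokable through the CLI; the orchestrated run writes the same intermediate
files the single-stage commands produce, plus a manifest recording seeds and
parameters so a rerun with the same config reproduces every number.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as fio
from .agonistic import agonistic_summary
from .association import build_association_matrix
from .matrix_stats import (
    build_dyadic_predictors,
    mrqap_dsp,
    node_permutation_regression,
)
from .metrics import flock_metrics, node_metrics
from .personality import bray_curtis_similarity, pca_score, tally_traits
from .temporal import compare_lag_null, lag_null_series

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]

#: Node-level responses modelled against personality score and age.
NODE_RESPONSES = (
    "degree",
    "betweenness",
    "avg_association_strength",
    "total_fights",
    "fights_won",
    "fights_lost",
    "support_given",
)


@dataclass
class PipelineConfig:
    sightings: str
    roster: str
    behaviour: str
    fights: str
    supports: str
    outdir: str
    edge_threshold: float = 0.0
    n_perm_mrqap: int = 1000
    n_perm_node: int = 1000
    n_perm_null: int = 100
    min_lag_support: int = 10
    category_mode: str = "gap-closed"  # or "strict"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_perm_mrqap", "n_perm_node", "n_perm_null"):
            if getattr(self, name) < 99 and name != "n_perm_null":
                raise ValueError(f"{name} must be >= 99")
        if self.n_perm_null < 1:
            raise ValueError("n_perm_null must be >= 1")
        if self.category_mode not in ("gap-closed", "strict"):
            raise ValueError(f"unknown category_mode {self.category_mode!r}")
        for name in ("sightings", "roster", "behaviour", "fights", "supports"):
            p = Path(getattr(self, name))
            if not p.exists():
                raise FileNotFoundError(f"{name} file not found: {p}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def _fmt(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, float_format="%.10g")


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage for one flock and write the report bundle.

    Returns a dict of the in-memory results keyed by stage name.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}

    def stage(name):
        logger.info("stage: %s", name)

    try:
        stage("ingest")
        roster = fio.read_roster(cfg.roster)
        sessions = fio.read_sightings(cfg.sightings)
        behaviour = fio.read_behaviour_events(cfg.behaviour)
        fights = fio.read_agonistic_events(cfg.fights, cfg.supports)
    except Exception as exc:
        raise RuntimeError(f"stage 'ingest' failed: {exc}") from exc

    try:
        stage("associations")
        hwi = build_association_matrix(sessions, roster)
        fio.write_association_matrix(hwi, out / "association_matrix.csv")
        results["association_matrix"] = hwi
    except Exception as exc:
        raise RuntimeError(f"stage 'associations' failed: {exc}") from exc

    try:
        stage("metrics")
        nm = node_metrics(hwi, cfg.edge_threshold)
        fm = flock_metrics(hwi, cfg.edge_threshold)
        _fmt(nm, out / "node_metrics.csv")
        pd.DataFrame([asdict(fm)]).to_csv(out / "flock_metrics.csv", index=False)
        results["node_metrics"], results["flock_metrics"] = nm, fm
    except Exception as exc:
        raise RuntimeError(f"stage 'metrics' failed: {exc}") from exc

    try:
        stage("temporal")
        series = lag_null_series(
            [s for s in sessions], n_perm=cfg.n_perm_null, seed=cfg.seed
        )
        lag_test = compare_lag_null(series, min_support=cfg.min_lag_support)
        _fmt(series.to_frame().set_index("lag"), out / "lag_rates.csv")
        pd.DataFrame([asdict(lag_test)]).to_csv(out / "lag_test.csv", index=False)
        results["lag_series"], results["lag_test"] = series, lag_test
    except Exception as exc:
        raise RuntimeError(f"stage 'temporal' failed: {exc}") from exc

    try:
        stage("personality")
        tallies = tally_traits(behaviour, roster)
        pca = pca_score(tallies, strict_categories=cfg.category_mode == "strict")
        sim = bray_curtis_similarity(tallies)
        _fmt(tallies, out / "trait_tallies.csv")
        _fmt(pca.to_frame(), out / "personality_scores.csv")
        _fmt(sim, out / "similarity_matrix.csv")
        extraction = pd.DataFrame(
            {
                "eigenvalue": [pca.eigenvalue],
                "pct_variance": [pca.pct_variance],
                **{f"loading_{t}": [v] for t, v in pca.loadings.items()},
                **{
                    f"correlation_{t}": [v]
                    for t, v in pca.component_correlations.items()
                },
            }
        )
        extraction.to_csv(out / "personality_pca.csv", index=False)
        results["personality"] = pca
    except Exception as exc:
        raise RuntimeError(f"stage 'personality' failed: {exc}") from exc

    try:
        stage("graph-export")
        fio.export_graph(
            hwi,
            roster,
            out / "network.graphml",
            personality=pca.scores.to_dict(),
            categories=pca.categories.to_dict(),
        )
    except Exception as exc:
        raise RuntimeError(f"stage 'graph-export' failed: {exc}") from exc

    try:
        stage("mrqap")
        predictors = build_dyadic_predictors(roster, pca, ids=hwi.ids)
        mrqap = mrqap_dsp(
            hwi, predictors, n_perm=cfg.n_perm_mrqap, seed=cfg.seed
        )
        t = mrqap.table.copy()
        t["r_squared"] = mrqap.r_squared
        t["n_permutations"] = mrqap.n_permutations
        t["seed"] = cfg.seed
        _fmt(t, out / "mrqap.csv")
        results["mrqap"] = mrqap
    except Exception as exc:
        raise RuntimeError(f"stage 'mrqap' failed: {exc}") from exc

    try:
        stage("agonistic")
        agon = agonistic_summary(fights, roster)
        _fmt(agon, out / "agonistic_summary.csv")
        results["agonistic"] = agon
    except Exception as exc:
        raise RuntimeError(f"stage 'agonistic' failed: {exc}") from exc

    try:
        stage("noderegress")
        ids = hwi.ids
        by_id = {r.bird_id: r for r in roster}
        X = pd.DataFrame(
            {
                "personality_score": pca.scores.loc[ids].to_numpy(),
                "age": [by_id[b].age for b in ids],
            },
            index=pd.Index(ids, name="bird_id"),
        )
        node_df = nm.join(agon)
        rows = []
        reg_results = {}
        for resp in NODE_RESPONSES:
            res = node_permutation_regression(
                node_df[resp].astype(float),
                X,
                n_perm=cfg.n_perm_node,
                seed=cfg.seed,
            )
            reg_results[resp] = res
            for pred, row in res.table.iterrows():
                rows.append(
                    {
                        "response": resp,
                        "predictor": pred,
                        "b": row["b"],
                        "p_upper": row["p_upper"],
                        "p_lower": row["p_lower"],
                        "p_two_sided": row["p_two_sided"],
                        "r_squared": res.r_squared,
                        "f_statistic": res.f_statistic,
                        "model_p": res.model_p,
                        "df_model": res.df_model,
                        "df_resid": res.df_resid,
                    }
                )
        pd.DataFrame(rows).to_csv(
            out / "node_regression.csv", index=False, float_format="%.10g"
        )
        results["node_regressions"] = reg_results
    except Exception as exc:
        raise RuntimeError(f"stage 'noderegress' failed: {exc}") from exc

    manifest = {
        "flocknet_version": __version__,
        "seed": cfg.seed,
        "parameters": {
            k: v for k, v in asdict(cfg).items() if k not in ("outdir",)
        },
        "n_birds": len(roster),
        "n_sessions": len(sessions),
        "outputs": sorted(
            p.name for p in out.iterdir() if p.is_file() and p.name != "manifest.json"
        ),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    results["manifest"] = manifest
    return results
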