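"""End-to-end orchestration: simulate/load -> preprocess -> estimate -> characterize.

A branch run covers one differentiation trajectory; a conservation run
compares two completed branch runs (species) at the centrality, edge-overlap,
and conserved-module levels. Every run writes its artifacts plus a manifest
recording the configuration, seed, and stage timings, and is bit-reproducible
given the same configuration and seed.
"""

from __future__ import annotations

import dataclasses
import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as tio
from .conservation import (
    aggregate_network,
    centrality_correlation,
    dual_hypergraph,
    edge_overlap_test,
    find_conserved_module,
)
from .energy import normalized_report
from .estimator import TimeVaryingGraphicalLasso
from .preprocess import LogNormalizer, PseudotimeBinner
from .properties import centralities, density_trajectory, global_properties, smallworld_check
from .similarity import cluster_stages, similarity_matrix
from .simulate import TVGGMSpec, make_precision_path, sample_cells

logger = logging.getLogger("tvggm")

__all__ = ["RunConfig", "run_branch", "run_conservation"]


@dataclass
class RunConfig:
    """Configuration of one branch run (either input files or a simulation)."""

    out_dir: str
    expression_path: str | None = None
    pseudotime_path: str | None = None
    simulation: TVGGMSpec | None = None
    branch: str = "branch"
    normalize: bool = False  # raw counts in, total-count log-normalize first
    n_bins: int = 25
    estimator_params: dict = field(default_factory=dict)
    run_properties: bool = True
    run_stages: bool = True
    run_energy: bool = True
    n_random: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        has_files = self.expression_path is not None
        has_sim = self.simulation is not None
        if has_files == has_sim:
            raise ValueError("exactly one of input paths or a simulation spec required")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        sim = raw.pop("simulation", None)
        if sim is not None:
            sim = TVGGMSpec(**sim)
        return cls(simulation=sim, **raw)


def _to_manifest_cfg(cfg: RunConfig) -> dict:
    d = dataclasses.asdict(cfg)
    return d


def run_branch(cfg: RunConfig) -> dict:
    """Execute one branch end to end; returns the result bundle.

    Stages: (simulate|load) -> [normalize] -> bin -> estimate series ->
    properties/stages/energy per the toggles. Any stage failure aborts with
    the stage name in the log.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"config": _to_manifest_cfg(cfg)}
    manifest: dict = {"config": _to_manifest_cfg(cfg), "outputs": {}, "timings": {}}
    stage = "input"
    t0 = _time.perf_counter()
    try:
        if cfg.simulation is not None:
            spec = dataclasses.replace(cfg.simulation, seed=cfg.seed)
            truth = make_precision_path(spec)
            expr, pt = sample_cells(truth, spec.n_cells, spec.dropout_rate, cfg.seed + 1)
            bundle["truth"] = truth
            tio.write_expression(expr, out / "expression.tsv")
            tio.write_pseudotime(pt, out / "pseudotime.tsv")
            manifest["outputs"]["expression"] = str(out / "expression.tsv")
            manifest["outputs"]["pseudotime"] = str(out / "pseudotime.tsv")
        else:
            expr = tio.read_expression(cfg.expression_path)
            pt = tio.read_pseudotime(cfg.pseudotime_path)
        manifest["timings"][stage] = _time.perf_counter() - t0
        logger.info("[%s] input ready: %d cells x %d genes", cfg.branch, *expr.shape)

        stage = "preprocess"
        t0 = _time.perf_counter()
        if cfg.normalize:
            expr = LogNormalizer().fit_transform(expr)
        binned = PseudotimeBinner(n_bins=cfg.n_bins).fit_transform(expr, pseudotime=pt)
        binned.to_tsv(out / "binned.tsv")
        manifest["outputs"]["binned"] = str(out / "binned.tsv")
        manifest["timings"][stage] = _time.perf_counter() - t0

        stage = "estimate"
        t0 = _time.perf_counter()
        est = TimeVaryingGraphicalLasso(**cfg.estimator_params)
        est.fit(binned)
        series = est.series_
        bundle["series"] = series
        bundle["estimator"] = est
        tio.write_series(series, out / "networks")
        manifest["outputs"]["networks"] = str(out / "networks")
        sel = pd.DataFrame(
            {
                "time": series.times,
                "h": [p[0] for p in est.selected_params_],
                "d": [p[1] for p in est.selected_params_],
                "lambda": [p[2] for p in est.selected_params_],
                "cv_score": est.cv_scores_,
                "n_edges": series.edge_counts(),
            }
        )
        sel.to_csv(out / "selected_params.tsv", sep="\t", index=False)
        manifest["outputs"]["selected_params"] = str(out / "selected_params.tsv")
        for row in sel.itertuples():
            logger.info(
                "[%s] t=%.3f h=%.3g d=%.3g lambda=%.3g edges=%d",
                cfg.branch, row.time, row.h, row.d, getattr(row, "_4"), row.n_edges,
            )
        manifest["timings"][stage] = _time.perf_counter() - t0

        graphs = series.to_graphs()
        if cfg.run_properties:
            stage = "properties"
            t0 = _time.perf_counter()
            traj = density_trajectory(series)
            bundle["density_trajectory"] = traj
            pd.DataFrame(
                {
                    "time": series.times,
                    "density": traj["density"],
                    "n_edges": traj["edge_count"],
                    "u_shape": traj["u_shape"],
                }
            ).to_csv(out / "density_trajectory.tsv", sep="\t", index=False)
            manifest["outputs"]["density_trajectory"] = str(out / "density_trajectory.tsv")
            cent = pd.concat(
                {t: centralities(g) for t, g in zip(series.times, graphs)},
                names=["time", "gene"],
            )
            cent.to_csv(out / "centralities.tsv", sep="\t")
            bundle["centralities"] = cent
            manifest["outputs"]["centralities"] = str(out / "centralities.tsv")
            manifest["timings"][stage] = _time.perf_counter() - t0

        if cfg.run_stages:
            stage = "stages"
            t0 = _time.perf_counter()
            sim = similarity_matrix(series)
            labels = cluster_stages(sim, k="auto")
            bundle["similarity"] = sim
            pd.DataFrame(sim.scores, index=series.times, columns=series.times).to_csv(
                out / "cnsi_matrix.tsv", sep="\t"
            )
            pd.DataFrame({"time": series.times, "stage": labels}).to_csv(
                out / "stages.tsv", sep="\t", index=False
            )
            manifest["outputs"]["cnsi_matrix"] = str(out / "cnsi_matrix.tsv")
            manifest["outputs"]["stages"] = str(out / "stages.tsv")
            manifest["timings"][stage] = _time.perf_counter() - t0
            logger.info("[%s] %d stages recovered", cfg.branch, sim.n_stages)

        if cfg.run_energy:
            stage = "energy"
            t0 = _time.perf_counter()
            rows = []
            for t, g in zip(series.times, graphs):
                if g.number_of_edges() == 0:
                    continue
                rep = normalized_report(g, n_random=cfg.n_random, seed=cfg.seed)
                rows.append(
                    {
                        "time": t,
                        "entropy_degree": rep.entropy_degree,
                        "entropy_betweenness": rep.entropy_betweenness,
                        "energy_adjacency": rep.energy_adjacency,
                        "energy_randic": rep.energy_randic,
                        "energy_laplacian": rep.energy_laplacian,
                        **{f"norm_{k}": v for k, v in rep.normalized.items()},
                    }
                )
            energy = pd.DataFrame(rows)
            energy.to_csv(out / "energy.tsv", sep="\t", index=False)
            bundle["energy"] = energy
            manifest["outputs"]["energy"] = str(out / "energy.tsv")
            manifest["timings"][stage] = _time.perf_counter() - t0
    except Exception:
        logger.exception("[%s] stage %r failed", cfg.branch, stage)
        raise
    manifest["seed"] = cfg.seed
    tio.write_manifest(manifest, out / "manifest.json")
    bundle["manifest"] = manifest
    return bundle


def run_conservation(
    bundle_a: dict,
    bundle_b: dict,
    ortholog_map: pd.DataFrame,
    out_dir,
    background_tau: float | None = None,
    n_random: int = 100,
    seed: int = 0,
) -> dict:
    """Cross-species comparison of two completed branch bundles."""
    for b in (bundle_a, bundle_b):
        if "series" not in b:
            raise ValueError("both branch bundles must contain an estimated series")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    series_a, series_b = bundle_a["series"], bundle_b["series"]
    agg_a, agg_b = aggregate_network(series_a), aggregate_network(series_b)
    corr = centrality_correlation(series_a, series_b, ortholog_map)
    overlap = edge_overlap_test(agg_a, agg_b, ortholog_map, n_permutations=1000, seed=seed)
    hg = dual_hypergraph(agg_a, agg_b, ortholog_map)
    module = find_conserved_module(hg, background_tau=background_tau)
    result: dict = {
        "aggregated_a": agg_a,
        "aggregated_b": agg_b,
        "centrality_correlation": corr,
        "edge_overlap": overlap,
        "dual_hypergraph": hg,
        "module": module,
    }
    corr.to_csv(out / "centrality_correlation.tsv", sep="\t")
    pd.DataFrame([{k: v for k, v in overlap.items() if k != "table"}]).to_csv(
        out / "edge_overlap.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        [{"gene_a": a, "gene_b": b} for a, b in module.hyper_nodes]
    ).to_csv(out / "module_edges.tsv", sep="\t", index=False)
    mod_graph = module.to_graph()
    if mod_graph.number_of_nodes() >= 3:
        sw = smallworld_check(mod_graph, n_random=n_random, seed=seed)
        result["module_smallworld"] = sw
        pd.DataFrame([dataclasses.asdict(sw)]).to_csv(
            out / "module_smallworld.tsv", sep="\t", index=False
        )
    tio.write_manifest(
        {"outputs": sorted(str(p) for p in out.iterdir()), "seed": seed},
        out / "manifest.json",
    )
    return result
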