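"""Reading and writing of the pipeline's plain-text artifacts.

Expression matrices travel as CSV/TSV (cells x genes, header of gene names)
or MTX triplets with row/column name sidecars; pseudo-time as a two-column
TSV; network series as per-time edge lists, one long-format TSV, and GraphML.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import csr_matrix

from .estimator import NetworkSeries, PrecisionEstimate

__all__ = [
    "read_expression",
    "write_expression",
    "read_pseudotime",
    "write_pseudotime",
    "read_gene_list",
    "write_series",
    "read_series_long",
    "write_manifest",
]


def read_expression(path) -> pd.DataFrame:
    """Cells x genes matrix from CSV/TSV (first column = cell ids) or MTX."""
    path = Path(path)
    if path.suffix == ".mtx":
        mat = mmread(path).tocsr()
        rows = _read_names(path.with_suffix(".rows.txt"))
        cols = _read_names(path.with_suffix(".cols.txt"))
        return pd.DataFrame(mat.toarray(), index=rows, columns=cols)
    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    return pd.read_csv(path, sep=sep, index_col=0)


def write_expression(expr: pd.DataFrame, path) -> None:
    path = Path(path)
    if path.suffix == ".mtx":
        mmwrite(path, csr_matrix(expr.to_numpy()))
        _write_names(path.with_suffix(".rows.txt"), expr.index)
        _write_names(path.with_suffix(".cols.txt"), expr.columns)
    else:
        sep = "\t" if path.suffix in (".tsv", ".txt") else ","
        expr.to_csv(path, sep=sep)


def _read_names(path) -> list[str]:
    return Path(path).read_text().splitlines()


def _write_names(path, names) -> None:
    Path(path).write_text("\n".join(map(str, names)) + "\n")


def read_pseudotime(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    return pd.Series(
        df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0], name="pseudotime"
    )


def write_pseudotime(pt: pd.Series, path) -> None:
    pd.DataFrame({"cell_id": pt.index, "pseudotime": pt.to_numpy()}).to_csv(
        path, sep="\t", index=False
    )


def read_gene_list(path) -> list[str]:
    return [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]


def write_series(series: NetworkSeries, outdir, prefix: str = "network") -> list[Path]:
    """Per-time edge-list TSVs, a long-format TSV, and GraphML files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    long_rows = []
    gene_idx = {g: i for i, g in enumerate(series.gene_names)}
    for k, est in enumerate(series.estimates):
        rows = []
        for a, b in sorted(est.edge_set):
            val = est.omega[gene_idx[a], gene_idx[b]]
            rows.append({"gene_a": a, "gene_b": b, "omega_value": val})
            long_rows.append(
                {"time": est.time, "gene_a": a, "gene_b": b, "value": val}
            )
        p = outdir / f"{prefix}_t{k:02d}.tsv"
        pd.DataFrame(rows, columns=["gene_a", "gene_b", "omega_value"]).to_csv(
            p, sep="\t", index=False
        )
        written.append(p)
        g = nx.Graph()
        g.add_nodes_from(series.gene_names)
        for a, b in est.edge_set:
            g.add_edge(a, b, weight=float(est.omega[gene_idx[a], gene_idx[b]]))
        gp = outdir / f"{prefix}_t{k:02d}.graphml"
        nx.write_graphml(g, gp)
        written.append(gp)
    lp = outdir / f"{prefix}_long.tsv"
    pd.DataFrame(long_rows, columns=["time", "gene_a", "gene_b", "value"]).to_csv(
        lp, sep="\t", index=False
    )
    written.append(lp)
    return written


def read_series_long(path, gene_names: list[str]) -> NetworkSeries:
    """Rebuild a NetworkSeries (edge sets + values) from the long-format TSV."""
    df = pd.read_csv(path, sep="\t")
    gene_idx = {g: i for i, g in enumerate(gene_names)}
    p = len(gene_names)
    estimates = []
    for t, sub in df.groupby("time", sort=True):
        omega = np.eye(p)
        edges = set()
        for _, row in sub.iterrows():
            i, j = gene_idx[row.gene_a], gene_idx[row.gene_b]
            omega[i, j] = omega[j, i] = row.value
            edges.add((row.gene_a, row.gene_b))
        estimates.append(
            PrecisionEstimate(float(t), omega, frozenset(edges), (np.nan,) * 3, np.nan)
        )
    return NetworkSeries(estimates, gene_names)


def write_manifest(manifest: dict, path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
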