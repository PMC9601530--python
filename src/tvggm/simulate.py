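"""Synthetic pseudo-time expression data from a known time-varying Gaussian graphical model.

The generator emulates a three-phase differentiation course (stable state,
transition, stable state): along a pseudo-time axis in [0, 1], cells are drawn
from a zero-mean multivariate Gaussian whose precision matrix ``Omega(t)``
follows a piecewise-support path — within each phase the conditional-independence
graph is fixed, and the sparse middle phase between two denser outer phases
produces the characteristic U-shaped density trajectory. Paired "species"
datasets sharing a conserved edge core, and uniform random-graph nulls, are
also provided so that every downstream analysis stage can be exercised without
real data.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular

__all__ = [
    "TVGGMSpec",
    "GroundTruth",
    "SpeciesPair",
    "make_precision_path",
    "sample_cells",
    "make_random_graph",
    "make_paired_species",
]


@dataclass(frozen=True)
class TVGGMSpec:
    """Parameters of the time-varying Gaussian graphical model generator.

    ``partial_corr_strength`` is the absolute partial correlation of every true
    edge; it is realized exactly (see :func:`make_precision_path`). Diagonal
    dominance limits how many edges of strength ``s`` a single gene can carry
    (strictly fewer than ``1/s``), so dense-and-strong combinations are
    rejected rather than silently weakened.
    """

    n_genes: int = 100
    n_cells: int = 3000
    n_time_anchors: int = 25
    phase_boundaries: tuple[float, float] = (1.0 / 3.0, 2.0 / 3.0)
    edge_density_per_phase: tuple[float, float, float] = (0.03, 0.01, 0.03)
    partial_corr_strength: float = 0.2
    conserved_core_fraction: float = 0.8
    dropout_rate: float = 0.1
    seed: int = 0
    shared_support: bool = False
    gene_prefix: str = "G"

    def __post_init__(self) -> None:
        b1, b2 = self.phase_boundaries
        if not (0.0 < b1 < b2 < 1.0):
            raise ValueError("phase_boundaries must be strictly increasing within (0, 1)")
        if self.n_genes < 2:
            raise ValueError("n_genes must be at least 2")
        if self.n_time_anchors < 3:
            raise ValueError("n_time_anchors must be at least 3")
        if len(self.edge_density_per_phase) != 3:
            raise ValueError("edge_density_per_phase must have three entries")
        for rho in self.edge_density_per_phase:
            if not (0.0 <= rho <= 1.0):
                raise ValueError("edge densities must lie in [0, 1]")
        if not (0.0 <= self.partial_corr_strength < 1.0):
            raise ValueError("partial_corr_strength must lie in [0, 1)")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must lie in [0, 1); 1 would zero all data")
        if not (0.0 <= self.conserved_core_fraction <= 1.0):
            raise ValueError("conserved_core_fraction must lie in [0, 1]")

    @property
    def gene_names(self) -> list[str]:
        return [f"{self.gene_prefix}{i + 1}" for i in range(self.n_genes)]


@dataclass
class GroundTruth:
    """Known precision-matrix path and edge supports at the anchor times."""

    gene_names: list[str]
    anchor_times: np.ndarray
    precision_path: np.ndarray  # (T, p, p)
    phase_of_anchor: np.ndarray  # (T,), values in {0, 1, 2}
    cell_pseudotimes: np.ndarray | None = None

    @property
    def true_edge_sets(self) -> list[frozenset[tuple[str, str]]]:
        out = []
        for om in self.precision_path:
            idx = np.argwhere(np.triu(np.abs(om) > 1e-12, k=1))
            out.append(
                frozenset((self.gene_names[i], self.gene_names[j]) for i, j in idx)
            )
        return out

    @property
    def aggregated_edges(self) -> frozenset[tuple[str, str]]:
        agg: set[tuple[str, str]] = set()
        for es in self.true_edge_sets:
            agg |= es
        return frozenset(agg)


@dataclass
class SpeciesPair:
    truth_a: GroundTruth
    truth_b: GroundTruth
    ortholog_map: pd.DataFrame  # columns: species_a, species_b
    core_edges: frozenset[tuple[str, str]]  # in species_a gene names


def _n_edges(p: int, density: float) -> int:
    return int(round(density * p * (p - 1) / 2))


def _sample_capped_support(
    p: int, m: int, cap: int, rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Random simple graph with m edges and maximum degree <= cap.

    Greedy accept over a shuffled pair list (close to Erdos-Renyi for low
    densities); falls back to near-regular stub pairing when the greedy pass
    cannot reach m (densities near the cap's capacity).
    """
    max_pairs = p * (p - 1) // 2
    if m > max_pairs or m > p * cap // 2:
        raise ValueError(
            f"cannot place {m} edges on {p} genes with per-gene degree cap {cap}; "
            "lower the edge density or the partial correlation strength"
        )
    if m == 0:
        return []
    iu, ju = np.triu_indices(p, k=1)
    for _ in range(30):
        order = rng.permutation(max_pairs)
        deg = np.zeros(p, dtype=int)
        edges: list[tuple[int, int]] = []
        for t in order:
            i, j = int(iu[t]), int(ju[t])
            if deg[i] < cap and deg[j] < cap:
                edges.append((i, j))
                deg[i] += 1
                deg[j] += 1
                if len(edges) == m:
                    return sorted(edges)
    # near-capacity regime: near-regular degree sequence + stub pairing
    base, extra = divmod(2 * m, p)
    degseq = np.full(p, base, dtype=int)
    degseq[rng.choice(p, size=extra, replace=False)] += 1
    if degseq.max() > cap:
        raise ValueError(
            f"cannot place {m} edges on {p} genes with per-gene degree cap {cap}"
        )
    for _ in range(500):
        stubs = np.repeat(np.arange(p), degseq)
        rng.shuffle(stubs)
        pairs = stubs.reshape(-1, 2)
        eset = {(min(a, b), max(a, b)) for a, b in pairs if a != b}
        if len(eset) == m:
            return sorted((int(a), int(b)) for a, b in eset)
    raise ValueError(
        f"failed to sample a degree-capped support with {m} edges on {p} genes"
    )


def _precision_from_support(
    p: int,
    edges: list[tuple[int, int]],
    strength: float,
    signs: dict[tuple[int, int], float],
) -> np.ndarray:
    """SPD precision with |partial correlation| == strength on every edge.

    Off-diagonals are o_ij = sign * s * sqrt(d_i d_j) and the diagonal is
    d_i = 1 + row sum of |o_i.| (strict diagonal dominance, hence SPD). The
    self-consistent diagonal is found by fixed-point iteration on u = sqrt(d);
    it exists iff s * degree_i < 1 for every gene, which is exactly the
    dominance feasibility condition.
    """
    omega = np.eye(p)
    if not edges:
        return omega
    s = strength
    deg = np.zeros(p, dtype=int)
    nbrs: list[list[int]] = [[] for _ in range(p)]
    for i, j in edges:
        deg[i] += 1
        deg[j] += 1
        nbrs[i].append(j)
        nbrs[j].append(i)
    if s * deg.max() >= 1.0:
        raise ValueError(
            f"strength {s} with maximum degree {deg.max()} cannot be made "
            "diagonally dominant (requires strength * degree < 1)"
        )
    u = np.ones(p)
    for _ in range(1000):
        ssum = np.array([u[nbrs[i]].sum() for i in range(p)])
        u_new = 0.5 * (s * ssum + np.sqrt((s * ssum) ** 2 + 4.0))
        if not np.all(np.isfinite(u_new)) or u_new.max() > 1e8:
            raise ValueError("diagonal fixed point diverged; reduce density or strength")
        if np.max(np.abs(u_new - u)) < 1e-13:
            u = u_new
            break
        u = u_new
    np.fill_diagonal(omega, u**2)
    for i, j in edges:
        v = signs[(i, j)] * s * u[i] * u[j]
        omega[i, j] = v
        omega[j, i] = v
    return omega


def _phase_of(t: np.ndarray, boundaries: tuple[float, float]) -> np.ndarray:
    b1, b2 = boundaries
    return np.where(t < b1, 0, np.where(t < b2, 1, 2)).astype(int)


def make_precision_path(
    spec: TVGGMSpec,
    supports: list[list[tuple[int, int]]] | None = None,
    signs: list[dict[tuple[int, int], float]] | None = None,
) -> GroundTruth:
    """Build the SPD precision-matrix path at the anchor times.

    Within a phase the edge support is fixed; edge magnitudes are constant in
    time (the degenerate case of linear interpolation between equal phase-entry
    and phase-exit values), so the path changes only across phase boundaries.
    ``supports``/``signs`` may be supplied to pin the supports (used for the
    paired-species construction).
    """
    p = spec.n_genes
    s = spec.partial_corr_strength
    rng = np.random.default_rng(spec.seed)
    cap = p - 1 if s == 0.0 else min(p - 1, int(math.floor(0.95 / s)))
    if supports is None:
        supports = []
        for k, rho in enumerate(spec.edge_density_per_phase):
            if spec.shared_support and k > 0:
                supports.append(supports[0])
            else:
                supports.append(_sample_capped_support(p, _n_edges(p, rho), cap, rng))
    if signs is None:
        signs = []
        for k, es in enumerate(supports):
            if spec.shared_support and k > 0:
                signs.append(signs[0])
            else:
                signs.append({e: float(rng.choice([-1.0, 1.0])) for e in es})
    phase_omegas = [
        _precision_from_support(p, supports[k], s, signs[k]) for k in range(3)
    ]
    anchor_times = np.linspace(0.0, 1.0, spec.n_time_anchors)
    phases = _phase_of(anchor_times, spec.phase_boundaries)
    path = np.stack([phase_omegas[ph] for ph in phases])
    return GroundTruth(
        gene_names=spec.gene_names,
        anchor_times=anchor_times,
        precision_path=path,
        phase_of_anchor=phases,
    )


def interpolate_precision(truth: GroundTruth, t: float) -> np.ndarray:
    """Precision at pseudo-time t: linear interpolation between anchors."""
    ts = truth.anchor_times
    t = float(np.clip(t, ts[0], ts[-1]))
    k = int(np.searchsorted(ts, t, side="right")) - 1
    k = min(max(k, 0), len(ts) - 2)
    w = (t - ts[k]) / (ts[k + 1] - ts[k])
    return (1.0 - w) * truth.precision_path[k] + w * truth.precision_path[k + 1]


def sample_cells(
    truth: GroundTruth,
    n_cells: int,
    dropout_rate: float,
    seed: int,
) -> tuple[pd.DataFrame, pd.Series]:
    """Draw cells from N(0, Sigma(t)) at uniform pseudo-times, then apply dropout.

    Each cell's pseudo-time is uniform on [0, 1]; its covariance is the inverse
    of the interpolated precision at that time. Dropout zeroes each entry
    independently with probability ``dropout_rate``. Returns a cells x genes
    DataFrame and an aligned pseudo-time Series.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be at least 1")
    if not (0.0 <= dropout_rate < 1.0):
        raise ValueError("dropout_rate must lie in [0, 1); 1 would zero all data")
    rng = np.random.default_rng(seed)
    p = len(truth.gene_names)
    times = rng.uniform(0.0, 1.0, size=n_cells)
    X = np.empty((n_cells, p))
    ts = truth.anchor_times
    brackets = np.clip(np.searchsorted(ts, times, side="right") - 1, 0, len(ts) - 2)
    # cholesky cache per interval whose two anchor matrices coincide
    same_flags = [
        np.array_equal(truth.precision_path[k], truth.precision_path[k + 1])
        for k in range(len(ts) - 1)
    ]
    chol_cache: dict[int, np.ndarray] = {}
    z = rng.standard_normal((n_cells, p))

    for c in range(n_cells):
        k = int(brackets[c])
        same = same_flags[k]
        if same and k in chol_cache:
            L = chol_cache[k]
        else:
            om = (
                truth.precision_path[k]
                if same
                else interpolate_precision(truth, times[c])
            )
            L = np.linalg.cholesky(om)
            if same:
                chol_cache[k] = L
        # x = L^{-T} z  ~  N(0, Omega^{-1})
        X[c] = solve_triangular(L.T, z[c], lower=False)
    if dropout_rate > 0.0:
        X[rng.random(size=X.shape) < dropout_rate] = 0.0
    cell_ids = [f"cell{c + 1}" for c in range(n_cells)]
    expr = pd.DataFrame(X, index=cell_ids, columns=truth.gene_names)
    pt = pd.Series(times, index=cell_ids, name="pseudotime")
    truth.cell_pseudotimes = times
    return expr, pt


def make_random_graph(n_nodes: int, n_edges: int, seed: int) -> nx.Graph:
    """Uniform simple undirected graph with exactly the given node/edge counts."""
    max_edges = n_nodes * (n_nodes - 1) // 2
    if n_edges > max_edges:
        raise ValueError(f"{n_edges} edges infeasible on {n_nodes} nodes")
    g = nx.gnm_random_graph(n_nodes, n_edges, seed=seed)
    return g


def make_paired_species(spec: TVGGMSpec) -> SpeciesPair:
    """Two species datasets sharing exactly ceil(c * |E_A|) aggregated true edges.

    Species B keeps the conserved core edges in the same phases as species A
    and replaces the rest with fresh edges drawn outside A's aggregated edge
    set, so the aggregated intersection is the core exactly.
    """
    truth_a = make_precision_path(spec)
    p = spec.n_genes
    s = spec.partial_corr_strength
    rng = np.random.default_rng(spec.seed + 1_000_003)
    cap = p - 1 if s == 0.0 else min(p - 1, int(math.floor(0.95 / s)))

    name_to_idx = {g: i for i, g in enumerate(truth_a.gene_names)}
    supports_a: list[list[tuple[int, int]]] = []
    phases_seen: list[int] = []
    for ph in range(3):
        k = int(np.argmax(truth_a.phase_of_anchor == ph))
        om = truth_a.precision_path[k]
        idx = np.argwhere(np.triu(np.abs(om) > 1e-12, k=1))
        supports_a.append([(int(i), int(j)) for i, j in idx])
        phases_seen.append(ph)
    union_a = sorted({e for es in supports_a for e in es})
    n_core = math.ceil(spec.conserved_core_fraction * len(union_a))
    core_idx = rng.choice(len(union_a), size=n_core, replace=False)
    core = {union_a[i] for i in core_idx}
    forbidden = set(union_a)

    supports_b: list[list[tuple[int, int]]] = []
    signs_b: list[dict[tuple[int, int], float]] = []
    iu, ju = np.triu_indices(p, k=1)
    all_pairs = list(zip(iu.tolist(), ju.tolist()))
    for ph in range(3):
        keep = [e for e in supports_a[ph] if e in core]
        need = len(supports_a[ph]) - len(keep)
        deg = np.zeros(p, dtype=int)
        for i, j in keep:
            deg[i] += 1
            deg[j] += 1
        fresh: list[tuple[int, int]] = []
        order = rng.permutation(len(all_pairs))
        for t in order:
            if need == 0:
                break
            e = all_pairs[t]
            i, j = e
            if e in forbidden or e in fresh or e in keep:
                continue
            if deg[i] < cap and deg[j] < cap:
                fresh.append(e)
                deg[i] += 1
                deg[j] += 1
                need -= 1
        if need > 0:
            raise ValueError("could not draw non-conserved replacement edges; lower density")
        sup = sorted(keep + fresh)
        supports_b.append(sup)
        signs_b.append({e: float(rng.choice([-1.0, 1.0])) for e in sup})

    spec_b = dataclasses.replace(spec, gene_prefix=spec.gene_prefix.lower() + "b")
    truth_b = make_precision_path(spec_b, supports=supports_b, signs=signs_b)
    names_a = truth_a.gene_names
    names_b = truth_b.gene_names
    ortholog_map = pd.DataFrame({"species_a": names_a, "species_b": names_b})
    core_named = frozenset((names_a[i], names_a[j]) for i, j in core)
    return SpeciesPair(truth_a, truth_b, ortholog_map, core_named)
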