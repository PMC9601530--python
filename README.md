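# tvggm — time-varying gene networks along single-cell pseudo-time

`tvggm` estimates how a gene–gene interaction network rewires along a
differentiation trajectory. Cells ordered on a pseudo-time axis t ∈ [0, 1]
are modeled as draws from a multivariate Gaussian N(0, Σ(t)) whose precision
matrix Ω(t) = Σ(t)⁻¹ changes smoothly; a nonzero off-diagonal Ω_{μν}(t) is a
direct (conditional) interaction between genes μ and ν at time t. The package
is aimed at single-cell analysts who want network-level — rather than
gene-level — descriptions of processes such as hematopoietic differentiation,
including the sparse "transition state" between two stable cell states.

## The estimator

At each evaluation time t_k the series of precision matrices is estimated by
the local group graphical lasso: minimize, over the neighborhood
N_{k,d} = {i : |t_i − t_k| ≤ d},

    (1/|N_{k,d}|) Σ_{i∈N_{k,d}} [ tr(Ω(t_i) Σ̂(t_i)) − log det Ω(t_i) ]
        + λ Σ_{μ≠ν} ‖( Ω_{μν}(t_i) )_{i∈N_{k,d}}‖₂

where Σ̂(t) is a kernel-weighted sample covariance with bandwidth h. The group
penalty couples each edge across neighboring time points, so the graph evolves
smoothly; d = 0 recovers the ordinary per-time graphical lasso and a large d
the time-constant model. The problem is solved by ADMM. The bandwidth h is
chosen globally and (d_k, λ_k) per time point by K-fold cross-validation
scored on refitted (support-constrained maximum-likelihood) estimates, and
unstable edges are pruned by a majority vote across fold fits (cv.vote).

Downstream, the network series is characterized by its density trajectory
(the "U shape" of a transition state), CNSI similarity between time points
with hierarchical staging, per-gene centralities (degree, betweenness,
clustering, PageRank, h-index), Shannon entropies and adjacency/Randić/
Laplacian graph energies against matched random-graph nulls, a discrete
power-law fit of the degree distribution, and cross-species conservation:
aggregated networks, ortholog-mapped centrality correlations, Fisher
edge-overlap tests, and conserved-module search on the dual hypergraph
(edges → nodes, linked when they share a gene).

A synthetic-data generator produces pseudo-time-ordered expression from a
known three-phase (stable → transition → stable) time-varying Gaussian
graphical model with exact edge partial correlations, dropout, and paired
"species" datasets sharing a conserved edge core, so the whole pipeline is
testable without any download.

## Worked example

The canonical three-phase experiment (40 genes, 3000 cells, phases of equal
length with edge densities 0.04 / 0.025 / 0.04 and edge partial correlations
of 0.4) runs the full pipeline — simulate, bin, estimate the 25-network
series, then characterize it:

```python
from tvggm.experiments import run_three_phase

out = run_three_phase(seed=5)
print("stages recovered:", out["n_stages"])
print("agreement with true phases:", round(out["stage_agreement"], 2))
print("U-shaped density:", out["u_shape"])
print("edges per time:", list(map(int, out["edge_count"])))
print("stage labels:", list(map(int, out["stage_labels"])))
```

Output (about two minutes on one CPU):

```
stages recovered: 3
agreement with true phases: 0.92
U-shaped density: True
edges per time: [38, 22, 53, 39, 40, 45, 44, 9, 7, 14, 18, 15, 14, 14, 8, 0, 0, 48, 48, 48, 47, 53, 47, 33, 51]
stage labels: [0, 0, 0, 0, 0, 0, 0, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 2, 2, 2, 2, 2, 2, 2, 2]
```

The estimated edge counts drop from ~40 in the first stable phase to ~15 in
the transition phase and recover afterwards (the U shape of a transition
state), and CNSI staging groups the 25 network time points into three
contiguous stages that match the true phases at 92% of time points. The
lower-level API (`TVGGMSpec`, `bin_cells`, `TimeVaryingGraphicalLasso`,
`similarity_matrix`, `cluster_stages`, `density_trajectory`, ...) exposes
each step separately.

A `tvggm` command-line interface wraps the same pipeline
(`tvggm simulate`, `tvggm run-all --config cfg.yaml`, `tvggm conserve`).

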