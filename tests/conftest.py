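"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import networkx as nx
import numpy as np
import pytest


def proximal_gradient_group_glasso(S_list, lam, max_iter=20000, tol=1e-12):
    """Independent solver of the local group graphical lasso objective.

    Proximal gradient (ISTA) with backtracking — a different algorithm family
    from the package's ADMM, used as the convex-programming oracle. Operates
    on the identical objective: (1/M) sum_i [tr(Om_i S_i) - logdet Om_i]
    + lam * sum_{mu != nu} ||(Om_i,munu)_i||_2.
    """
    S = np.stack([np.asarray(x, float) for x in S_list])
    M, p, _ = S.shape
    c = 1.0 / M
    Om = np.stack([np.eye(p)] * M)

    def smooth(O):
        val = 0.0
        for i in range(M):
            sign, ld = np.linalg.slogdet(O[i])
            if sign <= 0:
                return np.inf
            val += c * (np.sum(O[i] * S[i]) - ld)
        return val

    def penalty(O):
        norms = np.sqrt((O**2).sum(axis=0))
        return lam * (norms.sum() - np.trace(norms))

    def prox(V, kappa):
        norms = np.sqrt((V**2).sum(axis=0))
        with np.errstate(divide="ignore", invalid="ignore"):
            f = np.where(norms > 0, np.maximum(0.0, 1.0 - kappa / norms), 0.0)
        Z = V * f[None]
        d = np.arange(p)
        Z[:, d, d] = V[:, d, d]
        return Z

    step = 1.0
    fval = smooth(Om)
    obj_prev = fval + penalty(Om)
    for _ in range(max_iter):
        G = np.stack([c * (S[i] - np.linalg.inv(Om[i])) for i in range(M)])
        while True:
            cand = prox(Om - step * G, lam * step)
            fc = smooth(cand)
            if np.isfinite(fc) and fc <= fval + np.sum(G * (cand - Om)) + np.sum(
                (cand - Om) ** 2
            ) / (2 * step) + 1e-15:
                break
            step *= 0.5
            if step < 1e-13:
                break
        Om, fval = cand, fc
        obj = fval + penalty(Om)
        if abs(obj_prev - obj) < tol * max(1.0, abs(obj)):
            break
        obj_prev = obj
        step = min(step * 1.5, 10.0)
    return Om, obj_prev


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def fixture_graph_10():
    """10-node, 14-edge graph used against brute-force BFS oracles."""
    g = nx.Graph()
    g.add_edges_from(
        [
            (0, 1), (0, 2), (1, 2), (1, 3), (2, 4), (3, 4), (3, 5), (4, 6),
            (5, 6), (5, 7), (6, 8), (7, 8), (7, 9), (8, 9),
        ]
    )
    return g
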