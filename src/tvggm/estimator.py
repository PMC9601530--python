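"""Time-varying sparse Gaussian graphical model estimation over pseudo-time.

At each evaluation time t_k the precision matrix Omega(t_k) is estimated by
minimizing, over the time neighborhood N_{k,d} = {i : |t_i - t_k| <= d},

    (1/|N_{k,d}|) * sum_{i in N_{k,d}} [ tr(Omega(t_i) Shat(t_i)) - log det Omega(t_i) ]
    + lambda * sum_{mu != nu} || ( Omega_{mu nu}(t_i) )_{i in N_{k,d}} ||_2

where Shat(t_i) is a kernel-weighted sample covariance with bandwidth h. The
group penalty couples the same edge across neighboring time points, enforcing
smooth evolution of the conditional-independence graph. The problem is solved
by ADMM; (h, d_k, lambda_k) are chosen per time point by K-fold
cross-validation with the validation score

    CV_j(t_k) = tr( OmegaHat_rf^(-j)(t_k) Shat^(j)(t_k) ) - log det OmegaHat_rf^(-j)(t_k),

summed over folds, where OmegaHat_rf^(-j) is the refitted estimate — the
Gaussian MLE constrained to the support selected on the training folds
(scoring the shrunk estimates directly over-selects badly). Unstable edges
are finally pruned by a majority vote over the fold-specific fits (cv.vote).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from sklearn.base import BaseEstimator

from .preprocess import BinnedExpression

__all__ = [
    "ConvergenceError",
    "PrecisionEstimate",
    "NetworkSeries",
    "TimeVaryingGraphicalLasso",
    "kernel_covariance",
    "fit_local_group_lasso",
    "group_lasso_objective",
    "cv_vote",
    "estimate_series",
]

EDGE_TOL = 1e-6


class ConvergenceError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# result containers


@dataclass
class PrecisionEstimate:
    """Estimated precision matrix at one pseudo-time point."""

    time: float
    omega: np.ndarray
    edge_set: frozenset[tuple[str, str]]
    selected_params: tuple[float, float, float]  # (h, d, lambda)
    cv_score: float


@dataclass
class NetworkSeries:
    """Ordered series of estimated gene networks, one per evaluation time."""

    estimates: list[PrecisionEstimate]
    gene_names: list[str]

    def __post_init__(self) -> None:
        p = len(self.gene_names)
        for est in self.estimates:
            if est.omega.shape != (p, p):
                raise ValueError("all estimates must share the gene universe")

    def __len__(self) -> int:
        return len(self.estimates)

    @property
    def times(self) -> np.ndarray:
        return np.array([e.time for e in self.estimates])

    def to_graphs(self) -> list[nx.Graph]:
        graphs = []
        for est in self.estimates:
            g = nx.Graph()
            g.add_nodes_from(self.gene_names)
            for a, b in est.edge_set:
                ia, ib = self.gene_names.index(a), self.gene_names.index(b)
                g.add_edge(a, b, weight=float(est.omega[ia, ib]))
            graphs.append(g)
        return graphs

    def edge_counts(self) -> np.ndarray:
        return np.array([len(e.edge_set) for e in self.estimates])


# ---------------------------------------------------------------------------
# kernel-weighted covariance


def _kernel(u: np.ndarray, kind: str) -> np.ndarray:
    if kind == "epanechnikov":
        return np.where(np.abs(u) <= 1.0, 0.75 * (1.0 - u**2), 0.0)
    if kind == "gaussian":
        return np.exp(-0.5 * u**2)
    raise ValueError(f"unknown kernel {kind!r}")


def kernel_covariance(
    values: np.ndarray,
    times: np.ndarray,
    t: float,
    h: float,
    kernel: str = "epanechnikov",
) -> np.ndarray:
    """Kernel-weighted sample covariance centered at pseudo-time t.

    Weights w_i proportional to K((t_i - t)/h) are normalized to sum to one
    and the data are centered by the weighted mean, so the result is symmetric
    positive semidefinite.
    """
    if h <= 0:
        raise ValueError("bandwidth h must be positive")
    values = np.asarray(values, float)
    times = np.asarray(times, float)
    w = _kernel((times - t) / h, kernel)
    total = w.sum()
    if total <= 0:
        raise ValueError(
            f"all kernel weights vanish at t={t} with h={h}; increase the bandwidth"
        )
    w = w / total
    mu = w @ values
    xc = values - mu
    S = (xc * w[:, None]).T @ xc
    return 0.5 * (S + S.T)


# ---------------------------------------------------------------------------
# group graphical lasso via ADMM


def group_lasso_objective(S_list, omegas, lam: float) -> float:
    """Value of the local group graphical lasso objective at ``omegas``."""
    M = len(S_list)
    val = 0.0
    for S, om in zip(S_list, omegas):
        sign, logdet = np.linalg.slogdet(om)
        if sign <= 0:
            return np.inf
        val += (np.multiply(om, S).sum() - logdet) / M
    stack = np.stack(omegas)
    norms = np.sqrt((stack**2).sum(axis=0))
    off_sum = norms.sum() - np.trace(norms)  # both orderings mu != nu
    return val + lam * off_sum


def _admm_group_glasso(
    S: np.ndarray,
    lam: float,
    rho: float = 1.0,
    tol_abs: float = 1e-6,
    tol_rel: float = 1e-4,
    max_iter: int = 2000,
    warm: tuple[np.ndarray, np.ndarray] | None = None,
):
    """ADMM for the group graphical lasso over a stack of covariances.

    S has shape (M, p, p). Returns (Omega, Z, U, n_iter, converged): Omega is
    the smooth (positive definite) iterate, Z carries the exact group-sparse
    support.
    """
    M, p, _ = S.shape
    c = 1.0 / M
    if warm is not None:
        Z, U = warm[0].copy(), warm[1].copy()
    else:
        Z = np.broadcast_to(np.eye(p), (M, p, p)).copy()
        U = np.zeros((M, p, p))
    diag = np.arange(p)
    n_elem = np.sqrt(M * p * p)
    Omega = Z.copy()
    converged = False
    r_norm = s_norm = np.nan
    for it in range(1, max_iter + 1):
        A = rho * (Z - U) - c * S
        evals, evecs = np.linalg.eigh(A)
        om_evals = (evals + np.sqrt(evals**2 + 4.0 * rho * c)) / (2.0 * rho)
        Omega = np.einsum("mij,mj,mkj->mik", evecs, om_evals, evecs)
        V = Omega + U
        Z_old = Z
        if lam > 0:
            kappa = lam / rho  # the two factor-2s (mu!=nu vs. Frobenius) cancel
            norms = np.sqrt((V**2).sum(axis=0))
            with np.errstate(divide="ignore", invalid="ignore"):
                factor = np.where(norms > 0, np.maximum(0.0, 1.0 - kappa / norms), 0.0)
            Z = V * factor[None, :, :]
            Z[:, diag, diag] = V[:, diag, diag]
        else:
            Z = V.copy()
        U = U + Omega - Z
        r_norm = np.linalg.norm(Omega - Z)
        s_norm = rho * np.linalg.norm(Z - Z_old)
        eps_pri = n_elem * tol_abs + tol_rel * max(
            np.linalg.norm(Omega), np.linalg.norm(Z)
        )
        eps_dual = n_elem * tol_abs + tol_rel * rho * np.linalg.norm(U)
        if r_norm < eps_pri and s_norm < eps_dual:
            converged = True
            break
        # residual balancing keeps ill-conditioned (rank-deficient
        # covariance, small lambda) problems moving
        if it % 10 == 0:
            if r_norm > 10.0 * s_norm:
                rho *= 2.0
                U /= 2.0
            elif s_norm > 10.0 * r_norm:
                rho /= 2.0
                U *= 2.0
    return Omega, Z, U, it, converged, (r_norm, s_norm)


def support_constrained_mle(
    S: np.ndarray,
    support: np.ndarray,
    tol_abs: float = 1e-7,
    tol_rel: float = 1e-5,
    max_iter: int = 2000,
    warm: tuple[np.ndarray, np.ndarray] | None = None,
):
    """Gaussian MLE of the precision matrix restricted to a given edge support.

    Solves min tr(Omega S) - log det Omega subject to Omega_ij = 0 outside the
    (off-diagonal) support, by ADMM with a projection step. Used to score
    cross-validation candidates on refitted (unshrunk) estimates. Returns
    (omega, converged, state); the MLE may not exist for dense supports when
    S is rank deficient, in which case converged is False.
    """
    S = np.asarray(S, float)
    p = S.shape[0]
    gamma = float(np.trace(S) / p)
    if gamma <= 0 or not np.isfinite(gamma):
        gamma = 1.0
    St = S / gamma
    mask = np.asarray(support, bool).copy()
    mask |= mask.T
    np.fill_diagonal(mask, True)
    if warm is not None:
        Z, U = warm[0].copy(), warm[1].copy()
    else:
        Z = np.eye(p)
        U = np.zeros((p, p))
    rho = 1.0
    n_elem = float(p)
    for it in range(1, max_iter + 1):
        A = rho * (Z - U) - St
        evals, Q = np.linalg.eigh(A)
        om_evals = (evals + np.sqrt(evals**2 + 4.0 * rho)) / (2.0 * rho)
        Omega = (Q * om_evals) @ Q.T
        V = Omega + U
        Z_old = Z
        Z = np.where(mask, V, 0.0)
        U = U + Omega - Z
        r = np.linalg.norm(Omega - Z)
        s = rho * np.linalg.norm(Z - Z_old)
        eps_pri = n_elem * tol_abs + tol_rel * max(
            np.linalg.norm(Omega), np.linalg.norm(Z)
        )
        eps_dual = n_elem * tol_abs + tol_rel * rho * np.linalg.norm(U)
        if r < eps_pri and s < eps_dual:
            return Z / gamma, True, (Z, U)
        if not np.all(np.isfinite(Z)) or np.abs(Z).max() > 1e10:
            return Z / gamma, False, None
        if it % 10 == 0:
            if r > 10.0 * s:
                rho *= 2.0
                U /= 2.0
            elif s > 10.0 * r:
                rho /= 2.0
                U *= 2.0
    return Z / gamma, False, (Z, U)


def _ensure_pd(mat: np.ndarray, floor: float = 1e-8) -> np.ndarray:
    """Symmetrize and, if needed, add a ridge so the smallest eigenvalue > 0."""
    mat = 0.5 * (mat + mat.T)
    lo = np.linalg.eigvalsh(mat)[0]
    if lo <= floor:
        mat = mat + (floor - lo + floor) * np.eye(mat.shape[0])
    return mat


def fit_local_group_lasso(
    covariances,
    lam: float,
    rho: float = 1.0,
    tol_abs: float = 1e-6,
    tol_rel: float = 1e-4,
    max_iter: int = 2000,
    warm=None,
    on_nonconverged: str = "raise",
):
    """Solve the group graphical lasso over a time neighborhood.

    ``covariances`` is the list of kernel covariances at the neighborhood
    times. Returns (omegas, edge_supports, state): symmetric positive definite
    precision matrices with exactly group-sparse off-diagonal support, the
    boolean supports, and the ADMM state for warm starts.
    """
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    S = np.stack([np.asarray(Si, float) for Si in covariances])
    # the problem is equivalent under S -> S/gamma, lambda -> lambda/gamma,
    # Omega -> gamma * Omega; normalizing to unit diagonal scale keeps ADMM
    # with rho ~ 1 well conditioned (bin means have covariances ~ Sigma/n_bin)
    gamma = float(np.mean([np.trace(Si) / Si.shape[0] for Si in S]))
    if gamma <= 0 or not np.isfinite(gamma):
        gamma = 1.0
    Omega, Z, U, n_iter, conv, (r, s) = _admm_group_glasso(
        S / gamma,
        lam / gamma,
        rho=rho,
        tol_abs=tol_abs,
        tol_rel=tol_rel,
        max_iter=max_iter,
        warm=warm,
    )
    if not conv:
        msg = (
            f"ADMM did not converge in {n_iter} iterations "
            f"(primal residual {r:.3e}, dual residual {s:.3e})"
        )
        if on_nonconverged == "raise":
            raise ConvergenceError(msg)
        warnings.warn(msg, RuntimeWarning)
    p = S.shape[1]
    supports = np.abs(Z) > EDGE_TOL
    supports |= np.transpose(supports, (0, 2, 1))
    omegas = []
    for m in range(S.shape[0]):
        om = np.where(supports[m], Z[m], 0.0) / gamma
        om[np.arange(p), np.arange(p)] = Z[m].diagonal() / gamma
        omegas.append(_ensure_pd(om))
    return omegas, supports, (Z, U)


def _shift_warm(prev, nbh, m):
    """Map a neighboring time point's ADMM state onto the current neighborhood."""
    if prev is None:
        return None
    pnbh, (pZ, pU) = prev
    p = pZ.shape[1]
    Z0 = np.broadcast_to(np.eye(p), (m, p, p)).copy()
    U0 = np.zeros((m, p, p))
    common, ia, ib = np.intersect1d(nbh, pnbh, return_indices=True)
    if common.size == 0:
        return None
    Z0[ia] = pZ[ib]
    U0[ia] = pU[ib]
    return Z0, U0


def cv_vote(fold_edge_sets, threshold: float = 0.5) -> frozenset:
    """Consensus edges present in strictly more than ``threshold`` of folds."""
    folds = list(fold_edge_sets)
    if len(folds) < 2:
        raise ValueError("cv_vote needs at least two folds")
    counts: dict = {}
    for es in folds:
        for e in es:
            counts[e] = counts.get(e, 0) + 1
    cut = threshold * len(folds)
    return frozenset(e for e, n in counts.items() if n > cut)


# ---------------------------------------------------------------------------
# estimator


class TimeVaryingGraphicalLasso(BaseEstimator):
    """Series of sparse precision matrices along pseudo-time.

    Parameters
    ----------
    h_grid : bandwidths of the kernel covariance estimate.
    d_grid : neighborhood half-widths; 0 recovers the single-time graphical
        lasso and a width covering the whole axis the kernel-only limit.
    lambda_grid : sparsity penalties; ``None`` builds ``n_lambda`` values
        log-spaced down from the level that empties the graph.
    cv_folds : number of folds, interleaved by time rank so that every fold
        spans the time axis.
    vote_threshold : an edge must appear in strictly more than this fraction
        of fold fits to survive the consensus vote.
    eval_times : evaluation times; defaults to the bin times.

    Attributes (after ``fit``)
    --------------------------
    series_ : :class:`NetworkSeries` of per-time estimates.
    precisions_, edge_sets_, selected_params_, cv_scores_ : per-time views.
    cv_table_ : list of dict rows with all (h, d, lambda, time, score) entries.
    """

    def __init__(
        self,
        h_grid=(0.1, 0.2, 0.3),
        d_grid=(0.0, 0.05, 0.15, 0.3, 1.0),
        lambda_grid=None,
        n_lambda: int = 8,
        cv_folds: int = 5,
        vote_threshold: float = 0.5,
        kernel: str = "epanechnikov",
        admm_rho: float = 1.0,
        admm_tol_abs: float = 1e-6,
        admm_tol_rel: float = 1e-4,
        admm_max_iter: int = 2000,
        eval_times=None,
    ):
        self.h_grid = h_grid
        self.d_grid = d_grid
        self.lambda_grid = lambda_grid
        self.n_lambda = n_lambda
        self.cv_folds = cv_folds
        self.vote_threshold = vote_threshold
        self.kernel = kernel
        self.admm_rho = admm_rho
        self.admm_tol_abs = admm_tol_abs
        self.admm_tol_rel = admm_tol_rel
        self.admm_max_iter = admm_max_iter
        self.eval_times = eval_times

    # -- helpers ----------------------------------------------------------

    def _check_params(self):
        if len(self.h_grid) == 0 or any(h <= 0 for h in self.h_grid):
            raise ValueError("h_grid must be non-empty with positive bandwidths")
        if len(self.d_grid) == 0 or any(d < 0 for d in self.d_grid):
            raise ValueError("d_grid must be non-empty with nonnegative widths")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be at least 2")
        if not (0.5 <= self.vote_threshold <= 1.0):
            raise ValueError("vote_threshold must lie in [0.5, 1]")

    def _lambda_grid(self, values, times):
        if self.lambda_grid is not None:
            lams = sorted(self.lambda_grid, reverse=True)
            if any(l < 0 for l in lams):
                raise ValueError("lambda values must be nonnegative")
            return lams
        # largest off-diagonal covariance magnitude empties the graph
        smax = 0.0
        for h in self.h_grid:
            for t in times:
                S = kernel_covariance(values, times, t, h, self.kernel)
                off = np.abs(S - np.diag(np.diag(S)))
                smax = max(smax, off.max())
        smax = max(smax, 1e-3)
        # floor at smax/15: far below it the likelihood term is nearly
        # unbounded for rank-deficient kernel covariances and CV scores of
        # the overfitted supports become erratic
        return list(np.geomspace(smax * 1.05, smax / 15.0, self.n_lambda))

    def _neighborhood(self, times, tk, d):
        idx = np.flatnonzero(np.abs(times - tk) <= d + 1e-12)
        nearest = int(np.argmin(np.abs(times - tk)))
        if nearest not in idx:
            idx = np.sort(np.append(idx, nearest))
        return idx

    def _admm(self, S_list, lam, warm=None, coarse=False):
        # CV scoring only consumes the edge support, which stabilizes well
        # before full numerical convergence; the final refit on all data uses
        # the strict tolerances
        tol_rel = max(self.admm_tol_rel, 1e-3) if coarse else self.admm_tol_rel
        return fit_local_group_lasso(
            S_list,
            lam,
            rho=self.admm_rho,
            tol_abs=self.admm_tol_abs,
            tol_rel=tol_rel,
            max_iter=self.admm_max_iter,
            warm=warm,
            on_nonconverged="warn",
        )

    @staticmethod
    def _edges_from_support(support, gene_names):
        idx = np.argwhere(np.triu(support, k=1))
        return frozenset((gene_names[i], gene_names[j]) for i, j in idx)

    # -- core -------------------------------------------------------------

    def cross_validate(self, binned: BinnedExpression):
        """Grid search by K-fold CV; fills ``cv_table_`` and per-time selection.

        Folds are interleaved by time rank. For a compact-support kernel a
        validation fold may carry zero weight at some (t_k, h); such folds are
        skipped there and the score rescaled to the full fold count.
        """
        self._check_params()
        values, times = binned.values, binned.bin_times
        T = len(times)
        eval_times = (
            np.asarray(self.eval_times, float)
            if self.eval_times is not None
            else times.copy()
        )
        if np.any(np.diff(eval_times) < 0):
            raise ValueError("eval_times must be sorted")
        K = self.cv_folds
        if T < 2 * K:
            raise ValueError("not enough bins for the requested fold count")
        fold_id = np.arange(T) % K
        lambdas = self._lambda_grid(values, times)
        h_grid = sorted(self.h_grid)
        d_grid = sorted(self.d_grid)

        n_eval = len(eval_times)
        shape = (len(h_grid), len(d_grid), len(lambdas), n_eval)
        scores = np.zeros(shape)
        fold_counts = np.zeros(shape, dtype=int)
        self._fold_edges = {}  # (hi, di, li, k, j) -> frozenset of index pairs

        for hi, h in enumerate(h_grid):
            for j in range(K):
                train = fold_id != j
                S_val = []
                S_train_eval = []
                for tk in eval_times:
                    try:
                        S_val.append(
                            kernel_covariance(
                                values[~train], times[~train], tk, h, self.kernel
                            )
                        )
                    except ValueError:
                        S_val.append(None)
                    S_train_eval.append(
                        kernel_covariance(values[train], times[train], tk, h, self.kernel)
                    )
                refit_states: dict[tuple, tuple] = {}
                for di, d in enumerate(d_grid):
                    # identical neighborhoods (e.g. a width covering the whole
                    # axis) are solved once and re-scored at each center;
                    # shifted neighborhoods warm-start from the previous time
                    last_key, last_sols = None, None
                    prev_states: dict[int, tuple] = {}
                    for k, tk in enumerate(eval_times):
                        if S_val[k] is None:
                            continue
                        nbh = self._neighborhood(eval_times, tk, d)
                        center = int(np.argmin(np.abs(eval_times[nbh] - tk)))
                        key = tuple(nbh)
                        if key != last_key:
                            S_list = [S_train_eval[i] for i in nbh]
                            chained = None
                            sols = []
                            for li, lam in enumerate(lambdas):
                                warm = _shift_warm(prev_states.get(li), nbh, len(S_list))
                                if warm is None:
                                    warm = chained
                                omegas, supports, state = self._admm(S_list, lam, warm, coarse=True)
                                prev_states[li] = (nbh, state)
                                chained = state
                                sols.append((omegas, supports))
                            last_key, last_sols = key, sols
                        for li, lam in enumerate(lambdas):
                            omegas, supports = last_sols[li]
                            # validation score on the refitted (unshrunk)
                            # support-constrained MLE of the training data
                            om_rf, ok, rf_state = support_constrained_mle(
                                S_train_eval[k],
                                supports[center],
                                max_iter=300,
                                warm=refit_states.get((di, li)),
                            )
                            if rf_state is not None:
                                refit_states[(di, li)] = rf_state
                            if ok:
                                sign, logdet = np.linalg.slogdet(om_rf)
                                score = (
                                    float(np.multiply(om_rf, S_val[k]).sum() - logdet)
                                    if sign > 0
                                    else np.inf
                                )
                            else:
                                score = np.inf
                            scores[hi, di, li, k] += score
                            fold_counts[hi, di, li, k] += 1
                            sup = np.triu(supports[center], k=1)
                            self._fold_edges[(hi, di, li, k, j)] = frozenset(
                                map(tuple, np.argwhere(sup))
                            )

        with np.errstate(divide="ignore", invalid="ignore"):
            total = np.where(fold_counts > 0, scores * (K / np.maximum(fold_counts, 1)), np.inf)
        self._grids = (h_grid, d_grid, lambdas)
        self._eval_times = eval_times
        self.cv_table_ = []
        for hi, di, li, k in itertools.product(
            range(len(h_grid)), range(len(d_grid)), range(len(lambdas)), range(n_eval)
        ):
            self.cv_table_.append(
                {
                    "time": float(eval_times[k]),
                    "h": h_grid[hi],
                    "d": d_grid[di],
                    "lambda": lambdas[li],
                    "cv_score": float(total[hi, di, li, k]),
                }
            )
        # the bandwidth h is selected globally (it carries no per-time
        # subscript): argmin over h of the total CV score after per-time
        # minimization over (d, lambda); then (d_k, lambda_k) per time at
        # that h, ties broken toward sparser models (larger lambda, then
        # smaller d)
        per_h_total = np.nansum(np.nanmin(np.nanmin(total, axis=1), axis=1), axis=1)
        hi_star = int(np.nanargmin(per_h_total))
        selection = []
        for k in range(n_eval):
            sub = total[hi_star, :, :, k]
            best = np.nanmin(sub)
            cands = np.argwhere(sub <= best + 1e-9)
            cands = sorted(
                (tuple(c) for c in cands),
                key=lambda c: (-lambdas[c[1]], d_grid[c[0]]),
            )
            di, li = cands[0]
            hi = hi_star
            selection.append(
                {
                    "hi": hi,
                    "di": di,
                    "li": li,
                    "h": h_grid[hi],
                    "d": d_grid[di],
                    "lambda": lambdas[li],
                    "cv_score": float(total[hi, di, li, k]),
                }
            )
        self.cv_selection_ = selection
        return selection

    def fit(self, X, pseudotime=None):
        """Fit the full series: CV selection, refit on all data, cv.vote.

        ``X`` is a :class:`BinnedExpression`, or a bins x genes array given
        ``pseudotime`` (the bin times).
        """
        if isinstance(X, BinnedExpression):
            binned = X
        else:
            X = np.asarray(X, float)
            if pseudotime is None:
                raise ValueError("pseudotime (bin times) required for array input")
            binned = BinnedExpression(
                X,
                np.asarray(pseudotime, float),
                [f"g{i + 1}" for i in range(X.shape[1])],
                [1] * X.shape[0],
            )
        selection = self.cross_validate(binned)
        values, times = binned.values, binned.bin_times
        genes = binned.gene_names
        h_grid, d_grid, lambdas = self._grids
        eval_times = self._eval_times
        K = self.cv_folds

        S_all_cache: dict[int, list[np.ndarray]] = {}
        refit_cache: dict = {}
        estimates = []
        for k, sel in enumerate(selection):
            hi, di, li = sel["hi"], sel["di"], sel["li"]
            h, d, lam = sel["h"], sel["d"], sel["lambda"]
            if hi not in S_all_cache:
                S_all_cache[hi] = [
                    kernel_covariance(values, times, t, h, self.kernel)
                    for t in eval_times
                ]
            nbh = self._neighborhood(eval_times, eval_times[k], d)
            center = int(np.argmin(np.abs(eval_times[nbh] - eval_times[k])))
            cache_key = (hi, tuple(nbh), lam)
            if cache_key in refit_cache:
                omegas, supports = refit_cache[cache_key]
            else:
                omegas, supports, _ = self._admm(
                    [S_all_cache[hi][i] for i in nbh], lam
                )
                refit_cache[cache_key] = (omegas, supports)
            om = omegas[center]
            refit_edges = frozenset(
                map(tuple, np.argwhere(np.triu(supports[center], k=1)))
            )
            fold_sets = [
                self._fold_edges.get((hi, di, li, k, j), frozenset()) for j in range(K)
            ]
            consensus = cv_vote(fold_sets, self.vote_threshold)
            final = refit_edges & consensus
            om_final = np.diag(np.diag(om))
            for i, jj in final:
                om_final[i, jj] = om[i, jj]
                om_final[jj, i] = om[jj, i]
            om_final = _ensure_pd(om_final)
            estimates.append(
                PrecisionEstimate(
                    time=float(eval_times[k]),
                    omega=om_final,
                    edge_set=frozenset(
                        (genes[i], genes[jj]) for i, jj in final
                    ),
                    selected_params=(h, d, lam),
                    cv_score=sel["cv_score"],
                )
            )
        self.series_ = NetworkSeries(estimates, genes)
        self.precisions_ = [e.omega for e in estimates]
        self.edge_sets_ = [e.edge_set for e in estimates]
        self.selected_params_ = [e.selected_params for e in estimates]
        self.cv_scores_ = np.array([e.cv_score for e in estimates])
        return self


def estimate_series(binned: BinnedExpression, **params) -> NetworkSeries:
    """Functional entry point: fit a :class:`TimeVaryingGraphicalLasso`."""
    est = TimeVaryingGraphicalLasso(**params)
    est.fit(binned)
    return est.series_
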