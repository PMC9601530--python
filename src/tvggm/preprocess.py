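"""Expression normalization, gene selection, and pseudo-time binning.

The estimator consumes per-bin mean expression: cells are ordered by
pseudo-time, partitioned into equal-count bins, and averaged, which tames the
dropout noise of single-cell data while preserving the time ordering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "BinnedExpression",
    "LogNormalizer",
    "PseudotimeBinner",
    "normalize_expression",
    "select_genes",
    "bin_cells",
]


@dataclass
class BinnedExpression:
    """Bins x genes mean expression with bin pseudo-times rescaled to [0, 1]."""

    values: np.ndarray  # (n_bins, n_genes)
    bin_times: np.ndarray  # (n_bins,), strictly increasing, in [0, 1]
    gene_names: list[str]
    n_cells_per_bin: list[int]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.bin_times = np.asarray(self.bin_times, dtype=float)
        if self.values.shape != (len(self.bin_times), len(self.gene_names)):
            raise ValueError("values shape inconsistent with bin_times/gene_names")
        if np.any(np.diff(self.bin_times) <= 0):
            raise ValueError("bin_times must be strictly increasing")
        if self.bin_times[0] < -1e-12 or self.bin_times[-1] > 1 + 1e-12:
            raise ValueError("bin_times must lie in [0, 1]")

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.gene_names)
        df.insert(0, "bin_time", self.bin_times)
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "BinnedExpression":
        df = pd.read_csv(path, sep="\t")
        times = df.pop("bin_time").to_numpy()
        return cls(df.to_numpy(), times, list(df.columns), [0] * len(times))


class LogNormalizer(BaseEstimator, TransformerMixin):
    """Total-count normalization to a fixed scale followed by log(1 + x).

    Each cell's counts are divided by the cell total, multiplied by ``scale``
    (10,000 by default), and log1p-transformed — the standard scRNA-seq
    normalization. Stateless; ``fit`` only validates input.
    """

    def __init__(self, scale: float = 1e4):
        self.scale = scale

    def fit(self, X, y=None):
        self._validate(np.asarray(self._values(X), dtype=float), X)
        return self

    def transform(self, X):
        vals = np.asarray(self._values(X), dtype=float)
        self._validate(vals, X)
        totals = vals.sum(axis=1, keepdims=True)
        out = np.log1p(vals / totals * self.scale)
        if isinstance(X, pd.DataFrame):
            return pd.DataFrame(out, index=X.index, columns=X.columns)
        return out

    @staticmethod
    def _values(X):
        return X.to_numpy() if isinstance(X, pd.DataFrame) else X

    @staticmethod
    def _validate(vals, X):
        if vals.ndim != 2:
            raise ValueError("expected a cells x genes matrix")
        if np.any(vals < 0):
            raise ValueError("counts must be nonnegative")
        zero = np.flatnonzero(vals.sum(axis=1) == 0)
        if zero.size:
            label = (
                X.index[zero[0]] if isinstance(X, pd.DataFrame) else f"row {zero[0]}"
            )
            raise ValueError(f"cell {label!r} has all-zero counts")


def normalize_expression(raw, scale: float = 1e4):
    """Functional form of :class:`LogNormalizer`."""
    return LogNormalizer(scale=scale).fit_transform(raw)


def select_genes(
    expr_genes,
    annotated=None,
    lineage_table: pd.DataFrame | None = None,
    sd_cutoff: float = 2.5,
) -> list[str]:
    """Union of curated genes and lineage-variable genes.

    Takes (a) an annotated gene list intersected with the expression matrix's
    genes and (b) genes of the lineage table (genes x lineages expression)
    whose across-lineage standard deviation exceeds ``sd_cutoff``. Order is
    preserved (annotated first), duplicates removed.
    """
    if isinstance(expr_genes, pd.DataFrame):
        expr_genes = list(expr_genes.columns)
    expr_set = set(expr_genes)
    selected: list[str] = []
    if annotated is not None:
        for g in annotated:
            if g in expr_set and g not in selected:
                selected.append(g)
    if lineage_table is not None and len(lineage_table):
        sds = lineage_table.std(axis=1, ddof=1)
        for g in lineage_table.index:
            if sds[g] > sd_cutoff and g in expr_set and g not in selected:
                selected.append(g)
    if not selected:
        raise ValueError("gene selection produced an empty set")
    return selected


class PseudotimeBinner(BaseEstimator, TransformerMixin):
    """Partition pseudo-time-ordered cells into equal-count bins and average.

    Cells are sorted by pseudo-time (ties broken by stable input order) and
    split into ``n_bins`` contiguous groups; the remainder is spread over the
    earliest bins. Each bin's value is the per-gene mean; each bin's time is
    the mean member pseudo-time, min-max rescaled so the full range maps onto
    [0, 1].
    """

    def __init__(self, n_bins: int = 25):
        self.n_bins = n_bins

    def fit(self, X, pseudotime=None):
        n_cells = X.shape[0]
        if self.n_bins < 2:
            raise ValueError("n_bins must be at least 2")
        if n_cells < self.n_bins:
            raise ValueError(f"{n_cells} cells cannot fill {self.n_bins} bins")
        pt = self._align_pseudotime(X, pseudotime)
        if not np.all(np.isfinite(pt)):
            raise ValueError("every cell needs a finite pseudo-time")
        order = np.argsort(pt, kind="stable")
        q, r = divmod(n_cells, self.n_bins)
        sizes = [q + 1] * r + [q] * (self.n_bins - r)
        bounds = np.cumsum([0] + sizes)
        self.bin_members_ = [
            order[bounds[b] : bounds[b + 1]] for b in range(self.n_bins)
        ]
        self.n_cells_per_bin_ = sizes
        raw_times = np.array([pt[m].mean() for m in self.bin_members_])
        span = raw_times[-1] - raw_times[0]
        if span <= 0:
            raise ValueError("degenerate pseudo-time range across bins")
        self.bin_times_ = (raw_times - raw_times[0]) / span
        return self

    def transform(self, X) -> BinnedExpression:
        vals = X.to_numpy() if isinstance(X, pd.DataFrame) else np.asarray(X, float)
        genes = (
            list(X.columns)
            if isinstance(X, pd.DataFrame)
            else [f"g{i + 1}" for i in range(vals.shape[1])]
        )
        means = np.stack([vals[m].mean(axis=0) for m in self.bin_members_])
        return BinnedExpression(means, self.bin_times_, genes, self.n_cells_per_bin_)

    def fit_transform(self, X, pseudotime=None, **fit_params) -> BinnedExpression:
        return self.fit(X, pseudotime=pseudotime).transform(X)

    @staticmethod
    def _align_pseudotime(X, pseudotime):
        if pseudotime is None:
            raise ValueError("pseudotime is required")
        if isinstance(pseudotime, pd.Series) and isinstance(X, pd.DataFrame):
            missing = X.index.difference(pseudotime.index)
            if len(missing):
                raise ValueError(f"missing pseudo-times for cells: {list(missing)[:5]}")
            return pseudotime.reindex(X.index).to_numpy(dtype=float)
        pt = np.asarray(pseudotime, dtype=float)
        if pt.shape[0] != X.shape[0]:
            raise ValueError("pseudotime length must match the number of cells")
        return pt


def bin_cells(expr, pseudotime, n_bins: int = 25) -> BinnedExpression:
    """Functional form of :class:`PseudotimeBinner`."""
    return PseudotimeBinner(n_bins=n_bins).fit_transform(expr, pseudotime=pseudotime)
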