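"""Significance matrices, PCA by SVD with imputation, and UPGMA clustering.

The central object is a regions x conditions matrix of -log10 p-values
with missing cells allowed.  Analyses follow the ClustVis-style recipe:
rows/columns with too many missing values are removed, each row variable
is centered and scaled to unit variance, principal components are
extracted by iteratively imputing missing cells from a low-rank SVD
reconstruction, and conditions are clustered by average linkage on the
Pearson correlation distance d = 1 - r.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .enrichment import P_FLOOR, EnrichmentResult


# ---------------------------------------------------------------------------
# significance matrix assembly and filtering


def build_significance_matrix(
    results_by_condition: Mapping[str, Sequence[EnrichmentResult]],
) -> pd.DataFrame:
    """Assemble -log10 p cells from per-condition enrichment batteries.

    Rows are region (set) labels, columns are conditions; a (region,
    condition) pair without a result becomes a missing cell, and duplicate
    pairs are an error.  P-values are floored at 1e-300 before the log.
    """
    cells: Dict[Tuple[str, str], float] = {}
    regions: List[str] = []
    for cond, results in results_by_condition.items():
        for r in results:
            key = (r.set_label, cond)
            if key in cells:
                raise ValueError(f"duplicate cell for region={r.set_label!r}, condition={cond!r}")
            cells[key] = -np.log10(max(r.p_value, P_FLOOR))
            if r.set_label not in regions:
                regions.append(r.set_label)
    conditions = list(results_by_condition)
    mat = pd.DataFrame(np.nan, index=regions, columns=conditions, dtype=float)
    for (region, cond), v in cells.items():
        mat.loc[region, cond] = v
    return mat


def filter_missing(m: pd.DataFrame, max_frac: float = 0.70) -> pd.DataFrame:
    """Keep only rows, then columns, with a missing fraction below ``max_frac``.

    The boundary is exclusive: a row exactly ``max_frac`` missing is
    dropped.  Dropped labels are reported via a warning and in
    ``result.attrs``.  Raises if nothing survives.
    """
    if not 0 < max_frac <= 1:
        raise ValueError("max_frac must lie in (0, 1]")
    row_frac = m.isna().mean(axis=1)
    keep_rows = row_frac < max_frac
    dropped_rows = list(m.index[~keep_rows])
    out = m.loc[keep_rows]
    if out.empty:
        raise ValueError("filter_missing: all rows dropped")
    col_frac = out.isna().mean(axis=0)
    keep_cols = col_frac < max_frac
    dropped_cols = list(out.columns[~keep_cols])
    out = out.loc[:, keep_cols]
    if out.shape[1] == 0:
        raise ValueError("filter_missing: all columns dropped")
    if dropped_rows or dropped_cols:
        warnings.warn(
            f"filter_missing: dropped rows {dropped_rows} and columns {dropped_cols}"
        )
    out = out.copy()
    out.attrs["dropped_rows"] = dropped_rows
    out.attrs["dropped_cols"] = dropped_cols
    return out


# ---------------------------------------------------------------------------
# scaling


def _axis_apply(m: pd.DataFrame, axis: str) -> pd.DataFrame:
    if axis not in ("rows", "columns"):
        raise ValueError(f"axis must be 'rows' or 'columns', got {axis!r}")
    return m if axis == "rows" else m.T


def scale_unit_variance(m: pd.DataFrame, axis: str = "rows") -> pd.DataFrame:
    """Center each axis vector and divide by its sample SD (ddof=1).

    Zero-variance vectors are dropped with a warning; missing cells stay
    missing.  Statistics use observed cells only.
    """
    work = _axis_apply(m, axis).copy()
    means = work.mean(axis=1, skipna=True)
    sds = work.std(axis=1, ddof=1, skipna=True)
    constant = (sds == 0) | sds.isna()
    if constant.any():
        warnings.warn(
            f"scale_unit_variance: dropped constant vectors {list(work.index[constant])}"
        )
        work = work.loc[~constant]
        means = means[~constant]
        sds = sds[~constant]
    scaled = work.sub(means, axis=0).div(sds, axis=0)
    return scaled if axis == "rows" else scaled.T


def zscore_matrix(m: pd.DataFrame, axis: str = "rows") -> pd.DataFrame:
    """Z-scores along an axis: (x - mean)/SD with sample SD.

    Constant vectors become all zeros (with a warning) rather than being
    dropped, so the output keeps the input's shape; missing cells are
    preserved.
    """
    work = _axis_apply(m, axis).copy()
    means = work.mean(axis=1, skipna=True)
    sds = work.std(axis=1, ddof=1, skipna=True)
    constant = (sds == 0) | sds.isna()
    if constant.any():
        warnings.warn(
            f"zscore_matrix: constant vectors set to zero: {list(work.index[constant])}"
        )
    safe_sds = sds.where(~constant, 1.0)
    z = work.sub(means, axis=0).div(safe_sds, axis=0)
    z.loc[constant] = z.loc[constant].where(z.loc[constant].isna(), 0.0)
    return z if axis == "rows" else z.T


# ---------------------------------------------------------------------------
# PCA by SVD with imputation


@dataclass
class PCAResult:
    """Scores, loadings and explained variance from SVD-with-imputation PCA.

    scores: conditions x components (projections of the observation
        columns); loadings: regions x components (Pearson correlation of
        each row variable with each score vector); variance_explained:
        percent of total variance per extracted component.
    """

    scores: pd.DataFrame
    loadings: pd.DataFrame
    variance_explained: np.ndarray
    n_iterations: int
    converged: bool
    completed: pd.DataFrame = field(repr=False, default=None)


def pca_svd_impute(
    m: pd.DataFrame,
    n_components: int | None = None,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> PCAResult:
    """PCA of a (scaled) variables x observations matrix with missing cells.

    Missing cells are initialized to zero (the row mean after centering)
    and repeatedly replaced by the rank-``n_components`` SVD
    reconstruction until their maximum relative change falls below
    ``tol`` or ``max_iter`` passes elapse; a complete matrix exits after
    one pass and equals a direct SVD PCA.  Variance percentages come from
    the squared singular values of the completed matrix.
    """
    X = m.to_numpy(dtype=float)
    p, q = X.shape
    max_rank = min(p, q)
    if n_components is None:
        n_components = max_rank
    if not 1 <= n_components <= max_rank:
        raise ValueError(
            f"n_components must lie in [1, {max_rank}], got {n_components}"
        )
    missing = np.isnan(X)
    filled = np.where(missing, 0.0, X)
    n_iter = 0
    converged = True
    if missing.any():
        converged = False
        prev = filled[missing]
        for n_iter in range(1, max_iter + 1):
            U, s, Vt = np.linalg.svd(filled, full_matrices=False)
            recon = (U[:, :n_components] * s[:n_components]) @ Vt[:n_components]
            filled = np.where(missing, recon, X)
            cur = filled[missing]
            denom = np.linalg.norm(prev)
            change = np.linalg.norm(cur - prev) / (denom if denom > 0 else 1.0)
            prev = cur
            if change < tol:
                converged = True
                break
        if not converged:
            warnings.warn(
                f"pca_svd_impute: imputation did not converge in {max_iter} iterations"
            )
    else:
        n_iter = 1
    U, s, Vt = np.linalg.svd(filled, full_matrices=False)
    total = float(np.sum(s**2))
    if total == 0:
        raise ValueError("pca_svd_impute: zero matrix has no principal components")
    comp_names = [f"PC{i + 1}" for i in range(n_components)]
    scores = pd.DataFrame(
        (Vt[:n_components].T * s[:n_components]),
        index=m.columns,
        columns=comp_names,
    )
    # loadings: correlation of each original row variable with each score vector
    load = np.empty((p, n_components))
    for i in range(p):
        row = filled[i]
        for c in range(n_components):
            sc = scores.iloc[:, c].to_numpy()
            denom = row.std(ddof=1) * sc.std(ddof=1)
            if denom == 0:
                load[i, c] = 0.0
            else:
                load[i, c] = float(np.cov(row, sc, ddof=1)[0, 1] / denom)
    loadings = pd.DataFrame(load, index=m.index, columns=comp_names)
    variance = 100.0 * (s[:n_components] ** 2) / total
    completed = pd.DataFrame(filled, index=m.index, columns=m.columns)
    return PCAResult(
        scores=scores,
        loadings=loadings,
        variance_explained=variance,
        n_iterations=n_iter,
        converged=converged,
        completed=completed,
    )


# ---------------------------------------------------------------------------
# UPGMA clustering with Pearson correlation distance


@dataclass
class Dendrogram:
    """UPGMA merge tree.

    ``merges`` lists (node_a, node_b, height, new_node) with leaves
    numbered 0..n-1 in label order and internal nodes from n upward;
    heights are the average-linkage merge distances and are non-decreasing.
    """

    labels: List[str]
    merges: List[Tuple[int, int, float, int]]

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def members(self) -> Dict[int, Set[int]]:
        """Leaf membership of every node id."""
        out: Dict[int, Set[int]] = {i: {i} for i in range(self.n_leaves)}
        for a, b, _, new in self.merges:
            out[new] = out[a] | out[b]
        return out

    def cut(self, k: int) -> List[Set[str]]:
        """Partition the leaves into ``k`` clusters by undoing the last merges."""
        n = self.n_leaves
        if not 1 <= k <= n:
            raise ValueError(f"cut: k must lie in [1, {n}], got {k}")
        alive: Dict[int, Set[int]] = {i: {i} for i in range(n)}
        for a, b, _, new in self.merges[: n - k]:
            alive[new] = alive.pop(a) | alive.pop(b)
        return sorted(
            ({self.labels[i] for i in mem} for mem in alive.values()),
            key=lambda s: min(s),
        )

    def to_newick(self) -> str:
        """Ultrametric Newick string; leaf-to-root depth is half the root height."""
        heights: Dict[int, float] = {i: 0.0 for i in range(self.n_leaves)}
        children: Dict[int, Tuple[int, int]] = {}
        root = self.n_leaves - 1 if not self.merges else self.merges[-1][3]
        for a, b, h, new in self.merges:
            heights[new] = h
            children[new] = (a, b)

        def render(node: int, parent_height: float) -> str:
            branch = (parent_height - heights[node]) / 2.0
            if node < self.n_leaves:
                return f"{self.labels[node]}:{branch:.10g}"
            a, b = children[node]
            inner = ",".join(render(c, heights[node]) for c in (a, b))
            return f"({inner}):{branch:.10g}"

        if not self.merges:
            return f"{self.labels[0]};"
        a, b = children[root]
        inner = ",".join(render(c, heights[root]) for c in (a, b))
        return f"({inner});"


def pearson_distance_matrix(m: pd.DataFrame, axis: str = "columns") -> pd.DataFrame:
    """Pairwise d = 1 - r over the chosen axis, pairwise-complete cells.

    A vector that is constant (or has fewer than two observed values) on
    the cells it shares with some partner has no defined correlation and
    raises an error naming it.
    """
    vectors = _axis_apply(m, axis)
    labels = list(vectors.index)
    n = len(labels)
    if n < 2:
        raise ValueError("need at least two vectors to compute distances")
    V = vectors.to_numpy(dtype=float)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = ~np.isnan(V[i]) & ~np.isnan(V[j])
            if both.sum() < 2:
                raise ValueError(
                    f"correlation undefined between {labels[i]!r} and {labels[j]!r}: "
                    f"fewer than 2 shared observed cells"
                )
            xi, xj = V[i][both], V[j][both]
            if xi.std() == 0 or xj.std() == 0:
                culprit = labels[i] if xi.std() == 0 else labels[j]
                raise ValueError(
                    f"correlation undefined: vector {culprit!r} is constant"
                )
            r = float(np.corrcoef(xi, xj)[0, 1])
            dist[i, j] = dist[j, i] = 1.0 - r
    return pd.DataFrame(dist, index=labels, columns=labels)


def upgma(dist: pd.DataFrame) -> Dendrogram:
    """Average-linkage agglomeration of a symmetric distance matrix.

    Cluster-to-cluster distance is the arithmetic mean of all cross-pair
    leaf distances, maintained by the Lance-Williams size-weighted update.
    Ties are broken deterministically by the lexicographically smallest
    member label of the candidate pair.
    """
    labels = list(dist.index)
    n = len(labels)
    if n < 2:
        raise ValueError("upgma: need at least 2 items")
    D: Dict[int, Dict[int, float]] = {
        i: {j: float(dist.iloc[i, j]) for j in range(n) if j != i} for i in range(n)
    }
    size = {i: 1 for i in range(n)}
    smallest = {i: labels[i] for i in range(n)}  # lexicographic tie-break key
    merges: List[Tuple[int, int, float, int]] = []
    active = set(range(n))
    next_id = n
    while len(active) > 1:
        best = None
        for i in sorted(active):
            for j in sorted(active):
                if j <= i:
                    continue
                d = D[i][j]
                lo, hi = sorted((smallest[i], smallest[j]))
                key = (d, lo, hi)
                if best is None or key < best[0]:
                    best = (key, i, j)
        (_, _, _), a, b = best  # type: ignore[misc]
        h = D[a][b]
        new = next_id
        next_id += 1
        D[new] = {}
        for other in active:
            if other in (a, b):
                continue
            d_new = (size[a] * D[a][other] + size[b] * D[b][other]) / (
                size[a] + size[b]
            )
            D[new][other] = d_new
            D[other][new] = d_new
        size[new] = size[a] + size[b]
        smallest[new] = min(smallest[a], smallest[b])
        active.discard(a)
        active.discard(b)
        active.add(new)
        merges.append((a, b, h, new))
    return Dendrogram(labels=labels, merges=merges)


def cluster_upgma_pearson(m: pd.DataFrame, axis: str = "columns") -> Dendrogram:
    """UPGMA dendrogram of the rows or columns of a data matrix.

    Distances are d = 1 - Pearson r on pairwise-complete cells; identical
    vectors therefore merge at height 0 and perfectly anti-correlated
    vectors sit at distance 2.
    """
    dist = pearson_distance_matrix(m, axis=axis)
    return upgma(dist)


def write_matrix_tsv(m: pd.DataFrame, path, index_label: str = "row") -> None:
    m.to_csv(path, sep="\t", index_label=index_label, float_format="%.6g", na_rep="")


def read_matrix_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0).astype(float)
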