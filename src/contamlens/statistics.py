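"""Statistical procedures: dilution GLM, blank concordance, NJ clustering.

* :func:`fit_dilution_glm` — binomial logistic regression of contaminant-hit
  frequency on ln(input mass).  Under the mass-competition model the hit
  fraction is c/(c+m), so logit(p) = ln c − ln m and the true slope on the
  natural-log mass scale is −1; the fitted slope and its Wald z quantify the
  inverse relationship between sample concentration and contamination.
* :func:`blank_concordance` — Pearson correlation of log(count+1) genus
  profiles between pooled positive and pooled blank (negative-control)
  libraries.
* :func:`neighbor_joining` / :func:`heatmap_matrix` — classical
  neighbor-joining over Euclidean distances between log-transformed count
  vectors, used to order heatmap rows and columns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DilutionObservation",
    "DilutionFit",
    "ConcordanceResult",
    "NJNode",
    "NJTree",
    "HeatmapResult",
    "fit_dilution_glm",
    "blank_concordance",
    "neighbor_joining",
    "heatmap_matrix",
]


@dataclass(frozen=True)
class DilutionObservation:
    """One library: contaminant hit count out of total reads at input mass (pg)."""

    sample_id: str
    contaminant_hits: int
    total_reads: int
    input_mass: float

    def __post_init__(self) -> None:
        if not (0 <= self.contaminant_hits <= self.total_reads):
            raise ValueError(f"{self.sample_id}: hits outside [0, total]")
        if self.input_mass <= 0:
            raise ValueError(f"{self.sample_id}: input mass must be positive")


@dataclass(frozen=True)
class DilutionFit:
    intercept: float
    slope: float
    se_intercept: float
    se_slope: float
    z: float
    p: float
    iterations: int
    converged: bool


@dataclass(frozen=True)
class ConcordanceResult:
    genera: tuple
    positive_log: np.ndarray
    blank_log: np.ndarray
    pearson_r: float
    defined: bool


def fit_dilution_glm(
    observations: Sequence[DilutionObservation],
    tol: float = 1e-8,
    max_iter: int = 100,
) -> DilutionFit:
    """Maximum-likelihood binomial logit regression on ln(input mass), by IRLS.

    Convergence is declared when the deviance changes by less than ``tol``;
    non-convergence (e.g. separation) yields ``converged=False`` rather than
    an exception.  Standard errors come from the observed information matrix
    and inference is Wald (z = slope/se, two-sided normal p).
    """
    if len({o.input_mass for o in observations}) < 2:
        raise ValueError("need observations at >= 2 distinct masses")
    y = np.array([o.contaminant_hits for o in observations], dtype=float)
    n = np.array([o.total_reads for o in observations], dtype=float)
    if (y == 0).all() or (y == n).all():
        raise ValueError("degenerate input: all counts 0 or all counts equal totals")
    x = np.log([o.input_mass for o in observations])
    X = np.column_stack([np.ones_like(x), x])

    # start from the empirically adjusted proportions
    mu = (y + 0.5) / (n + 1.0)
    eta = np.log(mu / (1 - mu))
    beta = np.zeros(2)
    dev_old = np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        mu = 1.0 / (1.0 + np.exp(-eta))
        mu = np.clip(mu, 1e-12, 1 - 1e-12)
        W = n * mu * (1 - mu)
        z = eta + (y - n * mu) / (n * mu * (1 - mu))
        XtW = X.T * W
        beta = np.linalg.solve(XtW @ X, XtW @ z)
        eta = X @ beta
        with np.errstate(divide="ignore", invalid="ignore"):
            p_hat = 1.0 / (1.0 + np.exp(-eta))
            p_hat = np.clip(p_hat, 1e-12, 1 - 1e-12)
            dev = 2 * np.sum(
                np.where(y > 0, y * np.log(y / (n * p_hat)), 0.0)
                + np.where(n - y > 0, (n - y) * np.log((n - y) / (n - n * p_hat)), 0.0)
            )
        if abs(dev - dev_old) < tol:
            converged = True
            break
        dev_old = dev
    mu = np.clip(1.0 / (1.0 + np.exp(-X @ beta)), 1e-12, 1 - 1e-12)
    W = n * mu * (1 - mu)
    cov = np.linalg.inv((X.T * W) @ X)
    se = np.sqrt(np.diag(cov))
    zstat = beta[1] / se[1]
    pval = 2 * stats.norm.sf(abs(zstat))
    return DilutionFit(
        intercept=float(beta[0]),
        slope=float(beta[1]),
        se_intercept=float(se[0]),
        se_slope=float(se[1]),
        z=float(zstat),
        p=float(pval),
        iterations=it,
        converged=converged,
    )


def blank_concordance(
    positive_counts: Mapping, blank_counts: Mapping, pseudocount: float = 1.0
) -> ConcordanceResult:
    """Pearson r between ln(count+pseudocount) genus vectors of two pools.

    The genus universe is the union of genera observed in either pool;
    absent genera count 0 (the pseudocount keeps them in the comparison).
    A constant vector leaves r undefined (NaN, ``defined=False``).
    """
    genera = tuple(sorted(set(positive_counts) | set(blank_counts)))
    if len(genera) < 2:
        raise ValueError("need at least 2 genera in the union")
    pos = np.log(np.array([positive_counts.get(g, 0) for g in genera], float) + pseudocount)
    blk = np.log(np.array([blank_counts.get(g, 0) for g in genera], float) + pseudocount)
    if np.ptp(pos) == 0 or np.ptp(blk) == 0:
        return ConcordanceResult(genera, pos, blk, float("nan"), defined=False)
    r = float(stats.pearsonr(pos, blk).statistic)
    return ConcordanceResult(genera, pos, blk, r, defined=True)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------


@dataclass
class NJNode:
    name: str | None = None
    children: list[tuple["NJNode", float]] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class NJTree:
    """Unrooted NJ tree, represented rooted at the final (trifurcating) join."""

    root: NJNode
    labels: list[str]

    def leaf_order(self) -> list[str]:
        """Leaf names in depth-first traversal order from the final join."""
        order: list[str] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                order.append(node.name)
            else:
                stack.extend(child for child, _ in reversed(node.children))
        return order

    def leaf_distances(self) -> pd.DataFrame:
        """Pairwise patristic (path-length) distances between leaves."""
        dists: dict[str, dict[str, float]] = {}

        def collect(node: NJNode) -> dict[str, float]:
            if node.is_leaf:
                return {node.name: 0.0}
            below: list[dict[str, float]] = []
            for child, bl in node.children:
                sub = collect(child)
                below.append({k: v + bl for k, v in sub.items()})
            for i in range(len(below)):
                for j in range(i + 1, len(below)):
                    for a, da in below[i].items():
                        for b, db in below[j].items():
                            dists.setdefault(a, {})[b] = da + db
                            dists.setdefault(b, {})[a] = da + db
            merged: dict[str, float] = {}
            for sub in below:
                merged.update(sub)
            return merged

        collect(self.root)
        mat = pd.DataFrame(0.0, index=self.labels, columns=self.labels)
        for a in self.labels:
            for b in self.labels:
                if a != b:
                    mat.loc[a, b] = dists[a][b]
        return mat

    def newick(self) -> str:
        def fmt(node: NJNode) -> str:
            if node.is_leaf:
                return node.name
            inner = ",".join(f"{fmt(c)}:{bl:.10g}" for c, bl in node.children)
            return f"({inner})"

        return fmt(self.root) + ";"


def neighbor_joining(
    dist: np.ndarray | pd.DataFrame, labels: Sequence[str] | None = None
) -> NJTree:
    """Classical neighbor joining (Saitou–Nei Q-criterion agglomeration).

    Ties in the Q matrix break toward the lowest index pair.  An additive
    (tree-metric) input is reconstructed exactly.  Raises for asymmetric
    input, a nonzero diagonal, or fewer than 3 leaves.
    """
    if isinstance(dist, pd.DataFrame):
        if labels is None:
            labels = [str(c) for c in dist.columns]
        D = dist.to_numpy(dtype=float)
    else:
        D = np.asarray(dist, dtype=float)
    m = D.shape[0]
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if m < 3:
        raise ValueError("neighbor joining requires >= 3 leaves")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(D), 0):
        raise ValueError("distance matrix diagonal must be zero")
    if labels is None:
        labels = [f"t{i}" for i in range(m)]
    labels = [str(l) for l in labels]

    D = D.copy()
    nodes: list[NJNode] = [NJNode(name=l) for l in labels]
    active = list(range(m))
    while len(active) > 3:
        k = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (k - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # lowest-index tie-break: first occurrence of the minimum in row-major order
        flat = int(np.argmin(Q))
        i, j = divmod(flat, k)
        if i > j:
            i, j = j, i
        dij = sub[i, j]
        li = dij / 2 + (r[i] - r[j]) / (2 * (k - 2))
        lj = dij - li
        new = NJNode(children=[(nodes[active[i]], li), (nodes[active[j]], lj)])
        # distances from the new node to the remaining taxa
        ai, aj = active[i], active[j]
        newd = np.zeros(D.shape[0] + 1)
        for t, at in enumerate(active):
            if t in (i, j):
                continue
            newd[at] = (sub[i, t] + sub[j, t] - dij) / 2
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :-1] = newd[:-1]
        D[:-1, -1] = newd[:-1]
        nodes.append(new)
        active = [a for a in active if a not in (ai, aj)] + [D.shape[0] - 1]
    # final trifurcation: standard 3-point formulas
    a, b, c = active
    dab, dac, dbc = D[a, b], D[a, c], D[b, c]
    la = (dab + dac - dbc) / 2
    lb = (dab + dbc - dac) / 2
    lc = (dac + dbc - dab) / 2
    root = NJNode(children=[(nodes[a], la), (nodes[b], lb), (nodes[c], lc)])
    return NJTree(root=root, labels=labels)


@dataclass
class HeatmapResult:
    matrix: pd.DataFrame  # ln(count+pseudocount), NJ-ordered when clustered
    row_tree: NJTree | None
    col_tree: NJTree | None
    clustered_rows: bool
    clustered_cols: bool
    dropped_columns: list


def heatmap_matrix(
    counts: pd.DataFrame,
    min_hits: int = 200,
    pseudocount: float = 1.0,
) -> HeatmapResult:
    """Log-transformed count matrix with NJ-ordered rows and columns.

    Columns (genomes) whose total across samples falls below ``min_hits``
    are dropped; remaining counts become ln(count+pseudocount); rows and
    columns are ordered by depth-first traversal of neighbor-joining trees
    over Euclidean distances between the transformed vectors.  With fewer
    than 3 rows or columns the corresponding axis is returned unclustered.
    """
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    keep = counts.columns[counts.sum(axis=0) >= min_hits]
    dropped = [c for c in counts.columns if c not in set(keep)]
    sub = counts[keep]
    mat = np.log(sub.astype(float) + pseudocount)

    def order_axis(frame: pd.DataFrame) -> tuple[list, NJTree | None, bool]:
        if frame.shape[0] < 3:
            return list(frame.index), None, False
        vecs = frame.to_numpy()
        d = np.sqrt(((vecs[:, None, :] - vecs[None, :, :]) ** 2).sum(axis=2))
        np.fill_diagonal(d, 0.0)
        tree = neighbor_joining(d, labels=[str(i) for i in frame.index])
        name_to_idx = {str(i): i for i in frame.index}
        return [name_to_idx[n] for n in tree.leaf_order()], tree, True

    row_order, row_tree, rows_ok = order_axis(mat)
    col_order, col_tree, cols_ok = order_axis(mat.T)
    mat = mat.loc[row_order, col_order]
    return HeatmapResult(
        matrix=mat,
        row_tree=row_tree,
        col_tree=col_tree,
        clustered_rows=rows_ok,
        clustered_cols=cols_ok,
        dropped_columns=dropped,
    )
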