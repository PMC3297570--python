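"""Weighted gene co-expression network construction and module detection.

The pipeline mirrors the standard WGCNA recipe: an unsigned soft-thresholded
adjacency ``a_ij = cor(x_i, x_j)^beta`` (beta = 6 by default, even, so the
sign of the correlation is immaterial), the topological overlap matrix

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij),
    l_ij = sum_{u != i,j} a_iu a_uj,

average-linkage hierarchical clustering of ``1 - TOM``, a dynamic-height
tree cut honouring a minimum module size and a deepSplit aggressiveness
level, and merging of modules whose eigengenes are closer than a cut
height.  Module eigengenes are the first principal component of the
standardized module submatrix, with the sign fixed so the eigengene
correlates nonnegatively with the module's mean expression profile.

Modules are named with the conventional colour labels ("turquoise",
"blue", ...) in decreasing size order; "grey" is reserved for unassigned
genes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy import stats

log = logging.getLogger(__name__)

UNASSIGNED = "grey"

# WGCNA-style colour sequence used to label modules by decreasing size
MODULE_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan", "midnightblue",
    "lightcyan", "grey60", "lightgreen", "lightyellow", "royalblue", "darkred",
    "darkgreen", "darkturquoise", "darkgrey", "orange", "darkorange", "white",
    "skyblue", "saddlebrown", "steelblue", "paleturquoise", "violet",
    "darkolivegreen", "darkmagenta",
]


@dataclass
class NetworkParams:
    """Tuning parameters; the defaults reproduce the published settings."""

    power: int = 6
    min_module_size: int = 30
    deep_split: int = 2
    merge_cut_height: float = 0.3
    top_edges: int = 150

    def __post_init__(self) -> None:
        if self.power <= 0 or self.power % 2:
            raise ValueError("power must be a positive even integer")
        if not 0 <= self.deep_split <= 4:
            raise ValueError("deep_split must be in 0..4")
        if not 0.0 <= self.merge_cut_height <= 1.0:
            raise ValueError("merge_cut_height must be in [0, 1]")


# ---------------------------------------------------------------------------
# probe collapse


def collapse_probes(expr: pd.DataFrame, annotation: pd.DataFrame, power: int = 6) -> pd.DataFrame:
    """Collapse a probe-level matrix to one row per gene.

    ``annotation`` has columns ``gene`` and ``refseq`` indexed by probe ID.
    Probes without a refSeq gene are dropped.  A gene with one probe passes
    through; with two probes the one with the higher mean is kept; with
    three or more the probe of highest whole-network connectivity (row sum
    of the soft adjacency over all retained probes) wins.
    """
    ann = annotation.loc[annotation.index.intersection(expr.index)]
    ann = ann[ann["refseq"].astype(bool)]
    expr = expr.loc[ann.index]

    multi = ann.groupby("gene").size()
    need_conn = multi[multi >= 3].index
    conn = None
    if len(need_conn) > 0:
        adj = soft_adjacency(expr.to_numpy(), power)
        conn = pd.Series(connectivity(adj), index=expr.index)

    keep: list[str] = []
    gene_of: list[str] = []
    for gene, probes in ann.groupby("gene").groups.items():
        probes = list(probes)
        if len(probes) == 1:
            best = probes[0]
        elif len(probes) == 2:
            means = expr.loc[probes].mean(axis=1)
            best = means.idxmax()
        else:
            best = conn.loc[probes].idxmax()
        keep.append(best)
        gene_of.append(gene)
    out = expr.loc[keep]
    out.index = gene_of
    return out.sort_index()


# ---------------------------------------------------------------------------
# adjacency / TOM


def soft_adjacency(X: np.ndarray, power: int = 6) -> np.ndarray:
    """Unsigned soft adjacency cor(x_i, x_j)^power with zero diagonal.

    Zero-variance genes get zero correlation with everything (logged).
    """
    X = np.asarray(X, dtype=float)
    sd = X.std(axis=1)
    dead = sd == 0
    if dead.any():
        log.warning("%d zero-variance genes: correlations set to 0", int(dead.sum()))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        cor = np.corrcoef(X)
    cor[dead, :] = 0.0
    cor[:, dead] = 0.0
    adj = np.abs(cor) ** power
    np.fill_diagonal(adj, 0.0)
    return adj


def connectivity(adjacency: np.ndarray) -> np.ndarray:
    """Whole-network connectivity k_i = sum_{j != i} a_ij."""
    a = np.asarray(adjacency, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    return a.sum(axis=1) - np.diag(a)


def tom(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap matrix; TOM_ii = 1, entries in [0, 1]."""
    a = np.asarray(adjacency, dtype=float).copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    l = a @ a  # diag(a)=0 so (a@a)_ij = sum_{u != i,j} a_iu a_uj for i != j
    kmin = np.minimum.outer(k, k)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (l + a) / (kmin + 1.0 - a)
    t = np.nan_to_num(t, nan=0.0)
    np.fill_diagonal(t, 1.0)
    return np.clip(t, 0.0, 1.0)


def tom_dissimilarity(adjacency: np.ndarray) -> np.ndarray:
    d = 1.0 - tom(adjacency)
    np.fill_diagonal(d, 0.0)
    return d


# ---------------------------------------------------------------------------
# clustering and tree cut

# deepSplit 0..4 -> fraction of the dendrogram height range at which the
# static cut is placed; higher deepSplit cuts lower (more, smaller branches)
_DEEP_SPLIT_FRACTION = {0: 0.95, 1: 0.90, 2: 0.85, 3: 0.75, 4: 0.65}


def cluster_and_cut(
    diss: np.ndarray,
    params: NetworkParams,
    gene_ids: list[str] | None = None,
) -> tuple[np.ndarray, pd.Series]:
    """Average-linkage dendrogram plus a dynamic-height module cut.

    The cut height is ``h_min + f * (h_max - h_min)`` over the merge
    heights, with the fraction ``f`` looked up from ``deep_split`` (a
    documented constant table, higher deepSplit cutting deeper).  Branches
    below the cut with at least ``min_module_size`` leaves become modules,
    labelled by colour in decreasing size order; all other genes are
    "grey"/unassigned.

    Returns the scipy linkage matrix and a gene -> label Series.
    """
    d = np.asarray(diss, dtype=float)
    n = d.shape[0]
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(n)]
    if n < params.min_module_size:
        labels = pd.Series(UNASSIGNED, index=gene_ids)
        if n < 2:
            return np.empty((0, 4)), labels
        Z = hierarchy.linkage(squareform(d, checks=False), method="average")
        return Z, labels

    Z = hierarchy.linkage(squareform(d, checks=False), method="average")
    heights = Z[:, 2]
    cut = heights.min() + _DEEP_SPLIT_FRACTION[params.deep_split] * (
        heights.max() - heights.min()
    )
    raw = hierarchy.fcluster(Z, t=cut, criterion="distance")

    sizes = pd.Series(raw).value_counts()
    good = sizes[sizes >= params.min_module_size].index
    # colour labels by decreasing size, ties broken by cluster id for determinism
    order = sorted(good, key=lambda c: (-sizes[c], c))
    color_of = {c: MODULE_COLORS[i % len(MODULE_COLORS)] for i, c in enumerate(order)}
    labels = pd.Series(
        [color_of.get(c, UNASSIGNED) for c in raw], index=gene_ids, name="module"
    )
    return Z, labels


# ---------------------------------------------------------------------------
# eigengenes


def module_eigengene(X: np.ndarray) -> tuple[np.ndarray, float]:
    """First principal component over samples of a standardized module submatrix.

    Rows are genes (>= 1), columns samples.  Returns the unit-norm eigengene
    and the fraction of variance it explains.  The sign is fixed so the
    eigengene correlates nonnegatively with the module's mean expression
    profile.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 1:
        raise ValueError("module submatrix must be 2-D with at least one gene")
    sd = X.std(axis=1, ddof=0)
    sd[sd == 0] = 1.0
    Z = (X - X.mean(axis=1, keepdims=True)) / sd[:, None]
    # SVD of genes x samples: right singular vectors live in sample space
    _, s, vt = np.linalg.svd(Z, full_matrices=False)
    e = vt[0]
    var_explained = float(s[0] ** 2 / (s**2).sum()) if s.sum() > 0 else 0.0
    mean_profile = X.mean(axis=0)
    if mean_profile.std() > 0 and e.std() > 0:
        flip = np.corrcoef(e, mean_profile)[0, 1] < 0
    else:
        flip = e.sum() < 0
    if flip:
        e = -e
    return e / np.linalg.norm(e), var_explained


def eigengene_set(expr: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Eigengenes for every assigned module: samples x modules DataFrame.

    Column order is decreasing module size.  ``.attrs['var_explained']``
    carries the per-module variance-explained fractions.
    """
    modules = [
        m for m in labels.value_counts().index if m != UNASSIGNED
    ]
    cols = {}
    varexp = {}
    for m in modules:
        genes = labels.index[labels == m]
        e, v = module_eigengene(expr.loc[genes].to_numpy())
        cols[m] = e
        varexp[m] = v
    out = pd.DataFrame(cols, index=expr.columns)
    out.attrs["var_explained"] = varexp
    return out


def module_membership(expr: pd.DataFrame, eigengenes: pd.DataFrame) -> pd.DataFrame:
    """kME table: correlation of every gene with every module eigengene."""
    X = expr.to_numpy(dtype=float)
    E = eigengenes.to_numpy(dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)
    Ec = E - E.mean(axis=0, keepdims=True)
    xs = Xc.std(axis=1)
    dead = xs == 0
    if dead.any():
        log.warning("%d zero-variance genes: kME set to 0", int(dead.sum()))
    xs[dead] = 1.0
    es = Ec.std(axis=0)
    kme = (Xc @ Ec) / X.shape[1] / np.outer(xs, es)
    kme[dead, :] = 0.0
    return pd.DataFrame(
        np.clip(kme, -1.0, 1.0), index=expr.index, columns=eigengenes.columns
    )


def merge_modules(
    expr: pd.DataFrame, labels: pd.Series, merge_cut_height: float = 0.3
) -> pd.Series:
    """Iteratively merge module pairs with eigengene dissimilarity below the cut.

    Dissimilarity is ``1 - cor(E_a, E_b)``.  After each merge the combined
    module keeps the larger member's label and eigengenes are recomputed,
    until no pair qualifies.
    """
    labels = labels.copy()
    while True:
        eg = eigengene_set(expr, labels)
        if eg.shape[1] < 2:
            return labels
        cor = np.corrcoef(eg.to_numpy().T)
        diss = 1.0 - cor
        np.fill_diagonal(diss, np.inf)
        i, j = np.unravel_index(np.argmin(diss), diss.shape)
        if diss[i, j] >= merge_cut_height:
            return labels
        a, b = eg.columns[i], eg.columns[j]
        keep, drop = (a, b) if (labels == a).sum() >= (labels == b).sum() else (b, a)
        labels[labels == drop] = keep


# ---------------------------------------------------------------------------
# hub graphs


def top_connections(
    tom_matrix: np.ndarray,
    gene_ids: list[str],
    module_genes: list[str],
    top_edges: int = 150,
    n_hubs: int = 50,
) -> tuple[pd.DataFrame, list[str]]:
    """Strongest within-module TOM edges and the hub genes of that subgraph.

    Returns the edge list (gene_a, gene_b, weight) sorted by weight
    descending (ties broken by the lexicographic gene-ID pair, so the
    result is deterministic) and the ``n_hubs`` highest-degree nodes within
    the listed edges (ties again by gene ID).
    """
    idx = {g: i for i, g in enumerate(gene_ids)}
    mg = sorted(module_genes)
    if len(mg) < 2:
        raise ValueError("module must have at least 2 genes")
    rows = []
    for ai in range(len(mg)):
        for bi in range(ai + 1, len(mg)):
            a, b = mg[ai], mg[bi]
            rows.append((a, b, float(tom_matrix[idx[a], idx[b]])))
    edges = pd.DataFrame(rows, columns=["gene_a", "gene_b", "weight"])
    edges = edges.sort_values(
        ["weight", "gene_a", "gene_b"], ascending=[False, True, True]
    ).head(top_edges)
    degree = pd.concat([edges["gene_a"], edges["gene_b"]]).value_counts()
    hub_rank = degree.sort_index().sort_values(ascending=False, kind="stable")
    hubs = hub_rank.head(n_hubs).index.tolist()
    return edges.reset_index(drop=True), hubs


# ---------------------------------------------------------------------------
# region profiles


def region_profile(
    eigengenes: pd.DataFrame, metadata: pd.DataFrame, top_n: int = 10
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Per-region eigengene means and the top regions of each module."""
    meta = metadata.loc[eigengenes.index]
    means = eigengenes.groupby(meta["region"]).mean()
    top = {
        m: means[m].sort_values(ascending=False).head(top_n).index.tolist()
        for m in eigengenes.columns
    }
    return means, top


def select_representative_regions(profiles: pd.DataFrame, n: int = 100) -> list[str]:
    """Greedy representative-region choice.

    Start from the region whose profile (eigengene values across modules)
    has the highest standard deviation; then repeatedly add the region with
    the lowest maximal r-squared against the regions already chosen.
    """
    regions = list(profiles.index)
    if n >= len(regions):
        return regions
    P = profiles.to_numpy(dtype=float)
    chosen = [int(np.argmax(P.std(axis=1)))]
    remaining = [i for i in range(len(regions)) if i != chosen[0]]
    while len(chosen) < n:
        best, best_score = None, np.inf
        for i in remaining:
            r2s = []
            for j in chosen:
                with np.errstate(invalid="ignore"):
                    r = np.corrcoef(P[i], P[j])[0, 1]
                r2s.append(0.0 if np.isnan(r) else r * r)
            score = max(r2s)
            if score < best_score:
                best, best_score = i, score
        chosen.append(best)
        remaining.remove(best)
    return [regions[i] for i in chosen]


# ---------------------------------------------------------------------------
# cross-dataset concordance


def dataset_concordance(
    exprA: pd.DataFrame, exprB: pd.DataFrame, power: int = 6
) -> tuple[float, float]:
    """Agreement of two expression datasets over their shared genes.

    Returns (r_expression, r_connectivity): the correlation of per-gene
    mean expression ranks and the correlation of per-gene whole-network
    connectivity between the datasets.
    """
    shared = exprA.index.intersection(exprB.index)
    if len(shared) < 3:
        raise ValueError("need at least 3 shared genes")
    A = exprA.loc[shared]
    B = exprB.loc[shared]
    rank_a = stats.rankdata(A.mean(axis=1))
    rank_b = stats.rankdata(B.mean(axis=1))
    r_expr = float(np.corrcoef(rank_a, rank_b)[0, 1])
    ka = connectivity(soft_adjacency(A.to_numpy(), power))
    kb = connectivity(soft_adjacency(B.to_numpy(), power))
    r_conn = float(np.corrcoef(ka, kb)[0, 1])
    return r_expr, r_conn


# ---------------------------------------------------------------------------
# full pipeline


def build_network(
    expr: pd.DataFrame, params: NetworkParams | None = None
) -> dict:
    """Expression -> adjacency -> TOM -> modules -> merged modules -> eigengenes.

    Returns a dict with keys ``adjacency``, ``tom``, ``linkage``,
    ``labels`` (after merging), ``eigengenes`` and ``kme``.
    """
    params = params or NetworkParams()
    adj = soft_adjacency(expr.to_numpy(), params.power)
    t = tom(adj)
    d = 1.0 - t
    np.fill_diagonal(d, 0.0)
    Z, labels = cluster_and_cut(d, params, list(expr.index))
    if (labels != UNASSIGNED).any():
        labels = merge_modules(expr, labels, params.merge_cut_height)
    eg = eigengene_set(expr, labels)
    kme = module_membership(expr, eg) if eg.shape[1] else pd.DataFrame(index=expr.index)
    return {
        "adjacency": adj,
        "tom": t,
        "linkage": Z,
        "labels": labels,
        "eigengenes": eg,
        "kme": kme,
    }
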