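"""Gene-set enrichment of network modules by relative risk.

The central statistic is the relative risk of a gene set in a module,

    RR = (m_k / n_k) / (M / N),

the set's frequency among the module's ``n_k`` genes relative to its
frequency among all ``N`` network genes (the set is always intersected with
the universe first).  p-values come from permutation (random modules of the
same size), standard errors from bootstrap resampling of the module's
genes, and a rank-concentration check asks whether the overlapping genes
are drawn from the top of a cell-type specificity ranking.  A global
distribution test asks whether a set is spread non-randomly over the whole
partition, and the CNV burden replaces gene counts with base pairs covered,
correcting for gene length.

All permutation p-values use the (k+1)/(n+1) estimator and never return 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import UNASSIGNED


@dataclass
class RRResult:
    module: str
    set_name: str
    m_k: int
    n_k: int
    M: int
    N: int
    rr: float
    perm_p: float | None = None
    boot_se: float | None = None


def relative_risk(
    module_genes, gene_set, universe, module: str = "module", set_name: str = "set"
) -> RRResult:
    """RR of ``gene_set`` in ``module_genes`` against ``universe``."""
    uni = set(universe)
    mod = set(module_genes)
    if not mod <= uni:
        raise ValueError("module must be a subset of the universe")
    s = set(gene_set) & uni
    if not mod:
        raise ValueError("empty module")
    if not s:
        raise ValueError("gene set has no members in the universe")
    m_k = len(mod & s)
    rr = (m_k / len(mod)) / (len(s) / len(uni))
    return RRResult(module, set_name, m_k, len(mod), len(s), len(uni), rr)


def rr_permutation_p(
    module_genes, gene_set, universe, n_perm: int = 10_000, seed: int = 0
) -> RRResult:
    """Permutation p-value: random modules of the same size from the universe."""
    res = relative_risk(module_genes, gene_set, universe)
    rng = np.random.default_rng(seed)
    # RR is monotone in the overlap count at fixed sizes, so compare overlaps;
    # the overlap of a random same-size module is hypergeometric, which lets
    # the permutation null be sampled without materialising gene draws
    perm_overlap = rng.hypergeometric(res.M, res.N - res.M, res.n_k, n_perm)
    exceed = int((perm_overlap >= res.m_k).sum())
    res.perm_p = (exceed + 1) / (n_perm + 1)
    return res


def rr_bootstrap_se(
    module_genes, gene_set, universe, n_boot: int = 1000, seed: int = 0
) -> float:
    """Bootstrap SE of RR over resamples (with replacement) of the module's genes."""
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    mod = sorted(set(module_genes))
    if len(mod) < 2:
        raise ValueError("module of fewer than 2 genes has no bootstrap SE")
    uni = set(universe)
    s = set(gene_set) & uni
    base_rate = len(s) / len(uni)
    rng = np.random.default_rng(seed)
    in_set = np.array([g in s for g in mod])
    n_k = len(mod)
    rrs = np.empty(n_boot)
    for b in range(n_boot):
        pick = rng.integers(0, n_k, n_k)
        rrs[b] = (in_set[pick].mean()) / base_rate
    return float(rrs.std(ddof=1))


def rank_concentration(ranks, n_bins: int = 10) -> tuple[float, float]:
    """Are the overlapping genes concentrated at the top of a ranking?

    Histograms the rank scores of the set members found in a module into
    ``n_bins`` equal-width bins and returns the Pearson correlation (and
    two-sided p) between each bin's median rank and its count.  A strong
    negative correlation means the low (top) ranks dominate.
    """
    from scipy import stats

    ranks = np.asarray(ranks, dtype=float)
    if (ranks <= 0).any():
        raise ValueError("ranks must be positive")
    edges = np.linspace(ranks.min(), ranks.max(), n_bins + 1)
    idx = np.clip(np.digitize(ranks, edges[1:-1]), 0, n_bins - 1)
    medians, counts = [], []
    for b in range(n_bins):
        in_bin = ranks[idx == b]
        if len(in_bin):
            medians.append(np.median(in_bin))
            counts.append(len(in_bin))
    if len(counts) < 3:
        raise ValueError("need at least 3 non-empty bins")
    if len(set(counts)) == 1:  # perfectly flat histogram: no concentration
        return 0.0, 1.0
    r, p = stats.pearsonr(medians, counts)
    return float(r), float(p)


def global_distribution_test(
    labels: pd.Series, gene_set, n_perm: int = 10_000, seed: int = 0
) -> tuple[float, float]:
    """Is a gene set distributed non-randomly over the module partition?

    The statistic is the chi-square of the modules x (in-set / out-of-set)
    contingency table; the null permutes set membership over the gene
    universe.  Returns (statistic, permutation p).
    """
    uni = np.array(labels.index)
    in_set = np.isin(uni, np.array(sorted(set(gene_set))))
    if in_set.sum() == 0:
        raise ValueError("gene set has no members in the universe")
    lab = labels.to_numpy()
    cats, inv = np.unique(lab, return_inverse=True)
    n_mod = len(cats)
    n_per_mod = np.bincount(inv, minlength=n_mod)
    M, N = int(in_set.sum()), len(uni)

    exp_in = n_per_mod * (M / N)
    exp_out = n_per_mod * (1 - M / N)

    def chi2(obs_in: np.ndarray) -> np.ndarray:
        obs_out = n_per_mod - obs_in
        with np.errstate(invalid="ignore", divide="ignore"):
            t = (obs_in - exp_in) ** 2 / exp_in + (obs_out - exp_out) ** 2 / exp_out
        return np.nansum(t, axis=-1)

    observed = float(chi2(np.bincount(inv[in_set], minlength=n_mod)))
    rng = np.random.default_rng(seed)
    # permuting set membership over genes makes the per-module in-set counts
    # multivariate hypergeometric, so the null is sampled directly
    perm_counts = rng.multivariate_hypergeometric(n_per_mod, M, size=n_perm)
    exceed = int((chi2(perm_counts) >= observed).sum())
    return observed, (exceed + 1) / (n_perm + 1)


# ---------------------------------------------------------------------------
# CNV length-corrected burden


def _union_coverage(starts: np.ndarray, ends: np.ndarray) -> list[tuple[int, int]]:
    """Union of half-open intervals as a sorted disjoint list."""
    order = np.argsort(starts)
    merged: list[tuple[int, int]] = []
    for s, e in zip(starts[order], ends[order]):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((int(s), int(e)))
    return merged


def _covered_bp(gene_start: int, gene_end: int, cover: list[tuple[int, int]]) -> int:
    total = 0
    for s, e in cover:
        if e <= gene_start:
            continue
        if s >= gene_end:
            break
        total += min(e, gene_end) - max(s, gene_start)
    return total


def cnv_length_rr(
    cnv: pd.DataFrame, intervals: pd.DataFrame, labels: pd.Series
) -> pd.Series:
    """Length-corrected CNV relative risk per module.

    ``rr_k = (C_k / L_k) / (C / L)`` where ``C_k`` is the number of base
    pairs of module-k gene bodies covered by at least one CNV event
    (coverage via interval union, so duplicated or abutting events never
    double-count), ``L_k`` the total module gene length, and C, L the
    network-wide analogues.  Unassigned genes contribute to C and L but get
    no RR of their own.
    """
    if len(cnv) == 0:
        raise ValueError("empty CNV set")
    missing = set(labels.index) - set(intervals.index)
    if missing:
        raise ValueError(f"no intervals for {len(missing)} partitioned genes")
    cover_by_chrom = {
        chrom: _union_coverage(grp["start"].to_numpy(), grp["end"].to_numpy())
        for chrom, grp in cnv.groupby("chrom")
    }
    genes = intervals.loc[labels.index]
    lengths = (genes["end"] - genes["start"]).to_numpy(dtype=float)
    covered = np.array(
        [
            _covered_bp(int(r.start), int(r.end), cover_by_chrom.get(r.chrom, []))
            for r in genes.itertuples()
        ],
        dtype=float,
    )
    C, L = covered.sum(), lengths.sum()
    out = {}
    for mod in labels.unique():
        if mod == UNASSIGNED:
            continue
        mask = (labels == mod).to_numpy()
        C_k, L_k = covered[mask].sum(), lengths[mask].sum()
        out[mod] = (C_k / L_k) / (C / L)
    return pd.Series(out, name="cnv_rr").sort_index()


def cross_network_overlap(
    labels_a: pd.Series,
    labels_b: pd.Series,
    n_perm: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Overlap of two module partitions on their shared gene universe.

    Each module of partition B is treated as a gene set and tested for
    relative risk in each module of partition A.  Returns a long-form
    DataFrame (module_a, module_b, rr, perm_p).
    """
    shared = labels_a.index.intersection(labels_b.index)
    if len(shared) == 0:
        raise ValueError("no shared genes between partitions")
    la, lb = labels_a.loc[shared], labels_b.loc[shared]
    rows = []
    for i, ma in enumerate(m for m in la.unique() if m != UNASSIGNED):
        mod = la.index[la == ma]
        for mb in (m for m in lb.unique() if m != UNASSIGNED):
            s = lb.index[lb == mb]
            res = rr_permutation_p(mod, s, shared, n_perm=n_perm, seed=seed + i)
            rows.append((ma, mb, res.rr, res.perm_p))
    return pd.DataFrame(rows, columns=["module_a", "module_b", "rr", "perm_p"])
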