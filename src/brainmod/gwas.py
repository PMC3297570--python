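"""GSEA-style enrichment of modules for low GWAS p-values.

Each gene receives the minimum p-value of the SNPs inside its strand-
extended region (gene body plus 20 kb upstream and 10 kb downstream by
default).  Genes are ranked by ``-log10(min p)`` and a weighted
Kolmogorov-Smirnov-like running sum is computed for a module: module genes
("hits") step the sum up by their weight share, other genes step it down by
``1/(N - N_H)``; the enrichment score (ES) is the maximum of the running
sum, and the module genes at or before the argmax are the leading edge.

Significance comes from permuting module membership uniformly over the
genes that carry a statistic.  Each gene keeps its own min-p (and hence its
SNP-count advantage) in the null, which is what corrects for gene size.
Permutation stops adaptively: after ``stop_count`` null scores at least as
large as the observed one, or after ``max_perm`` permutations, with
``p = (k+1)/(n+1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


def map_snps_to_genes(
    gwas: pd.DataFrame,
    intervals: pd.DataFrame,
    up: int = 20_000,
    down: int = 10_000,
    strand_aware: bool = True,
) -> pd.DataFrame:
    """Per-gene min p and SNP count over strand-extended gene regions.

    ``gwas`` needs columns snp/chrom/bp/p; ``intervals`` is indexed by gene
    with chrom/start/end/strand (half-open coordinates).  A + strand gene
    [start, end) maps to [start-up, end+down); a - strand gene to
    [start-down, end+up).  With ``strand_aware=False`` both ends are
    extended by ``max(up, down)``.  A SNP inside several regions counts for
    every one of them.  Genes with no SNP are absent from the output.
    """
    out_rows = []
    for chrom, snps in gwas.groupby("chrom"):
        pos = snps["bp"].to_numpy()
        order = np.argsort(pos)
        pos = pos[order]
        pvals = snps["p"].to_numpy()[order]
        genes = intervals[intervals["chrom"] == chrom]
        for g in genes.itertuples():
            if not strand_aware:
                ext = max(up, down)
                lo, hi = g.start - ext, g.end + ext
            elif g.strand == "+":
                lo, hi = g.start - up, g.end + down
            else:
                lo, hi = g.start - down, g.end + up
            i, j = np.searchsorted(pos, lo), np.searchsorted(pos, hi)
            if j > i:
                out_rows.append((g.Index, j - i, float(pvals[i:j].min())))
    return (
        pd.DataFrame(out_rows, columns=["gene", "n_snps", "min_p"])
        .set_index("gene")
        .sort_index()
    )


@dataclass
class EnrichmentScore:
    es: float
    running_sum: np.ndarray
    ranked_genes: list[str]
    is_hit: np.ndarray
    argmax: int


def _ranked(gene_stats: pd.DataFrame) -> tuple[list[str], np.ndarray]:
    """Genes sorted by -log10(min_p) descending (ties by gene ID) + weights."""
    w = -np.log10(gene_stats["min_p"])
    order = sorted(gene_stats.index, key=lambda g: (-w[g], g))
    return order, w.loc[order].to_numpy()


def enrichment_score(
    gene_stats: pd.DataFrame, module_genes, weighted: bool = True
) -> EnrichmentScore:
    """Running-sum enrichment score of a module in the ranked gene list."""
    module = set(module_genes) & set(gene_stats.index)
    if not module:
        raise ValueError("module has no genes with GWAS statistics")
    ranked, weights = _ranked(gene_stats)
    is_hit = np.array([g in module for g in ranked])
    rs = _running_sum(weights, is_hit, weighted)
    arg = int(np.argmax(rs))
    return EnrichmentScore(float(rs[arg]), rs, ranked, is_hit, arg)


def _running_sum(weights: np.ndarray, is_hit: np.ndarray, weighted: bool) -> np.ndarray:
    n = len(weights)
    n_hit = int(is_hit.sum())
    if n_hit in (0, n):
        raise ValueError("module must be a proper nonempty subset of ranked genes")
    w = np.where(is_hit, weights if weighted else 1.0, 0.0)
    total = w.sum()
    step = np.where(is_hit, w / total, -1.0 / (n - n_hit))
    return np.cumsum(step)


def _es_only(weights: np.ndarray, is_hit: np.ndarray, weighted: bool) -> float:
    """ES without materialising the trace (used in the permutation loop)."""
    hits = np.flatnonzero(is_hit)
    w = weights[hits] if weighted else np.ones(len(hits))
    cum_hit = np.cumsum(w) / w.sum()
    miss_before = hits + 1 - np.arange(1, len(hits) + 1)
    down = miss_before / (len(weights) - len(hits))
    # the running sum is maximal immediately after some hit
    return float(np.max(cum_hit - down))


def adaptive_perm_p(
    gene_stats: pd.DataFrame,
    module_genes,
    max_perm: int = 100_000,
    stop_count: int = 20,
    seed: int = 0,
    weighted: bool = True,
) -> tuple[float, dict]:
    """Adaptive permutation p-value for the enrichment score.

    Module membership is reassigned uniformly at random among the genes
    carrying statistics; ties with the observed score count as exceedances.
    Returns ``(p, counters)`` with counters ``n_perms_run``,
    ``n_exceedances`` and the observed ``es``.
    """
    obs = enrichment_score(gene_stats, module_genes, weighted)
    ranked, weights = obs.ranked_genes, None
    _, weights = _ranked(gene_stats)
    n = len(ranked)
    n_hit = int(obs.is_hit.sum())
    rng = np.random.default_rng(seed)
    exceed = 0
    run = 0
    is_hit = np.zeros(n, dtype=bool)
    while run < max_perm and exceed < stop_count:
        is_hit[:] = False
        is_hit[rng.choice(n, n_hit, replace=False)] = True
        if _es_only(weights, is_hit, weighted) >= obs.es:
            exceed += 1
        run += 1
    return (exceed + 1) / (run + 1), {
        "n_perms_run": run,
        "n_exceedances": exceed,
        "es": obs.es,
    }


def leading_edge(score: EnrichmentScore) -> list[str]:
    """Module genes ranked at or before the running sum's maximum."""
    return [
        g
        for g, hit in zip(score.ranked_genes[: score.argmax + 1], score.is_hit)
        if hit
    ]


def genewide_p(min_p: float, n_snps: int) -> float:
    """Gene-wide p: Bonferroni over the gene's SNPs, min(1, min_p * n_snps)."""
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    return min(1.0, min_p * n_snps)


def combine_pvalues(pvals) -> float:
    """Fisher's method: -2 sum(ln p) against chi-square with 2k df."""
    p = np.asarray(pvals, dtype=float)
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    stat, combined = stats.combine_pvalues(p, method="fisher")
    return float(combined)


def bonferroni(p: float, m: int) -> float:
    """Bonferroni correction over m tests, capped at 1."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return min(1.0, p * m)


def enrichment_vs_rare_correlation(rare_rr, neglog_enrich_p) -> tuple[float, float]:
    """Pearson correlation between per-module rare-variant RR and GWAS
    enrichment (-log10 p), with its two-sided p-value."""
    x = np.asarray(rare_rr, dtype=float)
    y = np.asarray(neglog_enrich_p, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need two equal-length vectors over >= 3 modules")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


@dataclass
class ModuleEnrichment:
    module: str
    es: float
    perm_p: float
    n_perms_run: int
    n_exceedances: int
    leading_edge: list[str] = field(default_factory=list)


def module_enrichment_table(
    gene_stats: pd.DataFrame,
    labels: pd.Series,
    max_perm: int = 100_000,
    stop_count: int = 20,
    seed: int = 0,
    weighted: bool = True,
) -> pd.DataFrame:
    """Enrichment of every assigned module, with leading-edge genes."""
    from .network import UNASSIGNED

    rows = []
    modules = [m for m in labels.unique() if m != UNASSIGNED]
    for i, mod in enumerate(sorted(modules)):
        genes = labels.index[labels == mod]
        score = enrichment_score(gene_stats, genes, weighted)
        p, counters = adaptive_perm_p(
            gene_stats, genes, max_perm, stop_count, seed + i, weighted
        )
        rows.append(
            {
                "module": mod,
                "es": score.es,
                "perm_p": p,
                "n_perms_run": counters["n_perms_run"],
                "n_exceedances": counters["n_exceedances"],
                "leading_edge": ",".join(leading_edge(score)),
            }
        )
    return pd.DataFrame(rows)
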