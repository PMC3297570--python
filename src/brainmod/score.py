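"""Module-restricted polygenic risk scores from trio data.

A discovery TDT supplies per-SNP signed z-scores.  Tag SNPs are chosen by
greedy LD pruning (no two kept SNPs with r^2 > 0.25 inside a sliding
window), and an individual's score at threshold P_T is

    score_i = sum_j z_j * g_ij

over tag SNPs with discovery p < P_T (optionally restricted to SNPs in
genes of chosen modules), with ``g_ij`` the reference-allele count and
missing genotypes imputed as twice the founder reference-allele frequency.
Scores are evaluated by logistic regression of case status on the score
(Wald p, Nagelkerke pseudo-R^2).  Affected children are cases and
pseudocontrols are built from the untransmitted parental alleles, so each
family contributes one matched case-control pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synth import TrioGenotypeSet


def ld_prune(
    genotypes: np.ndarray, r2_max: float = 0.25, window: int = 50
) -> np.ndarray:
    """Greedy tag-SNP selection in marker order.

    ``genotypes`` is individuals x SNPs (missing = -1, mean-imputed for the
    correlation).  A SNP is kept iff its squared Pearson correlation with
    every previously kept SNP among the last ``window`` kept is at most
    ``r2_max``.  Returns the boolean keep mask.
    """
    G = np.asarray(genotypes, dtype=float)
    G = np.where(G < 0, np.nan, G)
    col_mean = np.nanmean(G, axis=0)
    G = np.where(np.isnan(G), col_mean, G)
    n_ind, n_snp = G.shape
    sd = G.std(axis=0)
    keep = np.zeros(n_snp, dtype=bool)
    kept_idx: list[int] = []
    Gc = G - G.mean(axis=0)
    for j in range(n_snp):
        if sd[j] == 0:
            continue  # monomorphic SNPs carry no information
        ok = True
        for k in kept_idx[-window:]:
            r = (Gc[:, j] @ Gc[:, k]) / (n_ind * sd[j] * sd[k])
            if r * r > r2_max:
                ok = False
                break
        if ok:
            keep[j] = True
            kept_idx.append(j)
    return keep


def pseudocontrols(trios: TrioGenotypeSet) -> tuple[np.ndarray, np.ndarray]:
    """Case and pseudocontrol genotype matrices from trios.

    The case is the affected child; the pseudocontrol genotype is the pair
    of alleles the parents did *not* transmit, ``f + m - c``.  Trios with a
    missing genotype at a SNP are missing (-1) there in both matrices.
    """
    f, m, c = trios.father, trios.mother, trios.child
    valid = (f >= 0) & (m >= 0) & (c >= 0)
    pc = np.where(valid, f + m - c, -1)
    pc = np.where((pc >= 0) & (pc <= 2), pc, -1)  # Mendel errors -> missing
    cases = np.where(valid, c, -1)
    return cases.astype(np.int8), pc.astype(np.int8)


def compute_scores(
    genotypes: np.ndarray,
    z: np.ndarray,
    ref_freq: np.ndarray | None = None,
) -> np.ndarray:
    """Per-individual weighted allele score sum_j z_j * g_ij.

    ``genotypes`` is individuals x SNPs with missing = -1; missing entries
    are imputed as ``2 * ref_freq`` (column means of the observed data when
    ``ref_freq`` is not given).
    """
    G = np.asarray(genotypes, dtype=float)
    G = np.where(G < 0, np.nan, G)
    if ref_freq is None:
        fill = np.nanmean(G, axis=0)
    else:
        fill = 2.0 * np.asarray(ref_freq, dtype=float)
    G = np.where(np.isnan(G), fill, G)
    return G @ np.asarray(z, dtype=float)


@dataclass
class LogisticFit:
    beta: float
    se: float
    wald_p: float
    nagelkerke_r2: float
    separated: bool = False
    degenerate: bool = False


def fit_logistic(status: np.ndarray, score: np.ndarray) -> LogisticFit:
    """Logistic regression of case status on a single score.

    Returns the slope, its Wald p-value and Nagelkerke's pseudo-R^2
    (Cox-Snell rescaled by its maximum).  A constant score yields the
    degenerate null fit (beta 0, p 1, R^2 0); perfect separation is
    detected and flagged rather than silently returning garbage.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import (
        PerfectSeparationError,
        PerfectSeparationWarning,
    )

    y = np.asarray(status, dtype=float)
    x = np.asarray(score, dtype=float)
    if set(np.unique(y)) != {0.0, 1.0}:
        raise ValueError("status must contain both 0s and 1s")
    n = len(y)
    if x.std() == 0:
        return LogisticFit(0.0, np.inf, 1.0, 0.0, degenerate=True)

    # standardize for numerical stability; the slope is rescaled back below
    x_sd = x.std()
    xs = (x - x.mean()) / x_sd
    X = sm.add_constant(xs)
    with warnings.catch_warnings():
        warnings.simplefilter("error", PerfectSeparationWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        try:
            fit = sm.Logit(y, X).fit(disp=0)
        except (PerfectSeparationWarning, PerfectSeparationError, np.linalg.LinAlgError):
            try:
                warnings.simplefilter("ignore")
                fit = sm.Logit(y, X).fit(method="bfgs", maxiter=500, disp=0)
            except Exception:
                return LogisticFit(np.inf, np.inf, 0.0, 1.0 - 1e-12, separated=True)
    ll1 = fit.llf
    # a (near) zero deviance with a non-constant response means separation:
    # the MLE slope is unbounded and the Wald statistic is meaningless
    if ll1 > -1e-4 * n or abs(fit.params[1]) > 50:
        return LogisticFit(np.inf, np.inf, 0.0, 1.0 - 1e-12, separated=True)
    ll0 = sm.Logit(y, np.ones((n, 1))).fit(disp=0).llf
    r2_cs = 1.0 - np.exp((2.0 / n) * (ll0 - ll1))
    r2_max = 1.0 - np.exp((2.0 / n) * ll0)
    r2 = float(max(0.0, r2_cs / r2_max)) if r2_max > 0 else 0.0
    beta = float(fit.params[1]) / x_sd
    se = float(fit.bse[1]) / x_sd
    wald_p = float(2.0 * stats.norm.sf(abs(beta) / se)) if se > 0 else 1.0
    return LogisticFit(beta, se, wald_p, r2)


DEFAULT_THRESHOLDS = (0.1, 0.2, 0.3, 0.4, 0.5)


def threshold_series(
    discovery: pd.DataFrame,
    target: TrioGenotypeSet,
    labels: pd.Series | None = None,
    snp_gene: pd.Series | None = None,
    modules: tuple[str, ...] = (),
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
    r2_max: float = 0.25,
    window: int = 50,
) -> pd.DataFrame:
    """Risk-score association over p-value thresholds and module scopes.

    ``discovery`` is a TDT summary with columns snp/p/z (and optionally
    gene); ``target`` provides the individuals to score.  For the
    genome-wide scope and for each requested module: prune tag SNPs on the
    target founders, keep those with discovery p < P_T (and in-module genes
    for module scopes), score cases and pseudocontrols, and fit the
    logistic model.  Returns one row per (scope, P_T).
    """
    disc = discovery.set_index("snp") if "snp" in discovery.columns else discovery
    shared = [s for s in target.snps["snp"] if s in disc.index]
    snp_order = {s: i for i, s in enumerate(target.snps["snp"])}
    cols = np.array([snp_order[s] for s in shared])
    founders = np.vstack([target.father, target.mother])[:, cols]
    keep = ld_prune(founders, r2_max=r2_max, window=window)
    tag_snps = np.array(shared)[keep]

    cases, controls = pseudocontrols(target)
    G = np.vstack([cases, controls])[:, cols][:, keep]
    status = np.concatenate([np.ones(target.n_families), np.zeros(target.n_families)])
    founders_kept = founders[:, keep]
    with np.errstate(invalid="ignore"):
        ref_freq = np.nanmean(np.where(founders_kept < 0, np.nan, founders_kept), axis=0) / 2.0

    pvals = disc.loc[tag_snps, "p"].to_numpy()
    zvals = disc.loc[tag_snps, "z"].to_numpy()
    if snp_gene is None and "gene" in disc.columns:
        snp_gene = disc["gene"]
    gene_of = snp_gene.loc[tag_snps].to_numpy() if snp_gene is not None else None

    scopes: list[tuple[str, np.ndarray]] = [("genome-wide", np.ones(len(tag_snps), bool))]
    for mod in modules:
        if labels is None or gene_of is None:
            raise ValueError("module scopes need a partition and SNP-to-gene map")
        mod_genes = set(labels.index[labels == mod])
        scopes.append((mod, np.array([g in mod_genes for g in gene_of])))

    rows = []
    for scope, in_scope in scopes:
        for pt in thresholds:
            sel = in_scope & (pvals < pt) & np.isfinite(zvals)
            if not sel.any():
                raise ValueError(f"no tag SNPs pass P_T={pt} in scope {scope!r}")
            s = compute_scores(G[:, sel], zvals[sel], ref_freq[sel])
            fit = fit_logistic(status, s)
            rows.append(
                {
                    "scope": scope,
                    "p_threshold": pt,
                    "n_snps": int(sel.sum()),
                    "beta": fit.beta,
                    "wald_p": fit.wald_p,
                    "nagelkerke_r2": fit.nagelkerke_r2,
                    "separated": fit.separated,
                }
            )
    return pd.DataFrame(rows)
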