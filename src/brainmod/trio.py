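"""Trio genotype QC and the transmission disequilibrium test (TDT).

The TDT compares, at each SNP, the number of times heterozygous parents
transmit the reference allele to an affected child (b) with the number of
times they do not (c); under the null of no association-with-linkage
``b ~ Binomial(b+c, 1/2)`` and ``chi2 = (b-c)^2/(b+c)`` is asymptotically
chi-square with 1 df, immune to population stratification.  The reference
allele is the A1 allele of the MAP record, and ``z = sign(b-c) * sqrt(chi2)``
is its signed association score.

QC follows the standard trio filters: founder minor allele frequency,
founder Hardy-Weinberg exact test, per-SNP call rate, and per-SNP /
per-family Mendelian error rates (error rates use informative trio-SNPs as
the denominator; trios with a missing genotype at a SNP are uninformative
there).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synth import TrioGenotypeSet


@dataclass
class QcThresholds:
    maf_min: float = 0.10
    hwe_p_min: float = 0.001
    call_rate_min: float = 0.90
    snp_mendel_max: float = 0.10
    family_mendel_max: float = 0.05


def hwe_exact(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional Hardy-Weinberg test on founder genotype counts.

    Conditions on the total sample size and minor-allele count, and sums
    the probabilities of all heterozygote configurations no more probable
    than the observed one.  A monomorphic SNP has a single configuration
    and p = 1.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be nonnegative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("no genotyped founders")
    n_a = 2 * n_aa + n_Aa  # count of the a allele
    n_minor = min(n_a, 2 * n - n_a)
    # possible heterozygote counts share the parity of the minor-allele count
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    # log P(het | n, n_minor) up to a constant: n! 2^het / (hom_min! het! hom_maj!)
    from scipy.special import gammaln

    hom_min = (n_minor - hets) // 2
    hom_maj = n - hets - hom_min
    logp = hets * np.log(2.0) - gammaln(hom_min + 1) - gammaln(hets + 1) - gammaln(hom_maj + 1)
    p = np.exp(logp - logp.max())
    p /= p.sum()
    obs = p[hets == n_Aa][0]
    return float(min(1.0, p[p <= obs * (1 + 1e-12)].sum()))


# transmissible reference-allele counts per parent genotype
_HOM_TRANSMIT = {0: 0, 2: 1}


def _mendel_mask(trios: TrioGenotypeSet) -> tuple[np.ndarray, np.ndarray]:
    """(errors, informative) boolean arrays over (family, SNP).

    A trio-SNP is informative when all three genotypes are present, and an
    error when the child's reference-allele count cannot be decomposed into
    one transmissible allele from each parent.
    """
    f, m, c = trios.father, trios.mother, trios.child
    informative = (f >= 0) & (m >= 0) & (c >= 0)
    lo = np.where(f == 1, 0, np.where(f == 2, 1, 0)) + np.where(
        m == 1, 0, np.where(m == 2, 1, 0)
    )
    hi = np.where(f == 1, 1, np.where(f == 2, 1, 0)) + np.where(
        m == 1, 1, np.where(m == 2, 1, 0)
    )
    errors = informative & ((c < lo) | (c > hi))
    return errors, informative


def mendel_errors(trios: TrioGenotypeSet) -> tuple[pd.Series, pd.Series]:
    """Mendelian error rates per SNP and per family (informative denominator)."""
    errors, informative = _mendel_mask(trios)
    with np.errstate(invalid="ignore"):
        snp_rate = errors.sum(axis=0) / informative.sum(axis=0)
        fam_rate = errors.sum(axis=1) / informative.sum(axis=1)
    return (
        pd.Series(snp_rate, index=trios.snps["snp"].to_numpy(), name="mendel_rate"),
        pd.Series(fam_rate, index=trios.family_ids, name="mendel_rate"),
    )


def founder_maf(trios: TrioGenotypeSet) -> pd.Series:
    """Minor allele frequency among founders, missing genotypes excluded."""
    founders = np.vstack([trios.father, trios.mother])
    valid = founders >= 0
    with np.errstate(invalid="ignore"):
        freq = np.where(founders >= 0, founders, 0).sum(axis=0) / (2.0 * valid.sum(axis=0))
    maf = np.minimum(freq, 1.0 - freq)
    return pd.Series(maf, index=trios.snps["snp"].to_numpy(), name="maf")


def qc_filter(
    trios: TrioGenotypeSet, thresholds: QcThresholds | None = None
) -> tuple[TrioGenotypeSet, pd.DataFrame]:
    """Apply the SNP filters and flag high-Mendel-error families.

    SNPs failing founder MAF, founder HWE, call rate or the per-SNP Mendel
    rate are removed; families whose Mendel rate exceeds the family
    threshold are removed.  Returns the filtered set and a report with one
    row per criterion (n_removed) plus per-SNP fail attribution in
    ``report.attrs['snp_fails']``.
    """
    th = thresholds or QcThresholds()
    n_snp = trios.n_snps

    maf = founder_maf(trios).to_numpy()
    maf_fail = maf < th.maf_min

    founders = np.vstack([trios.father, trios.mother])
    hwe_p = np.ones(n_snp)
    for j in range(n_snp):
        g = founders[:, j]
        g = g[g >= 0]
        if len(g):
            hwe_p[j] = hwe_exact(int((g == 2).sum()), int((g == 1).sum()), int((g == 0).sum()))
    hwe_fail = hwe_p <= th.hwe_p_min

    all_geno = np.vstack([trios.father, trios.mother, trios.child])
    call_rate = (all_geno >= 0).mean(axis=0)
    call_fail = call_rate < th.call_rate_min

    snp_mendel, fam_mendel = mendel_errors(trios)
    mendel_fail = np.nan_to_num(snp_mendel.to_numpy()) > th.snp_mendel_max

    snp_ok = ~(maf_fail | hwe_fail | call_fail | mendel_fail)
    if not snp_ok.any():
        raise ValueError("no SNPs survive QC")
    fam_ok = ~(np.nan_to_num(fam_mendel.to_numpy()) > th.family_mendel_max)

    out = trios.subset_snps(snp_ok)
    if not fam_ok.all():
        out = out.subset_families(fam_ok)

    report = pd.DataFrame(
        {
            "criterion": ["maf", "hwe", "call_rate", "snp_mendel", "family_mendel"],
            "n_removed": [
                int(maf_fail.sum()),
                int(hwe_fail.sum()),
                int(call_fail.sum()),
                int(mendel_fail.sum()),
                int((~fam_ok).sum()),
            ],
        }
    )
    report.attrs["snp_fails"] = pd.DataFrame(
        {
            "snp": trios.snps["snp"].to_numpy(),
            "maf": maf_fail,
            "hwe": hwe_fail,
            "call_rate": call_fail,
            "snp_mendel": mendel_fail,
        }
    )
    return out, report


def transmission_counts(trios: TrioGenotypeSet) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP (b, c): reference alleles transmitted / untransmitted by
    heterozygous parents.  Mendel-inconsistent or incomplete trios are
    uninformative."""
    f, m, c = trios.father, trios.mother, trios.child
    errors, informative = _mendel_mask(trios)
    usable = informative & ~errors
    f_het = (f == 1) & usable
    m_het = (m == 1) & usable
    hom_contrib = np.where(f == 2, 1, 0) + np.where(m == 2, 1, 0)
    # reference alleles the het parents jointly transmitted
    het_trans = np.where(usable, c - hom_contrib, 0)
    n_het = f_het.astype(int) + m_het.astype(int)
    b = np.where(usable, het_trans, 0).sum(axis=0).astype(float)
    c_count = np.where(usable, n_het - het_trans, 0).sum(axis=0).astype(float)
    return b, c_count


def tdt(trios: TrioGenotypeSet) -> pd.DataFrame:
    """TDT per SNP: b, c, chi2, p, odds ratio b/c and signed z for allele A1.

    SNPs with no informative heterozygous parents get NA statistics.
    """
    b, c = transmission_counts(trios)
    total = b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        chi2 = np.where(total > 0, (b - c) ** 2 / total, np.nan)
        orat = np.where(c > 0, b / c, np.nan)
    p = np.where(np.isnan(chi2), np.nan, stats.chi2.sf(chi2, df=1))
    z = np.sign(b - c) * np.sqrt(chi2)
    out = trios.snps[["snp", "chrom", "bp", "a1", "gene"]].copy() \
        if "gene" in trios.snps.columns else trios.snps[["snp", "chrom", "bp", "a1"]].copy()
    out["b"] = b
    out["c"] = c
    out["chi2"] = chi2
    out["p"] = p
    out["or"] = orat
    out["z"] = z
    return out


CHI2_DF1_MEDIAN = 0.4549364


def lambda_gc(chi2_values) -> float:
    """Genomic control inflation factor: median chi2 / median of chi-square(1)."""
    x = np.asarray(chi2_values, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) == 0:
        raise ValueError("no finite chi-square values")
    return float(np.median(x) / CHI2_DF1_MEDIAN)


def qq_data(pvals) -> pd.DataFrame:
    """Observed vs expected -log10 p under uniformity (expected i/(n+1))."""
    p = np.asarray(pvals, dtype=float)
    p = p[np.isfinite(p)]
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    obs = np.sort(p)
    n = len(obs)
    expected = np.arange(1, n + 1) / (n + 1.0)
    return pd.DataFrame(
        {"expected": -np.log10(expected)[::-1], "observed": -np.log10(obs)[::-1]}
    )
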