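"""Readers and writers for the plain-text formats the pipeline exchanges.

Expression matrices and summary tables are TSV (pandas), gene sets are
GMT-like (name, description, tab-separated members), intervals are BED
(0-based half-open), and trio genotypes are the PLINK PED/MAP text dialect
with "0 0" as the missing genotype.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .synth import TrioGenotypeSet


def read_expression(path) -> pd.DataFrame:
    """Genes x samples TSV with a header row of sample IDs; rejects missing values."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        raise ValueError(f"{path}: expression matrix contains missing values")
    return df


def write_expression(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t")


def read_gmt(path) -> dict[str, list[str]]:
    """GMT-like gene sets: one set per line, ``name<TAB>description<TAB>genes...``."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = parts[2:]
    return sets


def write_gmt(sets: dict[str, list[str]], path, description: str = "synthetic") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def read_bed(path, names: bool = False) -> pd.DataFrame:
    """BED intervals; with ``names`` a 4th (name) and 6th (strand) column are kept."""
    cols = ["chrom", "start", "end"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if names:
        df = df.iloc[:, :6]
        df.columns = cols + ["name", "score", "strand"][: df.shape[1] - 3]
    else:
        df = df.iloc[:, :3]
        df.columns = cols
    return df


def write_gene_bed(genes: pd.DataFrame, path) -> None:
    out = genes.reset_index()
    out["score"] = 0
    out[["chrom", "start", "end", "gene", "score", "strand"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def write_bed(intervals: pd.DataFrame, path) -> None:
    intervals[["chrom", "start", "end"]].to_csv(path, sep="\t", header=False, index=False)


def read_gene_bed(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "gene", "score", "strand"],
    )
    return df.set_index("gene")[["chrom", "start", "end", "strand"]]


# ---------------------------------------------------------------------------
# PED/MAP (PLINK text dialect)

_GENO_TO_ALLELES = {0: ("B", "B"), 1: ("A", "B"), 2: ("A", "A"), -1: ("0", "0")}


def _geno_strings(g: np.ndarray, a1: np.ndarray, a2: np.ndarray) -> list[str]:
    out = []
    for gj, a1j, a2j in zip(g, a1, a2):
        if gj < 0:
            out.append("0 0")
        elif gj == 0:
            out.append(f"{a2j} {a2j}")
        elif gj == 1:
            out.append(f"{a1j} {a2j}")
        else:
            out.append(f"{a1j} {a1j}")
    return out


def write_ped_map(trios: TrioGenotypeSet, ped_path, map_path) -> None:
    """Write trios as PED/MAP; children are coded affected (phenotype 2)."""
    snps = trios.snps
    chrom_num = snps["chrom"].astype(str).str.replace("chr", "", regex=False)
    pd.DataFrame(
        {
            "chrom": chrom_num,
            "snp": snps["snp"],
            "cm": 0,
            "bp": snps["bp"],
        }
    ).to_csv(map_path, sep="\t", header=False, index=False)

    a1 = snps["a1"].to_numpy()
    a2 = snps["a2"].to_numpy()
    with open(ped_path, "w") as fh:
        for i, fid in enumerate(trios.family_ids):
            members = [
                (f"{fid}_f", "0", "0", "1", "1", trios.father[i]),
                (f"{fid}_m", "0", "0", "2", "1", trios.mother[i]),
                (f"{fid}_c", f"{fid}_f", f"{fid}_m", "1", "2", trios.child[i]),
            ]
            for iid, pat, mat, sex, pheno, g in members:
                fields = [fid, iid, pat, mat, sex, pheno, *_geno_strings(g, a1, a2)]
                fh.write(" ".join(fields) + "\n")


def read_ped_map(
    ped_path, map_path, keep_families: list[str] | None = None
) -> TrioGenotypeSet:
    """Load trios from PED/MAP.

    Each family must contain a father, a mother and one child whose PAT/MAT
    point at them.  Genotypes are recoded as counts of the A1 allele (the
    lexicographically smaller allele observed at the SNP); "0 0" becomes -1.  An optional
    ``keep_families`` list restricts loading (e.g. to an externally derived
    ancestry-matched subset).
    """
    snps = pd.read_csv(map_path, sep=r"\s+", header=None, names=["chrom", "snp", "cm", "bp"])
    n_snp = len(snps)

    records: dict[str, dict[str, tuple]] = {}
    with open(ped_path) as fh:
        for line in fh:
            parts = line.split()
            fid, iid, pat, mat = parts[0], parts[1], parts[2], parts[3]
            if keep_families is not None and fid not in keep_families:
                continue
            alleles = parts[6:]
            if len(alleles) != 2 * n_snp:
                raise ValueError(f"{ped_path}: {iid} has {len(alleles) // 2} genotypes, "
                                 f"expected {n_snp}")
            records.setdefault(fid, {})[iid] = (pat, mat, alleles)

    # A1 = lexicographically smaller observed allele: deterministic, so the
    # coded genotypes do not depend on record order in the file
    observed: list[set] = [set() for _ in range(n_snp)]
    for fam in records.values():
        for _, _, alleles in fam.values():
            for j in range(n_snp):
                for a in (alleles[2 * j], alleles[2 * j + 1]):
                    if a != "0":
                        observed[j].add(a)
    a1 = np.array([min(o) if o else "0" for o in observed], dtype=object)
    a2 = np.array(
        [max(o) if len(o) > 1 else "0" for o in observed], dtype=object
    )

    def code(alleles: list[str]) -> np.ndarray:
        g = np.empty(n_snp, dtype=np.int8)
        for j in range(n_snp):
            x, y = alleles[2 * j], alleles[2 * j + 1]
            if x == "0" or y == "0":
                g[j] = -1
            else:
                g[j] = (x == a1[j]) + (y == a1[j])
        return g

    fids, fathers, mothers, children = [], [], [], []
    for fid, fam in sorted(records.items()):
        child = next(
            (v for v in fam.values() if v[0] != "0" and v[0] in {k for k in fam}), None
        )
        if child is None:
            raise ValueError(f"{ped_path}: family {fid} has no child with both parents")
        pat, mat, child_alleles = child
        fids.append(fid)
        fathers.append(code(fam[pat][2]))
        mothers.append(code(fam[mat][2]))
        children.append(code(child_alleles))

    snps_out = snps[["snp", "chrom", "bp"]].copy()
    snps_out["chrom"] = "chr" + snps_out["chrom"].astype(str)
    snps_out["a1"] = a1
    snps_out["a2"] = a2
    return TrioGenotypeSet(
        np.vstack(fathers), np.vstack(mothers), np.vstack(children), snps_out, fids
    )


def read_gwas_summary(path) -> pd.DataFrame:
    """GWAS summary TSV with at least SNP/CHR/BP/P columns (case-insensitive)."""
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.lower() for c in df.columns]
    required = {"snp", "chrom", "bp", "p"} - set(df.columns)
    if required:
        raise ValueError(f"{path}: missing columns {sorted(required)}")
    bad = ~((df["p"] > 0) & (df["p"] <= 1))
    if bad.any():
        raise ValueError(f"{path}: {int(bad.sum())} p-values outside (0, 1]")
    return df.sort_values(["chrom", "bp"]).reset_index(drop=True)
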