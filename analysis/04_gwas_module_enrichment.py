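"""Enrichment of modules for low GWAS p-values, combined across cohorts.

For each of the three simulated GWAS cohorts: map SNPs to strand-extended
gene regions (20 kb upstream / 10 kb downstream), take the per-gene minimum
p-value, and score every module with the weighted running-sum statistic
under adaptive permutation.  Per-cohort p-values are combined with Fisher's
method and Bonferroni-corrected over modules; leading-edge genes with
gene-wide p < 0.05 are reported.  Finally the per-module GWAS enrichment is
correlated with the rare-mutation relative risk.
"""

import numpy as np
import pandas as pd
from studyconf import DATA_DIR, OUT_DIR

from brainmod import io
from brainmod.gwas import (
    bonferroni,
    combine_pvalues,
    enrichment_score,
    enrichment_vs_rare_correlation,
    genewide_p,
    leading_edge,
    map_snps_to_genes,
    module_enrichment_table,
)

COHORTS = ("discovery", "replication1", "replication2")
MAX_PERM = 20_000


def main() -> None:
    labels = pd.read_csv(OUT_DIR / "module_partition.tsv", sep="\t", index_col=0)["module"]
    genes = io.read_gene_bed(DATA_DIR / "genes.bed")

    per_cohort = {}
    leading: dict[str, set] = {}
    for i, cohort in enumerate(COHORTS):
        gw = io.read_gwas_summary(DATA_DIR / f"gwas_{cohort}.tsv")
        stats = map_snps_to_genes(gw, genes)
        table = module_enrichment_table(stats, labels, max_perm=MAX_PERM, seed=100 + i)
        table["cohort"] = cohort
        per_cohort[cohort] = table.set_index("module")
        for r in table.itertuples():
            genes_le = set(r.leading_edge.split(",")) if r.leading_edge else set()
            sig = {
                g
                for g in genes_le
                if genewide_p(stats.loc[g, "min_p"], int(stats.loc[g, "n_snps"])) < 0.05
            }
            leading.setdefault(r.module, set()).update(sig)

    modules = per_cohort[COHORTS[0]].index
    combined = pd.DataFrame(index=modules)
    for cohort in COHORTS:
        combined[f"p_{cohort}"] = per_cohort[cohort]["perm_p"]
    combined["combined_p"] = [
        combine_pvalues([combined.loc[m, f"p_{c}"] for c in COHORTS]) for m in modules
    ]
    combined["bonferroni_p"] = [
        bonferroni(p, len(modules)) for p in combined["combined_p"]
    ]
    combined["n_leading_edge_genewide_sig"] = [len(leading.get(m, ())) for m in modules]
    combined.to_csv(OUT_DIR / "gwas_module_enrichment.tsv", sep="\t")
    pd.concat([t.reset_index() for t in per_cohort.values()]).to_csv(
        OUT_DIR / "gwas_module_enrichment_by_cohort.tsv", sep="\t", index=False
    )

    enr = pd.read_csv(OUT_DIR / "set_enrichment.tsv", sep="\t")
    rare = enr[enr["set"] == "rare_mutation_genes"].set_index("module")["rr"]
    shared = [m for m in modules if m in rare.index]
    r, p_corr = enrichment_vs_rare_correlation(
        rare.loc[shared], -np.log10(combined.loc[shared, "combined_p"])
    )

    print("combined module enrichment for low GWAS p-values:")
    for m in modules:
        row = combined.loc[m]
        flag = " *" if row["bonferroni_p"] < 0.05 else ""
        print(
            f"  {m}: per-cohort p = "
            + ", ".join(f"{row[f'p_{c}']:.2g}" for c in COHORTS)
            + f"; combined = {row['combined_p']:.2g}, Bonferroni = {row['bonferroni_p']:.2g}{flag}"
        )
    print(f"rare-vs-common enrichment correlation over {len(shared)} modules: "
          f"r = {r:.2f}, p = {p_corr:.2g}")


if __name__ == "__main__":
    main()
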