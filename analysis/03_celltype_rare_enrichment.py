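"""Cell-type, rare-mutation and CNV enrichment of the detected modules.

For every (module, gene set) pair: relative risk with a permutation
p-value and a bootstrap standard error.  The rare-mutation list also gets
the global distribution test over the whole partition, and the CNV events
get the length-corrected per-module burden.  Writes the enrichment table
and prints which modules carry signal.
"""

import numpy as np
import pandas as pd
from studyconf import DATA_DIR, OUT_DIR

from brainmod import io
from brainmod.enrich import (
    cnv_length_rr,
    global_distribution_test,
    rr_bootstrap_se,
    rr_permutation_p,
)
from brainmod.network import UNASSIGNED

N_PERM = 10_000


def main() -> None:
    partition = pd.read_csv(OUT_DIR / "module_partition.tsv", sep="\t", index_col=0)
    labels = partition["module"]
    sets = io.read_gmt(DATA_DIR / "gene_sets.gmt")
    universe = list(labels.index)

    rows = []
    for set_name, members in sets.items():
        for i, mod in enumerate(sorted(set(labels) - {UNASSIGNED})):
            module_genes = list(labels.index[labels == mod])
            res = rr_permutation_p(module_genes, members, universe, N_PERM, seed=hash((set_name, i)) % 2**31)
            se = rr_bootstrap_se(module_genes, members, universe, 1000, seed=i)
            rows.append(
                (mod, set_name, res.m_k, res.n_k, res.M, res.N, res.rr, se, res.perm_p)
            )
    table = pd.DataFrame(
        rows, columns=["module", "set", "m_k", "n_k", "M", "N", "rr", "boot_se", "perm_p"]
    )
    table.to_csv(OUT_DIR / "set_enrichment.tsv", sep="\t", index=False)

    stat, global_p = global_distribution_test(
        labels, sets["rare_mutation_genes"], n_perm=N_PERM, seed=1
    )

    genes = io.read_gene_bed(DATA_DIR / "genes.bed")
    cnv = io.read_bed(DATA_DIR / "cnv_events.bed")
    cnv_rr = cnv_length_rr(cnv, genes, labels)
    cnv_rr.to_frame().to_csv(OUT_DIR / "cnv_length_rr.tsv", sep="\t")

    sig = table[table["perm_p"] < 0.05 / len(table)]
    print(f"{len(sig)}/{len(table)} module-set pairs significant after Bonferroni:")
    for r in sig.itertuples():
        print(f"  {r.module} x {r.set}: RR = {r.rr:.2f} +/- {r.boot_se:.2f}, p = {r.perm_p:.2g}")
    print(f"rare-gene global distribution test: chi2 = {stat:.1f}, p = {global_p:.2g}")
    print("length-corrected CNV RR per module: "
          + ", ".join(f"{m}={v:.2f}" for m, v in cnv_rr.items()))


if __name__ == "__main__":
    main()
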