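"""Generate every input of the synthetic study and write it to disk.

Emits, under results/synthetic_study/: the expression matrix (TSV), sample
metadata, gene intervals (BED) with SNP positions, cell-type marker and
rare-mutation gene sets (GMT), trio genotypes (PED/MAP), GWAS summary
statistics for three simulated cohorts, de novo CNV intervals (BED), a
developmental expression series, and the ground-truth record the later
stages are checked against.
"""

import dataclasses

from studyconf import DATA_DIR, STUDY

from brainmod import io
from brainmod.synth import (
    gen_celltype_markers,
    gen_cnv_events,
    gen_dev_series,
    gen_expression,
    gen_gene_annotation,
    gen_gwas_summary,
    gen_rare_gene_list,
    gen_trios,
    sample_metadata,
)


def main() -> None:
    DATA_DIR.mkdir(parents=True, exist_ok=True)
    cfg = STUDY

    expr, truth = gen_expression(cfg)
    io.write_expression(expr, DATA_DIR / "expression.tsv")
    sample_metadata(cfg).to_csv(DATA_DIR / "samples.tsv", sep="\t")

    genes, snps = gen_gene_annotation(cfg)
    io.write_gene_bed(genes, DATA_DIR / "genes.bed")
    snps.to_csv(DATA_DIR / "snps.tsv", sep="\t", index=False)

    sets = {
        "neuron_markers": gen_celltype_markers(truth, 3.2, 300, cfg.seed + 20, "mod01"),
        "astrocyte_markers": gen_celltype_markers(truth, 3.9, 250, cfg.seed + 21, "mod02"),
        "oligodendrocyte_markers": gen_celltype_markers(truth, 3.0, 250, cfg.seed + 22, "mod03"),
        "rare_mutation_genes": gen_rare_gene_list(truth, 2.9, 110, cfg.seed + 23, "mod01"),
    }
    io.write_gmt(sets, DATA_DIR / "gene_sets.gmt")

    trios = gen_trios(cfg, snps, truth, missing_rate=0.01)
    io.write_ped_map(trios, DATA_DIR / "trios.ped", DATA_DIR / "trios.map")

    # three cohorts with the same planted module enrichment, different draws
    for i, cohort in enumerate(("discovery", "replication1", "replication2")):
        c = dataclasses.replace(cfg, seed=cfg.seed + 30 + i)
        gen_gwas_summary(snps, truth, c).to_csv(
            DATA_DIR / f"gwas_{cohort}.tsv", sep="\t", index=False
        )

    cnv = gen_cnv_events(genes, 3.0, cfg.seed + 40, truth=truth, target_module="mod01",
                         n_events=400)
    io.write_bed(cnv, DATA_DIR / "cnv_events.bed")

    dev, dev_meta = gen_dev_series(
        truth,
        {"mod01": "peaked-infancy", "mod02": "increasing", "mod03": "flat"},
        cfg.seed + 50,
    )
    io.write_expression(dev, DATA_DIR / "dev_expression.tsv")
    dev_meta.to_csv(DATA_DIR / "dev_arrays.tsv", sep="\t")

    truth.to_json(DATA_DIR / "truth.json")
    n_mod = len(cfg.module_sizes)
    print(
        f"wrote synthetic study to {DATA_DIR}: {cfg.n_genes} genes x "
        f"{cfg.n_samples} samples, {n_mod} planted modules, "
        f"{cfg.n_families} trio families, {len(snps)} SNPs, "
        f"{len(cnv)} CNV events, dev series over {dev_meta['age_days'].nunique()} ages"
    )


if __name__ == "__main__":
    main()
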