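"""Shared configuration of the synthetic study driven by the analysis scripts.

One set of conditions is used throughout: 2000 genes over 200 region
samples with seven planted co-expression modules, 500 trio families, three
SNPs per gene, transmission distortion (0.53 per SNP, a weak polygenic effect) and GWAS enrichment
(Beta(0.5, 1) p-values) planted in the first module.
"""

from pathlib import Path

from brainmod.synth import SynthConfig

DATA_DIR = Path(__file__).resolve().parent.parent / "results" / "synthetic_study"
OUT_DIR = DATA_DIR.parent

STUDY = SynthConfig(
    n_genes=2000,
    n_samples=200,
    module_sizes=(300, 200, 150, 100, 80, 60, 40),
    noise_sd=0.5,
    n_families=500,
    n_snps_per_gene=3,
    transmission_prob=0.53,
    enriched_module="mod01",
    gwas_beta_a=0.5,
    seed=2012,
)
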