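"""Synthetic inputs with planted ground truth.

Every generator is a pure function of its configuration and seed, and every
planted parameter (module membership, marker overlap, transmission
distortion, GWAS enrichment, CNV placement, developmental shape) is recorded
in a :class:`TruthRecord` so the downstream stage that is supposed to
recover it can be tested against the truth.

The expression model is a low-rank factor model: each planted module k has a
latent profile ``f_k`` drawn i.i.d. standard normal per sample, and gene g
in module k has profile ``loading_g * f_k + N(0, noise_sd^2)``.  Background
genes are pure unit-variance noise.  Samples play the role of brain regions
and are exchangeable; no spatial structure is modelled because the analysis
never uses region adjacency.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

UNASSIGNED = "grey"  # reserved label for genes in no module


@dataclass
class SynthConfig:
    """Parameters of the synthetic study.

    Defaults are a desk-scale version of the real study: a few thousand
    genes over a couple of hundred region samples, seven planted modules
    spanning the size range the network analysis must resolve, several
    hundred trio families, and null settings (``transmission_prob=0.5``,
    ``gwas_beta_a=1``) unless a signal is planted.
    """

    n_genes: int = 2000
    n_samples: int = 200
    module_sizes: tuple[int, ...] = (300, 200, 150, 100, 80, 60, 40)
    loading_range: tuple[float, float] = (0.6, 0.95)
    noise_sd: float = 0.5
    n_families: int = 500
    n_snps_per_gene: int = 3
    transmission_prob: float = 0.5
    enriched_module: str | None = None
    gwas_beta_a: float = 1.0
    maf_range: tuple[float, float] = (0.15, 0.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.module_sizes) > self.n_genes:
            raise ValueError(
                f"module_sizes sum to {sum(self.module_sizes)} > n_genes={self.n_genes}"
            )
        if not 0.0 <= self.transmission_prob <= 1.0:
            raise ValueError("transmission_prob must lie in [0, 1]")
        if not 0.0 < self.gwas_beta_a <= 1.0:
            raise ValueError("gwas_beta_a must lie in (0, 1]")


def module_labels(config: SynthConfig) -> list[str]:
    """Planted module names: ``mod01``, ``mod02``, ... by declaration order."""
    return [f"mod{k + 1:02d}" for k in range(len(config.module_sizes))]


@dataclass
class TruthRecord:
    """Planted ground truth, serialisable alongside the generated files."""

    module_of: dict[str, str] = field(default_factory=dict)
    loading: dict[str, float] = field(default_factory=dict)
    distorted_snps: list[str] = field(default_factory=list)
    set_overlap: dict[str, int] = field(default_factory=dict)

    def genes_in(self, module: str) -> list[str]:
        return [g for g, m in self.module_of.items() if m == module]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "TruthRecord":
        with open(path) as fh:
            return cls(**json.load(fh))


# ---------------------------------------------------------------------------
# expression


def gen_expression(config: SynthConfig) -> tuple[pd.DataFrame, TruthRecord]:
    """Expression matrix (genes x samples) with planted co-expression modules.

    Returns the matrix with gene IDs ``g0001``... as index and sample IDs
    ``s001``... as columns, plus the truth record mapping each gene to its
    planted module (:data:`UNASSIGNED` for background genes) and loading.
    """
    rng = np.random.default_rng(config.seed)
    genes = [f"g{i + 1:04d}" for i in range(config.n_genes)]
    samples = [f"s{j + 1:03d}" for j in range(config.n_samples)]
    labels = module_labels(config)

    X = np.empty((config.n_genes, config.n_samples))
    truth = TruthRecord()
    lo, hi = config.loading_range
    start = 0
    factors = rng.standard_normal((len(labels), config.n_samples))
    for k, size in enumerate(config.module_sizes):
        loadings = rng.uniform(lo, hi, size)
        noise = rng.standard_normal((size, config.n_samples)) * config.noise_sd
        X[start : start + size] = loadings[:, None] * factors[k] + noise
        for i in range(size):
            g = genes[start + i]
            truth.module_of[g] = labels[k]
            truth.loading[g] = float(loadings[i])
        start += size
    n_bg = config.n_genes - start
    X[start:] = rng.standard_normal((n_bg, config.n_samples))
    for g in genes[start:]:
        truth.module_of[g] = UNASSIGNED
        truth.loading[g] = 0.0

    expr = pd.DataFrame(X, index=genes, columns=samples)
    return expr, truth


def sample_metadata(config: SynthConfig, n_regions: int = 20) -> pd.DataFrame:
    """Region/donor labels for the samples, cycling over ``n_regions`` regions."""
    samples = [f"s{j + 1:03d}" for j in range(config.n_samples)]
    regions = [f"region{(j % n_regions) + 1:02d}" for j in range(config.n_samples)]
    donors = ["donorA" if j % 2 == 0 else "donorB" for j in range(config.n_samples)]
    return pd.DataFrame({"sample": samples, "region": regions, "donor": donors}).set_index(
        "sample"
    )


# ---------------------------------------------------------------------------
# genome annotation


def gen_gene_annotation(
    config: SynthConfig,
    mean_log_length: float = 10.0,
    sd_log_length: float = 1.0,
    n_chromosomes: int = 10,
    upstream_margin: int = 20_000,
    downstream_margin: int = 10_000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Non-overlapping gene intervals plus SNP positions inside them.

    Gene lengths are log-normal (median ``exp(mean_log_length)`` bp, about
    22 kb at the default, close to the human median).  Genes are laid out
    left to right on ``n_chromosomes`` synthetic chromosomes with gaps wide
    enough that even the margin-extended regions (upstream_margin /
    downstream_margin beyond the body, strand-aware) do not overlap.
    Intervals are 0-based half-open; SNP bp positions are 1-based as in MAP
    files.

    Returns ``(genes, snps)``: genes with columns chrom/start/end/strand
    indexed by gene, snps with columns snp/chrom/bp/gene/a1/a2.
    """
    rng = np.random.default_rng(config.seed + 1)
    genes = [f"g{i + 1:04d}" for i in range(config.n_genes)]
    lengths = np.exp(rng.normal(mean_log_length, sd_log_length, config.n_genes))
    lengths = np.maximum(lengths.astype(np.int64), 200)
    strands = rng.choice(["+", "-"], config.n_genes)
    gap = upstream_margin + downstream_margin + 5_000

    per_chrom = int(np.ceil(config.n_genes / n_chromosomes))
    rows = []
    snp_rows = []
    for i, g in enumerate(genes):
        chrom = i // per_chrom + 1
        within = i % per_chrom
        if within == 0:
            cursor = gap
        start = cursor
        end = start + int(lengths[i])
        rows.append((g, f"chr{chrom}", start, end, strands[i]))
        cursor = end + gap
        if config.n_snps_per_gene > 0:
            # SNPs inside the margin-extended region, mostly in the body
            lo = start - (upstream_margin if strands[i] == "+" else downstream_margin)
            hi = end + (downstream_margin if strands[i] == "+" else upstream_margin)
            pos = np.sort(rng.integers(max(lo, 0), hi, config.n_snps_per_gene))
            for j, p in enumerate(pos):
                snp_rows.append((f"{g}_snp{j + 1}", f"chr{chrom}", int(p) + 1, g))

    gene_df = pd.DataFrame(rows, columns=["gene", "chrom", "start", "end", "strand"]).set_index(
        "gene"
    )
    snp_df = pd.DataFrame(snp_rows, columns=["snp", "chrom", "bp", "gene"])
    snp_df["a1"] = "A"
    snp_df["a2"] = "B"
    return gene_df, snp_df


# ---------------------------------------------------------------------------
# gene sets


def gen_celltype_markers(
    truth: TruthRecord,
    target_rr: float,
    set_size: int,
    seed: int,
    module: str,
) -> list[str]:
    """Marker gene set whose expected relative risk in ``module`` is ``target_rr``.

    Each of the ``set_size`` members is drawn from the target module with
    probability ``target_rr * module_size / n_genes`` and from the rest of
    the universe otherwise, so the expected overlap is
    ``target_rr * set_size * module_size / n_genes`` and the expected RR is
    exactly ``target_rr``.  The realised overlap is recorded in
    ``truth.set_overlap``.
    """
    if target_rr < 0:
        raise ValueError("target_rr must be nonnegative")
    rng = np.random.default_rng(seed)
    universe = list(truth.module_of)
    in_mod = truth.genes_in(module)
    out_mod = [g for g in universe if truth.module_of[g] != module]
    n = len(universe)
    p_in = target_rr * len(in_mod) / n
    expected_overlap = p_in * set_size
    max_rr = n * min(set_size, len(in_mod)) / (set_size * len(in_mod))
    if p_in > 1 or expected_overlap > len(in_mod) or set_size - expected_overlap > len(out_mod):
        raise ValueError(
            f"target_rr={target_rr} infeasible for module of {len(in_mod)} in universe "
            f"{n} with set size {set_size}; maximum achievable RR is {max_rr:.3g}"
        )
    m = rng.binomial(set_size, p_in)
    m = min(m, len(in_mod))
    members = list(rng.choice(in_mod, m, replace=False)) + list(
        rng.choice(out_mod, set_size - m, replace=False)
    )
    truth.set_overlap[module] = int(m)
    return sorted(members)


def gen_rare_gene_list(
    truth: TruthRecord, target_rr: float, set_size: int, seed: int, module: str
) -> list[str]:
    """Rare-mutation gene list with configured module overlap (same scheme
    as :func:`gen_celltype_markers`)."""
    return gen_celltype_markers(truth, target_rr, set_size, seed, module)


# ---------------------------------------------------------------------------
# trios


@dataclass
class TrioGenotypeSet:
    """Genotypes of father/mother/child trios, coded as counts of allele A1.

    Arrays are (n_families, n_snps) int8; -1 marks a missing genotype.
    ``snps`` carries the MAP-style records (snp, chrom, bp, a1, a2 and the
    gene each SNP was placed in).  ``family_ids`` are the FIDs.
    """

    father: np.ndarray
    mother: np.ndarray
    child: np.ndarray
    snps: pd.DataFrame
    family_ids: list[str]

    @property
    def n_families(self) -> int:
        return self.father.shape[0]

    @property
    def n_snps(self) -> int:
        return self.father.shape[1]

    def subset_snps(self, mask: np.ndarray) -> "TrioGenotypeSet":
        return TrioGenotypeSet(
            self.father[:, mask],
            self.mother[:, mask],
            self.child[:, mask],
            self.snps.loc[np.asarray(mask)].reset_index(drop=True),
            self.family_ids,
        )

    def subset_families(self, keep: np.ndarray) -> "TrioGenotypeSet":
        keep = np.asarray(keep)
        return TrioGenotypeSet(
            self.father[keep],
            self.mother[keep],
            self.child[keep],
            self.snps,
            [f for f, k in zip(self.family_ids, keep) if k],
        )


def _transmit(parent: np.ndarray, p_ref: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Allele (0/1 count of A1) transmitted by each parent genotype.

    Homozygotes transmit their allele; heterozygotes transmit A1 with
    probability ``p_ref`` (broadcast over SNPs).
    """
    draw = rng.random(parent.shape) < p_ref
    out = np.where(parent == 2, 1, 0)
    out = np.where(parent == 1, draw.astype(int), out)
    return out


def gen_trios(
    config: SynthConfig,
    snps: pd.DataFrame,
    truth: TruthRecord,
    missing_rate: float = 0.0,
    mendel_error_snp: str | None = None,
    mendel_error_rate: float = 0.0,
) -> TrioGenotypeSet:
    """Trio genotypes with optional transmission distortion.

    Parents are drawn in Hardy-Weinberg equilibrium at allele frequencies
    uniform over ``config.maf_range``.  At SNPs inside genes of
    ``config.enriched_module`` the A1 allele is transmitted from
    heterozygous parents with probability ``config.transmission_prob``
    (0.5 elsewhere, the null).  Optionally genotypes are masked at
    ``missing_rate`` and Mendel errors are planted at one SNP by flipping
    the child genotype.
    """
    rng = np.random.default_rng(config.seed + 2)
    n_fam, n_snp = config.n_families, len(snps)
    freq = rng.uniform(*config.maf_range, n_snp)

    father = rng.binomial(2, freq, (n_fam, n_snp)).astype(np.int8)
    mother = rng.binomial(2, freq, (n_fam, n_snp)).astype(np.int8)

    p_ref = np.full(n_snp, 0.5)
    distorted: list[str] = []
    if config.enriched_module is not None and config.transmission_prob != 0.5:
        mod_genes = set(truth.genes_in(config.enriched_module))
        mask = snps["gene"].isin(mod_genes).to_numpy()
        p_ref[mask] = config.transmission_prob
        distorted = snps.loc[mask, "snp"].tolist()
    truth.distorted_snps = distorted

    child = (_transmit(father, p_ref, rng) + _transmit(mother, p_ref, rng)).astype(np.int8)

    if mendel_error_snp is not None and mendel_error_rate > 0:
        j = int(np.flatnonzero((snps["snp"] == mendel_error_snp).to_numpy())[0])
        hit = rng.random(n_fam) < mendel_error_rate
        # a homozygous-A1 father cannot have transmitted zero A1 alleles,
        # so this combination is impossible whatever the mother carries
        father[hit, j] = 2
        child[hit, j] = 0

    if missing_rate > 0:
        for arr in (father, mother, child):
            arr[rng.random(arr.shape) < missing_rate] = -1

    fids = [f"fam{f + 1:04d}" for f in range(n_fam)]
    return TrioGenotypeSet(father, mother, child, snps.reset_index(drop=True), fids)


# ---------------------------------------------------------------------------
# GWAS summary statistics


def gen_gwas_summary(
    snps: pd.DataFrame, truth: TruthRecord, config: SynthConfig
) -> pd.DataFrame:
    """Per-SNP summary statistics with optional planted module enrichment.

    Null SNPs get p ~ U(0,1); SNPs in genes of ``config.enriched_module``
    get p ~ Beta(gwas_beta_a, 1), which is stochastically smaller than
    uniform for ``gwas_beta_a < 1``.  z-scores satisfy
    ``|z| = Phi^{-1}(1 - p/2)`` with a random sign.
    """
    rng = np.random.default_rng(config.seed + 3)
    n = len(snps)
    p = rng.uniform(size=n)
    if config.enriched_module is not None and config.gwas_beta_a < 1.0:
        mod_genes = set(truth.genes_in(config.enriched_module))
        mask = snps["gene"].isin(mod_genes).to_numpy()
        p[mask] = rng.beta(config.gwas_beta_a, 1.0, int(mask.sum()))
    p = np.clip(p, 1e-300, 1.0)
    z = p_to_z(p) * rng.choice([-1.0, 1.0], n)
    out = snps[["snp", "chrom", "bp", "gene"]].copy()
    out["p"] = p
    out["z"] = z
    return out


def p_to_z(p: np.ndarray | float) -> np.ndarray | float:
    """Two-sided p-value to the magnitude of the normal score: |z| = Phi^-1(1-p/2)."""
    return stats.norm.isf(np.asarray(p) / 2.0)


# ---------------------------------------------------------------------------
# CNVs


def gen_cnv_events(
    genes: pd.DataFrame,
    module_bias: float,
    seed: int,
    truth: TruthRecord | None = None,
    target_module: str | None = None,
    n_events: int = 200,
) -> pd.DataFrame:
    """De novo CNV intervals (BED convention, 0-based half-open).

    Each event covers a uniform random subinterval of one gene body; genes
    are chosen with probability proportional to length, multiplied by
    ``module_bias`` for genes of ``target_module``.  ``module_bias=1`` is
    the uniform-per-bp null; ``module_bias=inf`` places every event inside
    the target module.
    """
    if module_bias < 0:
        raise ValueError("module_bias must be nonnegative")
    rng = np.random.default_rng(seed)
    lengths = (genes["end"] - genes["start"]).to_numpy(dtype=float)
    w = lengths.copy()
    if target_module is not None:
        if truth is None:
            raise ValueError("target_module requires a truth record")
        in_mod = np.array([truth.module_of.get(g) == target_module for g in genes.index])
        if np.isinf(module_bias):
            w = np.where(in_mod, lengths, 0.0)
        else:
            w = np.where(in_mod, lengths * module_bias, lengths)
    if w.sum() == 0:
        raise ValueError("no gene territory has positive weight")
    w = w / w.sum()
    picks = rng.choice(len(genes), n_events, p=w)
    rows = []
    for i in picks:
        g = genes.iloc[i]
        a, b = np.sort(rng.integers(g["start"], g["end"], 2))
        rows.append((g["chrom"], int(a), int(b) + 1))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


# ---------------------------------------------------------------------------
# developmental series

DEV_SHAPES = ("peaked-infancy", "increasing", "flat")

# BrainSpan-like age grid: post-conception weeks, months, years
DEFAULT_AGES = (
    [(w, "pcw") for w in (8, 12, 16, 21, 26, 32, 37)]
    + [(m, "mos") for m in (4, 10)]
    + [(y, "yrs") for y in (1, 3, 8, 13, 18, 25, 30, 40)]
)

_DAYS = {"pcw": 7.0, "mos": 30.44, "yrs": 365.25}
BIRTH_DAYS = 40 * 7.0  # age axis counts days post conception


def age_to_days(value: float, unit: str) -> float:
    """Normalize an age to days post conception (postnatal units add gestation)."""
    if unit == "pcw":
        return value * _DAYS["pcw"]
    return BIRTH_DAYS + value * _DAYS[unit]


def _shape_mean(shape: str, days: np.ndarray) -> np.ndarray:
    log_age = np.log10(days)
    if shape == "flat":
        return np.zeros_like(log_age)
    if shape == "increasing":
        # saturating rise over the whole age range
        return 2.0 / (1.0 + np.exp(-(log_age - 2.6) * 3.0))
    if shape == "peaked-infancy":
        # bump centred ~6 months after birth (log10 days ~ 2.66)
        return 2.0 * np.exp(-((log_age - np.log10(BIRTH_DAYS + 180)) ** 2) / (2 * 0.35**2))
    raise ValueError(f"unknown shape {shape!r}; expected one of {DEV_SHAPES}")


def gen_dev_series(
    truth: TruthRecord,
    shapes: dict[str, str],
    seed: int,
    ages: list[tuple[float, str]] | None = None,
    n_regions: int = 4,
    noise_sd: float = 0.5,
    amplitude_from_loading: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Age-indexed expression (genes x arrays) with planted trajectories.

    ``shapes`` maps module label to one of :data:`DEV_SHAPES`; modules not
    listed (and background genes) are flat.  Each (age, region) pair is one
    array.  Returns the matrix and array metadata (age_value, age_unit,
    age_days, region).
    """
    for s in shapes.values():
        if s not in DEV_SHAPES:
            raise ValueError(f"unknown shape {s!r}; expected one of {DEV_SHAPES}")
    rng = np.random.default_rng(seed)
    ages = list(DEFAULT_AGES) if ages is None else ages
    arrays = [
        (f"a{idx + 1:03d}", v, u, age_to_days(v, u), f"region{r + 1}")
        for idx, (v, u, r) in enumerate(
            (v, u, r) for (v, u) in ages for r in range(n_regions)
        )
    ]
    meta = pd.DataFrame(
        arrays, columns=["array", "age_value", "age_unit", "age_days", "region"]
    ).set_index("array")

    genes = list(truth.module_of)
    days = meta["age_days"].to_numpy()
    X = np.empty((len(genes), len(meta)))
    for i, g in enumerate(genes):
        shape = shapes.get(truth.module_of[g], "flat")
        amp = truth.loading[g] if amplitude_from_loading and shape != "flat" else 1.0
        X[i] = amp * _shape_mean(shape, days)
        if noise_sd > 0:
            X[i] += rng.normal(0, noise_sd, len(meta))
    return pd.DataFrame(X, index=genes, columns=meta.index), meta
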