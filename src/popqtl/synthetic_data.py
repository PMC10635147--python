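"""Synthetic cohorts with the statistical structure the pipeline assumes.

Genotypes follow a two-level Balding–Nichols hierarchy: an ancestral allele
frequency p0 per variant, continental-group frequencies drawn from
Beta(p0(1-F_G)/F_G, (1-p0)(1-F_G)/F_G), and population frequencies drawn
the same way around their group frequency with differentiation F_P.
Within each population, genotypes are Hardy–Weinberg draws from the
population frequency. Linkage disequilibrium is induced by thresholding
block-correlated latent Gaussians per haplotype (compound symmetry with
correlation rho within a block), so each site keeps its marginal frequency
while adjacent sites within a block are correlated.

Expression follows the multiplicative allelic-fold-change model: a causal
variant with log2 aFC delta scales a gene's expected expression by
((2 - d) + d * 2**delta) / 2 for dosage d, and independent causal variants
combine multiplicatively. Batch, sex and continental-group shifts act as
log2-additive effects, with lognormal residual noise.

Splicing phenotypes are logistic-normal intron-excision ratios per cluster:
intron logits shift additively with causal dosage and per-sample ratios sum
to one within each cluster.

Everything the generator draws is recorded in :class:`SimTruth`, which is
sufficient to recompute noiseless expected phenotypes.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import (
    CONTINENTAL_GROUPS,
    FeatureMatrix,
    GenotypeMatrix,
    SampleTable,
    VariantRecord,
    write_genotypes,
    write_phenotype_bed,
    write_sample_table,
)

logger = logging.getLogger(__name__)

LOG2_AFC_CAP = np.log2(100.0)


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort.

    Defaults mirror a 1KGP-like cohort: 5 continental groups x 5
    populations x 27-30 individuals (~725 samples), group-level
    differentiation F_G = 0.1 and population-level F_P = 0.02, multi-causal
    cis architecture with log2 aFC effects ~ Normal(0, 0.5^2) capped at
    +/- log2(100), and lognormal residual noise with sd 0.5 on the log2
    scale. Every dimension scales down for tests.
    """

    n_groups: int = 5
    pops_per_group: int = 5
    pop_size_range: tuple[int, int] = (27, 30)
    f_group: float = 0.10
    f_pop: float = 0.02
    n_genes: int = 50
    variants_per_gene: int = 100
    ld_block_size: int = 10
    ld_rho: float = 0.9
    p0_range: tuple[float, float] = (0.05, 0.95)
    p0_block_jitter: float = 0.05   # within-block sd of ancestral frequencies
    # comonotone Beta drift within blocks keeps LD consistent across groups;
    # turning it off lets linked variants drift independently, producing
    # group-specific LD patterns (the classic source of apparent effect-size
    # heterogeneity)
    block_freq_coupling: bool = True
    causal_mean: float = 1.0          # mean of truncated-Poisson causal count
    max_causal: int = 5
    fixed_causal_count: int | None = None  # overrides the Poisson draw
    causal_block_mode: str = "random"  # random | same | separate LD blocks
    causal_maf_min: float = 0.0       # cohort MAF floor when drawing causal sites
    fixed_afc: float | None = None    # |log2 aFC| magnitude (random sign) if set
    afc_sd: float = 0.5               # sd of log2 aFC effects
    noise_sd: float = 0.5             # lognormal residual sd (log2 scale)
    group_noise_scale: tuple[float, ...] | None = None  # per-group sd multipliers
    n_batches: int = 17
    batch_sd: float = 0.25            # sd of per-batch log2 shifts
    sex_effect: float = 0.2           # log2 shift for one sex
    group_shift_fraction: float = 0.0  # fraction of genes with group-level shifts
    group_shift_sd: float = 0.5       # sd of those shifts (log2)
    group_var_frac: float | None = None  # exact between-group variance fraction
    baseline_log2_range: tuple[float, float] = (3.0, 8.0)
    # splicing
    n_clusters: int = 30
    introns_per_cluster: tuple[int, int] = (2, 3)
    splice_causal_frac: float = 0.5
    splice_effect_sd: float = 1.0
    splice_logit_sd: float = 0.5
    cis_window: int = 1_000_000
    seed: int = 0

    def __post_init__(self):
        for name, f in (("f_group", self.f_group), ("f_pop", self.f_pop)):
            if not (0.0 < f < 1.0):
                raise ValueError(f"{name} must lie in (0, 1), got {f}")
        if not (0.0 <= self.ld_rho < 1.0):
            raise ValueError(f"ld_rho must lie in [0, 1), got {self.ld_rho}")
        if self.causal_block_mode not in ("random", "same", "separate"):
            raise ValueError(f"unknown causal_block_mode {self.causal_block_mode!r}")
        for name, v in (
            ("n_groups", self.n_groups),
            ("pops_per_group", self.pops_per_group),
            ("n_genes", self.n_genes),
            ("variants_per_gene", self.variants_per_gene),
        ):
            if v < 1:
                raise ValueError(f"{name} must be positive, got {v}")


@dataclass
class SimTruth:
    """Ground truth of one simulated cohort."""

    causal_variants: dict[str, list[str]] = field(default_factory=dict)
    causal_log2_afc: dict[str, list[float]] = field(default_factory=dict)
    group_shifts: dict[str, dict[str, float]] = field(default_factory=dict)
    baseline_log2: dict[str, float] = field(default_factory=dict)
    p0: dict[str, float] = field(default_factory=dict)
    group_freq: dict[str, dict[str, float]] = field(default_factory=dict)
    pop_freq: dict[str, dict[str, float]] = field(default_factory=dict)
    batch_effects: dict[str, float] = field(default_factory=dict)
    sex_effect: float = 0.0
    noise_sd: float = 0.0
    group_noise_scale: dict[str, float] = field(default_factory=dict)
    # splicing
    splice_causal: dict[str, dict] = field(default_factory=dict)

    def expected_log2_expression(
        self, gene: str, genotypes: GenotypeMatrix, samples: SampleTable
    ) -> np.ndarray:
        """Noiseless expected log2 expression under the generative model."""
        mu = np.full(genotypes.n_samples, self.baseline_log2[gene])
        idx = {v: i for i, v in enumerate(genotypes.variant_ids)}
        for vid, delta in zip(self.causal_variants[gene], self.causal_log2_afc[gene]):
            d = genotypes.dosage[idx[vid]]
            mu += np.log2(((2.0 - d) + d * 2.0**delta) / 2.0)
        shifts = self.group_shifts.get(gene)
        if shifts:
            mu += np.array([shifts[g] for g in samples.column("group")])
        mu += np.array([self.batch_effects[b] for b in samples.column("batch")])
        mu += np.where(samples.column("sex") == "F", self.sex_effect, 0.0)
        return mu

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SimTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def _beta_draw(rng, p: np.ndarray, f: float, u: np.ndarray | None = None) -> np.ndarray:
    """Balding–Nichols Beta draw around frequencies p with differentiation f.

    When ``u`` (per-variant uniforms) is given, draws are made through the
    Beta quantile function so variants sharing a u value are comonotone:
    their drifted frequencies move together, as in a real haplotype block,
    while each variant keeps its exact Balding–Nichols marginal.
    """
    p = np.clip(p, 0.0, 1.0)
    out = np.empty_like(p)
    fixed = (p <= 0.0) | (p >= 1.0)
    out[fixed] = p[fixed]
    free = ~fixed
    scale = (1.0 - f) / f
    if u is None:
        out[free] = rng.beta(p[free] * scale, (1.0 - p[free]) * scale)
    else:
        out[free] = stats.beta.ppf(u[free], p[free] * scale, (1.0 - p[free]) * scale)
    return out


def _truncated_poisson(rng, mean: float, upper: int, size: int) -> np.ndarray:
    k = np.arange(upper + 1)
    pmf = stats.poisson.pmf(k, mean)
    pmf /= pmf.sum()
    return rng.choice(k, size=size, p=pmf)


def simulate_genotypes(
    config: SimConfig,
) -> tuple[GenotypeMatrix, SampleTable, SimTruth]:
    """Draw the cohort: sample metadata, dosages, and frequency truth.

    Each gene gets its own cis block of ``variants_per_gene`` variants in a
    disjoint 2x-window region so downstream cis scans never overlap genes.
    """
    rng = np.random.default_rng(config.seed)
    truth = SimTruth(noise_sd=config.noise_sd)

    # --- samples -----------------------------------------------------------
    groups, pops, sample_ids, sample_pop, sample_group = [], [], [], [], []
    for g in range(config.n_groups):
        gname = (
            CONTINENTAL_GROUPS[g] if g < len(CONTINENTAL_GROUPS) else f"GRP{g + 1}"
        )
        groups.append(gname)
        for p in range(config.pops_per_group):
            pname = f"{gname}{p + 1:02d}"
            pops.append((pname, gname))
            n = int(rng.integers(config.pop_size_range[0], config.pop_size_range[1] + 1))
            for k in range(n):
                sample_ids.append(f"S{len(sample_ids):04d}")
                sample_pop.append(pname)
                sample_group.append(gname)
    n_samples = len(sample_ids)
    sex = rng.choice(["F", "M"], size=n_samples)
    # population-stratified batch assignment: cycle batches within population
    batch = np.empty(n_samples, dtype=object)
    offset = 0
    for pname, _ in pops:
        idx = [i for i, p in enumerate(sample_pop) if p == pname]
        for j, i in enumerate(idx):
            batch[i] = f"batch{(offset + j) % config.n_batches + 1:02d}"
        offset += 1
    samples = SampleTable(
        pd.DataFrame(
            {
                "sample": sample_ids,
                "population": sample_pop,
                "group": sample_group,
                "sex": sex,
                "batch": batch,
            }
        )
    )
    pop_of_sample = np.array(sample_pop)

    # --- variants and frequencies ------------------------------------------
    # Ancestral frequencies are anchored per LD block (with jitter) and the
    # Beta drift draws are comonotone within a block, so linked variants have
    # correlated frequencies everywhere — without which thresholded-Gaussian
    # LD would be much weaker than the latent rho suggests.
    m_per_gene = config.variants_per_gene
    n_variants = config.n_genes * m_per_gene
    n_blocks = int(np.ceil(m_per_gene / config.ld_block_size))
    block_of_variant = np.repeat(
        np.arange(config.n_genes * n_blocks), config.ld_block_size
    )[:n_variants]
    n_blocks_total = config.n_genes * n_blocks
    lo, hi = config.p0_range
    p0_block = rng.uniform(lo, hi, size=n_blocks_total)
    p0 = np.clip(
        p0_block[block_of_variant]
        + rng.normal(0.0, config.p0_block_jitter, size=n_variants),
        min(lo, 0.01),
        max(hi, 0.99),
    )

    pop_names = [p for p, _ in pops]
    group_freq = np.empty((config.n_groups, n_variants))
    pop_freq = np.empty((len(pop_names), n_variants))
    couple = config.block_freq_coupling
    for gi in range(config.n_groups):
        u = rng.uniform(size=n_blocks_total)[block_of_variant] if couple else None
        group_freq[gi] = _beta_draw(rng, p0, config.f_group, u=u)
    for pi, (_, gname) in enumerate(pops):
        gi = groups.index(gname)
        u = rng.uniform(size=n_blocks_total)[block_of_variant] if couple else None
        pop_freq[pi] = _beta_draw(rng, group_freq[gi], config.f_pop, u=u)

    variants: list[VariantRecord] = []
    span = 2 * config.cis_window + 200_000
    for g in range(config.n_genes):
        tss = config.cis_window + 100_000 + g * span
        offsets = np.sort(
            rng.choice(
                np.arange(-config.cis_window + 1, config.cis_window),
                size=m_per_gene,
                replace=False,
            )
        )
        for j, off in enumerate(offsets):
            vid = f"g{g:04d}_v{j:03d}"
            variants.append(VariantRecord("chr1", int(tss + off), vid, "A", "G"))

    # --- dosages with block LD ---------------------------------------------
    sqrt_rho = np.sqrt(config.ld_rho)
    sqrt_1m = np.sqrt(1.0 - config.ld_rho)
    dosage = np.zeros((n_variants, n_samples))
    pop_index = {p: i for i, p in enumerate(pop_names)}
    thresholds = stats.norm.ppf(np.clip(pop_freq, 0.0, 1.0))  # -inf/inf at fixation
    for pi, pname in enumerate(pop_names):
        cols = np.where(pop_of_sample == pname)[0]
        nc = len(cols)
        for hap in range(2):
            shared = rng.standard_normal((n_blocks_total, nc))
            noise = rng.standard_normal((n_variants, nc))
            z = sqrt_rho * shared[block_of_variant] + sqrt_1m * noise
            alleles = z < thresholds[pi][:, None]
            dosage[:, cols] += alleles
    genotypes = GenotypeMatrix(variants, sample_ids, dosage)

    for j, v in enumerate(variants):
        truth.p0[v.id] = float(p0[j])
        truth.group_freq[v.id] = {g: float(group_freq[gi, j]) for gi, g in enumerate(groups)}
        truth.pop_freq[v.id] = {p: float(pop_freq[pop_index[p], j]) for p in pop_names}

    # --- covariate effects --------------------------------------------------
    batches = sorted(set(batch))
    for b, eff in zip(batches, rng.normal(0.0, config.batch_sd, size=len(batches))):
        truth.batch_effects[b] = float(eff)
    truth.sex_effect = float(config.sex_effect)
    scales = config.group_noise_scale or tuple([1.0] * config.n_groups)
    truth.group_noise_scale = {g: float(s) for g, s in zip(groups, scales)}

    # --- causal architecture -----------------------------------------------
    if config.fixed_causal_count is not None:
        counts = np.full(config.n_genes, config.fixed_causal_count, dtype=int)
    else:
        counts = _truncated_poisson(
            rng, config.causal_mean, config.max_causal, config.n_genes
        )
    maf = genotypes.maf()
    for g in range(config.n_genes):
        gene = f"gene{g:04d}"
        truth.baseline_log2[gene] = float(rng.uniform(*config.baseline_log2_range))
        k = int(counts[g])
        start = g * m_per_gene
        cand = np.arange(start, start + m_per_gene)
        eligible = cand[maf[cand] > max(config.causal_maf_min, 0.0)]
        block_of = lambda i: (i - start) // config.ld_block_size  # noqa: E731
        chosen = np.empty(0, dtype=int)
        if config.causal_block_mode == "same" and k > 1:
            # all causals in one LD block so omitted signals tag each other
            block_ids = np.unique(block_of(cand))
            rng.shuffle(block_ids)
            for b in block_ids:
                in_block = eligible[block_of(eligible) == b]
                if len(in_block) >= k:
                    chosen = rng.choice(in_block, size=k, replace=False)
                    break
        elif config.causal_block_mode == "separate" and k > 1:
            # one causal per distinct LD block
            block_ids = np.unique(block_of(eligible))
            if len(block_ids) >= k:
                picks = rng.choice(block_ids, size=k, replace=False)
                chosen = np.array(
                    [rng.choice(eligible[block_of(eligible) == b]) for b in picks]
                )
        if len(chosen) == 0:
            n_draw = min(k, len(eligible))
            if n_draw < k:
                logger.info("gene %s: only %d polymorphic candidates", gene, n_draw)
            chosen = rng.choice(eligible, size=n_draw, replace=False)
        if config.fixed_afc is not None:
            deltas = config.fixed_afc * rng.choice([-1.0, 1.0], size=len(chosen))
        else:
            deltas = np.clip(
                rng.normal(0.0, config.afc_sd, size=len(chosen)),
                -LOG2_AFC_CAP, LOG2_AFC_CAP,
            )
        truth.causal_variants[gene] = [variants[i].id for i in np.sort(chosen)]
        truth.causal_log2_afc[gene] = [
            float(d) for _, d in sorted(zip(chosen, deltas))
        ]

    # --- group-level expression shifts --------------------------------------
    group_counts = samples.table.groupby("group").size()
    w = group_counts.reindex(groups).to_numpy(dtype=float)
    w /= w.sum()
    for g in range(config.n_genes):
        gene = f"gene{g:04d}"
        if config.group_var_frac is not None:
            f = config.group_var_frac
            raw = rng.standard_normal(config.n_groups)
            raw -= np.dot(w, raw)
            var = np.dot(w, raw**2)
            target = config.noise_sd**2 * f / (1.0 - f)
            raw *= np.sqrt(target / var) if var > 0 else 0.0
            truth.group_shifts[gene] = {gr: float(s) for gr, s in zip(groups, raw)}
        elif rng.random() < config.group_shift_fraction:
            raw = rng.normal(0.0, config.group_shift_sd, size=config.n_groups)
            truth.group_shifts[gene] = {gr: float(s) for gr, s in zip(groups, raw)}
    return genotypes, samples, truth


def simulate_expression(
    genotypes: GenotypeMatrix,
    samples: SampleTable,
    config: SimConfig,
    truth: SimTruth,
) -> FeatureMatrix:
    """Positive-scale expression under the multiplicative aFC model."""
    rng = np.random.default_rng(config.seed + 1)
    genes = sorted(truth.baseline_log2)
    sd = np.array(
        [
            config.noise_sd * truth.group_noise_scale.get(g, 1.0)
            for g in samples.column("group")
        ]
    )
    values = np.empty((len(genes), genotypes.n_samples))
    feats = []
    vid_pos = {v.id: v for v in genotypes.variants}
    for i, gene in enumerate(genes):
        mu = truth.expected_log2_expression(gene, genotypes, samples)
        eps = rng.normal(0.0, 1.0, size=genotypes.n_samples) * sd
        values[i] = 2.0 ** (mu + eps)
        cvars = truth.causal_variants[gene]
        if cvars:
            anchor = int(np.mean([vid_pos[v].pos for v in cvars]))
        else:
            g_index = int(gene.replace("gene", ""))
            span = 2 * config.cis_window + 200_000
            anchor = config.cis_window + 100_000 + g_index * span
        feats.append(
            {
                "feature_id": gene,
                "chrom": "chr1",
                "anchor": anchor,
                "strand": "+",
                "gene_id": gene,
                "cluster_id": None,
            }
        )
    return FeatureMatrix(pd.DataFrame(feats), list(genotypes.samples), values, "raw-count")


def simulate_splicing(
    genotypes: GenotypeMatrix,
    samples: SampleTable,
    config: SimConfig,
    truth: SimTruth,
) -> FeatureMatrix:
    """Intron-excision ratios from a logistic-normal cluster model.

    Each cluster is assigned to a simulated gene's cis region; with
    probability ``splice_causal_frac`` one intron's logit shifts linearly
    with the dosage of one causal cis variant.
    """
    rng = np.random.default_rng(config.seed + 2)
    lo, hi = config.introns_per_cluster
    if lo < 2:
        raise ValueError("clusters need at least 2 introns")
    genes = sorted(truth.baseline_log2)
    n = genotypes.n_samples
    feats, rows = [], []
    for c in range(config.n_clusters):
        gene = genes[c % len(genes)]
        g_index = int(gene.replace("gene", ""))
        k = int(rng.integers(lo, hi + 1))
        base = rng.normal(0.0, 1.0, size=k)
        logits = np.tile(base[:, None], (1, n))
        cluster = f"clu_{c:04d}"
        info: dict = {"gene": gene, "causal_variant": None, "target_intron": None,
                      "logit_effect": 0.0}
        if rng.random() < config.splice_causal_frac:
            cand = [v for v in genotypes.variant_ids if v.startswith(f"g{g_index:04d}_")]
            vid = cand[int(rng.integers(len(cand)))]
            d = genotypes.dosage[genotypes.variant_ids.index(vid)]
            eff = float(rng.normal(0.0, config.splice_effect_sd))
            tgt = int(rng.integers(k))
            logits[tgt] += eff * np.nan_to_num(d)
            info = {"gene": gene, "causal_variant": vid, "target_intron": tgt,
                    "logit_effect": eff}
        truth.splice_causal[cluster] = info
        logits += rng.normal(0.0, config.splice_logit_sd, size=(k, n))
        expl = np.exp(logits - logits.max(axis=0))
        ratios = expl / expl.sum(axis=0)
        span = 2 * config.cis_window + 200_000
        tss = config.cis_window + 100_000 + g_index * span
        for j in range(k):
            feats.append(
                {
                    "feature_id": f"{cluster}_in{j}",
                    "chrom": "chr1",
                    "anchor": int(tss + 1000 * (j + 1)),
                    "strand": "+",
                    "gene_id": gene,
                    "cluster_id": cluster,
                }
            )
            rows.append(ratios[j])
    return FeatureMatrix(
        pd.DataFrame(feats), list(genotypes.samples), np.vstack(rows), "excision-ratio"
    )


def simulate_cohort(config: SimConfig):
    """Convenience wrapper: genotypes, samples, expression, splicing, truth."""
    genotypes, samples, truth = simulate_genotypes(config)
    expression = simulate_expression(genotypes, samples, config, truth)
    splicing = simulate_splicing(genotypes, samples, config, truth)
    return genotypes, samples, expression, splicing, truth


def write_fixture(outdir, config: SimConfig, overwrite: bool = False) -> dict[str, str]:
    """Simulate a cohort and write VCF + BEDs + metadata TSV + truth JSON."""
    outdir = str(outdir)
    if os.path.isdir(outdir) and os.listdir(outdir) and not overwrite:
        raise FileExistsError(f"{outdir} exists and is not empty (use overwrite=True)")
    os.makedirs(outdir, exist_ok=True)
    genotypes, samples, expression, splicing, truth = simulate_cohort(config)
    paths = {
        "vcf": os.path.join(outdir, "genotypes.vcf"),
        "expression": os.path.join(outdir, "expression.bed"),
        "splicing": os.path.join(outdir, "splicing.bed"),
        "samples": os.path.join(outdir, "samples.tsv"),
        "truth": os.path.join(outdir, "truth.json"),
    }
    write_genotypes(paths["vcf"], genotypes)
    write_phenotype_bed(paths["expression"], expression)
    write_phenotype_bed(paths["splicing"], splicing)
    write_sample_table(paths["samples"], samples)
    truth.to_json(paths["truth"])
    return paths
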