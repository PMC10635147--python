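"""Self-contained calibration studies for the pipeline's core statistics.

Each function simulates its own study cohort with :mod:`popqtl.synthetic_data`
under fixed conditions, runs the relevant pipeline stage, and returns the
measured quantity (a coverage, an error, a rate). They serve as the
package's validation suite: the same studies back the statistical tests in
``tests/`` and the reproduction script in ``scripts/``.

Study sizes are chosen to put Monte-Carlo error well inside the decision
margins while staying desk-scale (single CPU, minutes).
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from ._rng import stage_seed
from .cis_mapping import call_significant, nominal_pass, permutation_pass
from .effect_size import estimate_afc
from .enrichment import AnnotationSet, enrichment_test, match_background
from .finemap import susie_fit
from .io_core import FeatureMatrix, GenotypeMatrix, SampleTable
from .normalization import compute_covariates, inverse_normal_transform, residualize
from .population_effects import interaction_scan, weir_cockerham_fst, _wc_pair
from .population_variance import partition_variance
from .synthetic_data import SimConfig, simulate_expression, simulate_genotypes

import pandas as pd


# ---------------------------------------------------------------------------
# Weir & Cockerham FST
# ---------------------------------------------------------------------------

def _wc_theta_general(counts_per_deme: list[np.ndarray]) -> float:
    """Independent transcription of the 1984 estimator in its general r-deme
    form (sample sizes n_i, frequencies p_i, heterozygote proportions h_i).

    Kept deliberately separate from the pipeline's two-deme implementation:
    this follows the published multi-deme formulas term by term and reduces
    to the pairwise case at r = 2.
    """
    r = len(counts_per_deme)
    n = np.array([c.sum() for c in counts_per_deme], dtype=float)  # diploids
    p = np.array(
        [(c[1] + 2 * c[2]) / (2 * c.sum()) for c in counts_per_deme], dtype=float
    )
    h = np.array([c[1] / c.sum() for c in counts_per_deme], dtype=float)
    nbar = n.mean()
    c2 = ((n / nbar - 1) ** 2).sum() / r  # squared CV of sample sizes
    nc = nbar * (1 - c2 / r) if r > 1 else nbar
    # equivalently nc = (r*nbar - sum(n^2)/(r*nbar)) / (r-1)
    nc = (r * nbar - (n**2).sum() / (r * nbar)) / (r - 1)
    pbar = (n * p).sum() / (r * nbar)
    s2 = (n * (p - pbar) ** 2).sum() / ((r - 1) * nbar)
    hbar = (n * h).sum() / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    denom = a + b + c
    return a / denom if denom != 0 else float("nan")


def _random_two_group_matrix(rng, n_per_group=20) -> tuple[GenotypeMatrix, SampleTable]:
    from .io_core import VariantRecord

    p1, p2 = rng.uniform(0.05, 0.95, size=2)
    d1 = rng.binomial(2, p1, size=n_per_group)
    d2 = rng.binomial(2, p2, size=n_per_group)
    if np.concatenate([d1, d2]).std() == 0:
        d1[0] = 1  # avoid the degenerate monomorphic toy
    dosage = np.concatenate([d1, d2])[None, :].astype(float)
    samples = [f"s{i}" for i in range(2 * n_per_group)]
    table = SampleTable(
        pd.DataFrame(
            {
                "sample": samples,
                "population": ["P1"] * n_per_group + ["P2"] * n_per_group,
                "group": ["G1"] * n_per_group + ["G2"] * n_per_group,
                "sex": "F",
                "batch": "b1",
            }
        )
    )
    genotypes = GenotypeMatrix(
        [VariantRecord("chr1", 100, "v0", "A", "G")], samples, dosage
    )
    return genotypes, table


def fst_formula_agreement(seed: int = 0, n_toys: int = 100) -> dict:
    """Max |pipeline theta - general-form oracle theta| over random toys."""
    rng = np.random.default_rng(stage_seed(seed, "fst-oracle"))
    max_diff = 0.0
    for _ in range(n_toys):
        genotypes, table = _random_two_group_matrix(rng)
        res = weir_cockerham_fst(genotypes, table, focal="G1")[0]
        theta = res.pairwise_theta["G2"]
        counts = []
        for grp in ("G1", "G2"):
            d = genotypes.dosage[0][table.column("group") == grp]
            counts.append(np.array([(d == k).sum() for k in (0, 1, 2)], dtype=float))
        oracle = _wc_theta_general(counts)
        if np.isnan(theta) and np.isnan(oracle):
            continue
        max_diff = max(max_diff, abs(theta - oracle))
    return {"max_abs_diff": max_diff, "n": n_toys}


def fst_balding_nichols_calibration(
    seed: int = 0, n_variants: int = 1000, n_per_group: int = 200, f: float = 0.1
) -> dict:
    """Mean pairwise theta over Balding–Nichols variants; should recover F."""
    cfg = SimConfig(
        n_groups=2, pops_per_group=1, pop_size_range=(n_per_group, n_per_group),
        n_genes=max(1, n_variants // 100), variants_per_gene=100,
        f_group=f, f_pop=1e-6, ld_rho=0.0,
        seed=stage_seed(seed, "fst-calibration"),
    )
    genotypes, samples, _ = simulate_genotypes(cfg)
    res = weir_cockerham_fst(genotypes, samples, focal=samples.column("group")[0])
    thetas = np.array([r.mean_theta for r in res])
    return {
        "mean_theta": float(np.nanmean(thetas)),
        "n": int(np.isfinite(thetas).sum()),
    }


# ---------------------------------------------------------------------------
# Fine-mapping calibration
# ---------------------------------------------------------------------------

def _residualized_cohort(cfg: SimConfig, n_pheno_pcs: int = 0):
    genotypes, samples, truth = simulate_genotypes(cfg)
    expr = simulate_expression(genotypes, samples, cfg, truth)
    normed = inverse_normal_transform(expr)
    cov = compute_covariates(
        genotypes, normed, samples, n_geno_pcs=5, n_pheno_pcs=n_pheno_pcs
    )
    resid = residualize(normed, cov)
    return genotypes, samples, truth, expr, resid


def finemap_single_causal_coverage(seed: int = 0, n_genes: int = 200) -> dict:
    """Fraction of reported 95% credible sets containing the causal variant."""
    cfg = SimConfig(
        n_genes=n_genes, variants_per_gene=100, ld_rho=0.9,
        fixed_causal_count=1, seed=stage_seed(seed, "finemap-single"),
    )
    genotypes, _, truth, _, resid = _residualized_cohort(cfg)
    m = cfg.variants_per_gene
    covered, total, sizes = 0, 0, []
    for gi in range(n_genes):
        gene = f"gene{gi:04d}"
        sl = slice(gi * m, (gi + 1) * m)
        _, sets = susie_fit(
            genotypes.dosage[sl], resid.values[gi],
            variant_ids=[v.id for v in genotypes.variants[sl]], feature_id=gene,
        )
        causal = truth.causal_variants[gene][0]
        for cs in sets:
            total += 1
            covered += causal in cs.variants
            sizes.append(len(cs.variants))
    return {
        "coverage": covered / max(total, 1),
        "n": total,
        "median_set_size": float(np.median(sizes)) if sizes else float("nan"),
    }


def finemap_two_causal_assignment(seed: int = 0, n_genes: int = 50) -> dict:
    """Rate at which two separated causal signals both land in credible sets.

    Two causal variants per gene (|log2 aFC| = 0.5 each, cohort MAF >= 0.05)
    in distinct LD blocks; success = at least two credible sets with each
    causal variant contained in one of them.
    """
    cfg = SimConfig(
        n_genes=n_genes, variants_per_gene=100, ld_rho=0.9,
        fixed_causal_count=2, fixed_afc=0.5, causal_block_mode="separate",
        causal_maf_min=0.05, seed=stage_seed(seed, "finemap-two"),
    )
    genotypes, _, truth, _, resid = _residualized_cohort(cfg)
    m = cfg.variants_per_gene
    ok = 0
    for gi in range(n_genes):
        gene = f"gene{gi:04d}"
        sl = slice(gi * m, (gi + 1) * m)
        _, sets = susie_fit(
            genotypes.dosage[sl], resid.values[gi],
            variant_ids=[v.id for v in genotypes.variants[sl]], feature_id=gene,
        )
        c1, c2 = truth.causal_variants[gene]
        ok += (
            len(sets) >= 2
            and any(c1 in cs.variants for cs in sets)
            and any(c2 in cs.variants for cs in sets)
        )
    return {"assignment_rate": ok / n_genes, "n": n_genes}


# ---------------------------------------------------------------------------
# aFC recovery
# ---------------------------------------------------------------------------

def afc_noiseless_recovery(seed: int = 0) -> dict:
    """Joint-fit error for two causal effects (1.0, -0.5) with zero noise."""
    cfg = SimConfig(
        n_genes=5, variants_per_gene=50, ld_rho=0.9,
        fixed_causal_count=2, causal_block_mode="separate", causal_maf_min=0.05,
        noise_sd=0.0, batch_sd=0.0, sex_effect=0.0,
        seed=stage_seed(seed, "afc-noiseless"),
    )
    genotypes, samples, truth = simulate_genotypes(cfg)
    for gene in truth.causal_log2_afc:
        truth.causal_log2_afc[gene] = [1.0, -0.5]
    expr = simulate_expression(genotypes, samples, cfg, truth)
    leads = {g: list(v) for g, v in truth.causal_variants.items()}
    est = estimate_afc(expr, genotypes, leads, n_boot=0)
    errs = []
    for e in est:
        lookup = dict(
            zip(truth.causal_variants[e.gene_id], truth.causal_log2_afc[e.gene_id])
        )
        errs.append(abs(e.log2_afc - lookup[e.variant_id]))
    return {"max_abs_error": float(max(errs)), "n": len(errs)}


def afc_grid_error(
    seed: int = 0,
    mafs=(0.05, 0.2, 0.5),
    deltas=(0.25, 0.5, 1.0, 2.0),
    genes_per_cell: int = 5,
    noise_sd: float = 0.5,
) -> dict:
    """Mean |log2 aFC error| over the MAF x effect-size grid at cohort scale."""
    per_cell = {}
    errs_common = []
    for maf in mafs:
        for delta in deltas:
            cfg = SimConfig(
                n_genes=genes_per_cell, variants_per_gene=5, ld_rho=0.0,
                pop_size_range=(29, 30),
                p0_range=(maf, maf), p0_block_jitter=0.0,
                f_group=1e-3, f_pop=1e-3,
                fixed_causal_count=1, fixed_afc=delta,
                noise_sd=noise_sd, batch_sd=0.0, sex_effect=0.0,
                seed=stage_seed(seed, f"afc-grid-{maf}-{delta}"),
            )
            genotypes, samples, truth = simulate_genotypes(cfg)
            expr = simulate_expression(genotypes, samples, cfg, truth)
            leads = {g: list(v) for g, v in truth.causal_variants.items() if v}
            est = estimate_afc(expr, genotypes, leads, n_boot=0)
            cell = []
            for e in est:
                lookup = dict(
                    zip(
                        truth.causal_variants[e.gene_id],
                        truth.causal_log2_afc[e.gene_id],
                    )
                )
                cell.append(abs(e.log2_afc - lookup[e.variant_id]))
            per_cell[(maf, delta)] = float(np.mean(cell))
            if maf >= 0.2:
                errs_common.extend(cell)
    return {
        "mean_abs_error_maf_ge_0.2": float(np.mean(errs_common)),
        "per_cell": per_cell,
        "n": len(errs_common),
    }


# ---------------------------------------------------------------------------
# Permutation machinery
# ---------------------------------------------------------------------------

def _mapping_cohort(n_genes, fixed, afc, seed, pop_size=50, n_perm=1000):
    cfg = SimConfig(
        n_genes=n_genes, variants_per_gene=50, ld_rho=0.9,
        pops_per_group=2, pop_size_range=(pop_size, pop_size),
        fixed_causal_count=fixed, fixed_afc=afc, causal_maf_min=0.1,
        p0_range=(0.3, 0.3) if fixed else (0.05, 0.95),
        seed=seed,
    )
    genotypes, samples, truth = simulate_genotypes(cfg)
    expr = simulate_expression(genotypes, samples, cfg, truth)
    normed = inverse_normal_transform(expr)
    cov = compute_covariates(genotypes, normed, samples, n_geno_pcs=5, n_pheno_pcs=0)
    resid = residualize(normed, cov)
    return permutation_pass(genotypes, resid, n_perm=n_perm, seed=seed + 1)


def null_effective_p_uniformity(
    seed: int = 0, n_reps: int = 10, n_genes: int = 50, pop_size: int = 28
) -> dict:
    """Mean KS p-value of gene-level effective p against Uniform(0,1)."""
    ks_ps = []
    for rep in range(n_reps):
        res = _mapping_cohort(
            n_genes, 0, None, stage_seed(seed, f"null-unif-{rep}"), pop_size=pop_size
        )
        peff = np.array([r.p_effective for r in res])
        ks_ps.append(stats.kstest(peff, "uniform").pvalue)
    return {"mean_ks_p": float(np.mean(ks_ps)), "n": n_reps}


def egene_call_fdr(
    seed: int = 0, n_reps: int = 10, n_true: int = 30, n_null: int = 70
) -> dict:
    """Empirical FDR and power of eGene calls at nominal FDR 0.05.

    Each replicate mixes genes with one causal variant (|log2 aFC| = 1,
    causal MAF ~ 0.3, n = 500) and null genes; calls are pooled across
    replicates.
    """
    n_called = n_false = n_true_called = 0
    for rep in range(n_reps):
        res_true = _mapping_cohort(
            n_true, 1, 1.0, stage_seed(seed, f"fdr-true-{rep}")
        )
        res_null = _mapping_cohort(
            n_null, 0, None, stage_seed(seed, f"fdr-null-{rep}")
        )
        for r in res_null:
            r.feature_id = "null_" + r.feature_id
        calls = call_significant(res_true + res_null, fdr=0.05)
        sig = calls.table[calls.table["significant"]]
        n_called += len(sig)
        n_false += int(sig["feature_id"].str.startswith("null_").sum())
        n_true_called += int((~sig["feature_id"].str.startswith("null_")).sum())
    return {
        "empirical_fdr": n_false / max(n_called, 1),
        "power": n_true_called / (n_reps * n_true),
        "n": n_called,
    }


# ---------------------------------------------------------------------------
# Interaction heterogeneity
# ---------------------------------------------------------------------------

def interaction_type1(seed: int = 0, n_genes: int = 1000, alpha: float = 0.05) -> dict:
    """Raw rejection rate of the single-model interaction test under
    purely additive single-causal generation (one gene = one replicate)."""
    cfg = SimConfig(
        n_genes=n_genes, variants_per_gene=10, ld_block_size=5, ld_rho=0.6,
        fixed_causal_count=1, fixed_afc=0.5, causal_maf_min=0.05,
        batch_sd=0.0, sex_effect=0.0, seed=stage_seed(seed, "inter-null"),
    )
    genotypes, samples, truth = simulate_genotypes(cfg)
    expr = simulate_expression(genotypes, samples, cfg, truth)
    y = np.log2(expr.values)
    mat = expr.with_values(y - y.mean(axis=1, keepdims=True), kind="normalized")
    leads = {g: list(v) for g, v in truth.causal_variants.items() if v}
    res = interaction_scan(genotypes, mat, samples, leads, mode="single", alpha=alpha)
    ps = np.array([r.p_single for r in res if r.tested])
    return {"rejection_rate": float(np.mean(ps < alpha)), "n": len(ps)}


def interaction_rescue(seed: int = 0, n_genes: int = 200, alpha: float = 0.05) -> dict:
    """Fraction of single-model Bonferroni interaction hits that lose
    significance once the gene's other causal signal enters the model.

    Generator: two additive causal variants per gene in the same LD block,
    |log2 aFC| = 1 each, group differentiation F_G = 0.15, with the block's
    frequencies drifting independently per group so LD patterns differ
    between groups — the mechanism that manufactures apparent heterogeneity.
    """
    cfg = SimConfig(
        n_genes=n_genes, variants_per_gene=10, ld_block_size=10, ld_rho=0.9,
        f_group=0.15, fixed_causal_count=2, fixed_afc=1.0,
        causal_block_mode="same", causal_maf_min=0.05, block_freq_coupling=False,
        batch_sd=0.0, sex_effect=0.0, seed=stage_seed(seed, "inter-rescue"),
    )
    genotypes, samples, truth = simulate_genotypes(cfg)
    expr = simulate_expression(genotypes, samples, cfg, truth)
    y = np.log2(expr.values)
    mat = expr.with_values(y - y.mean(axis=1, keepdims=True), kind="normalized")
    leads = {g: v for g, v in truth.causal_variants.items() if len(v) == 2}
    res = interaction_scan(genotypes, mat, samples, leads, mode="both", alpha=alpha)
    tested = [r for r in res if r.tested]
    thr = alpha / len(tested)
    hits = [r for r in tested if r.p_single <= thr]
    rescued = [r for r in hits if r.p_joint > thr]
    joint_raw = np.array([r.p_joint for r in tested])
    return {
        "rescue_fraction": len(rescued) / max(len(hits), 1),
        "n_hits": len(hits),
        "n_tested": len(tested),
        "single_raw_rejection": float(
            np.mean(np.array([r.p_single for r in tested]) < alpha)
        ),
        "joint_raw_rejection": float(np.mean(joint_raw < alpha)),
        "n": len(hits),
    }


# ---------------------------------------------------------------------------
# Variance partitioning
# ---------------------------------------------------------------------------

def variance_partition_recovery(
    seed: int = 0, n_genes: int = 200, target_frac: float = 0.10, n_perm: int = 999
) -> dict:
    """Recover a configured between-group variance fraction."""
    cfg = SimConfig(
        n_genes=n_genes, variants_per_gene=10, fixed_causal_count=0,
        group_var_frac=target_frac, batch_sd=0.2,
        seed=stage_seed(seed, "varpart"),
    )
    genotypes, samples, truth = simulate_genotypes(cfg)
    expr = simulate_expression(genotypes, samples, cfg, truth)
    normed = inverse_normal_transform(expr)
    cov = compute_covariates(genotypes, normed, samples, n_geno_pcs=0, n_pheno_pcs=0)
    resid = residualize(normed, cov)
    res = partition_variance(
        resid, samples, level="group", n_perm=n_perm,
        seed=stage_seed(seed, "varpart-perm"),
    )
    return {
        "mean_r2": res.mean_r2,
        "perm_pvalue": res.perm_pvalue,
        "p_floor": 1.0 / (n_perm + 1),
        "n": n_genes,
    }


# ---------------------------------------------------------------------------
# Enrichment
# ---------------------------------------------------------------------------

def _fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by direct hypergeometric summation."""
    n = a + b + c + d
    row1, col1 = a + b, a + c
    kmin, kmax = max(0, row1 + col1 - n), min(row1, col1)
    ks = np.arange(kmin, kmax + 1)
    pmf = stats.hypergeom.pmf(ks, n, col1, row1)
    p_obs = stats.hypergeom.pmf(a, n, col1, row1)
    return float(pmf[pmf <= p_obs * (1 + 1e-9)].sum())


def enrichment_fisher_oracle(seed: int = 0, n_tables: int = 50) -> dict:
    """Max |scipy Fisher p - direct hypergeometric summation| over random
    2x2 tables (plus the canonical 30/70 vs 10/90 table)."""
    rng = np.random.default_rng(stage_seed(seed, "fisher-oracle"))
    tables = [(30, 70, 10, 90)]
    for _ in range(n_tables):
        tables.append(tuple(int(x) for x in rng.integers(0, 60, size=4)))
    max_diff = 0.0
    for a, b, c, d in tables:
        if (a + b) == 0 or (c + d) == 0:
            continue
        _, p = stats.fisher_exact([[a, b], [c, d]])
        p_oracle = _fisher_two_sided_oracle(a, b, c, d)
        max_diff = max(max_diff, abs(p - p_oracle))
    return {"max_abs_diff": max_diff, "n": len(tables)}


def enrichment_planted_promoter(
    seed: int = 0, n_reps: int = 25, odds: float = 5.0,
    n_leads: int = 100, n_pool: int = 5000,
) -> dict:
    """Detection rate of a planted promoter preference for lead variants.

    Promoter intervals cover 20% of the region; leads fall inside with
    placement odds ``odds``:1 relative to density. Detection = promoter
    Bonferroni p < 0.05 with fold > 1. A decoy annotation straddles
    promoter and non-promoter space in the genome-wide 20:80 proportion, so
    its expected fold is 1 regardless of the planted preference; its mean
    log2 fold is the negative control.
    """
    detected = 0
    decoy_l2 = []
    region = 1_000_000
    prom = [(i * 20_000 + 1, i * 20_000 + 4_000) for i in range(50)]  # 20% cover
    in_prom = np.zeros(region + 1, dtype=bool)
    for s, e in prom:
        in_prom[s : e + 1] = True
    # decoy: per 20 kb window, 800 bp inside the promoter + 3200 bp outside
    decoy = [(i * 20_000 + 3_201, i * 20_000 + 7_200) for i in range(50)]
    ann = [
        AnnotationSet(
            "promoter",
            pd.DataFrame(prom, columns=["start", "end"]).assign(chrom="chr1")[
                ["chrom", "start", "end"]
            ],
        ),
        AnnotationSet(
            "decoy",
            pd.DataFrame(decoy, columns=["start", "end"]).assign(chrom="chr1")[
                ["chrom", "start", "end"]
            ],
        ),
    ]
    for rep in range(n_reps):
        rng = np.random.default_rng(stage_seed(seed, f"planted-{rep}"))
        p_in = odds * 0.2 / (odds * 0.2 + 0.8)
        lead_pos = np.where(
            rng.random(n_leads) < p_in,
            rng.choice(np.where(in_prom[1:])[0] + 1, size=n_leads),
            rng.choice(np.where(~in_prom[1:])[0] + 1, size=n_leads),
        )
        pool_pos = rng.integers(1, region + 1, size=n_pool)
        leads = pd.DataFrame(
            {
                "variant_id": [f"lead{i}" for i in range(n_leads)],
                "chrom": "chr1", "pos": lead_pos,
                "maf": rng.uniform(0.05, 0.5, n_leads),
                "distance": rng.integers(-500_000, 500_000, n_leads),
            }
        )
        pool = pd.DataFrame(
            {
                "variant_id": [f"bg{i}" for i in range(n_pool)],
                "chrom": "chr1", "pos": pool_pos,
                "maf": rng.uniform(0.05, 0.5, n_pool),
                "distance": rng.integers(-500_000, 500_000, n_pool),
            }
        )
        background = match_background(
            leads, pool, ratio=10, seed=stage_seed(seed, f"planted-bg-{rep}")
        )
        results = {r.annotation: r for r in enrichment_test(leads, background, ann)}
        prom_res = results["promoter"]
        detected += prom_res.p_bonferroni < 0.05 and prom_res.fold > 1.0
        decoy_l2.append(results["decoy"].log2_fold)
    return {
        "detection_rate": detected / n_reps,
        "mean_decoy_log2_fold": float(np.mean(decoy_l2)),
        "n": n_reps,
    }


# ---------------------------------------------------------------------------
# End-to-end recovery
# ---------------------------------------------------------------------------

def end_to_end_recovery(
    seed: int = 0,
    n_genes: int = 50,
    pops_per_group: int = 5,
    pop_size: tuple[int, int] = (27, 30),
    n_perm: int = 1000,
    min_abs_afc: float = 0.5,
    min_maf: float = 0.1,
) -> dict:
    """Run simulate -> normalize -> map-cis -> finemap and score recovery.

    Reports the fraction of genes carrying a causal variant with
    |log2 aFC| >= 0.5 and MAF >= 0.1 that are called eGenes at 5% FDR, and
    the fraction of their credible sets containing a true causal variant.
    """
    cfg = SimConfig(
        n_genes=n_genes, variants_per_gene=100, ld_rho=0.9,
        pops_per_group=pops_per_group, pop_size_range=pop_size,
        seed=stage_seed(seed, "e2e"),
    )
    genotypes, samples, truth = simulate_genotypes(cfg)
    expr = simulate_expression(genotypes, samples, cfg, truth)
    normed = inverse_normal_transform(expr)
    cov = compute_covariates(genotypes, normed, samples, n_geno_pcs=5, n_pheno_pcs=0)
    resid = residualize(normed, cov)
    maf = dict(zip(genotypes.variant_ids, genotypes.maf()))
    eligible = {
        gene
        for gene, (vs, ds) in (
            (g, (truth.causal_variants[g], truth.causal_log2_afc[g]))
            for g in truth.causal_variants
        )
        if any(abs(d) >= min_abs_afc and maf[v] >= min_maf for v, d in zip(vs, ds))
    }
    perm = permutation_pass(
        genotypes, resid, n_perm=n_perm, seed=stage_seed(seed, "e2e-perm")
    )
    calls = call_significant(perm, fdr=0.05)
    egenes = set(calls.table.loc[calls.table["significant"], "feature_id"])
    recall = len(eligible & egenes) / max(len(eligible), 1)

    m = cfg.variants_per_gene
    findex = {f: i for i, f in enumerate(resid.feature_ids)}
    n_sets = n_hit = 0
    for gene in sorted(eligible & egenes):
        gi = findex[gene]
        sl = slice(gi * m, (gi + 1) * m)
        _, sets = susie_fit(
            genotypes.dosage[sl], resid.values[gi],
            variant_ids=[v.id for v in genotypes.variants[sl]], feature_id=gene,
        )
        causal = set(truth.causal_variants[gene])
        for cs in sets:
            n_sets += 1
            n_hit += bool(causal & set(cs.variants))
    return {
        "egene_recall": recall,
        "n_eligible": len(eligible),
        "credible_set_hit_rate": n_hit / max(n_sets, 1),
        "n_sets": n_sets,
    }
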