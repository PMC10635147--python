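"""Population-level characterization of lead QTLs.

Operations here ask how causal regulatory signals behave across the
cohort's continental groups:

* Weir & Cockerham (1984) FST between the focal group and every other
  group for each lead variant (variance-component estimator; negative
  estimates retained).
* Geographic frequency classification of lead variants (globally common /
  absent in EUR / absent in EUR+AFR / other).
* Differential-expression coupling: lead-variant FST by DE decile of the
  eGene, contrasting the focal group against the rest.
* Genotype-by-continental-group interaction tests, in a single-signal
  model and a joint model conditioning on all other leads of the gene —
  the joint model absorbs apparent heterogeneity created by unmodelled
  additive signals.
* Constraint associations (pLI-style scores vs eGene status, credible-set
  counts, effect sizes) and an abstract cross-study credible-set
  replication operator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .finemap import CredibleSet
from .io_core import CohortError, FeatureMatrix, GenotypeMatrix, SampleTable


# ---------------------------------------------------------------------------
# Weir & Cockerham FST
# ---------------------------------------------------------------------------

@dataclass
class FstResult:
    variant_id: str
    focal_group: str
    pairwise_theta: dict[str, float]          # other group -> theta (NaN undefined)
    mean_theta: float
    components: dict[str, tuple[float, float, float]] = field(default_factory=dict)


def _wc_pair(
    n1: float, p1: float, h1: float, n2: float, p2: float, h2: float
) -> tuple[float, float, float]:
    """Weir & Cockerham (1984) variance components (a, b, c) for two demes.

    n: diploid sample sizes, p: alt-allele frequencies, h: observed
    heterozygote proportions.
    """
    r = 2.0
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (1.0 / (nbar - 1.0)) * (pbar * (1.0 - pbar) - ((r - 1.0) / r) * s2 - hbar / 4.0)
    )
    b = (nbar / (nbar - 1.0)) * (
        pbar * (1.0 - pbar) - ((r - 1.0) / r) * s2 - ((2.0 * nbar - 1.0) / (4.0 * nbar)) * hbar
    )
    c = hbar / 2.0
    return a, b, c


def weir_cockerham_fst(
    genotypes: GenotypeMatrix,
    samples: SampleTable,
    focal: str,
    variants: list[str] | None = None,
) -> list[FstResult]:
    """Pairwise focal-vs-other-group theta-hat per variant.

    Per (focal, other) pair theta = a / (a + b + c); pairs monomorphic in
    both groups are flagged undefined (NaN) rather than zero. The mean
    theta is the arithmetic mean over defined pairs.
    """
    groups = samples.column("group")
    uniq = list(pd.unique(groups))
    if focal not in uniq:
        raise CohortError(f"focal group {focal!r} absent from sample table")
    if len(uniq) < 2:
        raise CohortError("need at least two continental groups")
    if variants is None:
        variants = genotypes.variant_ids
    vindex = {v: i for i, v in enumerate(genotypes.variant_ids)}
    missing = [v for v in variants if v not in vindex]
    if missing:
        raise CohortError(f"variants absent from genotypes: {missing}")
    cols = {g: np.where(groups == g)[0] for g in uniq}
    results = []
    for vid in variants:
        row = genotypes.dosage[vindex[vid]]
        stats_by_group = {}
        for g, idx in cols.items():
            d = row[idx]
            d = d[~np.isnan(d)]
            if len(d) < 2:
                raise CohortError(f"group {g} has <2 genotyped samples at {vid}")
            stats_by_group[g] = (float(len(d)), float(d.mean() / 2.0), float(np.mean(d == 1.0)))
        n1, p1, h1 = stats_by_group[focal]
        pairwise, comps = {}, {}
        for g in uniq:
            if g == focal:
                continue
            n2, p2, h2 = stats_by_group[g]
            a, b, c = _wc_pair(n1, p1, h1, n2, p2, h2)
            denom = a + b + c
            pairwise[g] = a / denom if denom != 0.0 else float("nan")
            comps[g] = (a, b, c)
        thetas = [t for t in pairwise.values() if not np.isnan(t)]
        mean_theta = float(np.mean(thetas)) if thetas else float("nan")
        results.append(FstResult(vid, focal, pairwise, mean_theta, comps))
    return results


# ---------------------------------------------------------------------------
# Geographic frequency classification
# ---------------------------------------------------------------------------

FREQUENCY_CLASSES = ("globally_common", "absent_EUR", "absent_EUR_AFR", "other")


def classify_frequency_distribution(
    freqs: pd.DataFrame, common_threshold: float = 0.05
) -> pd.DataFrame:
    """Classify variants by their per-continental-group allele frequencies.

    ``freqs``: variants x groups table of alternate-allele frequencies
    (columns must include EUR and AFR). Classes, evaluated in order:
    absent_EUR_AFR (AF = 0 in both EUR and AFR, > 0 elsewhere), absent_EUR
    (AF = 0 in EUR, > 0 in at least one other group), globally_common
    (AF > threshold in all groups), otherwise other.
    """
    arr = freqs.to_numpy(dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise CohortError("allele frequencies must lie in [0, 1]")
    if np.any(arr.sum(axis=1) == 0):
        bad = freqs.index[arr.sum(axis=1) == 0].tolist()
        raise CohortError(f"variants monomorphic in every group: {bad[:5]}")
    for col in ("EUR", "AFR"):
        if col not in freqs.columns:
            raise CohortError(f"frequency table missing group column {col!r}")
    eur = freqs["EUR"].to_numpy(dtype=float)
    afr = freqs["AFR"].to_numpy(dtype=float)
    labels = np.full(len(freqs), "other", dtype=object)
    labels[(arr > common_threshold).all(axis=1)] = "globally_common"
    labels[(eur == 0) & (arr.max(axis=1) > 0)] = "absent_EUR"
    labels[(eur == 0) & (afr == 0) & (arr.max(axis=1) > 0)] = "absent_EUR_AFR"
    out = freqs.copy()
    out["class"] = labels
    return out


# ---------------------------------------------------------------------------
# Differential expression and FST coupling
# ---------------------------------------------------------------------------

def differential_expression_by_group(
    matrix: FeatureMatrix, samples: SampleTable, focal: str
) -> pd.DataFrame:
    """Two-sample contrast (focal group vs all others) per gene.

    Residualized expression is compared by an equal-variance linear
    contrast (identical to the pooled two-sample t-test); genes are ranked
    by p and binned into deciles, where decile 10 holds the smallest
    p-values. BH-adjusted q-values are included.
    """
    groups = samples.column("group")
    mask = groups == focal
    n1, n2 = int(mask.sum()), int((~mask).sum())
    if n1 == 0:
        raise CohortError(f"focal group {focal!r} absent")
    y = matrix.values
    m1 = y[:, mask].mean(axis=1)
    m2 = y[:, ~mask].mean(axis=1)
    ss = ((y[:, mask] - m1[:, None]) ** 2).sum(axis=1) + (
        (y[:, ~mask] - m2[:, None]) ** 2
    ).sum(axis=1)
    dfree = n1 + n2 - 2
    sp2 = ss / dfree
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * stats.t.sf(np.abs(t), dfree)
    q = sm.stats.multipletests(p, method="fdr_bh")[1]
    n = len(p)
    ranks = stats.rankdata(p, method="ordinal")  # 1 = smallest p
    decile = 10 - ((ranks - 1) * 10 // n).astype(int)
    return pd.DataFrame(
        {
            "gene_id": matrix.features["gene_id"].to_numpy(),
            "feature_id": matrix.feature_ids,
            "delta_mean": m1 - m2,
            "tstat": t,
            "pvalue": p,
            "qvalue": q,
            "decile": decile,
        }
    )


def fst_de_association(
    fst_by_gene: pd.DataFrame,
    de: pd.DataFrame,
    de_q_threshold: float = 0.05,
    n_boot: int = 200,
    seed: int = 0,
) -> dict:
    """Relate lead-eQTL frequency differentiation to differential expression.

    ``fst_by_gene``: columns gene_id, mean_theta (one row per eGene lead).
    Reports mean FST per DE decile, a Mann–Whitney rank-sum test of FST for
    DE (q <= threshold) vs non-DE eGenes, and the rank-biserial effect size
    with a bootstrap percentile interval.
    """
    merged = fst_by_gene.merge(de, on="gene_id")
    merged = merged[np.isfinite(merged["mean_theta"])]
    if merged.empty:
        raise CohortError("no genes shared between FST table and DE table")
    if merged["decile"].nunique() < 2:
        raise CohortError("degenerate DE binning: a single decile populated")
    decile_means = merged.groupby("decile")["mean_theta"].mean()
    is_de = merged["qvalue"] <= de_q_threshold
    x = merged.loc[is_de, "mean_theta"].to_numpy()
    z = merged.loc[~is_de, "mean_theta"].to_numpy()
    if len(x) and len(z):
        u, p = stats.mannwhitneyu(x, z, alternative="two-sided")
        rb = 2.0 * u / (len(x) * len(z)) - 1.0
        rng = np.random.default_rng(seed)
        boots = []
        for _ in range(n_boot):
            xb = rng.choice(x, size=len(x))
            zb = rng.choice(z, size=len(z))
            ub, _ = stats.mannwhitneyu(xb, zb, alternative="two-sided")
            boots.append(2.0 * ub / (len(xb) * len(zb)) - 1.0)
        ci = (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5)))
    else:
        u, p, rb, ci = float("nan"), float("nan"), float("nan"), (float("nan"),) * 2
    return {
        "decile_mean_fst": decile_means,
        "n_de": int(is_de.sum()),
        "n_non_de": int((~is_de).sum()),
        "mannwhitney_u": float(u),
        "pvalue": float(p),
        "rank_biserial": float(rb),
        "rank_biserial_ci": ci,
    }


# ---------------------------------------------------------------------------
# Genotype-by-group interaction scan
# ---------------------------------------------------------------------------

@dataclass
class InteractionResult:
    gene_id: str
    variant_id: str
    n_credible_sets: int
    p_single: float | None = None
    p_joint: float | None = None
    tested: bool = True
    skip_reason: str | None = None
    significant_single: bool | None = None
    significant_joint: bool | None = None


def _nested_f(y, x0, x1) -> float:
    """p-value of the F-test comparing nested OLS designs x0 within x1."""
    n = len(y)
    q0, _ = np.linalg.qr(x0)
    q1, _ = np.linalg.qr(x1)
    rss0 = float(np.sum((y - q0 @ (q0.T @ y)) ** 2))
    rss1 = float(np.sum((y - q1 @ (q1.T @ y)) ** 2))
    df_extra = np.linalg.matrix_rank(x1) - np.linalg.matrix_rank(x0)
    df_resid = n - np.linalg.matrix_rank(x1)
    if df_extra <= 0 or df_resid <= 0:
        return float("nan")
    f = ((rss0 - rss1) / df_extra) / (rss1 / df_resid)
    return float(stats.f.sf(max(f, 0.0), df_extra, df_resid))


def interaction_scan(
    genotypes: GenotypeMatrix,
    matrix: FeatureMatrix,
    samples: SampleTable,
    leads: dict[str, list[str]],
    mode: str = "both",
    alpha: float = 0.05,
    maf_min: float = 0.05,
    min_group_n: int = 10,
) -> list[InteractionResult]:
    """Genotype-by-continental-group interaction test per lead eQTL.

    A lead is tested only if its MAF is >= ``maf_min`` in at least two
    continental groups (groups smaller than ``min_group_n`` are excluded
    from the test and from the filter). Single mode compares
    y ~ g + group against y ~ g + group + g x group by an omnibus F-test;
    joint mode adds additive dosage terms for every other lead of the gene
    to both models. Bonferroni significance uses alpha / n tested leads.
    """
    if mode not in ("single", "joint", "both"):
        raise ValueError(f"unknown mode {mode!r}")
    if not leads:
        raise CohortError("empty lead list")
    if list(genotypes.samples) != list(matrix.samples):
        raise CohortError("genotypes and phenotypes are not sample-aligned")
    groups = samples.column("group")
    uniq, counts = np.unique(groups, return_counts=True)
    big = [g for g, c in zip(uniq, counts) if c >= min_group_n]
    use = np.isin(groups, big)
    dosage = genotypes.imputed()
    vindex = {v: i for i, v in enumerate(genotypes.variant_ids)}
    findex = {f: i for i, f in enumerate(matrix.feature_ids)}
    glabels = groups[use]
    guniq = pd.unique(glabels)
    onehot = np.column_stack([(glabels == g).astype(float) for g in guniq[1:]])

    results: list[InteractionResult] = []
    for gene, lead_ids in leads.items():
        if gene not in findex:
            raise CohortError(f"gene {gene} absent from phenotype matrix")
        y = matrix.values[findex[gene]][use]
        for vid in lead_ids:
            if vid not in vindex:
                raise CohortError(f"lead {vid} absent from genotypes")
            g = dosage[vindex[vid]][use]
            n_sets = len(lead_ids)
            if len(guniq) < 2:
                results.append(
                    InteractionResult(gene, vid, n_sets, tested=False,
                                      skip_reason="fewer than two groups of usable size")
                )
                continue
            af = np.array([g[glabels == gr].mean() / 2.0 for gr in guniq])
            maf = np.minimum(af, 1.0 - af)
            if np.sum(maf >= maf_min) < 2:
                results.append(
                    InteractionResult(gene, vid, n_sets, tested=False,
                                      skip_reason="MAF filter")
                )
                continue
            res = InteractionResult(gene, vid, n_sets)
            gx = g[:, None] * onehot
            others = [dosage[vindex[v]][use] for v in lead_ids if v != vid]
            oth = np.column_stack(others) if others else np.empty((len(y), 0))
            ones = np.ones((len(y), 1))
            if mode in ("single", "both"):
                x0 = np.column_stack([ones, g, onehot])
                x1 = np.column_stack([x0, gx])
                res.p_single = _nested_f(y, x0, x1)
            if mode in ("joint", "both"):
                x0 = np.column_stack([ones, g, onehot, oth])
                x1 = np.column_stack([x0, gx])
                res.p_joint = _nested_f(y, x0, x1)
            results.append(res)
    n_tested = sum(r.tested for r in results)
    if n_tested:
        thr = alpha / n_tested
        for r in results:
            if r.tested:
                if r.p_single is not None:
                    r.significant_single = r.p_single <= thr
                if r.p_joint is not None:
                    r.significant_joint = r.p_joint <= thr
    return results


# ---------------------------------------------------------------------------
# Constraint associations
# ---------------------------------------------------------------------------

def constraint_associations(
    constraint: pd.Series,
    egene_flags: pd.Series,
    n_sets: pd.Series,
    mean_abs_afc: pd.Series,
    top_fraction: float = 0.10,
) -> dict:
    """Constraint-score associations with eGene status, signal count, effect size.

    Three tests: (1) rank-sum of constraint score for eGenes vs non-eGenes;
    (2) quasi-Poisson GLM of credible-set count on a top-decile-constraint
    indicator (dispersion scales the SE, not the point estimate); (3)
    rank-sum of mean |log2 aFC| for top-decile vs other genes.
    """
    genes = constraint.index.intersection(egene_flags.index)
    constraint = constraint.loc[genes].astype(float)
    egene = egene_flags.loc[genes].astype(bool)
    if egene.sum() < 10 or (~egene).sum() < 10:
        raise CohortError("need >= 10 genes in each eGene/non-eGene stratum")
    w_egene, p_egene = stats.mannwhitneyu(
        constraint[egene], constraint[~egene], alternative="two-sided"
    )
    cutoff = constraint.quantile(1.0 - top_fraction)
    top = constraint >= cutoff
    if top.sum() < 10 or (~top).sum() < 10:
        raise CohortError("need >= 10 genes in each constraint stratum")

    counts = n_sets.reindex(genes).fillna(0).astype(float)
    x = sm.add_constant(top.astype(float).to_numpy())
    glm = sm.GLM(counts.to_numpy(), x, family=sm.families.Poisson()).fit(scale="X2")
    beta = float(glm.params[1])
    p_sets = float(glm.pvalues[1])

    afc = mean_abs_afc.reindex(genes)
    have = afc.notna()
    a_top = afc[have & top]
    a_rest = afc[have & ~top]
    if len(a_top) >= 10 and len(a_rest) >= 10:
        w_afc, p_afc = stats.mannwhitneyu(a_top, a_rest, alternative="two-sided")
    else:
        w_afc, p_afc = float("nan"), float("nan")
    return {
        "egene_score_rank_sum": {
            "statistic": float(w_egene), "pvalue": float(p_egene),
            "mean_egene": float(constraint[egene].mean()),
            "mean_non_egene": float(constraint[~egene].mean()),
        },
        "n_sets_quasipoisson": {
            "coefficient": beta, "pvalue": p_sets, "scale": float(glm.scale),
            "mean_top": float(counts[top].mean()),
            "mean_other": float(counts[~top].mean()),
        },
        "afc_rank_sum": {
            "statistic": float(w_afc), "pvalue": float(p_afc),
            "mean_top": float(a_top.mean()) if len(a_top) else float("nan"),
            "mean_other": float(a_rest.mean()) if len(a_rest) else float("nan"),
        },
    }


# ---------------------------------------------------------------------------
# Cross-study replication
# ---------------------------------------------------------------------------

@dataclass
class ReplicationStatus:
    gene_id: str
    set_index: int
    status: str  # replicated | not_replicated | gene_absent_in_B


def replication_compare(
    sets_a: list[CredibleSet],
    sets_b_by_gene: dict[str, set[str]],
) -> list[ReplicationStatus]:
    """Replication of study-A credible sets against study-B set unions.

    A set replicates iff its membership intersects the union of study B's
    credible sets for the same gene; genes with no sets in B are reported
    as gene_absent_in_B.
    """
    out = []
    for i, cs in enumerate(sets_a):
        gene = cs.gene_id or cs.feature_id
        union = sets_b_by_gene.get(gene)
        if not union:
            status = "gene_absent_in_B"
        elif set(cs.variants) & set(union):
            status = "replicated"
        else:
            status = "not_replicated"
        out.append(ReplicationStatus(gene, i, status))
    return out
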