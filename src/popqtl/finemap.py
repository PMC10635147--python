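"""Multi-signal fine-mapping by sum-of-single-effects Bayesian regression.

The model decomposes the cis genetic signal on a residualized phenotype
into at most L single-effect regressions: b = sum_l gamma_l * beta_l where
gamma_l selects exactly one variant (uniform prior) and beta_l is normal
with a per-effect prior variance estimated by empirical Bayes. Fitting is
iterative Bayesian stepwise selection (coordinate ascent on the
variational ELBO): each effect is refit against the residual left by all
other effects via the closed-form single-effect regression, whose
per-variant Bayes factors softmax into posterior inclusion weights.

Each converged effect yields a credible set: the smallest variant set by
descending inclusion weight whose cumulative mass reaches the coverage
level. Sets are filtered by purity (minimum absolute genotype correlation
among members) and deduplicated. Intron-level sets of one gene merge into
gene-level sets by transitive nonempty-intersection union.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp

from .io_core import CohortError, GenotypeMatrix

_PRIOR_FLOOR = 1e-9  # prior variances below this mean "effect unused"


@dataclass
class SusieFit:
    feature_id: str
    variant_ids: list[str]
    alpha: np.ndarray        # L x p posterior inclusion weights
    mu: np.ndarray           # L x p posterior means (given inclusion)
    prior_variance: np.ndarray  # length L
    sigma2: float
    elbo: list[float]
    converged: bool

    @property
    def pip(self) -> np.ndarray:
        """Marginal posterior inclusion probability: 1 - prod_l (1 - alpha_lv)."""
        used = self.prior_variance > _PRIOR_FLOOR
        if not used.any():
            return np.zeros(self.alpha.shape[1])
        return 1.0 - np.prod(1.0 - self.alpha[used], axis=0)


@dataclass
class CredibleSet:
    feature_id: str
    variants: list[str]
    inclusion: dict[str, float]
    coverage: float
    purity: float
    lead: str
    effect: int = 0
    gene_id: str | None = None
    source_introns: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.lead not in self.variants:
            raise ValueError("lead variant must be a member of the credible set")


def _single_effect(
    bhat: np.ndarray, shat2: np.ndarray, prior_var: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Posterior of one single-effect regression given per-variant OLS stats.

    Returns (alpha, posterior mean, posterior variance, log marginal lik
    relative to the null)."""
    with np.errstate(divide="ignore"):
        log_bf = 0.5 * np.log(shat2 / (shat2 + prior_var)) + 0.5 * (
            bhat**2 / shat2
        ) * (prior_var / (shat2 + prior_var))
    log_post = log_bf - np.log(len(bhat))  # uniform prior over variants
    ll = float(logsumexp(log_post))
    alpha = np.exp(log_post - ll)
    post_var = prior_var * shat2 / (prior_var + shat2)
    post_mean = (prior_var / (prior_var + shat2)) * bhat
    return alpha, post_mean, post_var, ll


def _optimize_prior_variance(
    bhat: np.ndarray, shat2: np.ndarray, current: float
) -> float:
    """Empirical-Bayes prior variance for one effect (1-D maximization)."""

    def neg_ll(log_v: float) -> float:
        return -_single_effect(bhat, shat2, np.exp(log_v))[3]

    res = minimize_scalar(neg_ll, bounds=(-30.0, 8.0), method="bounded")
    candidates = [np.exp(res.x), _PRIOR_FLOOR / 10.0]
    if current > 0:
        candidates.append(current)
    lls = [_single_effect(bhat, shat2, v)[3] for v in candidates]
    return float(candidates[int(np.argmax(lls))])


def susie_fit(
    dosages: np.ndarray,
    phenotype: np.ndarray,
    variant_ids: list[str] | None = None,
    feature_id: str = "",
    L: int = 10,
    coverage: float = 0.95,
    purity_min: float = 0.5,
    tol: float = 1e-3,
    max_iter: int = 100,
    estimate_sigma2: bool = True,
) -> tuple[SusieFit, list[CredibleSet]]:
    """Fit the sum-of-single-effects model to one cis block.

    ``dosages`` is (n_variants, n_samples); constant variants are held out
    of the model and reported with zero inclusion. The ELBO is monotone
    non-decreasing over iterations; convergence is declared when its change
    falls below ``tol``.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    dosages = np.asarray(dosages, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    m_all, n = dosages.shape
    if y.shape != (n,):
        raise CohortError("phenotype length does not match dosage columns")
    if y.std() == 0:
        raise CohortError("zero-variance phenotype")
    if variant_ids is None:
        variant_ids = [f"v{i}" for i in range(m_all)]

    sd = dosages.std(axis=1)
    keep = np.where(sd > 0)[0]
    x = (dosages[keep] - dosages[keep].mean(axis=1, keepdims=True)) / sd[keep][:, None]
    x = x.T  # n x p, standardized columns
    y = y - y.mean()
    p = x.shape[1]
    if p == 0:
        raise CohortError("no polymorphic variants in the cis block")
    d = np.full(p, float(n))  # x_j' x_j for standardized columns
    xty_all = None  # filled per effect from residuals

    alpha = np.full((L, p), 1.0 / p)
    mu = np.zeros((L, p))
    post_var = np.zeros((L, p))
    prior_var = np.full(L, 0.2 * float(y.var()))
    sigma2 = float(y.var())
    b_bar = np.zeros((L, p))
    xr = np.zeros(n)  # X @ sum_l b_bar_l

    elbo_trace: list[float] = []
    converged = False
    for _ in range(max_iter):
        for l in range(L):
            r_l = y - (xr - x @ b_bar[l])
            xtr = x.T @ r_l
            bhat = xtr / d
            shat2 = sigma2 / d
            prior_var[l] = _optimize_prior_variance(bhat, shat2, prior_var[l])
            a_l, m_l, v_l, _ = _single_effect(bhat, shat2, prior_var[l])
            alpha[l], mu[l], post_var[l] = a_l, m_l, v_l
            new_b = a_l * m_l
            xr += x @ (new_b - b_bar[l])
            b_bar[l] = new_b
        # expected residual sum of squares
        resid = y - xr
        mu2 = post_var + mu**2
        e_xb2 = ((alpha * mu2) @ d).sum()
        xb_bar2 = sum(float(np.sum((x @ b_bar[l]) ** 2)) for l in range(L))
        erss = float(resid @ resid) + e_xb2 - xb_bar2
        if estimate_sigma2:
            sigma2 = max(erss / n, 1e-12)
        kl = 0.0
        for l in range(L):
            a_l = alpha[l]
            nz = a_l > 1e-300
            kl += float(np.sum(a_l[nz] * np.log(a_l[nz] * p)))
            v0 = max(prior_var[l], 1e-300)
            kl_norm = 0.5 * (
                np.log(v0 / np.maximum(post_var[l], 1e-300))
                + (post_var[l] + mu[l] ** 2) / v0
                - 1.0
            )
            kl += float(np.sum(a_l * kl_norm))
        elbo = -0.5 * n * np.log(2 * np.pi * sigma2) - 0.5 * erss / sigma2 - kl
        elbo_trace.append(float(elbo))
        if len(elbo_trace) > 1 and abs(elbo_trace[-1] - elbo_trace[-2]) < tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"susie_fit({feature_id}): not converged after {max_iter} iters")

    full_alpha = np.zeros((L, m_all))
    full_mu = np.zeros((L, m_all))
    full_alpha[:, keep] = alpha
    full_mu[:, keep] = mu
    fit = SusieFit(
        feature_id, list(variant_ids), full_alpha, full_mu,
        prior_var.copy(), sigma2, elbo_trace, converged,
    )
    sets = _credible_sets(
        fit, x, keep, coverage=coverage, purity_min=purity_min
    )
    return fit, sets


def _credible_sets(
    fit: SusieFit,
    x_std: np.ndarray,
    keep: np.ndarray,
    coverage: float,
    purity_min: float,
) -> list[CredibleSet]:
    n = x_std.shape[0]
    sets: list[CredibleSet] = []
    seen: set[frozenset] = set()
    for l in range(fit.alpha.shape[0]):
        if fit.prior_variance[l] <= _PRIOR_FLOOR:
            continue
        a = fit.alpha[l]
        order = np.argsort(-a, kind="mergesort")
        csum = np.cumsum(a[order])
        k = int(np.searchsorted(csum, coverage) + 1)
        k = min(k, len(order))
        members = order[:k]
        if csum[k - 1] < coverage - 1e-9:
            continue  # mass spread over held-out constants; cannot reach coverage
        key = frozenset(int(i) for i in members)
        if key in seen:
            continue
        seen.add(key)
        # purity: min |cor| among members over standardized columns
        pos_in_keep = {int(v): i for i, v in enumerate(keep)}
        cols = [pos_in_keep[int(i)] for i in members if int(i) in pos_in_keep]
        if len(cols) <= 1:
            purity = 1.0
        else:
            sub = x_std[:, cols]
            corr = (sub.T @ sub) / n
            iu = np.triu_indices(len(cols), k=1)
            purity = float(np.abs(corr[iu]).min())
        if purity < purity_min:
            continue
        inclusion = {fit.variant_ids[int(i)]: float(a[int(i)]) for i in members}
        lead = fit.variant_ids[int(members[0])]
        sets.append(
            CredibleSet(
                fit.feature_id,
                [fit.variant_ids[int(i)] for i in members],
                inclusion, coverage, purity, lead, effect=l,
                gene_id=fit.feature_id or None,
            )
        )
    return sets


def merge_intron_credible_sets(per_intron: list[CredibleSet]) -> list[CredibleSet]:
    """Collapse a gene's intron-level credible sets into gene-level sets.

    Sets sharing at least one variant merge (transitive closure / union);
    the merged per-variant score is the maximum inclusion across source
    sets and the lead is re-selected. Output is independent of input order.
    """
    if not per_intron:
        return []
    genes = {cs.gene_id for cs in per_intron}
    if len(genes) > 1:
        raise CohortError(f"credible sets from multiple genes: {sorted(map(str, genes))}")
    gene = per_intron[0].gene_id

    ordered = sorted(per_intron, key=lambda c: (c.feature_id, sorted(c.variants)))
    parent = list(range(len(ordered)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    var_owner: dict[str, int] = {}
    for i, cs in enumerate(ordered):
        for v in cs.variants:
            if v in var_owner:
                ri, rj = find(i), find(var_owner[v])
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)
            else:
                var_owner[v] = i

    clusters: dict[int, list[CredibleSet]] = {}
    for i in range(len(ordered)):
        clusters.setdefault(find(i), []).append(ordered[i])

    merged = []
    for root in sorted(clusters):
        group = clusters[root]
        inclusion: dict[str, float] = {}
        for cs in group:
            for v, a in cs.inclusion.items():
                inclusion[v] = max(inclusion.get(v, 0.0), a)
        variants = sorted(inclusion, key=lambda v: (-inclusion[v], v))
        lead = variants[0]
        merged.append(
            CredibleSet(
                feature_id=str(gene),
                variants=variants,
                inclusion=inclusion,
                coverage=group[0].coverage,
                purity=min(cs.purity for cs in group),
                lead=lead,
                effect=min(cs.effect for cs in group),
                gene_id=gene,
                source_introns=sorted({cs.feature_id for cs in group}),
            )
        )
    return merged


def select_lead(cset: CredibleSet, genotypes: GenotypeMatrix) -> str:
    """Representative lead variant of a credible set.

    Highest inclusion score wins; ties break by higher MAF, then by lower
    genomic position. Deterministic for any input order.
    """
    if not cset.variants:
        raise CohortError("empty credible set")
    maf = dict(zip(genotypes.variant_ids, genotypes.maf()))
    pos = {v.id: (v.chrom, v.pos) for v in genotypes.variants}
    missing = [v for v in cset.variants if v not in pos]
    if missing:
        raise CohortError(f"credible-set variants absent from genotypes: {missing}")
    return min(
        cset.variants,
        key=lambda v: (-cset.inclusion.get(v, 0.0), -maf[v], pos[v]),
    )
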