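"""Nominal cis association scans and permutation-based gene-level inference.

For every feature, all variants within a window of its anchor (1 Mb of the
TSS by default) are tested by simple linear regression of the residualized
phenotype on dosage. Gene-level significance uses the permutation scheme
of the FastQTL lineage: the per-permutation minimum p over the cis window
is collected, a Beta distribution is fit to the permuted minima by maximum
likelihood, and the gene-level "effective" p-value is the Beta CDF at the
observed best p. Benjamini–Hochberg across features at the cohort FDR
yields eGene/sGene calls and per-feature nominal pair thresholds.

Splicing runs in grouped mode: a gene's null is the per-permutation
minimum over all of its introns, giving a gene-level sQTL test that
respects the correlation between introns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import CohortError, FeatureMatrix, GenotypeMatrix


@dataclass
class GenePermutationResult:
    feature_id: str
    best_p: float
    best_variant: str | None
    beta_a: float
    beta_b: float
    p_effective: float
    p_empirical: float
    n_perm: int
    n_cis_variants: int


@dataclass
class SignificanceCall:
    table: pd.DataFrame  # feature_id, p_effective, qvalue, significant, nominal_threshold
    fdr: float
    p_threshold: float   # effective-p value at the q = fdr boundary (NaN if none)
    significant_pairs: pd.DataFrame | None = None

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())


def _cis_index(
    genotypes: GenotypeMatrix, chrom: str, anchor: int, window: int
) -> np.ndarray:
    pos = np.array([v.pos for v in genotypes.variants])
    chroms = np.array([v.chrom for v in genotypes.variants])
    return np.where((chroms == chrom) & (np.abs(pos - anchor) <= window))[0]


def nominal_pass(
    genotypes: GenotypeMatrix,
    matrix: FeatureMatrix,
    window: int = 1_000_000,
    maf_min: float = 0.01,
) -> pd.DataFrame:
    """Simple-regression association of every feature with its cis variants.

    Returns one row per (feature, variant) pair with slope, slope SE,
    t statistic, two-sided p-value, cohort MAF and signed distance to the
    feature anchor. Features with no cis variants after the MAF filter are
    recorded with zero rows (not fatal).
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if list(genotypes.samples) != list(matrix.samples):
        raise CohortError("genotypes and phenotypes are not sample-aligned")
    dosage = genotypes.imputed()
    maf = genotypes.maf()
    n = genotypes.n_samples
    out = []
    for fi in range(matrix.n_features):
        feat = matrix.features.iloc[fi]
        idx = _cis_index(genotypes, feat["chrom"], int(feat["anchor"]), window)
        idx = idx[(maf[idx] >= maf_min) & (maf[idx] > 0)]
        if idx.size == 0:
            continue
        y = matrix.values[fi]
        yc = y - y.mean()
        g = dosage[idx]
        gc = g - g.mean(axis=1, keepdims=True)
        sgg = (gc**2).sum(axis=1)
        sgy = gc @ yc
        slope = sgy / sgg
        dfree = n - 2
        rss = (yc @ yc) - slope * sgy
        with np.errstate(invalid="ignore", divide="ignore"):
            se = np.sqrt(np.maximum(rss, 0.0) / dfree / sgg)
            tstat = slope / se
        pval = 2.0 * stats.t.sf(np.abs(tstat), dfree)
        anchor = int(feat["anchor"])
        for k, vi in enumerate(idx):
            v = genotypes.variants[vi]
            out.append(
                (
                    feat["feature_id"], v.id, slope[k], se[k], tstat[k],
                    min(max(pval[k], np.nextafter(0, 1)), 1.0),
                    maf[vi], v.pos - anchor,
                )
            )
    return pd.DataFrame(
        out,
        columns=[
            "feature_id", "variant_id", "slope", "slope_se", "tstat",
            "pvalue", "maf", "distance",
        ],
    )


def _r_to_p(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p for a Pearson correlation with n samples."""
    r = np.clip(r, -1.0, 1.0)
    dfree = n - 2
    with np.errstate(divide="ignore"):
        t = np.abs(r) * np.sqrt(dfree / np.maximum(1.0 - r * r, 1e-300))
    return np.minimum(2.0 * stats.t.sf(t, dfree), 1.0)


def _fit_beta(pvals: np.ndarray) -> tuple[float, float]:
    """Maximum-likelihood Beta(a, b) fit on (0,1)-clipped p-values."""
    x = np.clip(pvals, 1e-12, 1.0 - 1e-12)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        a, b, _, _ = stats.beta.fit(x, floc=0.0, fscale=1.0)
    return float(a), float(b)


def permutation_pass(
    genotypes: GenotypeMatrix,
    matrix: FeatureMatrix,
    window: int = 1_000_000,
    n_perm: int = 1000,
    seed: int = 0,
    maf_min: float = 0.01,
    grouping: dict[str, str] | None = None,
) -> list[GenePermutationResult]:
    """Beta-approximated permutation pass, per feature or per feature group.

    ``grouping`` maps feature_id -> group id (e.g. intron -> gene); when
    given, the observed and permuted best p-values are minimized over each
    group's members inside every permutation, yielding one result per group.
    """
    if n_perm < 10:
        raise ValueError("n_perm < 10 is not interpretable")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is low; beta fit may be unstable")
    if list(genotypes.samples) != list(matrix.samples):
        raise CohortError("genotypes and phenotypes are not sample-aligned")
    rng = np.random.default_rng(seed)
    n = genotypes.n_samples
    perm_idx = np.array([rng.permutation(n) for _ in range(n_perm)]).T  # n x n_perm
    dosage = genotypes.imputed()
    maf = genotypes.maf()

    per_feature: dict[str, tuple[float, str | None, np.ndarray, int]] = {}
    for fi in range(matrix.n_features):
        feat = matrix.features.iloc[fi]
        fid = feat["feature_id"]
        idx = _cis_index(genotypes, feat["chrom"], int(feat["anchor"]), window)
        idx = idx[(maf[idx] >= maf_min) & (maf[idx] > 0)]
        if idx.size == 0:
            continue
        y = matrix.values[fi]
        sd = y.std()
        if sd == 0:
            raise CohortError(f"zero-variance phenotype for feature {fid}")
        ys = (y - y.mean()) / sd
        g = dosage[idx]
        gs = (g - g.mean(axis=1, keepdims=True)) / g.std(axis=1, keepdims=True)
        r_obs = gs @ ys / n
        p_obs = _r_to_p(r_obs, n)
        best_i = int(np.argmin(p_obs))
        r_perm = gs @ ys[perm_idx] / n                       # m x n_perm
        best_perm_p = _r_to_p(np.abs(r_perm).max(axis=0), n)  # length n_perm
        per_feature[fid] = (
            float(p_obs[best_i]),
            genotypes.variants[idx[best_i]].id,
            best_perm_p,
            idx.size,
        )

    if grouping is None:
        units = {fid: [fid] for fid in per_feature}
    else:
        units = {}
        for fid in per_feature:
            units.setdefault(grouping.get(fid, fid), []).append(fid)

    results = []
    for unit, members in units.items():
        obs = min(per_feature[f][0] for f in members)
        best_var = min(
            ((per_feature[f][0], per_feature[f][1]) for f in members)
        )[1]
        perm = np.min(np.vstack([per_feature[f][2] for f in members]), axis=0)
        n_cis = max(per_feature[f][3] for f in members)
        a, b = _fit_beta(perm)
        p_eff = float(stats.beta.cdf(obs, a, b))
        p_emp = float((1 + np.sum(perm <= obs)) / (n_perm + 1))
        results.append(
            GenePermutationResult(
                unit, obs, best_var, a, b,
                min(max(p_eff, np.nextafter(0, 1)), 1.0), p_emp, n_perm, n_cis,
            )
        )
    return results


def call_significant(
    results: list[GenePermutationResult],
    fdr: float = 0.05,
    nominal: pd.DataFrame | None = None,
    grouping: dict[str, str] | None = None,
) -> SignificanceCall:
    """Benjamini–Hochberg eGene/sGene calls plus per-feature pair thresholds.

    The per-feature nominal threshold is BetaQuantile(p_threshold; a, b)
    where p_threshold is the effective-p value at the q = fdr boundary
    (midpoint between the last significant and first non-significant
    effective p). When a nominal-pass table is supplied, significant pairs
    are its rows with p <= the feature's threshold, restricted to
    significant features.
    """
    if not results:
        raise CohortError("no permutation results to call")
    df = pd.DataFrame(
        {
            "feature_id": [r.feature_id for r in results],
            "p_effective": [r.p_effective for r in results],
            "beta_a": [r.beta_a for r in results],
            "beta_b": [r.beta_b for r in results],
        }
    )
    m = len(df)
    order = np.argsort(df["p_effective"].to_numpy(), kind="mergesort")
    p_sorted = df["p_effective"].to_numpy()[order]
    q_sorted = np.minimum.accumulate((p_sorted * m / np.arange(1, m + 1))[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    df["qvalue"] = q
    df["significant"] = df["qvalue"] <= fdr

    sig_p = p_sorted[q_sorted <= fdr]
    if sig_p.size:
        last_sig = sig_p.max()
        above = p_sorted[p_sorted > last_sig]
        p_threshold = float((last_sig + above.min()) / 2) if above.size else float(last_sig)
    else:
        p_threshold = float("nan")
    with np.errstate(invalid="ignore"):
        df["nominal_threshold"] = np.where(
            df["significant"],
            stats.beta.ppf(p_threshold, df["beta_a"], df["beta_b"]),
            np.nan,
        )

    pairs = None
    if nominal is not None and sig_p.size:
        thr = df.set_index("feature_id")["nominal_threshold"]
        if grouping is not None:
            feat_thr = {f: thr.get(g, np.nan) for f, g in grouping.items()}
            nominal = nominal.assign(
                _thr=[feat_thr.get(f, thr.get(f, np.nan)) for f in nominal["feature_id"]]
            )
        else:
            nominal = nominal.assign(
                _thr=[thr.get(f, np.nan) for f in nominal["feature_id"]]
            )
        # small relative tolerance: the nominal and permutation passes compute
        # the same p through different but equivalent floating-point routes
        pairs = (
            nominal[nominal["pvalue"] <= nominal["_thr"] * (1 + 1e-9)]
            .drop(columns="_thr")
            .reset_index(drop=True)
        )
    return SignificanceCall(df, fdr, p_threshold, pairs)
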