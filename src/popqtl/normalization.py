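"""Phenotype filtering, rank-based normalization, and covariate regression.

The association stages all run on residualized phenotypes: features are
filtered for minimum signal, inverse-normal transformed per feature
(rank offset 0.5), and regressed on a covariate matrix built from genotype
principal components, phenotype principal components, batch indicators and
sex.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import CohortError, FeatureMatrix, GenotypeMatrix, SampleTable

logger = logging.getLogger(__name__)


def filter_features(
    matrix: FeatureMatrix,
    min_value: float = 1.0,
    min_fraction: float = 0.2,
) -> FeatureMatrix:
    """Keep features with value >= min_value in >= min_fraction of samples.

    For excision-ratio input, additionally drops zero-variance introns and
    any cluster left with fewer than two introns.
    """
    frac = np.mean(matrix.values >= min_value, axis=1)
    keep = frac >= min_fraction
    if matrix.kind == "excision-ratio":
        keep &= np.nanstd(matrix.values, axis=1) > 0
        surviving = matrix.features.loc[keep]
        counts = surviving.groupby("cluster_id")["feature_id"].transform("size")
        ok_clusters = set(surviving.loc[counts >= 2, "cluster_id"])
        keep &= matrix.features["cluster_id"].isin(ok_clusters).to_numpy()
    n_kept = int(keep.sum())
    logger.info(
        "filter_features: kept %d/%d (min_value=%g, min_fraction=%g)",
        n_kept, matrix.n_features, min_value, min_fraction,
    )
    if n_kept == 0:
        raise CohortError("all features removed by filtering")
    return matrix.subset_features(keep)


def inverse_normal_transform(matrix: FeatureMatrix) -> FeatureMatrix:
    """Per-feature rank inverse-normal transform.

    Each feature's values are replaced by Phi^-1((rank - 0.5) / n) with
    average ranks for ties. Any monotone transform of the input yields
    identical output.
    """
    values = matrix.values
    n = values.shape[1]
    out = np.empty_like(values, dtype=float)
    for i, row in enumerate(values):
        if np.nanstd(row) == 0:
            raise CohortError(
                f"constant feature {matrix.feature_ids[i]} cannot be rank-transformed"
            )
        ranks = stats.rankdata(row, method="average")
        out[i] = stats.norm.ppf((ranks - 0.5) / n)
    return matrix.with_values(out, kind="normalized")


def _ld_prune(dosage: np.ndarray, r2_max: float = 0.2, window: int = 50) -> np.ndarray:
    """Greedy LD pruning over a sliding window; returns row indices kept."""
    std = dosage.std(axis=1)
    poly = np.where(std > 0)[0]
    kept: list[int] = []
    x = dosage[poly]
    x = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, keepdims=True)
    n = x.shape[1]
    for i in range(len(poly)):
        ok = True
        for j in kept[-window:]:
            r = float(x[i] @ x[j]) / n
            if r * r > r2_max:
                ok = False
                break
        if ok:
            kept.append(i)
    return poly[np.array(kept, dtype=int)]


def compute_covariates(
    genotypes: GenotypeMatrix,
    matrix: FeatureMatrix,
    samples: SampleTable,
    n_geno_pcs: int = 5,
    n_pheno_pcs: int = 15,
) -> pd.DataFrame:
    """Build the covariate table: genotype PCs, phenotype PCs, batch, sex.

    Genotype PCs are computed from LD-pruned standardized dosages,
    phenotype PCs from the (already transformed) feature matrix. Batch is
    one-hot with the first level dropped; sex is a 0/1 indicator.
    Collinear columns are dropped with a warning.
    """
    n = genotypes.n_samples
    if max(n_geno_pcs, n_pheno_pcs) >= n:
        raise CohortError("number of PCs must be smaller than the sample count")
    cols: dict[str, np.ndarray] = {}

    d = genotypes.imputed()
    pruned = _ld_prune(d)
    x = d[pruned]
    x = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, keepdims=True)
    u, s, vt = np.linalg.svd(x.T, full_matrices=False)
    for k in range(min(n_geno_pcs, vt.shape[0])):
        cols[f"geno_PC{k + 1}"] = u[:, k] * s[k]

    y = matrix.values
    y = y - y.mean(axis=1, keepdims=True)
    uy, sy, _ = np.linalg.svd(y.T, full_matrices=False)
    for k in range(min(n_pheno_pcs, y.shape[0])):
        cols[f"pheno_PC{k + 1}"] = uy[:, k] * sy[k]

    batches = pd.unique(samples.column("batch"))
    for b in batches[1:]:
        cols[f"batch_{b}"] = (samples.column("batch") == b).astype(float)
    cols["sex_F"] = (samples.column("sex") == "F").astype(float)

    cov = pd.DataFrame(cols, index=samples.samples)
    # drop collinear columns (QR with pivoting on centered columns)
    mat = np.column_stack([np.ones(n), cov.to_numpy()])
    q, r, piv = _qr_rank(mat)
    keep_idx = sorted(i - 1 for i in piv if i > 0)  # 0 is the intercept
    dropped = [c for i, c in enumerate(cov.columns) if i not in keep_idx]
    if dropped:
        logger.warning("compute_covariates: dropped collinear columns %s", dropped)
        cov = cov.drop(columns=dropped)
    return cov


def _qr_rank(mat: np.ndarray, tol: float = 1e-8):
    """Column-pivoted QR; returns (q, r, independent column indices)."""
    from scipy.linalg import qr

    q, r, piv = qr(mat, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    rank = int(np.sum(diag > tol * diag[0])) if diag.size else 0
    return q, r, list(piv[:rank])


def residualize(matrix: FeatureMatrix, covariates: pd.DataFrame) -> FeatureMatrix:
    """OLS residuals of every feature against covariates plus intercept."""
    if list(covariates.index) != list(matrix.samples):
        covariates = covariates.loc[matrix.samples]
    x = np.column_stack([np.ones(len(covariates)), covariates.to_numpy(dtype=float)])
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise CohortError("covariate matrix is rank-deficient")
    q, _ = np.linalg.qr(x)
    y = matrix.values.T  # samples x features
    resid = y - q @ (q.T @ y)
    return matrix.with_values(resid.T, kind="normalized")
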