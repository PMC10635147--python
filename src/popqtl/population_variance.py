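"""Variance partitioning of molecular phenotypes across population labels.

Two questions about the distribution of expression/splicing diversity:

1. How much per-feature variance is explained by continental-group or
   population labels? Answered by one-way ANOVA R-squared per feature, with
   a label-permutation null for the cohort mean (one shared permutation
   across features per replicate, preserving inter-feature correlation).
2. Do within-group variances differ among continental groups? Answered by
   a gamma GLM with log link of per-feature per-group sample variances on
   the group factor, reported as an analysis-of-deviance chi-square with
   n_groups - 1 degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .io_core import CohortError, FeatureMatrix, SampleTable


@dataclass
class VariancePartitionResult:
    per_feature: pd.DataFrame  # feature_id, r2
    level: str
    mean_r2: float
    perm_pvalue: float
    n_perm: int

    def __post_init__(self):
        lo = 1.0 / (self.n_perm + 1)
        assert lo <= self.perm_pvalue <= 1.0


@dataclass
class GroupVarianceTest:
    group_mean_variance: pd.Series  # mean within-group variance per group
    statistic: float               # analysis-of-deviance chi-square
    df: int
    pvalue: float
    family: str = "gamma-log"
    n_obs: int = 0


def _label_r2(values: np.ndarray, codes: np.ndarray, n_labels: int) -> np.ndarray:
    """One-way ANOVA R^2 per feature (rows) for integer label codes."""
    n = values.shape[1]
    counts = np.bincount(codes, minlength=n_labels).astype(float)
    group_sums = np.zeros((values.shape[0], n_labels))
    np.add.at(group_sums.T, codes, values.T)
    group_means = group_sums / counts
    grand = values.mean(axis=1, keepdims=True)
    ss_between = (counts * (group_means - grand) ** 2).sum(axis=1)
    ss_total = ((values - grand) ** 2).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(ss_total > 0, ss_between / ss_total, 0.0)
    return r2


def partition_variance(
    matrix: FeatureMatrix,
    samples: SampleTable,
    level: str = "group",
    n_perm: int = 999,
    seed: int = 0,
) -> VariancePartitionResult:
    """Proportion of per-feature variance explained by population labels.

    The permutation p-value tests the cohort mean R^2: labels are permuted
    jointly across samples (same permutation applied to every feature), and
    p = (1 + #{permuted mean >= observed mean}) / (n_perm + 1), so the
    smallest reportable p is 1/(n_perm + 1).
    """
    if level not in ("group", "population"):
        raise ValueError(f"level must be 'group' or 'population', got {level!r}")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    labels = samples.column(level)
    uniq, codes = np.unique(labels, return_inverse=True)
    if len(uniq) < 2:
        raise CohortError(f"need >= 2 {level} labels")
    counts = np.bincount(codes)
    if counts.min() < 2:
        small = uniq[counts < 2]
        raise CohortError(f"labels with < 2 samples: {list(small)}")

    values = matrix.values
    r2 = _label_r2(values, codes, len(uniq))
    observed = float(r2.mean())

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        if _label_r2(values, perm, len(uniq)).mean() >= observed:
            exceed += 1
    p = (1 + exceed) / (n_perm + 1)
    per_feature = pd.DataFrame({"feature_id": matrix.feature_ids, "r2": r2})
    return VariancePartitionResult(per_feature, level, observed, p, n_perm)


def partition_variance_by_cluster(
    result: VariancePartitionResult, matrix: FeatureMatrix
) -> pd.DataFrame:
    """Average per-intron R^2 within splicing clusters for cluster-level reporting."""
    df = result.per_feature.merge(
        matrix.features[["feature_id", "cluster_id"]], on="feature_id"
    )
    return df.groupby("cluster_id", dropna=True)["r2"].mean().reset_index()


def within_group_variance_test(
    matrix: FeatureMatrix, samples: SampleTable, level: str = "group"
) -> GroupVarianceTest:
    """Do within-group phenotype variances differ among continental groups?

    Per-feature per-group sample variances (N = features x groups
    observations) are modelled by a gamma GLM with log link on the group
    factor; the analysis-of-deviance statistic is the scaled deviance drop
    of the group factor against the intercept-only model, referred to
    chi-square with n_groups - 1 df.
    """
    labels = samples.column(level)
    uniq, codes = np.unique(labels, return_inverse=True)
    counts = np.bincount(codes)
    if counts.min() < 3:
        raise CohortError(f"groups with < 3 samples: {list(uniq[counts < 3])}")
    values = matrix.values
    rows = []
    for gi, g in enumerate(uniq):
        v = values[:, codes == gi].var(axis=1, ddof=1)
        rows.append(pd.DataFrame({"group": g, "variance": v}))
    obs = pd.concat(rows, ignore_index=True)
    obs = obs[obs["variance"] > 0]

    x = pd.get_dummies(obs["group"], drop_first=True, dtype=float)
    x = sm.add_constant(x)
    family = sm.families.Gamma(link=sm.families.links.Log())
    full = sm.GLM(obs["variance"].to_numpy(), x.to_numpy(), family=family).fit()
    null = sm.GLM(
        obs["variance"].to_numpy(), np.ones((len(obs), 1)), family=family
    ).fit()
    stat = float((null.deviance - full.deviance) / full.scale)
    df = len(uniq) - 1
    p = float(stats.chi2.sf(max(stat, 0.0), df))
    group_means = obs.groupby("group")["variance"].mean()
    return GroupVarianceTest(group_means, stat, df, p, n_obs=len(obs))
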