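"""Enrichment of fine-mapped lead QTLs in genomic annotations.

Annotations enter as BED intervals (0-based half-open; converted to
internal 1-based closed). For each annotation the lead variants are
compared with a background of non-lead cis variants matched to the leads
on MAF decile and log-scale TSS-distance bin (default 10 background
variants per lead), using a 2x2 Fisher exact test with Bonferroni
correction over annotations (x deciles in decile mode).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import CohortError


@dataclass
class AnnotationSet:
    """Named interval set; intervals are internal 1-based closed [start, end]."""

    name: str
    intervals: pd.DataFrame  # columns chrom, start, end (1-based closed)

    def __post_init__(self):
        iv = self.intervals
        if (iv["end"] < iv["start"]).any():
            raise CohortError(f"annotation {self.name}: negative-length interval")
        srt = iv.sort_values(["chrom", "start"]).reset_index(drop=True)
        if not iv.reset_index(drop=True).equals(srt):
            warnings.warn(f"annotation {self.name}: intervals auto-sorted")
        self.intervals = srt


@dataclass
class EnrichmentResult:
    annotation: str
    n_lead_in: int
    n_lead_out: int
    n_background_in: int
    n_background_out: int
    fold: float
    log2_fold: float
    pvalue: float
    p_bonferroni: float
    decile: int | None = None


def read_annotation_bed(path, chr_prefix: str | None = None) -> list[AnnotationSet]:
    """Read a BED whose 4th column names the annotation.

    BED start/end are 0-based half-open; internal intervals are 1-based
    closed, i.e. [start+1, end]. ``chr_prefix`` may add/strip a 'chr'
    prefix to reconcile chromosome naming.
    """
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name"], usecols=[0, 1, 2, 3], dtype={0: str},
    )
    if chr_prefix == "add":
        df["chrom"] = np.where(
            df["chrom"].str.startswith("chr"), df["chrom"], "chr" + df["chrom"]
        )
    elif chr_prefix == "strip":
        df["chrom"] = df["chrom"].str.removeprefix("chr")
    df["start"] = df["start"].astype(int) + 1
    df["end"] = df["end"].astype(int)
    return [
        AnnotationSet(name, sub[["chrom", "start", "end"]].reset_index(drop=True))
        for name, sub in df.groupby("name", sort=True)
    ]


def annotate_variants(
    variants: pd.DataFrame, annotations: list[AnnotationSet]
) -> pd.DataFrame:
    """Boolean membership table (variants x annotations) by containment.

    ``variants`` needs columns variant_id, chrom, pos (1-based).
    """
    out = pd.DataFrame(index=variants["variant_id"])
    for ann in annotations:
        member = np.zeros(len(variants), dtype=bool)
        for chrom, sub in ann.intervals.groupby("chrom"):
            vm = variants["chrom"].to_numpy() == chrom
            if not vm.any():
                continue
            pos = variants.loc[vm, "pos"].to_numpy()
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            # sorted, possibly overlapping intervals: check candidate by bisect
            hit = np.zeros(len(pos), dtype=bool)
            for s, e in zip(starts, ends):
                hit |= (pos >= s) & (pos <= e)
            member[np.where(vm)[0]] = hit
        out[ann.name] = member
    return out


def match_background(
    leads: pd.DataFrame,
    pool: pd.DataFrame,
    ratio: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Sample non-lead background variants matched on MAF and TSS distance.

    Both tables need columns variant_id, chrom, pos, maf, distance. Leads
    are binned by MAF decile and log10 |distance| bin; each lead draws up
    to ``ratio`` background variants from its joint bin, relaxing to the
    MAF-only bin and then the whole pool if a bin is exhausted.
    """
    if leads.empty or pool.empty:
        raise CohortError("leads and background pool must be nonempty")
    pool = pool[~pool["variant_id"].isin(set(leads["variant_id"]))].reset_index(drop=True)
    maf_edges = np.quantile(pool["maf"], np.linspace(0, 1, 11))
    maf_edges[0], maf_edges[-1] = -np.inf, np.inf

    def bins(df):
        mb = np.searchsorted(maf_edges, df["maf"].to_numpy(), side="right") - 1
        db = np.clip(
            np.log10(np.maximum(np.abs(df["distance"].to_numpy()), 1.0)).astype(int), 0, 6
        )
        return mb, db

    pm, pdist = bins(pool)
    lm, ldist = bins(leads)
    rng = np.random.default_rng(seed)
    taken: list[int] = []
    available = np.ones(len(pool), dtype=bool)
    n_relaxed = 0
    for mb, db in zip(lm, ldist):
        cand = np.where(available & (pm == mb) & (pdist == db))[0]
        if len(cand) < ratio:
            n_relaxed += 1
            cand = np.where(available & (pm == mb))[0]
        if len(cand) < ratio:
            cand = np.where(available)[0]
        pick = rng.choice(cand, size=min(ratio, len(cand)), replace=False)
        available[pick] = False
        taken.extend(int(i) for i in pick)
    if n_relaxed:
        warnings.warn(
            f"background matching: {n_relaxed}/{len(leads)} bins exhausted, "
            "relaxed to MAF-only"
        )
    return pool.iloc[sorted(taken)].reset_index(drop=True)


def enrichment_test(
    leads: pd.DataFrame,
    background: pd.DataFrame,
    annotations: list[AnnotationSet],
    deciles: bool = False,
) -> list[EnrichmentResult]:
    """Fisher-exact enrichment of leads vs background per annotation.

    ``leads`` needs variant_id, chrom, pos and, for decile mode, abs_afc
    (|log2 aFC|, binned into deciles with decile 10 = largest effects).
    Fold enrichment is (lead in-rate)/(background in-rate); Bonferroni
    multiplies p by the number of annotation (x decile) tests.
    """
    if leads.empty or background.empty:
        raise CohortError("leads and background must be nonempty")
    overlap = set(leads["variant_id"]) & set(background["variant_id"])
    if overlap:
        raise CohortError(f"background overlaps leads: {sorted(overlap)[:5]}")
    mem_lead = annotate_variants(leads, annotations)
    mem_bg = annotate_variants(background, annotations)

    if deciles:
        if "abs_afc" not in leads.columns:
            raise CohortError("decile mode requires an abs_afc column on leads")
        ranks = stats.rankdata(leads["abs_afc"].to_numpy(), method="ordinal")
        dec = ((ranks - 1) * 10 // len(ranks)).astype(int) + 1  # 10 = largest
        strata = [(d, mem_lead[dec == d]) for d in range(1, 11)]
    else:
        strata = [(None, mem_lead)]

    n_tests = len(annotations) * len(strata)
    out = []
    for dec_idx, mem in strata:
        for ann in annotations:
            a_in = int(mem[ann.name].sum())
            a_out = int(len(mem) - a_in)
            b_in = int(mem_bg[ann.name].sum())
            b_out = int(len(mem_bg) - b_in)
            _, p = stats.fisher_exact([[a_in, a_out], [b_in, b_out]])
            lead_rate = a_in / max(a_in + a_out, 1)
            bg_rate = b_in / max(b_in + b_out, 1)
            fold = lead_rate / bg_rate if bg_rate > 0 else float("inf")
            with np.errstate(divide="ignore"):
                l2 = float(np.log2(fold)) if fold > 0 else float("-inf")
            out.append(
                EnrichmentResult(
                    ann.name, a_in, a_out, b_in, b_out, float(fold), l2,
                    float(p), float(min(1.0, p * n_tests)), dec_idx,
                )
            )
    return out
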