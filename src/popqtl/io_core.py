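"""Shared in-memory data model and readers/writers for standard formats.

The pipeline's containers are thin wrappers around numpy arrays and pandas
tables:

* :class:`GenotypeMatrix` — variants x samples alternate-allele dosages
  ({0,1,2}, NaN for missing) with :class:`VariantRecord` annotations.
* :class:`SampleTable` — per-sample metadata (population nested in
  continental group, sex, sequencing batch).
* :class:`FeatureMatrix` — features x samples molecular phenotypes
  (expression counts, normalized values, or intron-excision ratios), each
  feature anchored to a genomic position (TSS or intron start).

All internal coordinates are 1-based; BED half-open 0-based boundaries are
converted at the readers/writers so a single convention holds everywhere.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CONTINENTAL_GROUPS = ("AFR", "AMR", "EAS", "EUR", "SAS")


class CohortError(ValueError):
    """Raised for malformed or inconsistent cohort inputs."""


@dataclass(frozen=True)
class VariantRecord:
    """A biallelic variant. ``pos`` is 1-based."""

    chrom: str
    pos: int
    id: str
    ref: str
    alt: str

    def __post_init__(self):
        if self.pos < 1:
            raise CohortError(f"variant {self.id}: pos must be >= 1, got {self.pos}")
        if self.alt == self.ref:
            raise CohortError(f"variant {self.id}: alt equals ref ({self.ref})")


@dataclass
class GenotypeMatrix:
    """Alternate-allele dosage matrix with variant and sample annotations.

    ``dosage`` has shape (n_variants, n_samples); entries are in {0, 1, 2}
    or NaN for missing genotypes.
    """

    variants: list[VariantRecord]
    samples: list[str]
    dosage: np.ndarray

    def __post_init__(self):
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.variants), len(self.samples)):
            raise CohortError(
                f"dosage shape {self.dosage.shape} does not match "
                f"({len(self.variants)}, {len(self.samples)})"
            )
        if len(set(self.samples)) != len(self.samples):
            raise CohortError("duplicate sample ids in genotype matrix")
        with np.errstate(invalid="ignore"):
            bad = ~(np.isnan(self.dosage) | np.isin(self.dosage, (0.0, 1.0, 2.0)))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise CohortError(
                f"dosage[{i},{j}] = {self.dosage[i, j]} not in {{0,1,2}} or NaN"
            )

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def variant_ids(self) -> list[str]:
        return [v.id for v in self.variants]

    def imputed(self) -> np.ndarray:
        """Dosages with missing entries mean-imputed per variant."""
        d = self.dosage.copy()
        miss = np.isnan(d)
        if miss.any():
            means = np.nanmean(np.where(miss, np.nan, d), axis=1)
            means = np.where(np.isnan(means), 0.0, means)  # all-missing variant
            idx = np.where(miss)
            d[idx] = means[idx[0]]
        return d

    def alt_frequency(self) -> np.ndarray:
        """Per-variant alternate-allele frequency, ignoring missing calls."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.dosage, axis=1) / 2.0

    def maf(self) -> np.ndarray:
        af = self.alt_frequency()
        return np.minimum(af, 1.0 - af)

    def subset_samples(self, sample_ids: list[str]) -> "GenotypeMatrix":
        idx = _sample_index(self.samples, sample_ids, "genotype matrix")
        return GenotypeMatrix(self.variants, list(sample_ids), self.dosage[:, idx])

    def subset_variants(self, mask_or_ids) -> "GenotypeMatrix":
        if isinstance(mask_or_ids, np.ndarray) and mask_or_ids.dtype == bool:
            keep = np.where(mask_or_ids)[0]
        else:
            lookup = {v: i for i, v in enumerate(self.variant_ids)}
            missing = [v for v in mask_or_ids if v not in lookup]
            if missing:
                raise CohortError(f"variants absent from genotypes: {missing}")
            keep = np.array([lookup[v] for v in mask_or_ids], dtype=int)
        return GenotypeMatrix(
            [self.variants[i] for i in keep], self.samples, self.dosage[keep]
        )


@dataclass
class SampleTable:
    """Per-sample metadata: population, continental group, sex, batch.

    Every population label must map to exactly one continental group;
    batches may span populations.
    """

    table: pd.DataFrame  # columns: sample, population, group, sex, batch

    REQUIRED = ("sample", "population", "group", "sex", "batch")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise CohortError(f"sample table missing columns: {missing}")
        if self.table["sample"].duplicated().any():
            dups = self.table.loc[self.table["sample"].duplicated(), "sample"]
            raise CohortError(f"duplicate sample ids: {sorted(set(dups))}")
        ngroups = self.table.groupby("population")["group"].nunique()
        bad = ngroups[ngroups > 1]
        if len(bad):
            raise CohortError(
                f"populations mapped to multiple continental groups: {list(bad.index)}"
            )
        self.table = self.table.reset_index(drop=True)

    @property
    def samples(self) -> list[str]:
        return self.table["sample"].tolist()

    def column(self, name: str) -> np.ndarray:
        return self.table[name].to_numpy()

    def subset(self, sample_ids: list[str]) -> "SampleTable":
        sub = self.table.set_index("sample").loc[list(sample_ids)].reset_index()
        return SampleTable(sub)


@dataclass
class FeatureMatrix:
    """Molecular phenotypes: features x samples.

    ``features`` columns: feature_id, chrom, anchor (1-based TSS or intron
    start), strand, gene_id, cluster_id (NaN/None for expression).
    ``kind`` is one of 'raw-count', 'normalized', 'excision-ratio'.
    """

    features: pd.DataFrame
    samples: list[str]
    values: np.ndarray
    kind: str = "raw-count"

    FEATURE_COLS = ("feature_id", "chrom", "anchor", "strand", "gene_id", "cluster_id")
    KINDS = ("raw-count", "normalized", "excision-ratio")

    def __post_init__(self):
        if self.kind not in self.KINDS:
            raise CohortError(f"unknown value kind {self.kind!r}")
        for col in ("feature_id", "chrom", "anchor"):
            if col not in self.features.columns:
                raise CohortError(f"feature table missing column {col!r}")
        feats = self.features.copy()
        if "strand" not in feats.columns:
            feats["strand"] = "+"
        if "gene_id" not in feats.columns:
            feats["gene_id"] = feats["feature_id"]
        if "cluster_id" not in feats.columns:
            feats["cluster_id"] = None
        self.features = feats.reset_index(drop=True)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.features), len(self.samples)):
            raise CohortError(
                f"values shape {self.values.shape} does not match "
                f"({len(self.features)}, {len(self.samples)})"
            )
        if self.features["feature_id"].duplicated().any():
            dups = self.features.loc[
                self.features["feature_id"].duplicated(), "feature_id"
            ]
            raise CohortError(f"duplicate feature ids: {sorted(set(dups))[:5]}")
        if self.kind == "excision-ratio":
            v = self.values[~np.isnan(self.values)]
            if v.size and (v.min() < -1e-9 or v.max() > 1 + 1e-9):
                raise CohortError("excision ratios must lie in [0, 1]")

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def feature_ids(self) -> list[str]:
        return self.features["feature_id"].tolist()

    def subset_samples(self, sample_ids: list[str]) -> "FeatureMatrix":
        idx = _sample_index(self.samples, sample_ids, "feature matrix")
        return FeatureMatrix(
            self.features, list(sample_ids), self.values[:, idx], self.kind
        )

    def subset_features(self, mask: np.ndarray) -> "FeatureMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            keep = np.where(mask)[0]
        else:
            keep = mask
        return FeatureMatrix(
            self.features.iloc[keep].reset_index(drop=True),
            self.samples,
            self.values[keep],
            self.kind,
        )

    def with_values(self, values: np.ndarray, kind: str | None = None) -> "FeatureMatrix":
        return FeatureMatrix(self.features, self.samples, values, kind or self.kind)


def _sample_index(have: list[str], want: list[str], where: str) -> np.ndarray:
    lookup = {s: i for i, s in enumerate(have)}
    missing = [s for s in want if s not in lookup]
    if missing:
        raise CohortError(f"samples absent from {where}: {missing}")
    return np.array([lookup[s] for s in want], dtype=int)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_genotypes(
    vcf_path,
    region: str | None = None,
    sample_subset: list[str] | None = None,
    split_multiallelic: bool = False,
) -> GenotypeMatrix:
    """Read a VCF into a :class:`GenotypeMatrix` of alt-allele dosages.

    Multi-allelic records are rejected (counted and warned) by default, or
    split into one biallelic record per alternate allele when
    ``split_multiallelic`` is set. Missing genotypes become NaN.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(vcf_path))
    except Exception as exc:  # pragma: no cover - cyvcf2 error text varies
        raise CohortError(f"cannot open VCF {vcf_path}: {exc}") from exc

    file_samples = list(vcf.samples)
    if sample_subset is not None:
        missing = [s for s in sample_subset if s not in file_samples]
        if missing:
            raise CohortError(f"samples absent from VCF: {missing}")
        col_idx = np.array([file_samples.index(s) for s in sample_subset])
        samples = list(sample_subset)
    else:
        col_idx = np.arange(len(file_samples))
        samples = file_samples

    variants: list[VariantRecord] = []
    rows: list[np.ndarray] = []
    n_multi = 0
    iterator = vcf(region) if region else vcf
    for rec in iterator:
        alts = rec.ALT
        if len(alts) != 1:
            if not split_multiallelic:
                n_multi += 1
                continue
        gts = np.array(rec.genotypes, dtype=object)
        alleles = np.array([[g[0], g[1]] for g in gts], dtype=float)
        alleles[alleles < 0] = np.nan
        for ai, alt in enumerate(alts, start=1):
            dos = np.nansum(alleles == ai, axis=1).astype(float)
            dos[np.isnan(alleles).any(axis=1)] = np.nan
            vid = rec.ID or f"{rec.CHROM}_{rec.POS}_{rec.REF}_{alt}"
            if len(alts) > 1:
                vid = f"{vid}_alt{ai}"
            variants.append(VariantRecord(rec.CHROM, rec.POS, vid, rec.REF, alt))
            rows.append(dos[col_idx])
    vcf.close()
    if n_multi:
        warnings.warn(f"skipped {n_multi} multi-allelic records", stacklevel=2)
    dosage = np.vstack(rows) if rows else np.empty((0, len(samples)))
    return GenotypeMatrix(variants, samples, dosage)


def write_genotypes(path, genotypes: GenotypeMatrix) -> None:
    """Write a minimal VCF v4.2 (GT only, unphased) for the given dosages."""
    code = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = []
        for v in genotypes.variants:
            if v.chrom not in chroms:
                chroms.append(v.chrom)
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.samples)
            + "\n"
        )
        for v, row in zip(genotypes.variants, genotypes.dosage):
            gts = "\t".join(
                "./." if np.isnan(d) else code[float(d)] for d in row
            )
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.id}\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# Phenotype BED
# ---------------------------------------------------------------------------

def read_phenotype_bed(path, kind: str = "raw-count") -> FeatureMatrix:
    """Read a tensorQTL-style phenotype BED (chr, start, end, id, samples...).

    The BED ``start`` is 0-based half-open; the internal anchor is the
    1-based position ``start + 1``. Optional columns ``strand``, ``gene_id``
    and ``cluster_id`` may follow ``id`` (detected by header name).
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").lstrip("#").split("\t")
        if len(header) < 5:
            raise CohortError("phenotype BED needs 4 anchor columns plus samples")
        extra_cols = []
        i = 4
        while i < len(header) and header[i] in ("strand", "gene_id", "cluster_id"):
            extra_cols.append(header[i])
            i += 1
        samples = header[i:]
        ncol = len(header)
        feats: list[dict] = []
        rows: list[np.ndarray] = []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != ncol:
                raise CohortError(
                    f"{path}: row {lineno} has {len(parts)} fields, expected {ncol}"
                )
            chrom, start, _end, fid = parts[0], int(parts[1]), parts[2], parts[3]
            rec = {"feature_id": fid, "chrom": chrom, "anchor": start + 1}
            for k, col in enumerate(extra_cols):
                rec[col] = parts[4 + k]
            vals = np.empty(len(samples))
            for k, cell in enumerate(parts[i:]):
                if cell == "" or cell.upper() in ("NA", "NAN"):
                    raise CohortError(
                        f"{path}: empty value for feature {fid}, sample {samples[k]}"
                    )
                vals[k] = float(cell)
            feats.append(rec)
            rows.append(vals)
    features = pd.DataFrame(feats)
    if features["feature_id"].duplicated().any():
        dups = features.loc[features["feature_id"].duplicated(), "feature_id"]
        raise CohortError(f"duplicate feature ids in {path}: {sorted(set(dups))[:5]}")
    values = np.vstack(rows) if rows else np.empty((0, len(samples)))
    if "cluster_id" in features.columns:
        features["cluster_id"] = features["cluster_id"].replace({"": None, ".": None})
    return FeatureMatrix(features, samples, values, kind)


def write_phenotype_bed(path, matrix: FeatureMatrix) -> None:
    """Write a phenotype BED; the internal 1-based anchor becomes BED start."""
    feats = matrix.features
    has_cluster = feats["cluster_id"].notna().any()
    extra = ["strand", "gene_id"] + (["cluster_id"] if has_cluster else [])
    with open(path, "w") as fh:
        fh.write(
            "#chr\tstart\tend\tfeature_id\t" + "\t".join(extra) + "\t"
            + "\t".join(matrix.samples) + "\n"
        )
        for i, row in feats.iterrows():
            start = int(row["anchor"]) - 1
            cols = [row["chrom"], str(start), str(start + 1), row["feature_id"]]
            cols += [str(row[c]) if row[c] is not None else "." for c in extra]
            cols += [repr(float(v)) for v in matrix.values[i]]
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# Metadata / covariates TSV
# ---------------------------------------------------------------------------

def read_sample_table(path) -> SampleTable:
    return SampleTable(pd.read_csv(path, sep="\t", dtype=str))


def write_sample_table(path, samples: SampleTable) -> None:
    samples.table.to_csv(path, sep="\t", index=False)


def read_covariates(path) -> pd.DataFrame:
    """Covariates TSV (covariate rows x sample columns) -> samples x covariates."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.T


def write_covariates(path, cov: pd.DataFrame) -> None:
    cov.T.to_csv(path, sep="\t", index_label="covariate")


# ---------------------------------------------------------------------------
# Cohort alignment
# ---------------------------------------------------------------------------

def align_cohort(
    genotypes: GenotypeMatrix,
    phenotypes: FeatureMatrix,
    samples: SampleTable,
) -> tuple[GenotypeMatrix, FeatureMatrix, SampleTable]:
    """Restrict all three objects to their common samples in a shared order.

    Sample order follows the genotype matrix. The number of samples dropped
    from each object is logged.
    """
    common = [
        s
        for s in genotypes.samples
        if s in set(phenotypes.samples) and s in set(samples.samples)
    ]
    if not common:
        raise CohortError("no samples shared between genotypes, phenotypes, metadata")
    for name, obj in (
        ("genotypes", genotypes.samples),
        ("phenotypes", phenotypes.samples),
        ("metadata", samples.samples),
    ):
        dropped = len(obj) - len(common)
        if dropped:
            logger.info("align_cohort: dropped %d samples from %s", dropped, name)
    return (
        genotypes.subset_samples(common),
        phenotypes.subset_samples(common),
        samples.subset(common),
    )
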