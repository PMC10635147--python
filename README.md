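# popqtl

Population-scale *cis*-QTL analysis for globally diverse cohorts: variance
partitioning of molecular phenotypes across population labels, cis-e/sQTL
mapping with beta-approximated permutation inference, multi-signal
fine-mapping with credible sets, conditional allelic-fold-change effect
sizes, frequency-differentiation and effect-size-heterogeneity
characterization, and regulatory-annotation enrichment — plus a
Balding–Nichols synthetic-cohort generator with full ground truth.

## Who this is for

Statistical geneticists and computational biologists who map genetic
effects on expression or splicing in cohorts spanning multiple continental
groups and populations (e.g., 1000 Genomes-style designs with ~26
populations nested in 5 continental groups), and who need the downstream
population-genetic characterization of the discovered signals: how
differentiated are causal variants (Weir–Cockerham F_ST), which are absent
from historically over-sampled groups, and whether effects are
heterogeneous across ancestries once multiple causal signals per gene are
modelled.

## The models at the core

**Cis mapping.** For each feature (gene TSS or intron start), every variant
within a 1 Mb window is tested by linear regression of the residualized
phenotype on alt-allele dosage. Gene-level significance uses the
permutation scheme of the FastQTL lineage: the minimum cis p-value is
recorded for each of 1,000 phenotype permutations, a Beta(α, β)
distribution is fit to those minima by maximum likelihood, and the
gene-level p is Beta-CDF(best nominal p). Benjamini–Hochberg across genes
at 5% FDR yields eGenes/sGenes and per-gene nominal pair thresholds.
Splicing is tested at the gene level by taking the minimum across a gene's
introns *inside* each permutation.

**Fine-mapping.** A sum-of-single-effects Bayesian regression
(`b = Σ_l γ_l β_l`, one variant per effect, L ≤ 10) fit by coordinate
ascent on the variational ELBO, with per-effect empirical-Bayes prior
variances. Each effect yields a 95% credible set (smallest variant set
reaching the coverage), filtered at purity ≥ 0.5 (minimum |r| among
members). Intron-level sets merge into gene-level sets by transitive
nonempty intersection.

**Effect sizes.** The allelic fold change (aFC) of a lead variant is the
log2 expression ratio of the alt-carrying to the reference haplotype.
Expected log2 expression is `c + Σ_k log2(((2−d_k) + d_k·2^δ_k)/2)`; all
leads of a gene are fit jointly by bounded nonlinear least squares
(|δ| ≤ log2 100), so each δ is conditional on the gene's other signals.

**Population characterization.** Pairwise Weir & Cockerham (1984) θ̂
between a focal continental group and every other group per lead variant;
geographic frequency classes (globally common / absent-in-EUR /
absent-in-EUR+AFR / other, threshold 5%); focal-vs-rest differential
expression by decile coupled to F_ST; and a genotype-by-continental-group
interaction F-test in a single-signal model versus a joint model that
conditions on all other leads of the gene — the joint model absorbs
apparent heterogeneity created by unmodelled additive signals.

## Worked example

```python
from popqtl import SimConfig
from popqtl.pipeline_cli import PipelineConfig, run_pipeline

config = PipelineConfig(
    outdir="demo_run", seed=7,
    sim=dict(n_groups=5, pops_per_group=1, pop_size_range=(30, 30),
             n_genes=15, variants_per_gene=50, n_clusters=10),
    n_perm=200, n_boot=20, variance_n_perm=99, n_pheno_pcs=3,
)
manifest = run_pipeline(config)
for stage in manifest["stages"]:
    print(stage["name"], stage["status"])
```

prints

```
simulate ok
normalize ok
variance ok
map-cis ok
finemap ok
afc ok
popstats ok
enrich ok
```

and leaves under `demo_run/` the simulated VCF/BED/TSV inputs,
`variance/summary.json` (mean R² per label level with permutation p),
`map_cis/egenes.tsv` (gene-level effective p, q-value, eGene flag, nominal
pair threshold), `finemap/credible_sets.tsv` (variant, inclusion, purity,
lead flag), `afc/afc.tsv` (log2 aFC with bootstrap SE), the `popstats/`
F_ST/DE/interaction tables, and `enrich/enrichment.tsv`. A
`manifest.json` records a SHA-256 per output; re-running the same config
and seed reproduces every hash.

The same stages are exposed on the command line:

```bash
popqtl simulate --out fixture --seed 3 --genes 20
popqtl map-cis --vcf fixture/genotypes.vcf --bed fixture/expression.bed \
    --samples fixture/samples.tsv --out cis_out --window 1000000 \
    --perm 1000 --fdr 0.05
popqtl run-all --config pipeline.yaml
```

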