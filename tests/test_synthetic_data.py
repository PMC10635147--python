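import filecmp

import numpy as np
import pytest

from popqtl.io_core import read_genotypes, read_phenotype_bed, read_sample_table
from popqtl.synthetic_data import (
    SimConfig,
    SimTruth,
    simulate_expression,
    simulate_genotypes,
    simulate_splicing,
    write_fixture,
)


def test_config_rejects_bad_differentiation():
    with pytest.raises(ValueError):
        SimConfig(f_group=0.0)
    with pytest.raises(ValueError):
        SimConfig(f_pop=1.0)
    with pytest.raises(ValueError):
        SimConfig(ld_rho=1.0)


class TestGenotypeModel:
    def test_group_frequencies_collapse_to_ancestral_at_small_f(self):
        cfg = SimConfig(
            n_groups=5, pops_per_group=1, pop_size_range=(2, 2),
            n_genes=5, variants_per_gene=40, f_group=1e-5, f_pop=1e-5,
            seed=3,
        )
        _, _, truth = simulate_genotypes(cfg)
        for vid, p0 in truth.p0.items():
            for p in truth.group_freq[vid].values():
                assert abs(p - p0) < 0.05

    def test_balding_nichols_variance_identity(self):
        """Between-group frequency variance / p0(1-p0) estimates F_G."""
        cfg = SimConfig(
            n_groups=5, pops_per_group=1, pop_size_range=(2, 2),
            n_genes=100, variants_per_gene=100,
            p0_range=(0.5, 0.5), p0_block_jitter=0.0,
            f_group=0.1, f_pop=1e-6, ld_rho=0.0, seed=7,
        )
        _, _, truth = simulate_genotypes(cfg)
        gf = np.array([list(d.values()) for d in truth.group_freq.values()])
        ratio = (gf.var(axis=1, ddof=1) / 0.25).mean()
        assert ratio == pytest.approx(0.1, abs=0.01)

    def test_block_ld_strength(self):
        """Latent rho = 0.95 yields mean adjacent dosage |r| > 0.7 at n~750."""
        cfg = SimConfig(
            n_genes=10, variants_per_gene=20, ld_rho=0.95, ld_block_size=10,
            seed=13,
        )
        g, _, _ = simulate_genotypes(cfg)
        rs = []
        for gene in range(10):
            for b in range(2):
                idx = np.arange(gene * 20 + b * 10, gene * 20 + b * 10 + 10)
                for i in range(len(idx) - 1):
                    a, c = g.dosage[idx[i]], g.dosage[idx[i + 1]]
                    if a.std() > 0 and c.std() > 0:
                        rs.append(abs(np.corrcoef(a, c)[0, 1]))
        assert np.mean(rs) > 0.7

    def test_hardy_weinberg_dosages(self, small_cohort):
        g = small_cohort["genotypes"]
        assert set(np.unique(g.dosage)) <= {0.0, 1.0, 2.0}

    def test_cohort_shape_mirrors_config(self, small_cohort):
        cfg = small_cohort["config"]
        samples = small_cohort["samples"]
        assert len(set(samples.column("group"))) == cfg.n_groups
        assert len(set(samples.column("population"))) == cfg.n_groups * cfg.pops_per_group


class TestExpressionModel:
    def test_homozygote_ratio_equals_afc(self):
        """Single causal with log2 aFC 1, no noise: dosage-2 carriers
        express exactly twice the dosage-0 carriers."""
        cfg = SimConfig(
            n_genes=3, variants_per_gene=10, fixed_causal_count=1,
            fixed_afc=1.0, causal_maf_min=0.2,
            noise_sd=0.0, batch_sd=0.0, sex_effect=0.0, seed=5,
        )
        g, s, truth = simulate_genotypes(cfg)
        # force the sign so the ratio statement is deterministic
        for gene in truth.causal_log2_afc:
            truth.causal_log2_afc[gene] = [1.0] * len(truth.causal_variants[gene])
        expr = simulate_expression(g, s, cfg, truth)
        vindex = {v: i for i, v in enumerate(g.variant_ids)}
        checked = 0
        for i, gene in enumerate(sorted(truth.baseline_log2)):
            if not truth.causal_variants[gene]:
                continue
            d = g.dosage[vindex[truth.causal_variants[gene][0]]]
            ratio = expr.values[i][d == 2].mean() / expr.values[i][d == 0].mean()
            assert ratio == pytest.approx(2.0, rel=1e-9)
            checked += 1
        assert checked >= 2

    def test_no_causal_no_group_effect_is_label_exchangeable(self):
        cfg = SimConfig(
            n_genes=5, variants_per_gene=10, fixed_causal_count=0,
            batch_sd=0.0, sex_effect=0.0, pops_per_group=2,
            pop_size_range=(20, 20), seed=6,
        )
        g, s, truth = simulate_genotypes(cfg)
        expr = simulate_expression(g, s, cfg, truth)
        groups = s.column("group")
        from scipy.stats import kruskal

        ps = [
            kruskal(*[row[groups == grp] for grp in np.unique(groups)]).pvalue
            for row in expr.values
        ]
        assert min(ps) > 1e-3  # no gene shows structure beyond chance

    def test_truth_reconstructs_noiseless_expression(self):
        cfg = SimConfig(
            n_genes=4, variants_per_gene=10, noise_sd=0.0, seed=8,
        )
        g, s, truth = simulate_genotypes(cfg)
        expr = simulate_expression(g, s, cfg, truth)
        for i, gene in enumerate(sorted(truth.baseline_log2)):
            mu = truth.expected_log2_expression(gene, g, s)
            np.testing.assert_allclose(np.log2(expr.values[i]), mu, atol=1e-9)


class TestSplicingModel:
    def test_ratios_sum_to_one_within_cluster(self, small_cohort):
        sp = small_cohort["splicing"]
        for _, sub in sp.features.groupby("cluster_id"):
            np.testing.assert_allclose(
                sp.values[sub.index.to_numpy()].sum(axis=0), 1.0, atol=1e-12
            )

    def test_causal_dosage_shifts_target_intron(self):
        cfg = SimConfig(
            n_genes=4, variants_per_gene=20, n_clusters=20,
            splice_causal_frac=1.0, splice_effect_sd=2.0, seed=9,
        )
        g, s, truth = simulate_genotypes(cfg)
        sp = simulate_splicing(g, s, cfg, truth)
        vindex = {v: i for i, v in enumerate(g.variant_ids)}
        checked = 0
        for cluster, info in truth.splice_causal.items():
            d = g.dosage[vindex[info["causal_variant"]]]
            if info["logit_effect"] < 1.0 or (d == 2).sum() < 5 or (d == 0).sum() < 5:
                continue
            fid = f"{cluster}_in{info['target_intron']}"
            row = sp.values[sp.feature_ids.index(fid)]
            assert row[d == 2].mean() > row[d == 0].mean()
            checked += 1
        assert checked >= 3

    def test_single_intron_cluster_rejected(self, small_cohort):
        cfg = SimConfig(introns_per_cluster=(1, 1), seed=1)
        with pytest.raises(ValueError, match="at least 2"):
            simulate_splicing(
                small_cohort["genotypes"], small_cohort["samples"], cfg,
                SimTruth(baseline_log2={"gene0000": 5.0}),
            )


class TestFixture:
    CFG = dict(
        n_groups=2, pops_per_group=2, pop_size_range=(10, 10),
        n_genes=4, variants_per_gene=10, n_clusters=4,
    )

    def test_round_trip_and_determinism(self, tmp_path):
        paths = write_fixture(tmp_path / "a", SimConfig(seed=11, **self.CFG))
        g = read_genotypes(paths["vcf"])
        e = read_phenotype_bed(paths["expression"])
        sp = read_phenotype_bed(paths["splicing"], kind="excision-ratio")
        s = read_sample_table(paths["samples"])
        t = SimTruth.from_json(paths["truth"])
        assert g.n_variants == 40 and e.n_features == 4
        assert set(s.samples) == set(g.samples) == set(e.samples)
        assert all(v in g.variant_ids for vs in t.causal_variants.values() for v in vs)
        assert sp.kind == "excision-ratio"

        paths2 = write_fixture(tmp_path / "b", SimConfig(seed=11, **self.CFG))
        for k in paths:
            assert filecmp.cmp(paths[k], paths2[k], shallow=False), k

    def test_different_seeds_differ(self, tmp_path):
        p1 = write_fixture(tmp_path / "a", SimConfig(seed=1, **self.CFG))
        p2 = write_fixture(tmp_path / "b", SimConfig(seed=2, **self.CFG))
        assert not filecmp.cmp(p1["vcf"], p2["vcf"], shallow=False)

    def test_existing_dir_requires_overwrite(self, tmp_path):
        write_fixture(tmp_path / "a", SimConfig(seed=1, **self.CFG))
        with pytest.raises(FileExistsError):
            write_fixture(tmp_path / "a", SimConfig(seed=1, **self.CFG))
        write_fixture(tmp_path / "a", SimConfig(seed=1, **self.CFG), overwrite=True)
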