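import numpy as np
import pandas as pd
import pytest
from scipy import stats

from popqtl.finemap import CredibleSet
from popqtl.io_core import (
    CohortError,
    FeatureMatrix,
    GenotypeMatrix,
    SampleTable,
    VariantRecord,
)
from popqtl.population_effects import (
    classify_frequency_distribution,
    constraint_associations,
    differential_expression_by_group,
    fst_de_association,
    interaction_scan,
    replication_compare,
    weir_cockerham_fst,
)


def _two_group(d1, d2):
    d = np.concatenate([d1, d2]).astype(float)[None, :]
    n1, n2 = len(d1), len(d2)
    samples = [f"s{i}" for i in range(n1 + n2)]
    g = GenotypeMatrix([VariantRecord("chr1", 100, "v0", "A", "G")], samples, d)
    t = SampleTable(
        pd.DataFrame(
            {
                "sample": samples,
                "population": ["P1"] * n1 + ["P2"] * n2,
                "group": ["G1"] * n1 + ["G2"] * n2,
                "sex": "F",
                "batch": "b",
            }
        )
    )
    return g, t


class TestWeirCockerhamFst:
    def test_fixed_difference_theta_one(self):
        g, t = _two_group(np.full(20, 2.0), np.zeros(20))
        res = weir_cockerham_fst(g, t, focal="G1")[0]
        assert res.pairwise_theta["G2"] == pytest.approx(1.0)

    def test_identical_groups_nonpositive(self):
        d = np.array([0, 0, 1, 1, 2, 2, 1, 0, 2, 1], dtype=float)
        g, t = _two_group(d, d)
        res = weir_cockerham_fst(g, t, focal="G1")[0]
        assert res.pairwise_theta["G2"] <= 0.0

    def test_monomorphic_everywhere_is_undefined(self):
        g, t = _two_group(np.zeros(10), np.zeros(10))
        res = weir_cockerham_fst(g, t, focal="G1")[0]
        assert np.isnan(res.pairwise_theta["G2"])
        assert np.isnan(res.mean_theta)

    def test_allele_flip_invariance(self):
        rng = np.random.default_rng(0)
        d1, d2 = rng.integers(0, 3, 25), rng.integers(0, 3, 25)
        g, t = _two_group(d1, d2)
        theta = weir_cockerham_fst(g, t, focal="G1")[0].pairwise_theta["G2"]
        gf, tf = _two_group(2 - d1, 2 - d2)
        theta_f = weir_cockerham_fst(gf, tf, focal="G1")[0].pairwise_theta["G2"]
        assert theta == pytest.approx(theta_f, abs=1e-12)

    def test_missing_variant_named_in_error(self):
        g, t = _two_group(np.ones(5), np.ones(5))
        with pytest.raises(CohortError, match="vX"):
            weir_cockerham_fst(g, t, focal="G1", variants=["vX"])

    def test_mean_theta_over_multiple_groups(self):
        rng = np.random.default_rng(1)
        n = 60
        d = rng.integers(0, 3, size=(1, n)).astype(float)
        samples = [f"s{i}" for i in range(n)]
        t = SampleTable(
            pd.DataFrame(
                {
                    "sample": samples,
                    "population": np.repeat(["P1", "P2", "P3"], n // 3),
                    "group": np.repeat(["G1", "G2", "G3"], n // 3),
                    "sex": "F",
                    "batch": "b",
                }
            )
        )
        g = GenotypeMatrix([VariantRecord("chr1", 1, "v0", "A", "G")], samples, d)
        res = weir_cockerham_fst(g, t, focal="G2")[0]
        assert set(res.pairwise_theta) == {"G1", "G3"}
        vals = [v for v in res.pairwise_theta.values()]
        assert res.mean_theta == pytest.approx(np.mean(vals))


class TestFrequencyClassification:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["AFR", "AMR", "EAS", "EUR", "SAS"])

    def test_globally_common(self):
        out = classify_frequency_distribution(
            self._table([[0.2, 0.3, 0.1, 0.08, 0.15]])
        )
        assert out["class"].iloc[0] == "globally_common"

    def test_absent_eur(self):
        out = classify_frequency_distribution(
            self._table([[0.12, 0.1, 0.2, 0.0, 0.3]])
        )
        assert out["class"].iloc[0] == "absent_EUR"

    def test_absent_eur_afr_takes_precedence(self):
        out = classify_frequency_distribution(
            self._table([[0.0, 0.1, 0.2, 0.0, 0.3]])
        )
        assert out["class"].iloc[0] == "absent_EUR_AFR"

    def test_other_class(self):
        out = classify_frequency_distribution(
            self._table([[0.02, 0.1, 0.2, 0.01, 0.3]])
        )
        assert out["class"].iloc[0] == "other"

    def test_monomorphic_everywhere_rejected(self):
        with pytest.raises(CohortError):
            classify_frequency_distribution(self._table([[0.0] * 5]))

    def test_out_of_range_rejected(self):
        with pytest.raises(CohortError):
            classify_frequency_distribution(self._table([[1.2, 0.1, 0.1, 0.1, 0.1]]))


class TestDifferentialExpression:
    def _cohort(self, values, groups):
        n = values.shape[1]
        samples = [f"s{i}" for i in range(n)]
        feats = pd.DataFrame(
            {
                "feature_id": [f"g{i}" for i in range(values.shape[0])],
                "chrom": "chr1",
                "anchor": np.arange(values.shape[0]) + 1,
            }
        )
        m = FeatureMatrix(feats, samples, values, "normalized")
        t = SampleTable(
            pd.DataFrame(
                {
                    "sample": samples, "population": groups, "group": groups,
                    "sex": "F", "batch": "b",
                }
            )
        )
        return m, t

    def test_shifted_gene_lands_in_top_decile(self):
        rng = np.random.default_rng(2)
        values = rng.normal(size=(50, 200))
        groups = np.array(["AFR"] * 60 + ["EUR"] * 140)
        values[7, groups == "AFR"] += 1.0
        m, t = self._cohort(values, groups)
        de = differential_expression_by_group(m, t, focal="AFR")
        assert int(de.loc[de["gene_id"] == "g7", "decile"].iloc[0]) == 10

    def test_matches_two_sample_t_oracle(self):
        rng = np.random.default_rng(3)
        values = rng.normal(size=(10, 80))
        groups = np.array(["AFR"] * 30 + ["EUR"] * 50)
        m, t = self._cohort(values, groups)
        de = differential_expression_by_group(m, t, focal="AFR")
        for i in range(10):
            tt = stats.ttest_ind(values[i, :30], values[i, 30:], equal_var=True)
            assert de["pvalue"].iloc[i] == pytest.approx(tt.pvalue, abs=1e-10)
            assert de["tstat"].iloc[i] == pytest.approx(tt.statistic, abs=1e-10)

    def test_decile_occupancy_balanced(self):
        rng = np.random.default_rng(4)
        m, t = self._cohort(
            rng.normal(size=(100, 60)), np.array(["AFR"] * 20 + ["EUR"] * 40)
        )
        de = differential_expression_by_group(m, t, focal="AFR")
        assert de["decile"].value_counts().nunique() == 1

    def test_absent_focal_group_rejected(self):
        rng = np.random.default_rng(5)
        m, t = self._cohort(rng.normal(size=(5, 20)), np.array(["AFR"] * 20))
        with pytest.raises(CohortError):
            differential_expression_by_group(m, t, focal="EAS")


class TestFstDeAssociation:
    def test_degenerate_single_decile_rejected(self):
        fst = pd.DataFrame({"gene_id": ["g1", "g2"], "mean_theta": [0.1, 0.2]})
        de = pd.DataFrame(
            {"gene_id": ["g1", "g2"], "pvalue": [0.5, 0.6],
             "qvalue": [0.8, 0.9], "decile": [3, 3]}
        )
        with pytest.raises(CohortError, match="decile"):
            fst_de_association(fst, de)

    def test_no_overlap_rejected(self):
        fst = pd.DataFrame({"gene_id": ["gX"], "mean_theta": [0.1]})
        de = pd.DataFrame(
            {"gene_id": ["gY"], "pvalue": [0.5], "qvalue": [0.9], "decile": [1]}
        )
        with pytest.raises(CohortError):
            fst_de_association(fst, de)

    def test_null_coupling_is_flat(self):
        rng = np.random.default_rng(6)
        genes = [f"g{i}" for i in range(400)]
        fst = pd.DataFrame({"gene_id": genes, "mean_theta": rng.uniform(0, 0.3, 400)})
        p = rng.uniform(size=400)
        de = pd.DataFrame(
            {
                "gene_id": genes, "pvalue": p,
                "qvalue": np.minimum(p * 2, 1.0),
                "decile": 10 - (stats.rankdata(p, method="ordinal") - 1) * 10 // 400,
            }
        )
        out = fst_de_association(fst, de, n_boot=50, seed=0)
        assert out["pvalue"] > 0.01
        assert abs(out["rank_biserial"]) < 0.2


class TestInteractionScan:
    def _cohort(self, n_per_group=100, seed=0):
        rng = np.random.default_rng(seed)
        groups = np.repeat(["AFR", "EUR", "EAS"], n_per_group)
        n = len(groups)
        samples = [f"s{i}" for i in range(n)]
        t = SampleTable(
            pd.DataFrame(
                {"sample": samples, "population": groups, "group": groups,
                 "sex": "F", "batch": "b"}
            )
        )
        return rng, groups, samples, t

    def _mat(self, y, samples):
        feats = pd.DataFrame({"feature_id": ["g1"], "chrom": "chr1", "anchor": [1]})
        return FeatureMatrix(feats, samples, y[None, :], "normalized")

    def test_maf_filter_skips_with_reason(self):
        rng, groups, samples, t = self._cohort()
        d = np.zeros(300)
        idx = np.where(groups == "AFR")[0]
        d[idx[:20]] = 1.0  # MAF 0.1 in AFR only, 0 elsewhere
        g = GenotypeMatrix([VariantRecord("chr1", 1, "v0", "A", "G")], samples, d[None, :])
        res = interaction_scan(g, self._mat(rng.normal(size=300), samples), t,
                               {"g1": ["v0"]}, mode="single")
        assert not res[0].tested and res[0].skip_reason == "MAF filter"

    def test_true_interaction_detected_and_additive_not(self):
        rng, groups, samples, t = self._cohort(seed=7)
        d = rng.binomial(2, 0.4, 300).astype(float)
        g = GenotypeMatrix([VariantRecord("chr1", 1, "v0", "A", "G")], samples, d[None, :])
        slope = np.where(groups == "AFR", 1.0, 0.2)
        y_int = slope * d + rng.normal(0, 0.5, 300)
        y_add = 0.5 * d + rng.normal(0, 0.5, 300)
        r_int = interaction_scan(g, self._mat(y_int, samples), t, {"g1": ["v0"]},
                                 mode="single")[0]
        r_add = interaction_scan(g, self._mat(y_add, samples), t, {"g1": ["v0"]},
                                 mode="single")[0]
        assert r_int.p_single < 1e-6
        assert r_add.p_single > 0.01

    def test_joint_mode_conditions_on_other_leads(self):
        rng, groups, samples, t = self._cohort(seed=8)
        d1 = rng.binomial(2, 0.5, 300).astype(float)
        d2 = rng.binomial(2, 0.5, 300).astype(float)
        g = GenotypeMatrix(
            [VariantRecord("chr1", 1, "v0", "A", "G"),
             VariantRecord("chr1", 2, "v1", "A", "G")],
            samples, np.vstack([d1, d2]),
        )
        y = 0.5 * d1 + 0.7 * d2 + rng.normal(0, 0.5, 300)
        res = interaction_scan(g, self._mat(y, samples), t, {"g1": ["v0", "v1"]},
                               mode="both")
        assert all(r.p_single is not None and r.p_joint is not None for r in res)
        assert all(r.p_joint > 1e-4 for r in res)  # no spurious heterogeneity

    def test_empty_leads_rejected(self):
        rng, groups, samples, t = self._cohort()
        g = GenotypeMatrix([VariantRecord("chr1", 1, "v0", "A", "G")],
                           samples, np.zeros((1, 300)))
        with pytest.raises(CohortError):
            interaction_scan(g, self._mat(rng.normal(size=300), samples), t, {})


class TestConstraintAssociations:
    def _inputs(self, seed=0, coupled=False):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(300)]
        score = pd.Series(rng.uniform(size=300), index=genes)
        top = score >= score.quantile(0.9)
        if coupled:
            lam = np.where(top, 0.4, 1.2)
            n_sets = pd.Series(rng.poisson(lam), index=genes)
            afc = pd.Series(
                np.abs(rng.normal(0, np.where(top, 0.25, 0.6))), index=genes
            )
            egene = pd.Series(n_sets > 0, index=genes)
        else:
            n_sets = pd.Series(rng.poisson(1.0, 300), index=genes)
            afc = pd.Series(np.abs(rng.normal(0, 0.5, 300)), index=genes)
            egene = pd.Series(rng.random(300) < 0.6, index=genes)
        return score, egene, n_sets, afc

    def test_quasipoisson_point_estimate_equals_poisson(self):
        import statsmodels.api as sm

        score, egene, n_sets, afc = self._inputs(seed=1, coupled=True)
        out = constraint_associations(score, egene, n_sets, afc)
        top = (score >= score.quantile(0.9)).astype(float).to_numpy()
        x = sm.add_constant(top)
        plain = sm.GLM(n_sets.to_numpy(), x, family=sm.families.Poisson()).fit()
        assert out["n_sets_quasipoisson"]["coefficient"] == pytest.approx(
            float(plain.params[1]), abs=1e-8
        )

    def test_coupled_generator_detected_in_expected_direction(self):
        score, egene, n_sets, afc = self._inputs(seed=2, coupled=True)
        out = constraint_associations(score, egene, n_sets, afc)
        assert out["n_sets_quasipoisson"]["coefficient"] < 0
        assert out["n_sets_quasipoisson"]["pvalue"] < 0.01
        assert out["afc_rank_sum"]["pvalue"] < 0.01
        assert out["afc_rank_sum"]["mean_top"] < out["afc_rank_sum"]["mean_other"]

    def test_null_inputs_not_systematically_significant(self):
        ps = []
        for seed in range(8):
            score, egene, n_sets, afc = self._inputs(seed=10 + seed)
            out = constraint_associations(score, egene, n_sets, afc)
            ps.append(out["egene_score_rank_sum"]["pvalue"])
        assert np.mean(ps) > 0.2

    def test_small_stratum_rejected(self):
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(30)]
        score = pd.Series(rng.uniform(size=30), index=genes)
        egene = pd.Series([True] * 25 + [False] * 5, index=genes)
        with pytest.raises(CohortError):
            constraint_associations(
                score, egene, pd.Series(1, index=genes),
                pd.Series(0.5, index=genes),
            )


class TestReplication:
    def _set(self, gene, variants):
        return CredibleSet(gene, variants, {v: 0.5 for v in variants},
                           0.95, 1.0, variants[0], gene_id=gene)

    def test_three_statuses(self):
        sets_a = [
            self._set("g1", ["v1", "v2"]),
            self._set("g2", ["v1"]),
            self._set("g3", ["v5"]),
        ]
        b = {"g1": {"v2", "v9"}, "g2": {"v9"}}
        out = replication_compare(sets_a, b)
        assert [r.status for r in out] == [
            "replicated", "not_replicated", "gene_absent_in_B",
        ]
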