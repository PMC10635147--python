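import numpy as np
import pandas as pd
import pytest
from scipy import stats

from popqtl.cis_mapping import (
    call_significant,
    nominal_pass,
    permutation_pass,
)
from popqtl.io_core import CohortError, FeatureMatrix, GenotypeMatrix, VariantRecord


def _genotypes(dosage, positions=None, chrom="chr1"):
    dosage = np.asarray(dosage, dtype=float)
    m, n = dosage.shape
    positions = positions if positions is not None else (np.arange(m) + 1) * 1000
    variants = [
        VariantRecord(chrom, int(p), f"v{i}", "A", "G")
        for i, p in enumerate(positions)
    ]
    return GenotypeMatrix(variants, [f"s{j}" for j in range(n)], dosage)


def _phenotypes(values, anchors, samples):
    values = np.asarray(values, dtype=float)
    feats = pd.DataFrame(
        {
            "feature_id": [f"f{i}" for i in range(values.shape[0])],
            "chrom": "chr1",
            "anchor": anchors,
        }
    )
    return FeatureMatrix(feats, samples, values, "normalized")


class TestNominalPass:
    def test_exact_linear_phenotype(self):
        rng = np.random.default_rng(0)
        d = rng.integers(0, 3, size=(1, 40)).astype(float)
        g = _genotypes(d)
        m = _phenotypes(2.0 * d, [1000], g.samples)
        out = nominal_pass(g, m, window=10_000, maf_min=0.0)
        assert out["slope"].iloc[0] == pytest.approx(2.0)
        assert out["pvalue"].iloc[0] < 1e-30

    def test_monomorphic_variant_skipped(self):
        d = np.vstack([np.zeros(20), np.random.default_rng(1).integers(0, 3, 20)])
        g = _genotypes(d)
        m = _phenotypes(np.random.default_rng(2).normal(size=(1, 20)), [1500], g.samples)
        out = nominal_pass(g, m, window=10_000, maf_min=0.0)
        assert set(out["variant_id"]) == {"v1"}

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(3)
        d = rng.integers(0, 3, size=(12, 50)).astype(float)
        g = _genotypes(d)
        y = rng.normal(size=(1, 50))
        m = _phenotypes(y, [5000], g.samples)
        out = nominal_pass(g, m, window=100_000, maf_min=0.0).set_index("variant_id")
        for i in range(12):
            if d[i].std() == 0:
                continue
            x = np.column_stack([np.ones(50), d[i]])
            beta = np.linalg.solve(x.T @ x, x.T @ y[0])
            resid = y[0] - x @ beta
            s2 = resid @ resid / (50 - 2)
            se = np.sqrt(s2 * np.linalg.inv(x.T @ x)[1, 1])
            t = beta[1] / se
            p = 2 * stats.t.sf(abs(t), 48)
            row = out.loc[f"v{i}"]
            assert row["slope"] == pytest.approx(beta[1], abs=1e-10)
            assert row["slope_se"] == pytest.approx(se, abs=1e-10)
            assert row["pvalue"] == pytest.approx(p, rel=1e-8)

    def test_window_and_distance(self):
        d = np.random.default_rng(4).integers(0, 3, size=(3, 30)).astype(float)
        g = _genotypes(d, positions=[1000, 5000, 50_000])
        m = _phenotypes(np.random.default_rng(5).normal(size=(1, 30)), [4000], g.samples)
        out = nominal_pass(g, m, window=3000, maf_min=0.0)
        assert set(out["variant_id"]) == {"v0", "v1"}
        assert out.set_index("variant_id").loc["v0", "distance"] == -3000

    def test_invariant_to_residualized_covariate(self):
        """Adding a covariate already projected out leaves slopes unchanged."""
        from popqtl.normalization import residualize

        rng = np.random.default_rng(6)
        d = rng.integers(0, 3, size=(5, 60)).astype(float)
        g = _genotypes(d)
        cov = pd.DataFrame({"c": rng.normal(size=60)}, index=g.samples)
        y = rng.normal(size=(2, 60))
        m = residualize(_phenotypes(y, [1000, 2000], g.samples), cov)
        base = nominal_pass(g, m, window=100_000, maf_min=0.0)
        again = nominal_pass(g, residualize(m, cov), window=100_000, maf_min=0.0)
        np.testing.assert_allclose(base["slope"], again["slope"], atol=1e-8)

    def test_doubling_window_never_weakens_best_association(self):
        rng = np.random.default_rng(7)
        d = rng.integers(0, 3, size=(20, 40)).astype(float)
        g = _genotypes(d, positions=rng.integers(1, 200_000, size=20))
        m = _phenotypes(rng.normal(size=(3, 40)), [50_000, 90_000, 120_000], g.samples)
        small = nominal_pass(g, m, window=30_000, maf_min=0.0)
        big = nominal_pass(g, m, window=60_000, maf_min=0.0)
        for fid, sub in small.groupby("feature_id"):
            best_small = sub["pvalue"].min()
            best_big = big[big["feature_id"] == fid]["pvalue"].min()
            assert best_big <= best_small + 1e-15


class TestPermutationPass:
    def test_single_variant_null_is_uniform_beta(self):
        rng = np.random.default_rng(8)
        d = rng.integers(0, 3, size=(1, 80)).astype(float)
        g = _genotypes(d)
        m = _phenotypes(rng.normal(size=(1, 80)), [1000], g.samples)
        (res,) = permutation_pass(g, m, window=10_000, n_perm=2000, seed=1, maf_min=0.0)
        assert res.beta_a == pytest.approx(1.0, abs=0.15)
        assert res.beta_b == pytest.approx(1.0, abs=0.15)
        assert res.p_effective == pytest.approx(res.best_p, abs=0.05)

    def test_effective_tracks_empirical(self):
        """Beta-approximated p agrees in rank with the empirical p on nulls."""
        rng = np.random.default_rng(9)
        d = rng.integers(0, 3, size=(30, 60)).astype(float)
        g = _genotypes(d, positions=(np.arange(30) + 1) * 100)
        y = rng.normal(size=(25, 60))
        m = _phenotypes(y, [1500] * 25, g.samples)
        m.features["feature_id"] = [f"f{i}" for i in range(25)]
        res = permutation_pass(g, m, window=10_000, n_perm=500, seed=2, maf_min=0.0)
        eff = [r.p_effective for r in res]
        emp = [r.p_empirical for r in res]
        rho = stats.spearmanr(eff, emp).statistic
        assert rho > 0.95

    def test_grouped_mode_minimizes_over_members(self):
        rng = np.random.default_rng(10)
        d = rng.integers(0, 3, size=(10, 50)).astype(float)
        g = _genotypes(d)
        y = rng.normal(size=(3, 50))
        m = _phenotypes(y, [1000, 2000, 3000], g.samples)
        solo = permutation_pass(g, m, window=20_000, n_perm=200, seed=3, maf_min=0.0)
        grouped = permutation_pass(
            g, m, window=20_000, n_perm=200, seed=3, maf_min=0.0,
            grouping={f"f{i}": "gene1" for i in range(3)},
        )
        assert len(grouped) == 1
        assert grouped[0].best_p == pytest.approx(min(r.best_p for r in solo))
        # same observed minimum but a stricter (min-over-members) null, so
        # the grouped empirical p cannot fall below the best member's
        best_member = min(solo, key=lambda r: r.best_p)
        assert grouped[0].p_empirical >= best_member.p_empirical - 1e-12

    def test_nperm_bounds(self):
        d = np.random.default_rng(0).integers(0, 3, size=(2, 30)).astype(float)
        g = _genotypes(d)
        m = _phenotypes(np.random.default_rng(1).normal(size=(1, 30)), [1000], g.samples)
        with pytest.raises(ValueError):
            permutation_pass(g, m, n_perm=5)
        with pytest.warns(UserWarning):
            permutation_pass(g, m, window=10_000, n_perm=50, seed=0, maf_min=0.0)


class TestCallSignificant:
    def _results(self, pvals):
        from popqtl.cis_mapping import GenePermutationResult

        return [
            GenePermutationResult(f"f{i}", p, "v0", 1.0, 1.0, p, p, 1000, 10)
            for i, p in enumerate(pvals)
        ]

    def test_all_null_calls_nothing(self):
        calls = call_significant(self._results([1.0] * 20), fdr=0.05)
        assert calls.n_significant == 0

    def test_single_strong_signal_called(self):
        pvals = [1e-6] + list(np.linspace(0.2, 1.0, 100))
        calls = call_significant(self._results(pvals), fdr=0.05)
        tab = calls.table.set_index("feature_id")
        assert bool(tab.loc["f0", "significant"])
        assert calls.n_significant == 1

    def test_bh_matches_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(11)
        pvals = np.concatenate([rng.uniform(size=50), rng.uniform(0, 1e-4, 10)])
        calls = call_significant(self._results(pvals), fdr=0.05)
        expected = sm.stats.multipletests(pvals, method="fdr_bh")[1]
        np.testing.assert_allclose(calls.table["qvalue"], expected, atol=1e-12)

    def test_significant_pairs_respect_feature_thresholds(self):
        rng = np.random.default_rng(12)
        d = rng.integers(0, 3, size=(20, 100)).astype(float)
        g = _genotypes(d)
        y = 0.8 * d[3] + rng.normal(size=(1, 100))
        m = _phenotypes(y, [1000], g.samples)
        nominal = nominal_pass(g, m, window=100_000, maf_min=0.0)
        res = permutation_pass(g, m, window=100_000, n_perm=500, seed=4, maf_min=0.0)
        calls = call_significant(res, fdr=0.05, nominal=nominal)
        assert calls.n_significant == 1
        thr = calls.table["nominal_threshold"].iloc[0]
        assert (calls.significant_pairs["pvalue"] <= thr * (1 + 1e-9)).all()
        assert "v3" in set(calls.significant_pairs["variant_id"])

    def test_empty_input_rejected(self):
        with pytest.raises(CohortError):
            call_significant([], fdr=0.05)
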