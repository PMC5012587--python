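"""Copy assignment, relative expression, summaries, clustering, enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dfcomp.dosage import (assign_copy_number, compensation_summary,
                           covariate_regression, em_compensation_clusters,
                           relative_expression, sex_bias_enrichment,
                           sex_concordance, specificity_scores)
from dfcomp.mixture import GaussianMixtureEEE

from conftest import true_record_lfc


def _genes(intervals):
    return pd.DataFrame([
        ("2L", s, e, f"g{i}", e - s, "gene")
        for i, (s, e) in enumerate(intervals)],
        columns=["chrom", "start", "end", "gene_id", "length", "feature"])


class TestAssignCopyNumber:
    def test_interval_cases(self):
        genes = _genes([(100, 200), (600, 700), (450, 550)])
        panel = pd.DataFrame([("2L", 50, 500, "df1")],
                             columns=["chrom", "start", "end", "df_id"])
        copies = assign_copy_number(genes, panel)
        states = copies.set_index("gene_id")["state"]
        assert states["g0"] == "1"          # containment
        assert "g1" not in states.index     # disjoint -> two copy
        assert states["g2"] == "broken"     # partial overlap

    def test_gene_on_other_chromosome_is_two_copy(self):
        genes = _genes([(100, 200)])
        genes.loc[0, "chrom"] = "3R"
        panel = pd.DataFrame([("2L", 50, 500, "df1")],
                             columns=["chrom", "start", "end", "df_id"])
        assert len(assign_copy_number(genes, panel)) == 0

    def test_exhaustive_overlap_enumeration(self):
        """All relative interval placements classify per the overlap rule."""
        panel = pd.DataFrame([("2L", 100, 200, "d")],
                             columns=["chrom", "start", "end", "df_id"])
        cases = []
        for s in range(60, 260, 20):
            for ln in (10, 50, 120, 200):
                cases.append((s, s + ln))
        genes = _genes(cases)
        copies = assign_copy_number(genes, panel).set_index("gene_id")
        for i, (s, e) in enumerate(cases):
            gid = f"g{i}"
            contained = s >= 100 and e <= 200
            overlaps = s < 200 and e > 100
            if contained:
                assert copies.at[gid, "state"] == "1"
            elif overlaps:
                assert copies.at[gid, "state"] == "broken"
            else:
                assert gid not in copies.index


class TestRelativeExpression:
    def _toy(self, one_copy_factor):
        """4 genotypes x 2 reps, one deletion genotype halving gene g0."""
        fpkm = pd.DataFrame(
            {f"{g}_r{r}": [8.0, 4.0] for g in ("wt", "a", "b", "c")
             for r in (1, 2)}, index=["g0", "g1"])
        for r in (1, 2):
            fpkm.loc["g0", f"a_r{r}"] = 8.0 * one_copy_factor
        samples = pd.DataFrame({
            "sample_id": fpkm.columns,
            "genotype": [c.split("_")[0] for c in fpkm.columns],
            "sex": "female", "background": "iso",
            "replicate": [int(c[-1]) for c in fpkm.columns]})
        copies = pd.DataFrame({"gene_id": ["g0"], "df_id": ["a"],
                               "state": ["1"]})
        return fpkm, samples, copies

    def test_full_compensation_r0_c2(self):
        fpkm, samples, copies = self._toy(1.0)
        rec = relative_expression(fpkm, samples, copies)
        one = rec[rec["copy"] == "1"].iloc[0]
        assert one["R"] == pytest.approx(0.0)
        assert one["C"] == pytest.approx(2.0)

    def test_no_compensation_rm1_c1(self):
        fpkm, samples, copies = self._toy(0.5)
        rec = relative_expression(fpkm, samples, copies)
        one = rec[rec["copy"] == "1"].iloc[0]
        assert one["R"] == pytest.approx(-1.0)
        assert one["C"] == pytest.approx(1.0)

    def test_no_reference_flagged(self):
        fpkm, samples, copies = self._toy(0.5)
        # make the gene one-copy in every genotype except wt, then drop wt
        copies = pd.DataFrame({"gene_id": ["g0"] * 4,
                               "df_id": ["wt", "a", "b", "c"],
                               "state": ["1"] * 4})
        rec = relative_expression(fpkm, samples, copies)
        g0 = rec[(rec["gene_id"] == "g0") & (rec["copy"] == "1")]
        assert (g0["reason"] == "no_reference").all()

    def test_below_cutoff_excluded(self):
        fpkm, samples, copies = self._toy(0.5)
        rec = relative_expression(fpkm, samples, copies,
                                  cutoffs={"iso": 100.0})
        one = rec[rec["copy"] == "1"]
        assert one["excluded"].all()
        assert (one["reason"] == "below_cutoff").all()

    def test_reference_consistency_under_genotype_removal(self):
        """Dropping a genotype only changes a gene's reference through that
        genotype's samples."""
        fpkm, samples, copies = self._toy(0.7)
        rec_full = relative_expression(fpkm, samples, copies)
        keep = samples[samples["genotype"] != "c"]
        rec_drop = relative_expression(fpkm[keep["sample_id"]], keep, copies)
        r1 = rec_full[rec_full["copy"] == "1"].iloc[0]["R"]
        r2 = rec_drop[rec_drop["copy"] == "1"].iloc[0]["R"]
        # genotype c had identical values to the rest -> reference unchanged
        assert r1 == pytest.approx(r2)

    def test_noise_free_recovery_against_truth(self, noisefree_panel,
                                               small_results_factory=None):
        from dfcomp import CompensationModel
        from dfcomp.simulate import intergenic_ids

        p = noisefree_panel
        model = CompensationModel(
            p["counts"], p["samples"], p["bundle"].genes, p["bundle"].dfs,
            lengths=p["lengths"], spikes=p["spikes"],
            intergenic_ids=intergenic_ids(p["counts"]))
        res = model.fit()
        one = res.records[(res.records["copy"] == "1")
                          & ~res.records["excluded"]].copy()
        truth = true_record_lfc(one, p["bundle"].truth.effects)
        r = np.corrcoef(one["R"], truth)[0, 1]
        assert r > 0.99
        assert np.abs(one["R"] - truth).median() < 0.02


class TestCompensationSummary:
    def _records(self, r_one, r_two):
        one = pd.DataFrame({"R": r_one, "copy": "1", "excluded": False})
        two = pd.DataFrame({"R": r_two, "copy": "2", "excluded": False})
        df = pd.concat([one, two], ignore_index=True)
        df["C"] = 2.0 ** (df["R"] + 1)
        return df

    def test_no_compensation_null(self):
        rng = np.random.default_rng(0)
        r2 = rng.normal(0, 0.3, 500)
        rec = self._records(r2 - 1.0, r2)  # one copy = two copy shifted -1
        s = compensation_summary(rec)
        assert s.mean_fold == pytest.approx(2.0 ** r2.mean(), rel=1e-6)
        assert s.ks_D < 0.01  # identical shapes after the -1 shift

    def test_full_compensation_mean_fold_2(self):
        rng = np.random.default_rng(1)
        rec = self._records(rng.normal(0, 1e-9, 100), rng.normal(0, 0.2, 100))
        s = compensation_summary(rec)
        assert s.mean_fold == pytest.approx(2.0, rel=1e-4)

    def test_statistics_match_scipy_oracle(self):
        rng = np.random.default_rng(2)
        r1 = rng.normal(-0.6, 0.4, 400)
        r2 = rng.normal(0, 0.3, 600)
        s = compensation_summary(self._records(r1, r2))
        assert s.skewness_p2 == pytest.approx(
            3 * (r1.mean() - np.median(r1)) / r1.std(ddof=1), abs=1e-12)
        assert s.kurtosis == pytest.approx(
            stats.kurtosis(r1, fisher=False), abs=1e-12)
        assert s.mwu_p == pytest.approx(
            stats.mannwhitneyu(r1, r2, alternative="two-sided").pvalue,
            abs=1e-10)
        ks = stats.ks_2samp(r1, r2 - 1.0)
        assert s.ks_D == pytest.approx(ks.statistic, abs=1e-10)
        # symmetric sample -> near-zero skewness
        sym = compensation_summary(self._records(rng.normal(-1, 0.2, 2000),
                                                 r2))
        # Monte-Carlo tolerance ~3 sd: sd(3(mean-median)/s) ~ 2.27/sqrt(n)
        assert abs(sym.skewness_p2) < 0.15

    def test_degenerate_input_raises(self):
        with pytest.raises(ValueError):
            compensation_summary(self._records(np.full(40, -1.0),
                                               np.zeros(40)))


class TestSexConcordance:
    def _records(self, rf, rm):
        n = len(rf)
        rows = []
        for i in range(n):
            rows.append((f"g{i}", "d1", "female", "iso", "1", rf[i], False))
            rows.append((f"g{i}", "d1", "male", "iso", "1", rm[i], False))
        return pd.DataFrame(rows, columns=[
            "gene_id", "genotype", "sex", "background", "copy", "R",
            "excluded"])

    def test_identical_records(self):
        r = np.linspace(-1, 0, 20)
        out = sex_concordance(self._records(r, r))
        assert out["r"] == pytest.approx(1.0)
        assert out["slope"] == pytest.approx(1.0)

    def test_antisymmetric_records(self):
        r = np.linspace(-1, 1, 20)
        out = sex_concordance(self._records(r, -r))
        assert out["r"] == pytest.approx(-1.0)

    def test_shared_variance_gives_analytic_correlation(self):
        rng = np.random.default_rng(3)
        n = 4000
        shared = rng.normal(0, 0.4, n)
        rf = shared + rng.normal(0, 0.3, n)
        rm = shared + rng.normal(0, 0.3, n)
        out = sex_concordance(self._records(rf, rm))
        expect = 0.4**2 / (0.4**2 + 0.3**2)
        se = (1 - expect**2) / np.sqrt(n - 3)
        assert abs(out["r"] - expect) < 3 * se

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            sex_concordance(self._records([0.1], [0.1]))


class TestEmClusters:
    def test_separated_clouds_high_accuracy(self):
        rng = np.random.default_rng(0)
        x = np.vstack([rng.normal(-1, 0.05, (100, 2)),
                       rng.normal(0, 0.05, (100, 2))])
        fit = GaussianMixtureEEE(random_state=0).fit(x)
        labels = np.array([0] * 100 + [1] * 100)
        acc = max((fit.labels_ == labels).mean(),
                  (fit.labels_ != labels).mean())
        assert acc >= 0.99

    def test_degenerate_identical_points(self):
        x = np.ones((50, 2))
        with pytest.warns(UserWarning):
            fit = GaussianMixtureEEE(random_state=0).fit(x)
        assert np.isfinite(fit.loglik_)

    @pytest.mark.parametrize("seed", range(20))
    def test_loglik_matches_sklearn_tied_oracle(self, seed):
        from sklearn.mixture import GaussianMixture

        rng = np.random.default_rng(seed)
        n = int(rng.integers(80, 200))
        cov = np.array([[0.05, 0.02], [0.02, 0.08]])
        d = rng.uniform(0.8, 1.5)
        x = np.vstack([rng.multivariate_normal([-d, -d], cov, n),
                       rng.multivariate_normal([0, 0], cov, n)])
        fit = GaussianMixtureEEE(random_state=seed).fit(x)
        sk = GaussianMixture(2, covariance_type="tied", reg_covar=1e-12,
                             n_init=5, random_state=0, tol=1e-10,
                             max_iter=5000).fit(x)
        ll_sk = sk.score(x) * len(x)
        assert fit.loglik_ >= ll_sk - 1e-6
        assert abs(fit.loglik_ - ll_sk) < 1e-4 * abs(ll_sk) + 1e-6

    def test_eee_mixture_parameter_recovery(self):
        rng = np.random.default_rng(5)
        cov = np.array([[0.04, 0.015], [0.015, 0.05]])
        mu = np.array([[-1.0, -0.9], [-0.1, 0.0]])
        n = 250
        x = np.vstack([rng.multivariate_normal(mu[0], cov, n),
                       rng.multivariate_normal(mu[1], cov, n)])
        fit = GaussianMixtureEEE(random_state=0).fit(x)
        order = np.argsort(fit.means_[:, 0])
        for j, true_mu in zip(order, mu):
            se = np.sqrt(np.diag(cov) / n)
            assert np.all(np.abs(fit.means_[j] - true_mu) < 4 * se)
        from sklearn.metrics import adjusted_rand_score

        labels = np.array([0] * n + [1] * n)
        assert adjusted_rand_score(labels, fit.labels_) >= 0.9

    def test_cluster_records_interface(self):
        rng = np.random.default_rng(6)
        rows = []
        for i in range(120):
            r_iso = -1.0 + (0.9 if i < 40 else 0.0) + rng.normal(0, 0.05)
            r_hyb = -1.0 + (0.9 if i < 40 else 0.0) + rng.normal(0, 0.05)
            for bg, r in (("isogenic", r_iso), ("hybrid", r_hyb)):
                rows.append((f"g{i}", "d1", "female", bg, "1", r, False))
        rec = pd.DataFrame(rows, columns=[
            "gene_id", "genotype", "sex", "background", "copy", "R",
            "excluded"])
        out = em_compensation_clusters(rec)
        ass = out["assignments"].set_index("gene_id")
        better = {f"g{i}" for i in range(40)}
        called = set(ass.index[ass["cluster"] == "better"])
        assert called == better


class TestSexBiasEnrichment:
    def test_exact_hand_enumeration(self):
        """Population 10 with 5 male-biased; cluster of 4, all male-biased:
        upper tail P = C(5,4) C(5,0) / C(10,4) = 5/210."""
        labels = pd.Series({f"g{i}": ("male" if i < 5 else "none")
                            for i in range(10)})
        out = sex_bias_enrichment([f"g{i}" for i in range(4)], labels,
                                  {"pop": [f"g{i}" for i in range(10)]})
        row = out[out["bias_class"] == "male"].iloc[0]
        assert row["p_upper"] == pytest.approx(5 / 210)

    def test_cluster_equals_population(self):
        labels = pd.Series({f"g{i}": "male" for i in range(6)})
        out = sex_bias_enrichment([f"g{i}" for i in range(6)], labels,
                                  {"pop": [f"g{i}" for i in range(6)]})
        assert np.allclose(out["p_upper"].iloc[0], 1.0)
        assert np.allclose(out["p_lower"], 1.0)

    def test_not_subset_raises(self):
        labels = pd.Series({"a": "male"})
        with pytest.raises(ValueError):
            sex_bias_enrichment(["zzz"], labels, {"pop": ["a"]})

    def test_upper_p_uniform_under_random_clusters(self):
        rng = np.random.default_rng(0)
        pop = [f"g{i}" for i in range(60)]
        labels = pd.Series({g: ("male" if i < 20 else "none")
                            for i, g in enumerate(pop)})
        ps = []
        for _ in range(1000):
            cluster = rng.choice(pop, 15, replace=False)
            out = sex_bias_enrichment(cluster, labels, {"pop": pop})
            ps.append(out[out["bias_class"] == "male"]["p_upper"].iloc[0])
        # discrete conservative uniformity: P(p <= x) <= x
        ps = np.array(ps)
        for x in (0.05, 0.1, 0.25, 0.5):
            assert (ps <= x).mean() <= x + 0.03


class TestSpecificityScores:
    def test_uniform_profile(self):
        out = specificity_scores(np.ones(6))
        assert out["tau"] == pytest.approx(0.0)
        assert out["tsps"] == pytest.approx(0.0)

    def test_single_tissue_limit(self):
        x = np.zeros(8)
        x[3] = 5.0
        out = specificity_scores(x)
        assert out["tau"] == pytest.approx(1.0)
        assert out["tsps"] == pytest.approx(np.log2(8))

    def test_worked_example(self):
        out = specificity_scores([1.0, 0.5, 0.0])
        assert out["tau"] == pytest.approx(0.75)

    def test_all_zero_flagged(self):
        out = specificity_scores(np.zeros(4))
        assert out["flag"] == "all_zero"
        assert np.isnan(out["tau"])


class TestCovariateRegression:
    def _records(self, r):
        return pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(len(r))], "copy": "1",
            "R": r, "excluded": False})

    def test_exact_linear_relationship(self):
        x = np.linspace(1, 5, 40)
        r = 0.3 * x - 1.0
        cov = pd.Series(x, index=[f"g{i}" for i in range(40)])
        out = covariate_regression(self._records(r), cov)
        assert out["slope"] == pytest.approx(0.3, abs=1e-10)
        assert out["p"] < 1e-20

    def test_type_one_error_calibrated_under_null(self):
        rng = np.random.default_rng(1)
        hits = 0
        n_sim = 500
        for _ in range(n_sim):
            r = rng.normal(-0.7, 0.3, 50)
            cov = pd.Series(rng.normal(0, 1, 50),
                            index=[f"g{i}" for i in range(50)])
            out = covariate_regression(self._records(r), cov)
            hits += out["p"] < 0.05
        assert 0.03 <= hits / n_sim <= 0.07

    def test_binary_label_uses_mwu(self):
        rng = np.random.default_rng(2)
        r = np.concatenate([rng.normal(-1, 0.1, 30),
                            rng.normal(-0.3, 0.1, 30)])
        lab = pd.Series(["hk"] * 30 + ["other"] * 30,
                        index=[f"g{i}" for i in range(60)])
        out = covariate_regression(self._records(r), lab)
        assert out["kind"] == "binary"
        assert out["p"] < 1e-6

    def test_constant_covariate_raises(self):
        cov = pd.Series(np.ones(20), index=[f"g{i}" for i in range(20)])
        with pytest.raises(ValueError):
            covariate_regression(self._records(np.linspace(-1, 0, 20)), cov)
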