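"""Parameter-recovery and calibration studies on the synthetic panel.

These routines exercise the full pipeline on generated data with known
ground truth: per-gene compensation recovery, null calibration of the
stratified and covariate tests, type-I calibration of the moderated DE test,
propagation-slope recovery and the female-specific repressive-domain
contrast.  They are used both by the validation test-suite and by the
reproduction script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .config import SimulationConfig
from .de import fit_all_genotypes, fit_moderated_de
from .dosage import assign_copy_number, covariate_regression
from .model import CompensationModel
from .network import propagation_correlation
from .simulate import gene_rows, generate_panel, intergenic_ids, \
    simulate_counts


def default_panel(seed: int):
    """The default synthetic screen: 2500 genes, 40 deletions, two sexes,
    two backgrounds, duplicates, dispersion 0.05."""
    cfg = SimulationConfig(seed=seed)
    bundle = generate_panel(cfg)
    counts, samples, spikes, lengths = simulate_counts(bundle, cfg)
    return cfg, bundle, counts, samples, spikes, lengths


def fit_panel(bundle, counts, samples, spikes, lengths):
    model = CompensationModel(
        counts, samples, bundle.genes, bundle.dfs, lengths=lengths,
        spikes=spikes, domains=bundle.domains, network=bundle.network,
        intergenic_ids=intergenic_ids(counts))
    return model.fit()


def record_truth(one_copy_records: pd.DataFrame,
                 truth_effects: pd.DataFrame) -> np.ndarray:
    """Expected direct log2 dose response per one-copy record."""
    dose = truth_effects[truth_effects["cause"] == "dose"].set_index(
        ["gene_id", "df_id"])
    key = list(zip(one_copy_records["gene_id"],
                   one_copy_records["genotype"]))
    base = dose["base_lfc"].loc[key].to_numpy()
    boost = dose["female_boost_lfc"].loc[key].to_numpy()
    female = (one_copy_records["sex"] == "female").to_numpy()
    return base + np.where(female, boost, 0.0)


def compensation_recovery(results, bundle) -> dict:
    """Per-gene correlation with true compensation and recovery of the
    no-compensation (c=0) and full-compensation (c=1) strata."""
    rec = results.records
    one = rec[(rec["copy"] == "1") & ~rec["excluded"]].copy()
    one["true"] = record_truth(one, bundle.truth.effects)
    per_gene = one.groupby("gene_id").agg(R=("R", "mean"),
                                          true=("true", "mean"))
    r = float(np.corrcoef(per_gene["R"], per_gene["true"])[0, 1])
    out = {"per_gene_r": r, "n_genes": len(per_gene),
           "n_records": len(one)}
    for name, target in (("c0", -1.0), ("c1", 0.0)):
        sub = one[np.isclose(one["true"], target)]
        out[f"{name}_mean_R"] = float(sub["R"].mean())
        out[f"{name}_se"] = float(sub["R"].std() / np.sqrt(len(sub)))
        out[f"{name}_n"] = len(sub)
    return out


def null_test_calibration(seed: int, n_sims: int = 500,
                          n_records: int = 120) -> dict:
    """P-value uniformity of the domain-stratified Mann-Whitney test and the
    covariate F-test when compensation is drawn from a single distribution
    with no domain or covariate structure."""
    from .chromatin import domain_stratified_tests

    rng = np.random.default_rng(seed)
    mwu_ps, cov_ps = [], []
    gene_ids = [f"g{i}" for i in range(n_records)]
    for _ in range(n_sims):
        r = rng.normal(-0.7, 0.35, n_records)
        states = rng.choice(["Rep", "Act", "Null"], n_records)
        rec = pd.DataFrame({
            "gene_id": gene_ids, "genotype": "d", "sex": "female",
            "background": "iso", "copy": "1", "R": r, "excluded": False})
        labels = pd.DataFrame({"hic_state": states}, index=gene_ids)
        out = domain_stratified_tests(rec, labels, "hic_state")
        ok = out[out["flag"] == ""]
        if len(ok):
            mwu_ps.append(float(ok["mwu_p"].iloc[
                int(rng.integers(len(ok)))]))
        cov = pd.Series(rng.normal(0, 1, n_records), index=gene_ids)
        cov_ps.append(covariate_regression(rec, cov)["p"])
    return {
        "mwu_uniformity_p": float(stats.kstest(mwu_ps, "uniform").pvalue),
        "covariate_uniformity_p": float(
            stats.kstest(cov_ps, "uniform").pvalue),
        "n_sims": n_sims,
    }


def de_null_calibration(seed: int, n_reps: int = 5, n_genes: int = 2000,
                        n_genotypes: int = 6, reps: int = 3,
                        dispersion: float = 0.05) -> dict:
    """Type-I error of the moderated test on null negative-binomial data."""
    rng = np.random.default_rng(seed)
    fracs, discoveries = [], []
    for _ in range(n_reps):
        mu = rng.lognormal(5, 1.2, n_genes)
        cols, genos = [], []
        for g in range(n_genotypes):
            for r in range(reps):
                lam = rng.gamma(1 / dispersion, mu * dispersion)
                cols.append(rng.poisson(lam))
                genos.append(f"g{g}")
        counts = pd.DataFrame(np.array(cols).T,
                              index=[f"G{i}" for i in range(n_genes)],
                              columns=[f"s{i}" for i in range(len(cols))])
        samples = pd.DataFrame({
            "sample_id": counts.columns, "genotype": genos,
            "sex": "female", "background": "iso",
            "replicate": [i % reps + 1 for i in range(len(cols))]})
        res = fit_moderated_de(counts, samples, "g0", "female", "iso")
        fracs.append(float((res["p"] < 0.05).mean()))
        discoveries.append(int((res["adj_p"] < 0.05).sum()))
    return {"type1_rate": float(np.mean(fracs)),
            "bh_discoveries_per_rep": float(np.mean(discoveries)),
            "n_tests": n_reps * n_genes}


def propagation_recovery(bundle, counts, samples, cfg,
                         sex: str = "male",
                         background: str = "isogenic") -> pd.DataFrame:
    """Per-degree slope of measured neighbour change on true source change;
    unbiased recovery of alpha**k (true regressor avoids attenuation)."""
    gene_counts = counts.loc[gene_rows(counts)]
    de = fit_all_genotypes(gene_counts, samples,
                           strata=[(sex, background)])
    copies = assign_copy_number(bundle.genes, bundle.dfs)
    dose = bundle.truth.effects.query("cause == 'dose'")
    true_src = {(r.gene_id, r.df_id): r.base_lfc
                for r in dose.itertuples()}
    if sex == "female":
        true_src = {(r.gene_id, r.df_id): r.base_lfc + r.female_boost_lfc
                    for r in dose.itertuples()}
    out = propagation_correlation(de, bundle.network, copies,
                                  source_values=true_src,
                                  aggregate_sources=True)
    out["alpha_k"] = [cfg.propagation_alpha**k for k in out["degree"]]
    return out


def repressive_domain_contrast(results) -> pd.DataFrame:
    """Female vs male repressive-domain effects: per-state median R,
    Mann-Whitney p against the complement, and the median shift relative to
    the stratum-wide one-copy median."""
    rec = results.records
    one = rec[(rec["copy"] == "1") & ~rec["excluded"]]
    overall = one.groupby(["sex", "background"])["R"].median()
    frames = []
    for source, state in (("lad", "LamB"), ("hic_state", "Rep")):
        t = results.domain_tests(source)
        t = t[t["state"] == state].copy()
        t["stratum_median_R"] = [
            overall.loc[(r.sex, r.background)] for r in t.itertuples()]
        t["median_shift"] = t["median_R"] - t["stratum_median_R"]
        frames.append(t)
    return pd.concat(frames, ignore_index=True)


def breakpoint_distance_slope(results) -> dict:
    """OLS of two-copy relative expression on gene-rank offset from the
    breakpoint; under no cis effect the confidence interval covers zero."""
    prof = results.breakpoint_profile(max_offset=50)
    two = prof[(prof["copy"] == "2") & np.isfinite(prof["R"])]
    reg = stats.linregress(two["offset"], two["R"])
    return {"slope": float(reg.slope), "stderr": float(reg.stderr),
            "p": float(reg.pvalue), "n": len(two)}
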