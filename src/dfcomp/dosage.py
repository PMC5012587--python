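"""Per-gene dosage-response estimation against a pooled two-copy reference.

The central statistic: for a gene made hemizygous by a deletion genotype, its
one-copy expression is compared with the same gene's two-copy expression in
all other genotypes of the same sex and genetic background.  On the log2
scale,

    R = median one-copy log2 expression - median two-copy reference log2,

so R = -1 means expression exactly halved (no compensation) and R = 0 means
unchanged (full compensation).  The compensation factor C = 2**(R + 1) maps
this to fold units (1 = none, 2 = full).  Summaries (mean fold, Pearson's
second skewness coefficient, kurtosis, Mann-Whitney and Kolmogorov-Smirnov
tests against the halved two-copy null), sex concordance, covariate
regressions, shared-covariance EM clustering across backgrounds and sex-bias
enrichment all operate on these records.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .mixture import GaussianMixtureEEE

LOG_EPS = 2.0**-10  # floor for log2 expression of zero-FPKM observations


def assign_copy_number(genes: pd.DataFrame, panel: pd.DataFrame) -> pd.DataFrame:
    """Copy state of every (gene, deletion genotype) pair.

    A gene is one-copy iff its interval is fully contained in the genotype's
    deletion, ``broken`` iff it overlaps a breakpoint (partial overlap), and
    two-copy otherwise.  Returns a long table of the non-two-copy pairs
    (columns gene_id, df_id, state); genes/genotypes absent from the table
    are two-copy, including genes on chromosomes without deletions.
    """
    rows = []
    for chrom, pgrp in panel.groupby("chrom"):
        sub = genes[genes["chrom"] == chrom]
        gs = sub["start"].to_numpy()
        ge = sub["end"].to_numpy()
        gid = sub["gene_id"].to_numpy()
        for _, d in pgrp.iterrows():
            overlap = (gs < d["end"]) & (ge > d["start"])
            contained = (gs >= d["start"]) & (ge <= d["end"])
            for g in gid[contained]:
                rows.append((g, d["df_id"], "1"))
            for g in gid[overlap & ~contained]:
                rows.append((g, d["df_id"], "broken"))
    return pd.DataFrame(rows, columns=["gene_id", "df_id", "state"])


def _affected_matrix(gene_index: pd.Index, copies: pd.DataFrame,
                     genotypes: list) -> pd.DataFrame:
    """Boolean genes x genotypes matrix of non-two-copy states."""
    aff = pd.DataFrame(False, index=gene_index, columns=genotypes)
    sub = copies[copies["gene_id"].isin(gene_index)
                 & copies["df_id"].isin(genotypes)]
    for _, r in sub.iterrows():
        aff.at[r["gene_id"], r["df_id"]] = True
    return aff


def relative_expression(fpkm: pd.DataFrame, samples: pd.DataFrame,
                        copies: pd.DataFrame, cutoffs: dict | None = None,
                        include_two_copy: bool = True,
                        ref_exclusions: pd.DataFrame | None = None
                        ) -> pd.DataFrame:
    """Relative expression records against the pooled two-copy reference.

    For each stratum (sex x background) and each gene: every genotype's
    expression is summarized as the median log2 FPKM over its replicates,
    and the reference is the median of these genotype summaries over all
    genotypes that carry the gene at two copies.  Using the same
    median-over-replicates transform on both sides keeps the comparison
    unbiased under overdispersed counts (the log of a noisy count is biased
    low by the same amount in both terms).  One-copy records get
    R = one-copy genotype median - reference; two-copy records
    (``include_two_copy``) get the genotype median minus the same reference
    and form the comparison distribution for summaries.

    ``ref_exclusions`` (columns gene_id, df_id) removes additional
    genotypes from a gene's reference — e.g. genotypes whose deletion lies
    within the propagation range of the gene in the interaction network, so
    that secondary (trans) perturbations do not depress the reference.

    Records are flagged ``excluded`` when the gene has no two-copy reference
    genotype or its reference median FPKM is at or below the background's
    expression cutoff; broken genes never appear (they are handled by the
    breakpoint analyses).
    """
    fpkm = fpkm.loc[[g for g in fpkm.index
                     if not str(g).startswith("INTERGENIC-")]]
    logf = np.log2(np.maximum(fpkm.to_numpy(dtype=float), LOG_EPS))
    raw = fpkm.to_numpy(dtype=float)
    gene_index = fpkm.index
    state_map = {(r.gene_id, r.df_id): r.state
                 for r in copies.itertuples() if r.gene_id in set(gene_index)}
    records = []
    for (sex, bg), grp in samples.groupby(["sex", "background"], sort=False):
        cols = [c for c in grp["sample_id"] if c in fpkm.columns]
        if not cols:
            continue
        col_idx = [fpkm.columns.get_loc(c) for c in cols]
        sub = logf[:, col_idx]
        col_geno = grp.set_index("sample_id").loc[cols, "genotype"].to_numpy()
        genotypes = list(dict.fromkeys(col_geno))
        aff = _affected_matrix(gene_index, copies, genotypes)
        if ref_exclusions is not None and len(ref_exclusions):
            excl = aff.copy()
            sub_x = ref_exclusions[
                ref_exclusions["gene_id"].isin(gene_index)
                & ref_exclusions["df_id"].isin(genotypes)]
            for r in sub_x.itertuples():
                excl.at[r.gene_id, r.df_id] = True
        else:
            excl = aff

        # genotype-level medians (genes x genotypes)
        geno_med = np.empty((len(gene_index), len(genotypes)))
        geno_fpkm_med = np.empty_like(geno_med)
        for j, g in enumerate(genotypes):
            jj = np.where(col_geno == g)[0]
            geno_med[:, j] = np.median(sub[:, jj], axis=1)
            geno_fpkm_med[:, j] = np.median(raw[:, col_idx][:, jj], axis=1)

        ref_mask = excl[genotypes].to_numpy()
        masked = np.ma.masked_array(geno_med, mask=ref_mask)
        ref_med = np.ma.median(masked, axis=1).filled(np.nan)
        n_ref = (~ref_mask).sum(axis=1)
        ref_fpkm_med = np.ma.median(
            np.ma.masked_array(geno_fpkm_med, mask=ref_mask),
            axis=1).filled(np.nan)
        cutoff = (cutoffs or {}).get(bg, 0.0)
        below = ref_fpkm_med <= cutoff

        gene_pos = {g: i for i, g in enumerate(gene_index)}
        for j, g in enumerate(genotypes):
            med = geno_med[:, j]
            for gene in gene_index:
                st = state_map.get((gene, g))
                i = gene_pos[gene]
                if st == "broken":
                    continue
                copy = "1" if st == "1" else "2"
                if copy == "2" and not include_two_copy:
                    continue
                excluded = False
                reason = ""
                if n_ref[i] == 0 or not np.isfinite(ref_med[i]):
                    excluded, reason = True, "no_reference"
                elif below[i]:
                    excluded, reason = True, "below_cutoff"
                r = med[i] - ref_med[i] if not excluded else np.nan
                if copy == "1" or (include_two_copy and not excluded):
                    records.append((gene, g, sex, bg, copy, r,
                                    2.0**(r + 1) if np.isfinite(r) else np.nan,
                                    int(n_ref[i]), excluded, reason))
    out = pd.DataFrame(records, columns=[
        "gene_id", "genotype", "sex", "background", "copy", "R", "C",
        "n_ref_samples", "excluded", "reason"])
    return out


def network_reference_exclusions(network, copies: pd.DataFrame,
                                 max_degree: int = 3) -> pd.DataFrame:
    """(gene, genotype) pairs to drop from reference pools: genes within
    ``max_degree`` network hops of a genotype's one-copy genes, whose
    expression may carry propagated secondary effects of that deletion."""
    from .network import neighbor_shells

    one = copies[copies["state"] == "1"]
    rows = []
    for df_id, grp in one.groupby("df_id"):
        sources = [g for g in grp["gene_id"] if g in network]
        if not sources:
            continue
        sa = neighbor_shells(network, sources, max_degree=max_degree)
        for members in sa.shells.values():
            rows.extend((g, df_id) for g in members)
    return pd.DataFrame(rows, columns=["gene_id", "df_id"])


@dataclass
class SummaryStats:
    """Distributional summary of one-copy relative expression."""

    n_one: int
    n_two: int
    mean_R: float
    mean_fold: float            # 2**(mean(R) + 1)
    arith_mean_fold: float      # arithmetic mean of per-record C
    median_R: float
    skewness_p2: float          # Pearson's second coefficient, 3(mean-med)/sd
    kurtosis: float             # fourth standardized moment (normal = 3)
    mwu_p: float
    ks_D: float
    ks_p: float

    def as_series(self) -> pd.Series:
        return pd.Series(self.__dict__)


def compensation_summary(records: pd.DataFrame,
                         two_copy_records: pd.DataFrame | None = None
                         ) -> SummaryStats:
    """Summary statistics of the one-copy relative-expression distribution.

    ``records`` may contain both copy classes (two-copy rows are split out)
    or only one-copy rows with the two-copy distribution supplied separately.
    The KS statistic D compares the one-copy distribution with the two-copy
    distribution shifted by -1 log2, i.e. the no-compensation null.
    """
    rec = records[~records["excluded"]]
    if two_copy_records is None:
        two = rec[rec["copy"] == "2"]
        one = rec[rec["copy"] == "1"]
    else:
        one = rec[rec["copy"] == "1"] if "copy" in rec else rec
        two = two_copy_records[~two_copy_records["excluded"]]
    r1 = one["R"].dropna().to_numpy()
    r2 = two["R"].dropna().to_numpy()
    if len(np.unique(r1)) < 2:
        raise ValueError("need >=2 distinct one-copy values")
    if len(r1) < 30:
        warnings.warn("fewer than 30 one-copy records; summary is unstable")
    sd = r1.std(ddof=1)
    mean, median = float(r1.mean()), float(np.median(r1))
    skew = 3.0 * (mean - median) / sd if sd > 0 else np.nan
    kurt = float(stats.kurtosis(r1, fisher=False))
    if len(r2):
        mwu = stats.mannwhitneyu(r1, r2, alternative="two-sided")
        ks = stats.ks_2samp(r1, r2 - 1.0)
        mwu_p, ks_d, ks_p = float(mwu.pvalue), float(ks.statistic), float(
            ks.pvalue)
    else:
        mwu_p = ks_d = ks_p = np.nan
    return SummaryStats(
        n_one=len(r1), n_two=len(r2), mean_R=mean,
        mean_fold=float(2.0**(mean + 1.0)),
        arith_mean_fold=float(np.mean(2.0**(r1 + 1.0))),
        median_R=median, skewness_p2=float(skew), kurtosis=kurt,
        mwu_p=mwu_p, ks_D=ks_d, ks_p=ks_p)


def sex_concordance(records: pd.DataFrame) -> dict:
    """Female/male concordance of one-copy responses from the same deletions.

    Pairs R per (gene, genotype, background) across sexes; returns Pearson r,
    the OLS slope of male on female response, and the regression F-test p.
    """
    rec = records[(records["copy"] == "1") & ~records["excluded"]]
    pivot = rec.pivot_table(index=["gene_id", "genotype", "background"],
                            columns="sex", values="R")
    pivot = pivot.dropna()
    if pivot.shape[0] < 3 or pivot.shape[1] < 2:
        raise ValueError("need >=3 (gene, genotype) pairs in both sexes")
    f = pivot["female"].to_numpy()
    m = pivot["male"].to_numpy()
    r, _ = stats.pearsonr(f, m)
    reg = stats.linregress(f, m)
    return {"r": float(r), "slope": float(reg.slope),
            "p": float(reg.pvalue), "n_pairs": len(f)}


def em_compensation_clusters(records: pd.DataFrame, sex: str = "female",
                             per_df: bool = False,
                             backgrounds: tuple[str, str] = ("isogenic",
                                                             "hybrid"),
                             random_state: int = 0) -> dict:
    """Cluster per-gene compensation across genetic backgrounds (EEE EM).

    X axis: mean one-copy R in the first background, Y axis: the second, one
    point per gene (or per (gene, genotype) when ``per_df``).  A 2-component
    shared-covariance Gaussian mixture is fitted; the component with larger
    mean R is reported as the ``better`` compensated cluster.
    """
    rec = records[(records["copy"] == "1") & ~records["excluded"]
                  & (records["sex"] == sex)]
    keys = ["gene_id", "genotype"] if per_df else ["gene_id"]
    pivot = rec.pivot_table(index=keys, columns="background", values="R")
    pivot = pivot.reindex(columns=list(backgrounds)).dropna()
    if len(pivot) < 20:
        raise ValueError("need >=20 genes present in both backgrounds")
    x = pivot.to_numpy()
    fit = GaussianMixtureEEE(n_components=2,
                             random_state=random_state).fit(x)
    better = int(np.argmax(fit.means_.sum(axis=1)))
    labels = np.where(fit.labels_ == better, "better", "modest")
    out = pivot.reset_index()
    out["cluster"] = labels
    out["posterior_better"] = fit.resp_[:, better]
    return {"assignments": out, "fit": fit, "better_component": better}


def sex_bias_enrichment(cluster_genes, bias_labels: pd.Series,
                        background_sets: dict) -> pd.DataFrame:
    """Hypergeometric enrichment of sex-biased genes in a cluster.

    For each background set and each bias class (male / female), tests
    over-representation (upper tail, P[X >= k]) and under-representation
    (lower tail, P[X <= k]) of the class within the cluster drawn from the
    background set.
    """
    cluster = set(cluster_genes)
    rows = []
    for name, bg in background_sets.items():
        bg = set(bg)
        if not cluster <= bg:
            raise ValueError(f"cluster is not a subset of background {name!r}")
        m = len(bg)
        n_draw = len(cluster)
        for klass in ("male", "female"):
            biased = {g for g in bg if bias_labels.get(g) == klass}
            big_k = len(biased)
            k = len(cluster & biased)
            upper = float(stats.hypergeom.sf(k - 1, m, big_k, n_draw))
            lower = float(stats.hypergeom.cdf(k, m, big_k, n_draw))
            rows.append((name, klass, k, n_draw, big_k, m,
                         k / n_draw if n_draw else np.nan,
                         big_k / m if m else np.nan, upper, lower))
    return pd.DataFrame(rows, columns=[
        "background_set", "bias_class", "k_in_cluster", "cluster_size",
        "k_in_background", "background_size", "prop_cluster",
        "prop_background", "p_upper", "p_lower"])


def specificity_scores(profile) -> dict:
    """Tissue-specificity indices tau and TSPS for one expression profile.

    tau = sum(1 - x_i / max(x)) / (N - 1); TSPS = sum p_i log2(p_i N) with
    p_i = x_i / sum(x) (relative entropy against the uniform profile).  Both
    are 0 for a uniform profile; a profile expressed in a single tissue has
    tau = 1 and TSPS = log2(N).  All-zero profiles are undefined (NaN,
    flagged).
    """
    x = np.asarray(profile, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("profile must be 1-D with >=2 tissues")
    if (x < 0).any():
        raise ValueError("profile must be non-negative")
    if x.sum() == 0:
        return {"tau": np.nan, "tsps": np.nan, "flag": "all_zero"}
    n = len(x)
    tau = float(np.sum(1.0 - x / x.max()) / (n - 1))
    p = x / x.sum()
    nz = p > 0
    tsps = float(np.sum(p[nz] * np.log2(p[nz] * n)))
    return {"tau": tau, "tsps": tsps, "flag": ""}


def covariate_regression(records: pd.DataFrame, covariate: pd.Series,
                         on: str = "gene_id") -> dict:
    """Relationship between dosage response R and a per-gene covariate.

    Continuous covariates (e.g. median expression, tau, TSPS, deletion
    length): OLS of R on the covariate with the F-test p (equivalent to the
    slope t-test in simple regression).  Binary labels (e.g. housekeeping):
    Mann-Whitney U between the two groups.
    """
    rec = records[(records.get("copy", "1") == "1") & ~records["excluded"]]
    vals = rec[on].map(covariate) if on else covariate
    r = rec["R"].to_numpy()
    v = np.asarray(vals)
    if v.dtype == object or isinstance(v[0] if len(v) else 0, str):
        labels = pd.Series(v)
        ok = labels.notna() & np.isfinite(r)
        labels, rr = labels[ok.to_numpy()], r[ok.to_numpy()]
        groups = labels.unique()
        if len(groups) != 2:
            raise ValueError("binary covariate must have exactly 2 levels")
        a = rr[(labels == groups[0]).to_numpy()]
        b = rr[(labels == groups[1]).to_numpy()]
        mwu = stats.mannwhitneyu(a, b, alternative="two-sided")
        return {"kind": "binary", "groups": list(groups),
                "median_diff": float(np.median(a) - np.median(b)),
                "p": float(mwu.pvalue), "n": len(rr)}
    v = v.astype(float)
    ok = np.isfinite(v) & np.isfinite(r)
    v, r = v[ok], r[ok]
    if len(v) < 3:
        raise ValueError("need >=3 finite records")
    if len(v) < 10:
        warnings.warn("fewer than 10 finite records for covariate regression")
    if np.ptp(v) == 0:
        raise ValueError("constant covariate")
    reg = stats.linregress(v, r)
    return {"kind": "continuous", "slope": float(reg.slope),
            "intercept": float(reg.intercept), "r": float(reg.rvalue),
            "p": float(reg.pvalue), "stderr": float(reg.stderr), "n": len(v)}
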