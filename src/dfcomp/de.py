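"""Precision-weighted, empirical-Bayes-moderated differential expression.

Implements the voom/limma contract from first principles for the two-group
contrast used throughout the panel analysis: each genotype's replicates are
compared against all other genotypes of the same sex and genetic background
("rest-of-dataset" reference).

Pipeline per contrast:

1. log2-CPM with TMM effective library sizes and a 0.5 pseudo-count;
2. gene-wise ordinary least squares on the two-group design;
3. lowess trend of sqrt(residual SD) against mean log2 count, giving
   per-observation precision weights 1 / trend(fitted log-count)**4;
4. weighted least squares with those weights;
5. empirical-Bayes variance moderation: gene-wise variances are shrunk toward
   a prior variance with prior degrees of freedom, both estimated by matching
   moments of log sample variances to a scaled F distribution;
6. moderated t statistics on the augmented degrees of freedom;
7. Benjamini-Hochberg adjustment within the contrast family.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment with monotonicity enforcement.

    Order-preserving; NaNs propagate and are excluded from the ranking.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if mask.any():
        if (p[mask] < 0).any() or (p[mask] > 1).any():
            raise ValueError("p-values must lie in [0, 1]")
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def fit_f_dist(variances: np.ndarray, df1: float) -> tuple[float, float]:
    """Moment estimation of the scale and df of a scaled F distribution.

    Models sample variances s^2 ~ s0^2 * F(df1, df0) and returns
    ``(s0^2, df0)``; df0 may be infinite when the variances are more
    concordant than the sampling distribution alone allows.
    """
    x = np.asarray(variances, dtype=float)
    x = x[np.isfinite(x) & (x > 0)]
    if len(x) < 2:
        return float(np.median(x)) if len(x) else 1.0, np.inf
    z = np.log(x)
    e = z - special.digamma(df1 / 2.0) + np.log(df1 / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, df1 / 2.0)
    if evar > 0:
        df0 = 2.0 * trigamma_inverse(evar)
        s0 = np.exp(emean + special.digamma(df0 / 2.0) - np.log(df0 / 2.0))
    else:
        df0 = np.inf
        s0 = np.exp(emean)
    return float(s0), float(df0)


def squeeze_var(variances: np.ndarray, df: float) -> dict:
    """Empirical-Bayes shrinkage of gene-wise variances toward the prior.

    Posterior variance = (df0 * s0^2 + df * s^2) / (df0 + df), a convex
    combination of the prior and the observed variance.
    """
    s0, df0 = fit_f_dist(variances, df)
    if np.isinf(df0):
        post = np.full_like(variances, s0)
    else:
        post = (df0 * s0 + df * variances) / (df0 + df)
    return {"var_post": post, "var_prior": s0, "df_prior": df0}


def _log_cpm(counts: np.ndarray, eff_lib: np.ndarray) -> np.ndarray:
    return np.log2((counts + 0.5) / (eff_lib + 1.0) * 1e6)


def voom_weights(counts: np.ndarray, eff_lib: np.ndarray, design: np.ndarray,
                 span: float = 0.5):
    """Mean-variance trend and per-observation precision weights.

    Returns (logcpm, weights, trend_xy).  The trend regresses the square root
    of the residual standard deviation from a gene-wise OLS fit on the average
    log2 count, and observation weights are the inverse fourth power of the
    trend evaluated at each observation's fitted log2 count.
    """
    y = _log_cpm(counts, eff_lib)
    n, p = design.shape
    beta, resid_var = _ols(y, design)
    sigma = np.sqrt(resid_var)
    amean = y.mean(axis=1)
    sx = amean + np.mean(np.log2(eff_lib + 1.0)) - np.log2(1e6)
    sy = np.sqrt(sigma)
    ok = np.isfinite(sy) & (sigma > 0)
    trend = lowess(sy[ok], sx[ok], frac=span, it=3, return_sorted=True)
    tx, ty = trend[:, 0], trend[:, 1]
    # per-observation fitted log2 count
    fitted = beta @ design.T
    fitted_count = fitted + np.log2(eff_lib + 1.0)[None, :] - np.log2(1e6)
    w = np.interp(fitted_count, tx, ty, left=ty[0], right=ty[-1])
    w = 1.0 / np.clip(w, 1e-6, None) ** 4
    return y, w, (tx, ty)


def _ols(y: np.ndarray, design: np.ndarray):
    """Gene-wise OLS of y (genes x samples) on a common design."""
    n, p = design.shape
    xtx_inv = np.linalg.inv(design.T @ design)
    beta = y @ design @ xtx_inv
    resid = y - beta @ design.T
    var = (resid**2).sum(axis=1) / (n - p)
    return beta, var


def _wls(y: np.ndarray, w: np.ndarray, design: np.ndarray):
    """Gene-wise weighted least squares with per-observation weights."""
    n, p = design.shape
    xw = np.einsum("gn,np->gnp", w, design)
    xtwx = np.einsum("gnp,nq->gpq", xw, design)
    xtwy = np.einsum("gnp,gn->gp", xw, y)
    xtwx_inv = np.linalg.inv(xtwx)
    beta = np.einsum("gpq,gq->gp", xtwx_inv, xtwy)
    resid = y - beta @ design.T
    var = np.einsum("gn,gn->g", w * resid, resid) / (n - p)
    unscaled = np.sqrt(xtwx_inv[:, 1, 1])
    return beta, var, unscaled


def fit_moderated_de(counts: pd.DataFrame, samples: pd.DataFrame,
                     target_genotype: str, sex: str, background: str,
                     norm_factors: pd.DataFrame | None = None,
                     reference: str = "rest", span: float = 0.5,
                     wt_label: str = "wt") -> pd.DataFrame:
    """Moderated two-group DE of one genotype against the rest of its stratum.

    ``reference='rest'`` pools all other genotypes of the same sex and
    background (the screen-wide convention); ``reference='wildtype'`` uses
    only wild-type samples.  Returns a per-gene table with ``log2fc``,
    moderated ``t``, raw ``p``, BH-``adj_p`` and a ``flag`` column
    (``zero_variance`` genes get NaN statistics).
    """
    from .normalize import tmm_factors

    stratum = samples[(samples["sex"] == sex)
                      & (samples["background"] == background)]
    tgt = stratum[stratum["genotype"] == target_genotype]
    if len(tgt) < 2:
        raise ValueError(
            f"genotype {target_genotype} has <2 samples in {sex}/{background}")
    if reference == "rest":
        rest = stratum[stratum["genotype"] != target_genotype]
    elif reference == "wildtype":
        rest = stratum[stratum["genotype"] == wt_label]
    else:
        raise ValueError(f"unknown reference {reference!r}")
    if rest["genotype"].nunique() < (2 if reference == "rest" else 1):
        raise ValueError("reference group requires >=2 other genotypes")

    ids = pd.concat([tgt, rest])["sample_id"].tolist()
    sub = counts[ids]
    if norm_factors is None:
        norm_factors = tmm_factors(sub)
    eff_lib = norm_factors["effective_lib_size"].reindex(ids).to_numpy()
    group = np.array([1.0] * len(tgt) + [0.0] * len(rest))
    design = np.column_stack([np.ones(len(ids)), group])

    x = sub.to_numpy(dtype=float)
    y, w, _ = voom_weights(x, eff_lib, design, span=span)
    beta, var, unscaled = _wls(y, w, design)
    df_resid = len(ids) - 2

    flag = np.where(var <= 0, "zero_variance", "")
    ok = var > 0
    sq = squeeze_var(var[ok], df_resid)
    var_post = np.full(len(var), np.nan)
    var_post[ok] = sq["var_post"]
    df_total = df_resid + sq["df_prior"]
    t = np.full(len(var), np.nan)
    p = np.full(len(var), np.nan)
    t[ok] = beta[ok, 1] / (unscaled[ok] * np.sqrt(var_post[ok]))
    if np.isinf(df_total):
        p[ok] = 2.0 * stats.norm.sf(np.abs(t[ok]))
    else:
        p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df_total)

    out = pd.DataFrame({
        "gene_id": sub.index,
        "genotype": target_genotype,
        "sex": sex,
        "background": background,
        "log2fc": beta[:, 1],
        "t": t,
        "p": p,
        "adj_p": bh_adjust(p),
        "flag": flag,
    })
    out.attrs["df_prior"] = sq["df_prior"]
    out.attrs["var_prior"] = sq["var_prior"]
    return out


def fit_all_genotypes(counts: pd.DataFrame, samples: pd.DataFrame,
                      genotypes=None, strata=None,
                      norm_factors: pd.DataFrame | None = None,
                      wt_label: str = "wt", **kwargs) -> pd.DataFrame:
    """Moderated DE for every (genotype, sex, background) combination.

    Library factors are estimated once on the full matrix and reused across
    contrasts.  Returns the concatenated per-contrast tables.
    """
    from .normalize import tmm_factors

    if norm_factors is None:
        norm_factors = tmm_factors(counts[samples["sample_id"]])
    if strata is None:
        strata = [(s, b)
                  for b in samples["background"].unique()
                  for s in samples["sex"].unique()]
    results = []
    for sex, background in strata:
        stratum = samples[(samples["sex"] == sex)
                          & (samples["background"] == background)]
        gts = genotypes
        if gts is None:
            gts = [g for g in stratum["genotype"].unique() if g != wt_label]
        for g in gts:
            results.append(
                fit_moderated_de(counts, samples, g, sex, background,
                                 norm_factors=norm_factors,
                                 wt_label=wt_label, **kwargs))
    return pd.concat(results, ignore_index=True)
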