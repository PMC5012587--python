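"""Normalization and library QC.

FPKM with the spike-in denominator convention (spike-in reads may be counted
in the per-library total so that gene FPKM and spike-in FPKM share a scale),
trimmed-mean-of-M-values (TMM) between-sample scaling, intergenic-based
expression cutoffs, low-count gene filtering, replicate-correlation QC and
spike-in ratiometric QC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def compute_fpkm(counts: pd.DataFrame, lengths: pd.Series,
                 spikes: pd.DataFrame | None = None,
                 include_spikeins_in_denominator: bool = False,
                 totals: pd.Series | None = None) -> pd.DataFrame:
    """Fragments per kilobase per million mapped fragments.

    ``FPKM = count / (length_kb * mapped_millions)``.  When
    ``include_spikeins_in_denominator`` is set, per-library totals include
    spike-in counts as well as gene counts, so that spike-in-derived detection
    limits are on the same scale as gene expression.  ``totals`` overrides the
    per-library denominator entirely (e.g. TMM effective library sizes).
    """
    lengths = lengths.reindex(counts.index)
    if (lengths <= 0).any() or lengths.isna().any():
        bad = lengths.index[(lengths <= 0) | lengths.isna()]
        raise ValueError(f"non-positive or missing length for {list(bad[:5])}")
    if totals is not None:
        totals = totals.reindex(counts.columns).astype(float)
    else:
        totals = counts.sum(axis=0).astype(float)
        if spikes is not None and include_spikeins_in_denominator:
            totals = totals + spikes[counts.columns].sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"sample(s) with zero total counts: {list(zero.index)}")
    fpkm = counts.div(lengths / 1e3, axis=0).div(totals / 1e6, axis=1)
    return fpkm


def _tmm_pair(obs: np.ndarray, ref: np.ndarray, lib_obs: float, lib_ref: float,
              trim_m: float, trim_a: float) -> float:
    """TMM factor of one library against the reference (log2 scale -> 2**f).

    Doubly-expressed genes only; trim the tails of M (log count ratio) and A
    (mean log count); precision weights from the delta-method binomial
    variance of M.  M is taken on raw counts, so the factor absorbs relative
    sequencing depth as well as composition bias; the composition-only factor
    of the usual effective-library-size convention is recovered as
    ``factor * geomean(lib) / lib``.
    """
    both = (obs > 0) & (ref > 0)
    if not both.any():
        raise ValueError("no genes expressed in both library and reference")
    o = obs[both]
    r = ref[both]
    m = np.log2(o / r)
    a = 0.5 * np.log2(o * r)
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    w = ((lib_obs - obs[both]) / (lib_obs * obs[both])
         + (lib_ref - ref[both]) / (lib_ref * ref[both]))
    n = len(m)
    lo_l = np.floor(n * trim_m) + 1
    hi_l = n + 1 - lo_l
    lo_s = np.floor(n * trim_a) + 1
    hi_s = n + 1 - lo_s
    rank_m = stats.rankdata(m)
    rank_a = stats.rankdata(a)
    keep = ((rank_m >= lo_l) & (rank_m <= hi_l)
            & (rank_a >= lo_s) & (rank_a <= hi_s))
    if not keep.any():
        return 1.0
    f = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
    if not np.isfinite(f) or abs(f) < 1e-10:
        f = 0.0
    return float(2.0**f)


def tmm_factors(counts: pd.DataFrame, trim_m: float = 0.3,
                trim_a: float = 0.05) -> pd.DataFrame:
    """Per-sample TMM scaling factors, normalized to geometric mean 1.

    The reference sample is the one whose 75th-percentile relative abundance
    is closest to the mean across samples.  Returns a table with columns
    ``factor``, ``lib_size`` and ``effective_lib_size``.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM requires at least 2 samples")
    x = counts.to_numpy(dtype=float)
    lib = x.sum(axis=0)
    if (lib == 0).any():
        raise ValueError("sample with zero total counts")
    f75 = np.array([np.quantile(x[:, j] / lib[j], 0.75)
                    for j in range(x.shape[1])])
    ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    factors = np.array([
        _tmm_pair(x[:, j], x[:, ref_idx], lib[j], lib[ref_idx], trim_m, trim_a)
        for j in range(x.shape[1])
    ])
    factors /= np.exp(np.mean(np.log(factors)))
    geomean_lib = np.exp(np.mean(np.log(lib)))
    return pd.DataFrame({
        "factor": factors,
        "lib_size": lib,
        "effective_lib_size": geomean_lib * factors,
    }, index=counts.columns)


def intergenic_cutoff(fpkm: pd.DataFrame, intergenic_ids,
                      samples: pd.DataFrame | None = None,
                      percentile: float = 0.95,
                      method: str = "quantile") -> dict:
    """Expression cutoff from intergenic background signal, per background.

    Pools intergenic FPKM over all samples of each genetic background and
    returns the ``percentile`` quantile (linear interpolation).  With
    ``method='median_above'`` the median of the values above that quantile is
    returned instead.  Genes at or below the cutoff are treated as unexpressed
    downstream.
    """
    ids = [i for i in intergenic_ids if i in fpkm.index]
    if not ids:
        raise ValueError("empty intergenic set")
    sub = fpkm.loc[ids]
    if samples is None:
        groups = {"all": list(fpkm.columns)}
    else:
        groups = {bg: grp["sample_id"].tolist()
                  for bg, grp in samples.groupby("background")}
    cutoffs = {}
    for bg, cols in groups.items():
        vals = sub[cols].to_numpy().ravel()
        q = float(np.quantile(vals, percentile))
        if method == "median_above":
            above = vals[vals > q]
            q = float(np.median(above)) if len(above) else q
        cutoffs[bg] = q
    return cutoffs


def filter_genes(counts: pd.DataFrame, fpkm: pd.DataFrame | None = None,
                 cutoffs: dict | None = None,
                 samples: pd.DataFrame | None = None,
                 min_reads: int = 1, max_zero_fraction: float = 0.5
                 ) -> pd.Series:
    """Boolean retention mask over genes.

    Drops genes with fewer than ``min_reads`` reads in more than
    ``max_zero_fraction`` of samples (strictly more, so a gene at exactly the
    boundary is retained).  If ``fpkm``/``cutoffs`` are given, additionally
    drops genes whose median FPKM is at or below the background cutoff in
    every background.
    """
    low = (counts < min_reads).sum(axis=1) / counts.shape[1]
    keep = low <= max_zero_fraction
    if fpkm is not None and cutoffs is not None:
        expressed = pd.Series(False, index=counts.index)
        if samples is None:
            cut = max(cutoffs.values())
            expressed |= fpkm.median(axis=1) > cut
        else:
            for bg, grp in samples.groupby("background"):
                cut = cutoffs.get(bg, max(cutoffs.values()))
                med = fpkm[grp["sample_id"]].median(axis=1)
                expressed |= med > cut
        keep &= expressed
    if not keep.any():
        warnings.warn("gene filter removed every gene")
    return keep


@dataclass
class QCReport:
    retained: list
    report: pd.DataFrame


def replicate_qc(fpkm: pd.DataFrame, samples: pd.DataFrame,
                 r_min: float = 0.9) -> QCReport:
    """Replicate-correlation QC.

    Pearson r of log2(FPKM + 1) between replicates of each (genotype, sex,
    background) group.  Groups whose best pair falls below ``r_min`` are
    excluded with a warning; groups with more than two passing replicates are
    reduced to the best-correlated pair.  Idempotent on its own output.
    """
    logf = np.log2(fpkm + 1.0)
    retained: list = []
    rows = []
    for key, grp in samples.groupby(["genotype", "sex", "background"],
                                    sort=False):
        ids = grp["sample_id"].tolist()
        if len(ids) < 2:
            rows.append((*key, None, None, np.nan, "excluded_single"))
            warnings.warn(f"group {key} has <2 replicates; excluded")
            continue
        best_r, best_pair = -np.inf, None
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                r = float(np.corrcoef(logf[ids[i]], logf[ids[j]])[0, 1])
                if r > best_r:
                    best_r, best_pair = r, (ids[i], ids[j])
        if best_r < r_min:
            rows.append((*key, *best_pair, best_r, "excluded_low_r"))
            warnings.warn(f"group {key} best replicate r={best_r:.3f} < "
                          f"{r_min}; excluded")
            continue
        retained.extend(best_pair)
        rows.append((*key, *best_pair, best_r, "pass"))
    report = pd.DataFrame(rows, columns=["genotype", "sex", "background",
                                         "sample_a", "sample_b", "r",
                                         "status"])
    return QCReport(retained=retained, report=report)


def spikein_ratio_qc(spikes: pd.DataFrame, samples: pd.DataFrame,
                     pseudocount: float = 0.5) -> dict:
    """Ratiometric spike-in QC between paired libraries.

    Libraries within a (genotype, sex, background) group received alternating
    spike mixes (odd replicates mix A, even replicates mix B); for each spike
    and each A/B pair the observed log2 ratio of spike-normalized counts is
    compared with the subpool's expected ratio (0, +log2 1.5 or -log2 1.5).
    Returns per-spike observations, a per-pool summary, and the compression
    slope (regression of observed - expected on log2 mean abundance; ~0 means
    no ratio compression).
    """
    sample_cols = [c for c in samples["sample_id"] if c in spikes.columns]
    mat = spikes.set_index("spike_id")[sample_cols].astype(float)
    totals = mat.sum(axis=0)
    if (totals == 0).any():
        missing = list(totals.index[totals == 0])
        warnings.warn(f"libraries without spike-ins excluded: {missing}")
        mat = mat.drop(columns=totals.index[totals == 0])
    norm = mat.div(mat.sum(axis=0), axis=1)
    meta = samples.set_index("sample_id")
    rows = []
    pools = spikes.set_index("spike_id")["pool"]
    expected = spikes.set_index("spike_id")["expected_log2_ratio"]
    for key, grp in samples.groupby(["genotype", "sex", "background"],
                                    sort=False):
        a = [s for s in grp["sample_id"]
             if s in norm.columns and meta.at[s, "replicate"] % 2 == 1]
        b = [s for s in grp["sample_id"]
             if s in norm.columns and meta.at[s, "replicate"] % 2 == 0]
        for sa in a:
            for sb in b:
                va = norm[sa] * 1e6 + pseudocount
                vb = norm[sb] * 1e6 + pseudocount
                obs = np.log2(va / vb)
                ab = 0.5 * np.log2(va * vb)
                for sid in obs.index:
                    rows.append((sid, pools[sid], sa, sb, float(obs[sid]),
                                 float(ab[sid]), float(expected[sid])))
    table = pd.DataFrame(rows, columns=["spike_id", "pool", "lib_a", "lib_b",
                                        "observed_log2_ratio",
                                        "log2_abundance",
                                        "expected_log2_ratio"])
    if len(table) == 0:
        raise ValueError("no paired libraries with spike-ins")
    summary = (table.groupby("pool")
               .agg(mean_observed=("observed_log2_ratio", "mean"),
                    sd_observed=("observed_log2_ratio", "std"),
                    expected=("expected_log2_ratio", "first"),
                    n=("observed_log2_ratio", "size"))
               .reset_index())
    dev = table["observed_log2_ratio"] - table["expected_log2_ratio"]
    slope = stats.linregress(table["log2_abundance"], dev)
    return {"table": table, "summary": summary,
            "compression_slope": float(slope.slope),
            "compression_p": float(slope.pvalue)}
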