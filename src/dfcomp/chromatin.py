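"""Chromatin-domain stratification and breakpoint-proximity analyses.

Genes are assigned to labeled genomic domains (DamID chromatin states, Hi-C
structural states, lamina-associated domains) by the midpoint rule; one-copy
relative expression is then compared between states, two-copy genes left in
the un-deleted remnant of a "broken" domain are tested against the global
two-copy distribution, and breakpoint-centered profiles collect relative
expression by signed gene-rank offset from every deletion breakpoint (one-copy
side negative, two-copy side positive) with a sliding-window median absolute
deviation track.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats


def map_genes_to_domains(genes: pd.DataFrame, domains: pd.DataFrame,
                         rule: str = "midpoint") -> pd.DataFrame:
    """Per-gene state label for each domain source.

    ``midpoint`` (default): the gene's label is the state of the domain
    containing its midpoint.  ``any_overlap``: the state of the first domain
    the gene overlaps at all.  Genes outside every domain of a source are
    ``unassigned``.  Returns a genes x sources table indexed by gene_id.
    """
    out = pd.DataFrame(index=genes["gene_id"])
    mid = ((genes["start"] + genes["end"]) // 2).to_numpy()
    for source, sub in domains.groupby("source"):
        sub = sub.sort_values("start")
        ds = sub["start"].to_numpy()
        de = sub["end"].to_numpy()
        st = sub["state"].to_numpy()
        label = np.full(len(genes), "unassigned", dtype=object)
        if rule == "midpoint":
            idx = np.searchsorted(ds, mid, side="right") - 1
            ok = idx >= 0
            inside = np.zeros(len(genes), bool)
            inside[ok] = mid[ok] < de[idx[ok]]
            label[inside] = st[idx[inside]]
        elif rule == "any_overlap":
            gs = genes["start"].to_numpy()
            ge = genes["end"].to_numpy()
            for i in range(len(genes)):
                hits = np.where((ds < ge[i]) & (de > gs[i]))[0]
                if len(hits):
                    label[i] = st[hits[0]]
        else:
            raise ValueError(f"unknown rule {rule!r}")
        out[source] = label
    return out


def domain_stratified_tests(records: pd.DataFrame, labels: pd.DataFrame,
                            source: str, min_n: int = 5) -> pd.DataFrame:
    """Mann-Whitney tests of each domain state against all other states.

    One-copy R values, per sex and background; states with fewer than
    ``min_n`` records in a stratum are skipped with a flag.  Genes outside
    every domain of the source stay in the complement (for sparse sources
    such as LADs the natural contrast is in-domain vs not-in-domain) but are
    not themselves tested as a state.
    """
    rec = records[(records["copy"] == "1") & ~records["excluded"]].copy()
    rec["state"] = rec["gene_id"].map(labels[source])
    rec = rec[rec["state"].notna()]
    rows = []
    for (sex, bg), grp in rec.groupby(["sex", "background"], sort=False):
        for state in sorted(set(grp["state"]) - {"unassigned"}):
            inside = grp.loc[grp["state"] == state, "R"].to_numpy()
            outside = grp.loc[grp["state"] != state, "R"].to_numpy()
            if len(inside) < min_n or len(outside) < min_n:
                rows.append((source, sex, bg, state, len(inside), np.nan,
                             np.nan, np.nan, np.nan, "understaffed"))
                continue
            mwu = stats.mannwhitneyu(inside, outside,
                                     alternative="two-sided")
            q1, q3 = np.percentile(inside, [25, 75])
            rows.append((source, sex, bg, state, len(inside),
                         float(np.median(inside)), float(np.mean(inside)),
                         float(q3 - q1), float(mwu.pvalue), ""))
    return pd.DataFrame(rows, columns=[
        "source", "sex", "background", "state", "n", "median_R", "mean_R",
        "iqr", "mwu_p", "flag"])


def broken_domain_flanking(records: pd.DataFrame, domains: pd.DataFrame,
                           panel: pd.DataFrame, genes: pd.DataFrame,
                           source: str, state: str) -> dict:
    """Two-copy expression inside deletion-disrupted domains of one state.

    A domain is "broken" by a genotype when a deletion breakpoint falls
    strictly inside it; the two-copy genes of that genotype whose midpoints
    lie in the un-deleted remnant of the domain are collected and their
    relative expression compared (Mann-Whitney) with the global two-copy
    distribution.
    """
    dom = domains[(domains["source"] == source)
                  & (domains["state"] == state)]
    two = records[(records["copy"] == "2") & ~records["excluded"]]
    mid = ((genes["start"] + genes["end"]) // 2)
    gene_mid = dict(zip(genes["gene_id"], mid))
    flank_rows = []
    for _, d in panel.iterrows():
        for bp in (d["start"], d["end"]):
            hit = dom[(dom["start"] < bp) & (bp < dom["end"])]
            for _, h in hit.iterrows():
                # remnant: part of the domain not removed by the deletion
                for lo, hi in ((h["start"], max(h["start"], d["start"])),
                               (min(h["end"], d["end"]), h["end"])):
                    if hi <= lo:
                        continue
                    in_rem = two[(two["genotype"] == d["df_id"])
                                 & two["gene_id"].map(
                                     lambda g: lo <= gene_mid.get(g, -1) < hi)]
                    flank_rows.append(in_rem)
    if not flank_rows:
        warnings.warn(f"no broken {source}/{state} domains in the panel")
        return {"records": pd.DataFrame(columns=two.columns), "mwu_p": np.nan,
                "n": 0, "flag": "no_broken_domains"}
    flank = pd.concat(flank_rows).drop_duplicates(
        subset=["gene_id", "genotype", "sex", "background"])
    if len(flank) == 0:
        return {"records": flank, "mwu_p": np.nan, "n": 0,
                "flag": "no_flanking_genes"}
    mwu = stats.mannwhitneyu(flank["R"].dropna(), two["R"].dropna(),
                             alternative="two-sided")
    return {"records": flank, "mwu_p": float(mwu.pvalue), "n": len(flank),
            "flag": ""}


def breakpoint_profile(records: pd.DataFrame, panel: pd.DataFrame,
                       genes: pd.DataFrame, copies: pd.DataFrame,
                       max_offset: int | None = None,
                       proximal_bp: int = 100) -> pd.DataFrame:
    """Breakpoint-centered offset records.

    For every breakpoint of every genotype, genes are ranked by distance on
    each side: the one-copy (deleted) side takes negative offsets (-1 is the
    deleted gene nearest the breakpoint), the two-copy side positive offsets.
    Broken genes are skipped.  The bp distance from the breakpoint to the
    nearest gene edge is recorded, with a flag for promoter-proximal genes
    (within ``proximal_bp`` of the breakpoint).
    """
    gsort = genes.sort_values("start").reset_index(drop=True)
    gid = gsort["gene_id"].to_numpy()
    gs = gsort["start"].to_numpy()
    ge = gsort["end"].to_numpy()
    state_map = {(r.gene_id, r.df_id): r.state for r in copies.itertuples()}
    rec_map = {}
    for r in records.itertuples():
        rec_map.setdefault((r.gene_id, r.genotype), []).append(r)
    rows = []
    for _, d in panel.iterrows():
        df_id = d["df_id"]
        for side, bp in (("start", d["start"]), ("end", d["end"])):
            # inside-deletion genes ordered by increasing distance from bp
            inside = np.where((gs >= d["start"]) & (ge <= d["end"]))[0]
            outside = (np.where(ge <= bp)[0] if side == "start"
                       else np.where(gs >= bp)[0])
            if side == "start":
                inside = inside[np.argsort(gs[inside])]
                outside = outside[np.argsort(-ge[outside])]
            else:
                inside = inside[np.argsort(-ge[inside])]
                outside = outside[np.argsort(gs[outside])]
            for sign, order in ((-1, inside), (+1, outside)):
                rank = 0
                for i in order:
                    g = gid[i]
                    st = state_map.get((g, df_id))
                    if st == "broken":
                        continue
                    if sign > 0 and st == "1":  # other breakpoint's interior
                        continue
                    rank += 1
                    if max_offset is not None and rank > max_offset:
                        break
                    dist = int(min(abs(gs[i] - bp), abs(ge[i] - bp)))
                    for r in rec_map.get((g, df_id), ()):
                        if r.excluded:
                            continue
                        rows.append((g, df_id, f"{df_id}:{side}", r.sex,
                                     r.background, sign * rank, dist,
                                     dist <= proximal_bp, r.copy, r.R))
    return pd.DataFrame(rows, columns=[
        "gene_id", "genotype", "breakpoint", "sex", "background", "offset",
        "bp_distance", "within_100bp", "copy", "R"])


def sliding_mad(values, window: int = 30) -> pd.DataFrame:
    """Unscaled median absolute deviation in sliding windows of ``window``
    values, step 1.  Fewer values than the window yields a single truncated
    window with a flag."""
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) == 0:
        raise ValueError("no finite values")
    if len(x) < window:
        warnings.warn("fewer values than window; single truncated window")
        mad = float(np.median(np.abs(x - np.median(x))))
        return pd.DataFrame({"window_start": [0], "mad": [mad],
                             "n": [len(x)], "flag": ["truncated"]})
    mads = []
    for i in range(len(x) - window + 1):
        w = x[i:i + window]
        mads.append(float(np.median(np.abs(w - np.median(w)))))
    return pd.DataFrame({"window_start": np.arange(len(mads)), "mad": mads,
                         "n": window, "flag": ""})


def offset_mad_track(offsets: pd.DataFrame, window: int = 30) -> pd.DataFrame:
    """Sliding MAD of relative expression in breakpoint-offset order."""
    ordered = offsets.sort_values(["offset", "bp_distance"])
    track = sliding_mad(ordered["R"].to_numpy(), window=window)
    # annotate each window with the median offset of its members
    offs = ordered.loc[np.isfinite(ordered["R"]), "offset"].to_numpy()
    centers = []
    if (track["flag"] == "truncated").any():
        centers = [float(np.median(offs))]
    else:
        for i in range(len(track)):
            centers.append(float(np.median(offs[i:i + window])))
    track["offset_center"] = centers
    return track
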