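"""Synthetic Df/+ panel generator with known ground truth.

Counts are simulated directly at the gene level (no read simulation): each
sample draws negative-binomial counts around an expected expression that
combines a per-gene baseline, the gene-dose effect of the sample's deletion
genotype, a female-only boost for hemizygous genes inside repressive chromatin,
sex- and background-specific multiplicative effects, and network-propagated
secondary effects on two-copy neighbours of the deleted genes.

The dose law is multiplicative on the two-copy expectation: a one-copy gene
with true compensation coefficient ``c`` is expressed at ``2**(c - 1)`` times
its two-copy level, so c = 0 halves expression and c = 1 leaves it unchanged.
Propagated effects decay geometrically with network distance: a two-copy gene
at shell k from the deleted genes shifts by ``alpha**k`` times the (mean)
source log2 fold-change.  Propagation is applied once along shortest paths
(single-pass BFS), so cycles do not re-amplify the perturbation.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .config import ConfigurationError, MixtureComponent, SimulationConfig

DOMAIN_SOURCES = {
    "damid_state": (["HP1", "Act(Y)", "Act(R)", "PcG", "Null"],
                    [0.10, 0.25, 0.20, 0.15, 0.30]),
    "hic_state": (["Act", "Rep", "Null"], [0.40, 0.30, 0.30]),
    "lad": (["LamB", "none"], [0.35, 0.65]),
}


@dataclass
class TruthTable:
    """Ground truth of a simulated panel.

    ``genes`` carries the per-gene parameters (c_g, domain membership, sex
    bias, background effect, baseline weight); ``effects`` records every
    genotype-specific expected log2 fold-change with its cause (``dose``,
    ``broken`` or ``propagation``) so each simulated deviation from baseline
    is attributable to exactly one cause plus sampling noise.
    """

    genes: pd.DataFrame
    effects: pd.DataFrame
    spike_ratios: pd.DataFrame


@dataclass
class PanelBundle:
    """Annotation, deletions, domains, network and truth for one panel."""

    genes: pd.DataFrame
    dfs: pd.DataFrame
    domains: pd.DataFrame
    network: nx.Graph
    truth: TruthTable


def _draw_mixture(rng: np.random.Generator,
                  mixture: tuple[MixtureComponent, ...],
                  n: int) -> tuple[np.ndarray, np.ndarray]:
    weights = np.array([c.weight for c in mixture])
    comp = rng.choice(len(mixture), size=n, p=weights)
    values = np.empty(n)
    for i, c in enumerate(mixture):
        idx = comp == i
        m = int(idx.sum())
        if m == 0:
            continue
        if c.kind == "point":
            values[idx] = c.params[0]
        elif c.kind == "beta":
            a, b, lo, hi = c.params
            values[idx] = lo + (hi - lo) * rng.beta(a, b, size=m)
        elif c.kind == "uniform":
            lo, hi = c.params
            values[idx] = rng.uniform(lo, hi, size=m)
        else:  # pragma: no cover - guarded by config validation
            raise ConfigurationError(f"unknown mixture kind {c.kind!r}")
    return values, comp


def _tile_genes(rng: np.random.Generator, config: SimulationConfig) -> pd.DataFrame:
    n = config.n_genes
    lengths = np.maximum(
        200, rng.lognormal(mean=7.4, sigma=0.6, size=n)
    ).astype(np.int64)
    total = int(lengths.sum())
    if total >= config.chrom_length:
        raise ConfigurationError("genes do not fit on the chromosome arm")
    free = config.chrom_length - total
    gaps = rng.dirichlet(np.ones(n + 1)) * free
    gaps = np.floor(gaps).astype(np.int64)
    starts = np.cumsum(gaps[:-1] + np.concatenate([[0], lengths[:-1]]))
    genes = pd.DataFrame(
        {
            "chrom": config.chrom,
            "start": starts,
            "end": starts + lengths,
            "gene_id": [f"G{i:05d}" for i in range(n)],
            "length": lengths,
            "feature": "gene",
        }
    )
    return genes


def _draw_deletions(rng: np.random.Generator, config: SimulationConfig,
                    genes: pd.DataFrame) -> pd.DataFrame:
    lo, hi = config.df_length_range
    rows = []
    starts = genes["start"].to_numpy()
    ends = genes["end"].to_numpy()
    for i in range(config.n_dfs):
        for _ in range(1000):
            length = int(rng.integers(lo, hi + 1))
            start = int(rng.integers(0, config.chrom_length - length))
            end = start + length
            covered = (starts >= start) & (ends <= end)
            if covered.any():
                rows.append((config.chrom, start, end, f"Df{i:03d}"))
                break
        else:  # pragma: no cover - essentially impossible with sane configs
            raise ConfigurationError("could not place a deletion covering a gene")
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "df_id"])


def _draw_domains(rng: np.random.Generator, config: SimulationConfig) -> pd.DataFrame:
    rows = []
    for source, (states, probs) in DOMAIN_SOURCES.items():
        pos = 0
        while pos < config.chrom_length:
            length = max(20_000, int(rng.exponential(config.domain_mean_length)))
            end = min(pos + length, config.chrom_length)
            state = states[rng.choice(len(states), p=np.asarray(probs))]
            if state != "none":  # 'none' gaps model regions outside any LAD
                rows.append((config.chrom, pos, end, source, state))
            pos = end
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "source", "state"])


def _gene_domain_state(genes: pd.DataFrame, domains: pd.DataFrame,
                       source: str) -> pd.Series:
    # midpoint rule on non-overlapping, sorted intervals
    sub = domains[domains["source"] == source].sort_values("start")
    mid = ((genes["start"] + genes["end"]) // 2).to_numpy()
    idx = np.searchsorted(sub["start"].to_numpy(), mid, side="right") - 1
    state = np.full(len(genes), "unassigned", dtype=object)
    ok = idx >= 0
    inside = np.zeros(len(genes), bool)
    inside[ok] = mid[ok] < sub["end"].to_numpy()[idx[ok]]
    state[inside] = sub["state"].to_numpy()[idx[inside]]
    return pd.Series(state, index=genes.index)


def assign_copy_states(genes: pd.DataFrame, dfs: pd.DataFrame) -> pd.DataFrame:
    """Long table of non-two-copy states (see dosage.assign_copy_number)."""
    from .dosage import assign_copy_number

    return assign_copy_number(genes, dfs)


def generate_panel(config: SimulationConfig) -> PanelBundle:
    """Generate gene annotation, deletion panel, chromatin domains, gene
    network and ground truth for one synthetic screen.

    Deterministic given ``config.seed``: the same config yields byte-identical
    bundles.
    """
    rng = np.random.default_rng(config.seed)
    genes = _tile_genes(rng, config)
    dfs = _draw_deletions(rng, config, genes)
    domains = _draw_domains(rng, config)

    # network over the whole genome: the profiled arm plus unobserved
    # rest-of-genome nodes (random placement so arm genes are not all hubs)
    n_total = config.n_genes * max(config.network_genome_factor, 1)
    graph = nx.barabasi_albert_graph(
        n_total, config.network_m, seed=int(rng.integers(2**31))
    )
    perm = rng.permutation(n_total)
    arm_ids = genes["gene_id"].tolist()
    mapping = {}
    bg = 0
    for rank, node in enumerate(perm):
        if rank < config.n_genes:
            mapping[node] = arm_ids[rank]
        else:
            mapping[node] = f"BG{bg:05d}"
            bg += 1
    graph = nx.relabel_nodes(graph, mapping)

    c_g, comp = _draw_mixture(rng, tuple(config.compensation_mixture),
                              config.n_genes)
    comp_names = np.array([c.kind if c.kind != "point" else f"point{c.params[0]:g}"
                           for c in config.compensation_mixture])

    truth_genes = genes[["gene_id", "start", "end", "length"]].copy()
    truth_genes["c_g"] = c_g
    truth_genes["mixture_component"] = comp_names[comp]
    repressive = np.zeros(config.n_genes, bool)
    for source in DOMAIN_SOURCES:
        state = _gene_domain_state(genes, domains, source)
        truth_genes[source] = state.to_numpy()
        repressive |= state.isin(config.repressive_states).to_numpy()
    truth_genes["repressive"] = repressive

    n_bias = int(round(config.sex_biased_fraction * config.n_genes))
    bias = np.full(config.n_genes, "none", dtype=object)
    chosen = rng.choice(config.n_genes, size=n_bias, replace=False)
    bias[chosen[: n_bias // 2]] = "male"
    bias[chosen[n_bias // 2:]] = "female"
    truth_genes["sex_bias"] = bias
    truth_genes["background_lfc"] = rng.normal(0, config.background_sd,
                                               config.n_genes)
    weights = rng.lognormal(*config.base_expression, size=config.n_genes)
    truth_genes["base_weight"] = weights / weights.sum()

    # genotype-specific expected effects (sex-independent part + female boost)
    copies = assign_copy_states(genes, dfs)
    cmap = truth_genes.set_index("gene_id")
    arm = set(cmap.index)
    eff_rows = []
    for df_id, grp in copies.groupby("df_id", sort=True):
        one = grp.loc[grp["state"] == "1", "gene_id"].tolist()
        broken = grp.loc[grp["state"] == "broken", "gene_id"].tolist()
        source_lfc = {}
        for g in one:
            base = cmap.at[g, "c_g"] - 1.0
            boost = (config.female_repressive_boost
                     if cmap.at[g, "repressive"] else 0.0)
            source_lfc[g] = base
            eff_rows.append((g, df_id, "dose", 0, base, boost))
        for g in broken:
            # only the intact homolog is expressed; no compensation modelled
            eff_rows.append((g, df_id, "broken", 0, -1.0, 0.0))
        if one and config.propagation_alpha != 0:
            present = [g for g in one if g in graph]
            affected = set(one) | set(broken)
            shells, nearest = _bfs_shells(graph, present,
                                          config.propagation_depth)
            for k in range(1, config.propagation_depth + 1):
                for g in shells.get(k, ()):
                    if g in affected or g not in arm:
                        continue  # direct effects win; unprofiled genes skip
                    src_mean = float(np.mean([source_lfc[s] for s in nearest[g]]))
                    lfc = config.propagation_alpha**k * src_mean
                    eff_rows.append((g, df_id, "propagation", k, lfc, 0.0))
    effects = pd.DataFrame(
        eff_rows,
        columns=["gene_id", "df_id", "cause", "shell", "base_lfc",
                 "female_boost_lfc"],
    )

    spike_ratios = _spike_design(config)
    truth = TruthTable(genes=truth_genes, effects=effects,
                       spike_ratios=spike_ratios)
    return PanelBundle(genes=genes, dfs=dfs, domains=domains, network=graph,
                       truth=truth)


def _bfs_shells(graph: nx.Graph, sources: list[str], depth: int):
    """Single-pass multi-source BFS; returns shell membership and, per shell
    gene, the set of sources at exactly the shell distance (nearest sources)."""
    dist = {s: 0 for s in sources}
    nearest: dict[str, set] = {s: {s} for s in sources}
    shells: dict[int, list] = {}
    frontier = list(sources)
    for k in range(1, depth + 1):
        nxt = []
        for u in frontier:
            for v in graph[u]:
                if v not in dist:
                    dist[v] = k
                    nearest[v] = set(nearest[u]) if k == 1 else set(nearest[u])
                    nxt.append(v)
                elif dist[v] == k:
                    nearest[v] |= nearest[u]
        shells[k] = sorted(nxt)
        frontier = nxt
    return shells, nearest


def _spike_design(config: SimulationConfig) -> pd.DataFrame:
    """Spike-in pool design: three subpools at mix-A:mix-B concentration
    ratios 1:1, 1:1.5 and 1.5:1, concentrations log-spaced over a 2**15
    range within each subpool."""
    # symmetric subpools keep the two mix totals equal, so observed A/B
    # count ratios recover the designed ratios exactly in the noise-free
    # limit (as in balanced external RNA control mixes)
    pools = {"1:1": (1.0, 1.0), "1:1.5": (1.0, 1.5), "1.5:1": (1.5, 1.0)}
    rows = []
    i = 0
    for pool, (fa, fb) in pools.items():
        concs = np.logspace(0, 15, config.spikein_n_per_pool, base=2.0)
        for c in concs:
            rows.append((f"SPIKE-{i:03d}", pool, c * fa, c * fb,
                         float(np.log2(fa / fb))))
            i += 1
    return pd.DataFrame(
        rows, columns=["spike_id", "pool", "conc_a", "conc_b",
                       "expected_log2_ratio"])


def sample_table(config: SimulationConfig, dfs: pd.DataFrame) -> pd.DataFrame:
    genotypes = ["wt"] + dfs["df_id"].tolist()
    rows = []
    for bg in config.backgrounds:
        for sex in config.sexes:
            for g in genotypes:
                for r in range(1, config.replicates + 1):
                    rows.append((f"{g}_{bg}_{sex}_r{r}", g, sex, bg, r))
    return pd.DataFrame(
        rows, columns=["sample_id", "genotype", "sex", "background",
                       "replicate"])


def simulate_counts(bundle: PanelBundle, config: SimulationConfig,
                    seed: int | None = None):
    """Simulate the count matrix, sample table and spike-in table.

    Counts are negative binomial with mean ``library_size * depth_factor *
    weight * 2**lfc`` and variance ``mu + dispersion * mu**2``; with
    ``dispersion == 0`` the rounded expectation is returned (noise-free
    limit).  Returns ``(counts, samples, spikes)``.
    """
    if seed is None:
        seed = config.seed + 1
    rng = np.random.default_rng(seed)
    truth = bundle.truth
    samples = sample_table(config, bundle.dfs)

    tg = truth.genes
    base = tg["base_weight"].to_numpy()
    gene_ids = tg["gene_id"].tolist()

    # intergenic background probes: weak uniform expression, never perturbed
    n_int = config.n_intergenic
    int_ids = [f"INTERGENIC-{i:04d}" for i in range(n_int)]
    int_w = np.full(n_int, config.intergenic_level / max(config.n_genes, 1))
    int_len = rng.integers(500, 3000, size=n_int)

    eff = truth.effects
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    by_df = {df_id: grp for df_id, grp in eff.groupby("df_id")}

    sex_bias = tg["sex_bias"].to_numpy()
    bg_lfc = tg["background_lfc"].to_numpy()
    male_shift = np.where(sex_bias == "male", config.sex_effect_log2,
                          np.where(sex_bias == "female",
                                   -config.sex_effect_log2, 0.0))

    gene_frac = 1.0 - config.spikein_total_fraction
    spikes = truth.spike_ratios
    conc_a = spikes["conc_a"].to_numpy()
    conc_b = spikes["conc_b"].to_numpy()

    counts = np.empty((len(gene_ids) + n_int, len(samples)), dtype=np.int64)
    spike_counts = np.empty((len(spikes), len(samples)), dtype=np.int64)
    prop_noise_cache: dict[str, np.ndarray] = {}

    for j, s in samples.iterrows():
        lfc = np.zeros(len(gene_ids))
        if s["sex"] == "male":
            lfc += male_shift
        if s["background"] != config.backgrounds[0]:
            lfc += bg_lfc
        if s["genotype"] != "wt" and s["genotype"] in by_df:
            grp = by_df[s["genotype"]]
            idx = np.fromiter((gene_pos[g] for g in grp["gene_id"]), dtype=int)
            add = grp["base_lfc"].to_numpy().copy()
            if s["sex"] == "female":
                add = add + grp["female_boost_lfc"].to_numpy()
            # one per-gene Gaussian jitter on propagated effects per genotype
            if s["genotype"] not in prop_noise_cache:
                jit = np.zeros(len(grp))
                prop = (grp["cause"] == "propagation").to_numpy()
                jit[prop] = rng.normal(0, config.propagation_noise_sd,
                                       prop.sum())
                prop_noise_cache[s["genotype"]] = jit
            add = add + prop_noise_cache[s["genotype"]]
            lfc[idx] += add
        depth = rng.lognormal(0, config.depth_sd) if config.depth_sd else 1.0
        lib = config.library_size * depth
        mu = lib * gene_frac * base * np.exp2(lfc)
        mu = np.concatenate([mu, lib * gene_frac * int_w])
        if np.any(mu < 0):  # pragma: no cover
            raise ConfigurationError("negative expected counts")
        counts[:, j] = _nb_draw(rng, mu, config.dispersion)

        conc = conc_a if s["replicate"] % 2 == 1 else conc_b
        smu = lib * config.spikein_total_fraction * conc / conc.sum()
        spike_counts[:, j] = _nb_draw(rng, smu, config.dispersion)

    counts_df = pd.DataFrame(counts, index=gene_ids + int_ids,
                             columns=samples["sample_id"].tolist())
    counts_df.index.name = "gene_id"
    spikes_out = pd.concat(
        [spikes,
         pd.DataFrame(spike_counts, index=spikes.index,
                      columns=samples["sample_id"].tolist())], axis=1)
    lengths = pd.Series(
        np.concatenate([tg["length"].to_numpy(), int_len]),
        index=gene_ids + int_ids, name="length")
    return counts_df, samples, spikes_out, lengths


def _nb_draw(rng: np.random.Generator, mu: np.ndarray,
             dispersion: float) -> np.ndarray:
    if dispersion == 0:
        return np.rint(mu).astype(np.int64)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mu * dispersion)
    return rng.poisson(lam).astype(np.int64)


def simulate_panel(config: SimulationConfig):
    """Convenience wrapper: generate a panel and simulate its counts."""
    bundle = generate_panel(config)
    counts, samples, spikes, lengths = simulate_counts(bundle, config)
    return bundle, counts, samples, spikes, lengths


def write_fixture(bundle: PanelBundle, counts: pd.DataFrame,
                  samples: pd.DataFrame, spikes: pd.DataFrame,
                  lengths: pd.Series, outdir) -> None:
    """Write a complete fixture (annotation, counts, truth) to ``outdir``.

    Files round-trip losslessly through :mod:`dfcomp.io` readers.
    """
    from . import io

    io.write_fixture(bundle, counts, samples, spikes, lengths, outdir)


def intergenic_ids(counts: pd.DataFrame) -> list[str]:
    """The intergenic background-probe rows of a simulated count matrix."""
    return [g for g in counts.index if g.startswith("INTERGENIC-")]


def gene_rows(counts: pd.DataFrame) -> list[str]:
    return [g for g in counts.index if not g.startswith("INTERGENIC-")]
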