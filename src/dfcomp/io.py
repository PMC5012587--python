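"""Readers and writers for the plain-text panel formats.

All tables are TSV with a header row; genomic intervals use 0-based half-open
(BED-style) coordinates.  ``read_fixture`` reconstructs everything written by
``write_fixture`` losslessly.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import pandas as pd


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_counts(path) -> pd.DataFrame:
    counts = pd.read_csv(path, sep="\t", index_col=0)
    counts.index.name = "gene_id"
    return counts


def read_samples(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_genes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_dfs(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_domains(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_network(path) -> nx.Graph:
    edges = pd.read_csv(path, sep="\t")
    g = nx.Graph()
    g.add_edges_from(edges.itertuples(index=False, name=None))
    return g


def read_spikeins(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_fixture(bundle, counts: pd.DataFrame, samples: pd.DataFrame,
                  spikes: pd.DataFrame, lengths: pd.Series, outdir) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_tsv(counts, out / "counts.tsv", index=True)
    write_tsv(samples, out / "samples.tsv")
    write_tsv(bundle.genes, out / "genes.bed")
    write_tsv(bundle.dfs, out / "dfs.bed")
    write_tsv(bundle.domains, out / "domains.bed")
    edges = pd.DataFrame(sorted(bundle.network.edges()),
                         columns=["gene_a", "gene_b"])
    write_tsv(edges, out / "network.tsv")
    write_tsv(spikes, out / "spikeins.tsv")
    write_tsv(bundle.truth.genes, out / "truth.tsv")
    write_tsv(bundle.truth.effects, out / "truth_effects.tsv")
    probe = lengths[~lengths.index.isin(bundle.genes["gene_id"])]
    probe.rename_axis("probe_id").reset_index().to_csv(
        out / "intergenic.tsv", sep="\t", index=False)


def read_fixture(indir) -> dict:
    """Read a fixture directory back into in-memory tables.

    Returns a dict with keys counts, samples, genes, dfs, domains, network,
    spikes, truth_genes, truth_effects, lengths, intergenic_ids.
    """
    ind = Path(indir)
    counts = read_counts(ind / "counts.tsv")
    genes = read_genes(ind / "genes.bed")
    probe = pd.read_csv(ind / "intergenic.tsv", sep="\t")
    lengths = pd.concat([
        genes.set_index("gene_id")["length"],
        probe.set_index("probe_id")["length"],
    ])
    lengths = lengths.reindex(counts.index)
    return {
        "counts": counts,
        "samples": read_samples(ind / "samples.tsv"),
        "genes": genes,
        "dfs": read_dfs(ind / "dfs.bed"),
        "domains": read_domains(ind / "domains.bed"),
        "network": read_network(ind / "network.tsv"),
        "spikes": read_spikeins(ind / "spikeins.tsv"),
        "truth_genes": pd.read_csv(ind / "truth.tsv", sep="\t"),
        "truth_effects": pd.read_csv(ind / "truth_effects.tsv", sep="\t"),
        "lengths": lengths,
        "intergenic_ids": probe["probe_id"].tolist(),
    }
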