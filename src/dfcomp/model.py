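"""Model/results facades over the analysis pipeline.

``CompensationModel`` bundles a count matrix with its sample, gene, deletion,
domain and network annotation; ``fit()`` runs normalization, QC, copy-number
assignment and relative-expression estimation and returns a
``CompensationResults`` carrying the per-record estimates, per-stratum
summaries and the downstream analyses (concordance, clustering, domain and
breakpoint tests, network propagation) as methods.

``ModeratedDEModel`` wraps the voom-style moderated differential-expression
fits the network analyses consume.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import chromatin as _chromatin
from . import de as _de
from . import dosage as _dosage
from . import network as _network
from . import normalize as _normalize


class CompensationModel:
    """Dosage-compensation analysis of a Df/+ expression panel.

    Parameters
    ----------
    counts : genes x samples integer matrix (may include intergenic probes,
        identified by ``intergenic_ids``).
    samples : sample table (sample_id, genotype, sex, background, replicate).
    genes : gene annotation (chrom, start, end, gene_id, length).
    dfs : deletion panel (chrom, start, end, df_id).
    spikes, domains, network : optional spike-in table, domain annotation and
        interaction graph for the corresponding analyses.
    """

    def __init__(self, counts, samples, genes, dfs, lengths=None, spikes=None,
                 domains=None, network=None, intergenic_ids=None,
                 include_spikeins_in_denominator: bool = True,
                 cutoff_percentile: float = 0.95,
                 network_reference_guard: bool = True):
        self.counts = counts
        self.samples = samples
        self.genes = genes
        self.dfs = dfs
        if lengths is None:
            lengths = genes.set_index("gene_id")["length"].reindex(
                counts.index)
        self.lengths = lengths
        self.spikes = spikes
        self.domains = domains
        self.network = network
        self.intergenic_ids = list(intergenic_ids or [])
        self.include_spikeins = include_spikeins_in_denominator
        self.cutoff_percentile = cutoff_percentile
        self.network_reference_guard = network_reference_guard

    @classmethod
    def from_fixture(cls, indir, **kwargs) -> "CompensationModel":
        from . import io

        fx = io.read_fixture(indir)
        return cls(fx["counts"], fx["samples"], fx["genes"], fx["dfs"],
                   lengths=fx["lengths"], spikes=fx["spikes"],
                   domains=fx["domains"], network=fx["network"],
                   intergenic_ids=fx["intergenic_ids"], **kwargs)

    def fit(self, replicate_qc: bool = False,
            r_min: float = 0.9) -> "CompensationResults":
        factors = _normalize.tmm_factors(self.counts)
        # TMM-corrected denominators: effective library size (composition
        # bias from the deleted segment itself is trimmed away), optionally
        # inflated by spike-in totals on the same relative scale
        lib = factors["lib_size"]
        totals = factors["effective_lib_size"]
        if self.include_spikeins and self.spikes is not None:
            spike_tot = self.spikes[self.counts.columns].sum(axis=0)
            totals = totals * (1.0 + spike_tot / lib)
        fpkm = _normalize.compute_fpkm(self.counts, self.lengths,
                                       totals=totals)
        if self.intergenic_ids:
            cutoffs = _normalize.intergenic_cutoff(
                fpkm, self.intergenic_ids, self.samples,
                percentile=self.cutoff_percentile)
        else:
            cutoffs = {}
        samples = self.samples
        qc_report = None
        if replicate_qc:
            qc = _normalize.replicate_qc(fpkm, samples, r_min=r_min)
            samples = samples[samples["sample_id"].isin(qc.retained)]
            qc_report = qc.report
        keep = _normalize.filter_genes(self.counts, fpkm=fpkm,
                                       cutoffs=cutoffs or None,
                                       samples=samples)
        keep &= ~self.counts.index.isin(self.intergenic_ids)
        copies = _dosage.assign_copy_number(self.genes, self.dfs)
        # genotypes whose deletion is network-proximal to a gene may carry
        # propagated secondary effects of that deletion; keep them out of
        # the gene's two-copy reference pool
        ref_excl = None
        if self.network is not None and self.network_reference_guard:
            ref_excl = _dosage.network_reference_exclusions(self.network,
                                                            copies)
        records = _dosage.relative_expression(
            fpkm.loc[keep], samples, copies, cutoffs=cutoffs,
            ref_exclusions=ref_excl)
        return CompensationResults(self, records, copies, fpkm, factors,
                                   cutoffs, qc_report)


class CompensationResults:
    """Fitted dosage-compensation estimates and downstream analyses."""

    def __init__(self, model, records, copies, fpkm, factors, cutoffs,
                 qc_report=None):
        self.model = model
        self.records = records
        self.copies = copies
        self.fpkm = fpkm
        self.norm_factors = factors
        self.cutoffs = cutoffs
        self.qc_report = qc_report

    # -- summaries -----------------------------------------------------
    def stratum_summaries(self) -> pd.DataFrame:
        rows = []
        for (sex, bg), grp in self.records.groupby(["sex", "background"],
                                                   sort=False):
            s = _dosage.compensation_summary(grp)
            row = s.as_series()
            row["sex"], row["background"] = sex, bg
            rows.append(row)
        return pd.DataFrame(rows).set_index(["sex", "background"])

    def summary(self) -> str:
        tab = self.stratum_summaries()
        lines = ["Dosage compensation summary (one-copy genes vs pooled "
                 "two-copy reference)", "=" * 72]
        for (sex, bg), row in tab.iterrows():
            lines.append(
                f"{sex:>7}/{bg:<9} n={int(row['n_one']):5d}  "
                f"mean fold={row['mean_fold']:.3f}  "
                f"median R={row['median_R']:+.3f}  "
                f"skew={row['skewness_p2']:+.3f}  "
                f"kurtosis={row['kurtosis']:.2f}  "
                f"KS D={row['ks_D']:.3f}  MWU p={row['mwu_p']:.2e}")
        lines.append("=" * 72)
        lines.append("fold 1 = no compensation, 2 = full; "
                     "KS D vs two-copy distribution shifted -1 log2")
        return "\n".join(lines)

    # -- dosage analyses ----------------------------------------------
    def sex_concordance(self) -> dict:
        return _dosage.sex_concordance(self.records)

    def cluster_backgrounds(self, sex: str = "female", **kwargs) -> dict:
        return _dosage.em_compensation_clusters(self.records, sex=sex,
                                                **kwargs)

    def sex_bias_enrichment(self, cluster_genes, bias_labels,
                            background_sets) -> pd.DataFrame:
        return _dosage.sex_bias_enrichment(cluster_genes, bias_labels,
                                           background_sets)

    def covariate_regression(self, covariate, **kwargs) -> dict:
        return _dosage.covariate_regression(self.records, covariate, **kwargs)

    def deletion_length_regression(self) -> dict:
        lengths = (self.model.dfs.set_index("df_id")
                   .eval("end - start"))
        return _dosage.covariate_regression(self.records, lengths,
                                            on="genotype")

    # -- chromatin analyses -------------------------------------------
    def domain_labels(self, rule: str = "midpoint") -> pd.DataFrame:
        if self.model.domains is None:
            raise ValueError("model has no domain annotation")
        return _chromatin.map_genes_to_domains(self.model.genes,
                                               self.model.domains, rule=rule)

    def domain_tests(self, source: str, **kwargs) -> pd.DataFrame:
        return _chromatin.domain_stratified_tests(
            self.records, self.domain_labels(), source, **kwargs)

    def broken_domain_flanking(self, source: str, state: str) -> dict:
        return _chromatin.broken_domain_flanking(
            self.records, self.model.domains, self.model.dfs,
            self.model.genes, source, state)

    def breakpoint_profile(self, **kwargs) -> pd.DataFrame:
        return _chromatin.breakpoint_profile(self.records, self.model.dfs,
                                             self.model.genes, self.copies,
                                             **kwargs)

    def breakpoint_mad_track(self, window: int = 30,
                             **kwargs) -> pd.DataFrame:
        return _chromatin.offset_mad_track(self.breakpoint_profile(**kwargs),
                                           window=window)

    # -- plotting ------------------------------------------------------
    def plot_compensation_distribution(self, sex=None, background=None,
                                       ax=None):
        """Density of one-copy relative expression against the two-copy and
        halved two-copy (no compensation) distributions."""
        import matplotlib.pyplot as plt

        rec = self.records[~self.records["excluded"]]
        if sex is not None:
            rec = rec[rec["sex"] == sex]
        if background is not None:
            rec = rec[rec["background"] == background]
        one = rec.loc[rec["copy"] == "1", "R"].dropna()
        two = rec.loc[rec["copy"] == "2", "R"].dropna()
        if ax is None:
            _, ax = plt.subplots()
        bins = np.linspace(-2.5, 1.5, 81)
        ax.hist(two, bins=bins, density=True, histtype="step",
                linestyle="--", label="two copy")
        ax.hist(two - 1.0, bins=bins, density=True, histtype="step",
                linestyle=":", label="two copy shifted -1 (no compensation)")
        ax.hist(one, bins=bins, density=True, histtype="step",
                label="one copy")
        ax.set_xlabel("relative expression R (log2)")
        ax.set_ylabel("density")
        ax.legend()
        return ax


class ModeratedDEModel:
    """Per-genotype moderated differential expression over a panel."""

    def __init__(self, counts, samples, wt_label: str = "wt"):
        self.counts = counts
        self.samples = samples
        self.wt_label = wt_label
        self._factors = None

    @property
    def norm_factors(self):
        if self._factors is None:
            self._factors = _normalize.tmm_factors(
                self.counts[self.samples["sample_id"]])
        return self._factors

    def fit(self, genotype: str, sex: str, background: str,
            **kwargs) -> "DEResults":
        table = _de.fit_moderated_de(self.counts, self.samples, genotype,
                                     sex, background,
                                     norm_factors=self.norm_factors,
                                     wt_label=self.wt_label, **kwargs)
        return DEResults(self, table)

    def fit_all(self, **kwargs) -> "DEResults":
        table = _de.fit_all_genotypes(self.counts, self.samples,
                                      norm_factors=self.norm_factors,
                                      wt_label=self.wt_label, **kwargs)
        return DEResults(self, table)


class DEResults:
    """Moderated DE tables plus the network-propagation analyses."""

    def __init__(self, model, table: pd.DataFrame):
        self.model = model
        self.table = table

    def summary(self, alpha: float = 0.05) -> str:
        t = self.table
        lines = ["Moderated differential expression "
                 "(each genotype vs rest of stratum)", "=" * 68]
        for (g, sex, bg), grp in t.groupby(["genotype", "sex", "background"],
                                           sort=False):
            n_sig = int((grp["adj_p"] < alpha).sum())
            lines.append(f"{g:>10} {sex:>7}/{bg:<9} genes={len(grp):5d}  "
                         f"adj p<{alpha:g}: {n_sig}")
        lines.append("=" * 68)
        return "\n".join(lines)

    def propagation_correlation(self, network, copies,
                                **kwargs) -> pd.DataFrame:
        return _network.propagation_correlation(self.table, network, copies,
                                                **kwargs)

    def significant_counts(self, copies, **kwargs) -> dict:
        return _network.significant_counts(self.table, copies, **kwargs)

    def background_overlap(self, other: "DEResults", network, copies,
                           **kwargs) -> pd.DataFrame:
        return _network.background_overlap(self.table, other.table, network,
                                           copies, **kwargs)
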