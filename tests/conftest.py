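import numpy as np
import pandas as pd
import pytest

from dfcomp import SimulationConfig, generate_panel, simulate_counts
from dfcomp.simulate import intergenic_ids


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_genes=300, n_dfs=8, seed=42)


@pytest.fixture(scope="session")
def small_panel(small_config):
    bundle = generate_panel(small_config)
    counts, samples, spikes, lengths = simulate_counts(bundle, small_config)
    return {"config": small_config, "bundle": bundle, "counts": counts,
            "samples": samples, "spikes": spikes, "lengths": lengths}


@pytest.fixture(scope="session")
def noisefree_panel():
    cfg = SimulationConfig(n_genes=300, n_dfs=15, seed=5, dispersion=0.0,
                           depth_sd=0.0)
    bundle = generate_panel(cfg)
    counts, samples, spikes, lengths = simulate_counts(bundle, cfg)
    return {"config": cfg, "bundle": bundle, "counts": counts,
            "samples": samples, "spikes": spikes, "lengths": lengths}


@pytest.fixture(scope="session")
def small_results(small_panel):
    from dfcomp import CompensationModel

    p = small_panel
    model = CompensationModel(
        p["counts"], p["samples"], p["bundle"].genes, p["bundle"].dfs,
        lengths=p["lengths"], spikes=p["spikes"],
        domains=p["bundle"].domains, network=p["bundle"].network,
        intergenic_ids=intergenic_ids(p["counts"]))
    return model.fit()


def true_record_lfc(one_copy_records: pd.DataFrame,
                    truth_effects: pd.DataFrame) -> np.ndarray:
    """Expected direct log2FC per one-copy record (dose + female boost)."""
    dose = truth_effects[truth_effects["cause"] == "dose"].set_index(
        ["gene_id", "df_id"])
    key = list(zip(one_copy_records["gene_id"], one_copy_records["genotype"]))
    base = dose["base_lfc"].loc[key].to_numpy()
    boost = dose["female_boost_lfc"].loc[key].to_numpy()
    female = (one_copy_records["sex"] == "female").to_numpy()
    return base + np.where(female, boost, 0.0)
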