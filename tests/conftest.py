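import numpy as np
import pandas as pd
import pytest

from xsilence import features as ft
from xsilence import simulate as sim


@pytest.fixture(scope="session")
def wt_config():
    return sim.SimulationConfig(n_genes=500, seed=11, alpha=1.0, expr_effect=0.5)


@pytest.fixture(scope="session")
def wt_dataset(wt_config):
    """Genes, truth and a Dox+NoDox count table for the default WT chromosome."""
    genes, truth, counts = sim.simulate_experiment(wt_config)
    return genes, truth, counts


@pytest.fixture(scope="session")
def wt_segmentation(wt_dataset, wt_config):
    genes, _, _ = wt_dataset
    return ft.Segmentation(sim.simulate_segmentation(genes, wt_config))


@pytest.fixture(scope="session")
def wt_profile(wt_config):
    return sim.simulate_4c(wt_config)


@pytest.fixture
def toy_counts():
    """Four genes x two samples, hand-computable."""
    rows = []
    data = {
        "g1": [(5, 5), (6, 4)],
        "g2": [(0, 10), (1, 9)],
        "g3": [(3, 9), (4, 8)],
        "g4": [(12, 0), (9, 3)],
    }
    for gene, pairs in data.items():
        for rep, (xi, xa) in enumerate(pairs, start=1):
            cond = "nodox" if rep == 1 else "dox"
            rows.append(
                {
                    "gene_id": gene,
                    "sample_id": f"WT_{cond}_rep1",
                    "condition": cond,
                    "genotype": "WT",
                    "replicate": 1,
                    "xi": xi,
                    "xa": xa,
                }
            )
    return pd.DataFrame(rows)
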