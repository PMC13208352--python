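import pandas as pd
import pytest

import adipokinome as ak


@pytest.fixture(scope="session")
def small_map():
    """50 kinases over 144 peptides, default rank distribution."""
    return ak.generate_map(50, 144, seed=42)


@pytest.fixture(scope="session")
def noise_free_experiment():
    """One kinase at x3 over 5 exclusively-mapped peptides, no noise."""
    kmap = ak.generate_map(1, 5, substrates_per_kinase=(5, 5), seed=1)
    truth = ak.PlantedTruth(
        kinase_multipliers={"KIN01": 3.0},
        baseline_rates={p: 10.0 for p in kmap.universe},
        noise_cv=0.0,
    )
    return ak.simulate_experiment(truth, kmap, seed=0)


@pytest.fixture()
def score_table():
    """Small hand-built kinase score table for atlas-level tests."""
    return pd.DataFrame({
        "kinase": ["AKT1", "CDK1", "FYN", "LYN", "MTOR"],
        "assay": ["STK", "STK", "PTK", "PTK", "STK"],
        "kinase_statistic": [0.8, -0.4, 0.0, -1.2, 0.6],
        "mean_log2fc": [0.9, -0.5, 0.1, -1.1, 0.45],
        "final_score": [2.5, 1.8, 0.4, 3.0, 1.1],
        "meow": [2.0, -1.2, 0.05, -3.3, 0.7],
    })


def planted_run(seed: int, **kwargs):
    """Full planted-recovery analysis; returns (scores, planted ids)."""
    exp, planted = ak.planted_experiment(seed=seed, **kwargs)
    out = ak.analyze(
        exp.readings, exp.map,
        config=ak.PipelineConfig(seed=seed),
    )
    return out, planted
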