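import numpy as np
import pandas as pd
import pytest

from rvburden.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_dataset():
    """A small cohort with planted class-I risk in constrained genes."""
    n_genes = 200
    n_con = 30
    cfg = SimulationConfig(
        n_cases=800,
        n_controls=800,
        n_external_controls=2000,
        n_genes=n_genes,
        fraction_constrained=0.15,
        risk_genes=[(i, 1.8) for i in range(n_con)],
        baseline_rates={"class_I": 0.15 / 30, "class_II": 0.2 / 30, "synonymous": 1.0 / 30},
        seed=202,
    )
    return simulate_cohort(cfg)


@pytest.fixture()
def toy_gene_counts():
    """Hand-built per-gene count table covering all filter branches."""
    return pd.DataFrame(
        {
            "gene_id": ["GA", "GB", "GC", "GD"],
            "case_class_I": [8, 0, 3, 1],
            "control_class_I": [1, 2, 3, 0],
            "case_class_II": [4, 1, 0, 2],
            "control_class_II": [1, 5, 0, 1],
            "case_synonymous": [2, 2, 2, 10],
            "control_synonymous": [6, 6, 6, 10],
        }
    )
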