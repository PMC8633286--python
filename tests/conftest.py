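import numpy as np
import pandas as pd
import pytest

from csfpanel.synthetic import (PlantedEffect, SimulationConfig,
                                generate_cohort)


@pytest.fixture(scope="session")
def small_cohort():
    """Compact cohort exercising all four groups, batches and QC pools."""
    cfg = SimulationConfig(
        seed=11, n_peptides=6,
        n_per_group={"control": 8, "PD": 10, "MSA": 6, "PSP": 4},
        planted_effects=[PlantedEffect("PEP001", "MSA", 2.0, "down")],
        age_rho={"PEP002": 0.5}, n_batches=3)
    return generate_cohort(cfg)


@pytest.fixture()
def tiny_matrix():
    """Hand-written intensity matrix: 3 peptides x 10 PD + 10 MSA samples."""
    rng = np.random.default_rng(0)
    samples = [f"PD_{i}" for i in range(10)] + [f"MSA_{i}" for i in range(10)]
    groups = pd.Series(["PD"] * 10 + ["MSA"] * 10, index=samples)
    base = rng.uniform(1e5, 1e6, size=(3, 20))
    mat = pd.DataFrame(base, index=["A", "B", "C"], columns=samples)
    # A: detected 8/10 PD, 2/10 MSA; B: complete; C: all missing
    mat.loc["A", samples[8:10]] = np.nan
    mat.loc["A", samples[12:]] = np.nan
    mat.loc["C"] = np.nan
    return mat, groups
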