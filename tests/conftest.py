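import numpy as np
import pandas as pd
import pytest

from minorsplice.simulate import SimulationConfig, simulate_study


def tiny_config(**overrides) -> SimulationConfig:
    """A small two-cohort study used across integration tests."""
    base = dict(
        seed=3,
        cohorts=("CA", "CB"),
        n_patients=8,
        n_minor_introns=20,
        n_annotated_extra=10,
        n_major_introns=3,
        n_genes=150,
        n_migs=60,
        n_components=15,
        n_stem_genes=20,
        activity_sd=4.0,
        dpsi_effects={"CA": {0: 15.0, 1: 15.0, 2: -15.0}},
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def tiny_study():
    return simulate_study(tiny_config())


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


@pytest.fixture()
def sample_sheet():
    rows = []
    for cohort, n in (("AA", 6), ("BB", 4)):
        for p in range(1, n + 1):
            patient = f"TCGA-{cohort}-{p:04d}"
            rows.append((f"{patient}-01A", patient, "tumor", cohort))
            rows.append((f"{patient}-11A", patient, "normal", cohort))
    return pd.DataFrame(rows, columns=["sample_id", "patient_id", "tissue",
                                       "cohort"])
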