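import numpy as np
import pandas as pd
import pytest

from methlink.synthetic import CohortConfig, generate_cohort, generate_methylation


@pytest.fixture(scope="session")
def small_config() -> CohortConfig:
    return CohortConfig(n_subjects=80, n_probes=400, n_modules=4,
                        module_size=20, n_cell_markers=100, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    phenos, latents = generate_cohort(small_config)
    return phenos, latents


@pytest.fixture(scope="session")
def small_methylation(small_config, small_cohort):
    phenos, latents = small_cohort
    beta, manifest, labels = generate_methylation(phenos, small_config, latents)
    return beta, manifest, labels


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def toy_manifest() -> pd.DataFrame:
    """10 probes: 2 on X, 1 on Y, 1 rs, 1 cross-hybridizing, 5 clean."""
    rows = {
        "cg01": ("1", False, False), "cg02": ("2", False, False),
        "cg03": ("3", False, False), "cg04": ("4", False, False),
        "cg05": ("5", False, False),
        "cgX1": ("X", False, False), "cgX2": ("X", False, False),
        "cgY1": ("Y", False, False),
        "rs01": ("7", True, False),
        "cgH1": ("8", False, True),
    }
    return pd.DataFrame(
        {"chromosome": [v[0] for v in rows.values()],
         "position": range(1, 11),
         "gene_symbols": [""] * 10,
         "is_rs_probe": [v[1] for v in rows.values()],
         "is_crosshyb": [v[2] for v in rows.values()]},
        index=pd.Index(rows.keys(), name="probe_id"),
    )
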