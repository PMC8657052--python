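import pandas as pd
import pytest

from ccrcc_ecm import simulate
from ccrcc_ecm.reference import load_matrisome_reference


@pytest.fixture(scope="session")
def matrisome_ref():
    return load_matrisome_reference()


@pytest.fixture(scope="session")
def proteomics_default():
    """One default proteomics simulation shared across read-only tests."""
    config = simulate.ProteomicsSimConfig(seed=11)
    records, truth = simulate.gen_proteomics(config)
    return config, records, truth


@pytest.fixture(scope="session")
def sc_default():
    """One default single-cell simulation with a planted ECM-producing CAF."""
    config = simulate.ScSimConfig(
        seed=7, ecm_load=(("c_caf", 8.0), ("c_fib", 3.0))
    )
    adata, truth = simulate.gen_counts(config)
    return config, adata, truth


@pytest.fixture(scope="session")
def toy_composition():
    """36 distinct core percentages, normalized to 100."""
    values = pd.Series(
        [float(i) for i in range(1, 37)], index=[f"G{i:02d}" for i in range(1, 37)]
    )
    core_pct = 100.0 * values / values.sum()
    return pd.DataFrame({"core_pct": core_pct})
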