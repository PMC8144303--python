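import numpy as np
import pandas as pd
import pytest

from ncpanel import panel_io, synthetic_data


@pytest.fixture(scope="session")
def sim_default():
    """One default synthetic experiment shared across read-only tests."""
    return synthetic_data.simulate_matrix(synthetic_data.SimConfig(seed=7))


@pytest.fixture(scope="session")
def sim_lanes():
    return synthetic_data.simulate_panel(synthetic_data.SimConfig(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def make_matrix(values, samples=None, scale="log2", code_classes=None):
    """Small CountMatrix from a dict gene → row of values."""
    df = pd.DataFrame(values).T
    if samples is not None:
        df.columns = samples
    else:
        df.columns = [f"s{i+1}" for i in range(df.shape[1])]
    cc = pd.Series(code_classes) if code_classes is not None else None
    return panel_io.CountMatrix(df.astype(float if scale != "raw" else int),
                                scale=scale, code_classes=cc)


def make_design(n_per_cell=3):
    rows = []
    i = 0
    for a in ("nTg", "APP"):
        for b in ("Arg1_suff", "Arg1_insuff"):
            for _ in range(n_per_cell):
                i += 1
                rows.append({"sample_id": f"s{i}", "APP": a, "Arg1": b})
    df = pd.DataFrame(rows).set_index("sample_id")
    return panel_io.DesignTable(
        df, ("APP", "Arg1"),
        {"APP": ("nTg", "APP"), "Arg1": ("Arg1_suff", "Arg1_insuff")},
    )
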