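import numpy as np
import pandas as pd
import pytest

from ffeprof import (
    QuantMatrix,
    SimulationConfig,
    build_consensus,
    build_westerns,
    simulate_run,
    synthetic_markers,
)


@pytest.fixture(scope="session")
def templates():
    return SimulationConfig().templates


@pytest.fixture(scope="session")
def template_peak_counts(templates):
    return {t.name: len(t.peaks) for t in templates}


@pytest.fixture(scope="session")
def noise_free_run():
    """Small noise-free simulation shared by shape-recovery tests."""
    config = SimulationConfig(n_proteins_per_compartment=8, noise_cv=0.0,
                              dual_fraction=0.0, missing_rate=0.0, seed=11)
    run, matrix, truth = simulate_run(config)
    return config, run, matrix, truth


@pytest.fixture(scope="session")
def noise_free_westerns(noise_free_run):
    _, run, matrix, _ = noise_free_run
    return build_westerns(matrix, run=run)


@pytest.fixture(scope="session")
def noise_free_consensus(noise_free_run, noise_free_westerns):
    _, _, _, truth = noise_free_run
    return build_consensus(noise_free_westerns, synthetic_markers(truth))


@pytest.fixture()
def toy_quant():
    """3 proteins x 2 pooled samples x 3 replicates, 18 records."""
    rows = []
    for p in ("A", "B", "C"):
        for s in (1, 2):
            for r in (1, 2, 3):
                rows.append((p, s, r, float(10 * s + r)))
    df = pd.DataFrame(rows, columns=["protein_id", "sample", "replicate",
                                     "peak_area"])
    return QuantMatrix(df, level="pooled")


@pytest.fixture()
def fraction_ramp():
    """One protein, one replicate, peak_area = fraction index (1..96)."""
    df = pd.DataFrame({
        "protein_id": "ramp",
        "sample": np.arange(1, 97),
        "replicate": 1,
        "peak_area": np.arange(1, 97, dtype=float),
    })
    return QuantMatrix(df, level="fraction")
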