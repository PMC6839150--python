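import numpy as np
import pandas as pd
import pytest

from roscore.cohort_io import ClinicalTable, ExpressionMatrix


def make_clinical(times, events, **extra) -> ClinicalTable:
    """Build a minimal validated clinical table from arrays."""
    n = len(times)
    ids = [f"S{i + 1:04d}" for i in range(n)]
    df = pd.DataFrame({"os_years": np.asarray(times, float), "os_event": list(events)},
                      index=pd.Index(ids, name="sample_id"))
    for key, values in extra.items():
        df[key] = values
    return ClinicalTable(df)


def make_expression(values, genes=None, samples=None) -> ExpressionMatrix:
    values = np.atleast_2d(np.asarray(values, float))
    g, n = values.shape
    genes = genes or [f"G{i + 1:03d}" for i in range(g)]
    samples = samples or [f"S{i + 1:04d}" for i in range(n)]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def sim_cohort_strong():
    """One medium cohort with a strong planted signal, reused across tests."""
    from roscore.simulate import (
        SimulationConfig,
        _alternating_signal,
        _gene_names,
        simulate_cohort,
    )

    cfg = SimulationConfig(
        n_patients=400,
        n_genes=60,
        signal=_alternating_signal(_gene_names(60), 10, 0.6),
        baseline=("exponential", 0.18),
        censoring=("exponential", 0.08),
        seed=7,
    )
    return simulate_cohort(cfg)
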