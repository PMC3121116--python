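import numpy as np
import pandas as pd
import pytest

from netscreen.data_io import (
    CASE,
    CONTROL,
    ExpressionMatrix,
    SampleMeta,
    TimeSegment,
)


def make_expression(
    values: np.ndarray,
    genes: list[str],
    weeks=(4,),
    replicates=None,
    strains=(CASE, CONTROL),
) -> ExpressionMatrix:
    """Wrap a genes x samples array in an ExpressionMatrix with a full
    strain/week/replicate grid inferred from the column count."""
    n_samples = values.shape[1]
    per_strain = n_samples // len(strains)
    if replicates is None:
        replicates = per_strain // len(weeks)
    samples = []
    for strain in strains:
        for week in weeks:
            for rep in range(1, replicates + 1):
                samples.append(
                    SampleMeta(f"{strain}_w{week}_r{rep}", strain, week, rep)
                )
    assert len(samples) == n_samples, "column count does not match the grid"
    df = pd.DataFrame(values, index=genes, columns=[s.sample_id for s in samples])
    return ExpressionMatrix(df, samples)


def make_single_strain(values: np.ndarray, genes: list[str]) -> ExpressionMatrix:
    """All samples from one strain/week: the shape GCP operates on."""
    m = values.shape[1]
    samples = [SampleMeta(f"s{k}", CASE, 4, k + 1) for k in range(m)]
    df = pd.DataFrame(values, index=genes, columns=[s.sample_id for s in samples])
    return ExpressionMatrix(df, samples)


@pytest.fixture
def rng():
    return np.random.default_rng(20110620)


@pytest.fixture(scope="session")
def benchmark_bundle():
    from netscreen.synthetic_data import standard_benchmark

    return standard_benchmark(seed=1)


@pytest.fixture
def seg4():
    return TimeSegment("4w", {4})
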