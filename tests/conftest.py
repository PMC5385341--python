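import numpy as np
import pandas as pd
import pytest

from selrep.counts_io import CountMatrix


def make_matrix(values, genes=None, samples=None) -> CountMatrix:
    values = np.asarray(values)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    return CountMatrix(pd.DataFrame(values, index=genes, columns=samples))


def make_metadata(groups, samples=None, **extra) -> pd.DataFrame:
    samples = samples or [f"s{i}" for i in range(len(groups))]
    return pd.DataFrame(
        {"group": list(groups), **extra}, index=pd.Index(samples, name="sample_id")
    )


@pytest.fixture
def two_group_matrix():
    """Six samples in two groups with one clearly repressed gene."""
    rng = np.random.default_rng(42)
    base = rng.poisson(200, size=(30, 6))
    base[0, :3] = rng.poisson(10, size=3)  # repressed in group A
    cm = make_matrix(base)
    meta = make_metadata(["A"] * 3 + ["B"] * 3)
    return cm, meta
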