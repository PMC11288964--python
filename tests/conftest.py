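import numpy as np
import pandas as pd
import pytest

from riboratio import QuantTable, load_catalog


@pytest.fixture
def catalog():
    return load_catalog()


@pytest.fixture
def small_quant():
    """3 RPs + 2 non-RPs x 3 samples with one missing value."""
    values = pd.DataFrame(
        {
            "s1": [3.0, 1.0, 2.0, 100.0, 50.0],
            "s2": [6.0, 2.0, np.nan, 80.0, 40.0],
            "s3": [30.0, 10.0, 20.0, 90.0, 45.0],
        },
        index=["RPL5", "RPS19", "RPL11", "GAPDH", "ACTB"],
    )
    groups = {"s1": "ctl", "s2": "ctl", "s3": "trt"}
    return QuantTable(values, groups)


def random_quant(rng: np.random.Generator, n_prot=12, n_samp=5,
                 missing_rate=0.15) -> QuantTable:
    vals = rng.lognormal(mean=8.0, sigma=1.5, size=(n_prot, n_samp))
    mask = rng.random(vals.shape) < missing_rate
    # keep every sample non-empty
    for j in range(n_samp):
        if mask[:, j].all():
            mask[rng.integers(n_prot), j] = False
    vals = np.where(mask, np.nan, vals)
    frame = pd.DataFrame(
        vals,
        index=[f"P{i}" for i in range(n_prot)],
        columns=[f"s{j}" for j in range(n_samp)],
    )
    return QuantTable(frame)
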