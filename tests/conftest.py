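import numpy as np
import pandas as pd
import pytest

from methyldrift import io as mio
from methyldrift import synth


@pytest.fixture(scope="session")
def small_config():
    return synth.CohortConfig(seed=7)


@pytest.fixture(scope="session")
def small_manifest(small_config):
    return synth.generate_manifest(small_config)


@pytest.fixture(scope="session")
def small_cohort(small_config, small_manifest):
    return synth.generate_cohort(small_manifest, small_config)


@pytest.fixture(scope="session")
def be_matrix(small_cohort):
    sheet = small_cohort.sheet
    ids = list(sheet.loc[sheet["tissue"] == "BE", "sample_id"])
    return mio.MethylationMatrix(small_cohort.matrix.values[ids])


@pytest.fixture(scope="session")
def ns_matrix(small_cohort):
    sheet = small_cohort.sheet
    ids = list(sheet.loc[sheet["tissue"] == "NS", "sample_id"])
    return mio.MethylationMatrix(small_cohort.matrix.values[ids])


@pytest.fixture
def toy_matrix():
    """5 probes x 4 samples with one missing value."""
    rng = np.random.default_rng(3)
    values = pd.DataFrame(
        rng.uniform(0.05, 0.95, size=(5, 4)),
        index=[f"cg{i:03d}" for i in range(5)],
        columns=[f"S{j}" for j in range(4)],
    )
    values.iloc[1, 2] = np.nan
    return mio.MethylationMatrix(values)
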