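import numpy as np
import pandas as pd
import pytest

from stsdel.catalog import STSCatalog, STSRecord
from stsdel.pipeline import run_simulated_pipeline
from stsdel.qc import DepthMatrix
from stsdel.simulate import SimScenario, simulate_cohort


@pytest.fixture
def toy_catalog() -> STSCatalog:
    """Ten single-copy STSs at 100-kb spacing except a couple of short gaps."""
    starts = [100, 300, 500, 10_000, 20_000, 50_000, 200_000, 210_000, 400_000, 400_500]
    return STSCatalog(
        [
            STSRecord(
                sts_id=f"t{k}",
                chrom="chrY",
                start=s,
                end=s + 150,
                copy_class="single",
            )
            for k, s in enumerate(starts)
        ]
    )


def make_matrix(values, sample_ids=None, sts_ids=None, normalized=False) -> DepthMatrix:
    values = np.asarray(values, dtype=float)
    sample_ids = sample_ids or [f"s{i}" for i in range(values.shape[0])]
    sts_ids = sts_ids or [f"m{j}" for j in range(values.shape[1])]
    frame = pd.DataFrame(values, index=sample_ids, columns=sts_ids)
    return DepthMatrix(frame, normalized=normalized)


@pytest.fixture(scope="session")
def default_cohort():
    return simulate_cohort(SimScenario(seed=1))


@pytest.fixture(scope="session")
def default_result(default_cohort):
    return run_simulated_pipeline(default_cohort, seed=1)
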