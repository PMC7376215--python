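import numpy as np
import pandas as pd
import pytest

from oxrip.io_formats import CountMatrix, make_sample_sheet
from oxrip.synthetic_data import SimConfig, simulate_ripseq


@pytest.fixture
def design_sheet():
    """Standard 2 conditions x 2 fractions x 2 replicates sample sheet."""
    rows = [
        (f"{cond}_{frac}_{rep}", cond, frac, rep)
        for cond in ("exposed", "control")
        for frac in ("input", "rip")
        for rep in (1, 2)
    ]
    return make_sample_sheet(rows)


@pytest.fixture
def small_counts(design_sheet):
    rng = np.random.default_rng(7)
    frame = pd.DataFrame(
        rng.poisson(50, size=(20, 8)),
        index=[f"TX{i:03d}" for i in range(20)],
        columns=design_sheet.sample_ids,
    )
    return CountMatrix(frame, design_sheet)


@pytest.fixture(scope="session")
def default_sim():
    """One default synthetic dataset shared across tests (seed fixed)."""
    return simulate_ripseq(SimConfig(), seed=1)
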