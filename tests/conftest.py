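import numpy as np
import pytest

from rickertnr.io import ProgramTimeSeries
from rickertnr.ricker import RickerParams, simulate


@pytest.fixture
def small_program(tmp_path):
    """A minimal 3-year program CSV on disk."""
    path = tmp_path / "prog.csv"
    path.write_text("year,surgeries\n2000,10\n2001,12\n2002,9\n")
    return path


@pytest.fixture
def constant_program():
    """Constant surgeries and census: nothing changes, ever."""
    return ProgramTimeSeries(
        program_id="flat",
        years=list(range(2000, 2010)),
        surgeries=[50] * 10,
        census=[200] * 10,
    )


@pytest.fixture
def ricker_trajectory():
    """A noise-free Ricker path rising from well below K."""
    params = RickerParams.from_r_m(0.5, K_index=400.0)
    return simulate(params, N_1=40.0, T=25)


@pytest.fixture
def rng():
    return np.random.default_rng(20210628)
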