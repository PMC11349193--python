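import pandas as pd
import pytest

from xflux import default_fixture_spec, default_scheme, read_data, simulate_plate
from xflux.fixtures import write_experiment


@pytest.fixture(scope="session")
def noiseless_spec():
    return default_fixture_spec(n_plates=1, well_count=3)


@pytest.fixture(scope="session")
def noisy_spec():
    return default_fixture_spec(
        n_plates=3, well_count=4, noise_sd_well=3.0, noise_sd_plate=5.0, seed=11
    )


@pytest.fixture(scope="session")
def noiseless_table(noiseless_spec):
    """Simulated plate as written to disk (background wells included)."""
    return simulate_plate(noiseless_spec, 0)


@pytest.fixture(scope="session")
def noiseless_exp_table(noiseless_table):
    """The same plate as seen after reading (background wells excluded)."""
    from xflux import RateTable

    data = noiseless_table.data
    return RateTable(
        data[data["group_label"] != "Background"].reset_index(drop=True)
    )


@pytest.fixture(scope="session")
def scheme12():
    return default_scheme(12)


@pytest.fixture()
def plate_dir(tmp_path, noiseless_spec):
    """Directory with one noiseless plate written in the Wave xlsx dialect."""
    write_experiment(noiseless_spec, tmp_path / "plates")
    return tmp_path / "plates"


@pytest.fixture()
def multi_plate_dir(tmp_path, noisy_spec):
    write_experiment(noisy_spec, tmp_path / "plates")
    return tmp_path / "plates"
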