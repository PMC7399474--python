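import numpy as np
import pytest

from sfdikit.forward_model import MCSettings, build_table, run_white_mc
from sfdikit.spectral_bands import build_all_bands, select_bands


@pytest.fixture(scope="session")
def small_table():
    """Shared forward table at reduced photon count (round-trip tests are
    self-consistent against the table, so MC noise cancels)."""
    from sfdikit.validation import default_table_grids

    mu_a_grid, musp_grid, fx_grid = default_table_grids()
    return build_table(
        mu_a_grid, musp_grid, fx_grid, MCSettings(n_photons=120_000, seed=7)
    )


@pytest.fixture(scope="session")
def mc_records_small():
    """50k-photon white MC run (mu_s'=1, g=0, n=1.4)."""
    return run_white_mc(1.0, g=0.0, n=1.4, n_photons=50_000, seed=11)


@pytest.fixture(scope="session")
def demo_bands():
    from sfdikit.demo import demo_filter_curves, demo_led_spectra

    return build_all_bands(demo_led_spectra(), demo_filter_curves())


@pytest.fixture(scope="session")
def selected_bands(demo_bands):
    names = select_bands(demo_bands)
    by_name = {b.name: b for b in demo_bands}
    return tuple(by_name[n] for n in names)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
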