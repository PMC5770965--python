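import numpy as np
import pytest

from phibind import (
    AcquisitionConfig,
    KineticScheme,
    generate_dataset,
    make_panel,
)
from phibind.pipeline import RunConfig, fit_dataset
from phibind.synthetic_data import PanelConfig


@pytest.fixture(scope="session")
def worked_scheme():
    """Three-state scheme used as the running worked example throughout."""
    return KineticScheme(k_on=1e6, k_off=1.0, k_f=5.0, k_u=0.5)


@pytest.fixture(scope="session")
def default_panel():
    return make_panel(seed=1)


@pytest.fixture(scope="session")
def noiseless_acquisition():
    return AcquisitionConfig(
        trace_noise_sd=0.0, anisotropy_noise_sd=0.0, competition_rel_noise=0.0
    )


@pytest.fixture(scope="session")
def noiseless_records(default_panel, noiseless_acquisition):
    """Zero-noise dataset fitted end to end (shared: it is the slow part)."""
    ds = generate_dataset(default_panel, noiseless_acquisition, seed=1)
    return fit_dataset(ds)


@pytest.fixture(scope="session")
def run_config():
    return RunConfig(seed=1)


@pytest.fixture()
def small_panel_config():
    """A trimmed panel for pipeline/file-roundtrip tests."""
    return PanelConfig(
        interface_positions={"helix_A": (121,), "kink": (128,), "helix_B": (137,)},
        surface_positions={"helix_A": (119,), "helix_B": (132,)},
    )


@pytest.fixture()
def small_acquisition():
    return AcquisitionConfig(
        partner_concs_M=tuple(3e-6 * (i + 1) for i in range(6)),
        n_time_points=300,
        n_replicates=2,
    )


def random_schemes(n, seed, three_state_fraction=0.8):
    """Random positive-rate schemes spanning several decades."""
    rng = np.random.default_rng(seed)
    schemes = []
    for _ in range(n):
        k_on = 10 ** rng.uniform(4, 8)
        k_off = 10 ** rng.uniform(-2, 2)
        if rng.random() < three_state_fraction:
            k_f = 10 ** rng.uniform(-2, 2)
            k_u = 10 ** rng.uniform(-2, 2)
        else:
            k_f = k_u = 0.0
        schemes.append(KineticScheme(k_on=k_on, k_off=k_off, k_f=k_f, k_u=k_u))
    return schemes
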