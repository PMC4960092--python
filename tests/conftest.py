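import numpy as np
import pytest

from pfrkit import PhantomSpec, make_volume_waveform, render_pc_series, render_ssfp_stack


@pytest.fixture(scope="session")
def spec():
    """Default phantom: 62 bpm, EDV 150 / ESV 65 mL, VENC 150 cm/s."""
    return PhantomSpec()


@pytest.fixture(scope="session")
def small_spec():
    """Same heart on a 96x96 matrix — faster to render, geometry still fits."""
    return PhantomSpec(matrix=96)


@pytest.fixture(scope="session")
def waveform(spec):
    return make_volume_waveform(spec)


@pytest.fixture(scope="session")
def noise_free_series(small_spec):
    return render_pc_series(small_spec.with_(noise_sd_velocity=0.0))


@pytest.fixture(scope="session")
def exact_stack(small_spec):
    return render_ssfp_stack(small_spec, mode="exact")


@pytest.fixture()
def rng():
    return np.random.default_rng(20160725)
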