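import numpy as np
import pytest

from wfom import io_cli, mbll, spectra, synth


@pytest.fixture(scope="session")
def ext_table():
    return spectra.load_extinction()


@pytest.fixture(scope="session")
def pathlengths():
    return io_cli.load_pathlength_fixture()


@pytest.fixture(scope="session")
def blood():
    return spectra.BloodAssumptions()


def channel_specs(table, pathlengths, wavelengths=(("green", 530.0), ("red", 630.0))):
    specs = []
    for name, wl in wavelengths:
        xi = mbll.extinction_matrix(table, [wl])[0]
        specs.append(synth.ReflChannelSpec(name, xi[0], xi[1], pathlengths.x(wl)))
    return specs


@pytest.fixture(scope="session")
def phantom():
    return synth.make_scene(seed=3)


@pytest.fixture(scope="session")
def phantom_hemo_truth(phantom):
    """Truth concentration movies wrapped as a HemoMovie."""
    return mbll.HemoMovie(
        d_hbo=phantom.d_hbo,
        d_hbr=phantom.d_hbr,
        valid=np.ones(phantom.d_hbo.shape[1:], dtype=bool),
        baseline_window=phantom.baseline_window,
    )


def rel_rms(estimate, truth):
    scale = np.sqrt(np.mean(np.asarray(truth) ** 2))
    if scale == 0:
        return float(np.sqrt(np.mean(np.asarray(estimate) ** 2)))
    return float(np.sqrt(np.mean((np.asarray(estimate) - np.asarray(truth)) ** 2)) / scale)
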