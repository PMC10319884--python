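import numpy as np
import pytest

import mirhsi as M


@pytest.fixture(scope="session")
def cfg():
    return M.OpticalConfig()


@pytest.fixture(scope="session")
def cfg_full():
    """The instrument's stated spectral sampling (1069 bands)."""
    return M.OpticalConfig(n_bands=1069)


@pytest.fixture(scope="session")
def library():
    return M.default_library()


@pytest.fixture(scope="session")
def mir(cfg):
    return M.generate_mir_pulse(cfg)


@pytest.fixture(scope="session")
def chirped(cfg):
    return M.generate_chirped_pulse(cfg)


@pytest.fixture(scope="session")
def microchannel_noiseless(cfg, library):
    """Noiseless microchannel cube, its background and retrieved transmittance."""
    phantom = M.make_phantom("microchannel5")
    cube, background = M.simulate_cube(phantom, library, cfg, seed=11, noise=False)
    _, cal = M.generate_chirped_pulse(cfg)
    tcube = M.retrieve_cube(cube, background, cal)
    return phantom, cube, background, tcube


@pytest.fixture(scope="session")
def microchannel_noisy(cfg, library):
    """Microchannel cube at the 2.77% frame-noise level."""
    phantom = M.make_phantom("microchannel5")
    cube, background = M.simulate_cube(phantom, library, cfg, seed=12, noise=True)
    _, cal = M.generate_chirped_pulse(cfg)
    tcube = M.retrieve_cube(cube, background, cal)
    return phantom, cube, background, tcube


def teaching_from_truth(tcube, phantom, seed=5, n_regions=8):
    """Teaching regions sampled inside each channel's true extent."""
    constraint = M.RegionConstraint(x_min=1, x_max=6, y_min=1, y_max=12,
                                    area_min=2, area_max=60, n_regions=n_regions)
    class_labels = {name: lab for lab, name in sorted(phantom.legend.items())}
    return M.sample_teaching_regions(tcube.data, constraint, seed=seed,
                                     label_map=phantom.labels,
                                     class_labels=class_labels)
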