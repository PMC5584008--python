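import warnings

import pytest

from ecleanse import composite_scene, make_test_suite_scenes, run_ec


@pytest.fixture(scope="session")
def scenes():
    """The canonical named test scenes (one fixed seed for the whole session)."""
    return make_test_suite_scenes(seed=7)


@pytest.fixture(scope="session")
def composite():
    """Full-size composite scene: (volume, truth, spec)."""
    return composite_scene(seed=1)


@pytest.fixture(scope="session")
def ec_result(composite):
    """run_ec output on the composite scene: (input volume, truth, output, report)."""
    vol, truth, _spec = composite
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out, report = run_ec(vol)
    return vol, truth, out, report
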