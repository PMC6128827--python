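import warnings

import numpy as np
import pytest

from snarezip.conditions import rupture_scheme
from snarezip.dwell import extract_latencies
from snarezip.polymer import ConstructSpec
from snarezip.simulate import ForceProtocol, NoiseModel, simulate


@pytest.fixture(scope="session")
def spec() -> ConstructSpec:
    return ConstructSpec()


def simulate_jump_dwells(
    spec,
    scheme,
    target_force,
    n_dwells,
    seed,
    window_s=120.0,
    sampling_rate=100.0,
):
    """Simulate serial force-jump traces and extract unzip latencies."""
    traces = []
    protocol = ForceProtocol.jump(10.0, target_force, 1.0, window_s)
    rng = np.random.default_rng(seed)
    for _ in range(n_dwells):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            traces.append(
                simulate(
                    scheme,
                    protocol,
                    spec,
                    NoiseModel(1.0),
                    sampling_rate,
                    seed=int(rng.integers(2**31)),
                    stop_after_first_transition_s=2.0,
                )
            )
    return extract_latencies(traces, target_force)


@pytest.fixture(scope="session")
def no_cpx_rupture():
    return rupture_scheme("none", include_snap25=False)
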