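"""Shared fixtures.

The expensive incremental-estimation runs are session-scoped and use a
reduced sampling grid (11 equidistant points instead of the protocol default
of 21) so the whole suite stays within a few minutes on one CPU; the
generator's noise and kinetics settings are the protocol defaults.
"""

from dataclasses import replace

import numpy as np
import pytest

from splineflux.dynamics import DynamicModel
from splineflux.estimation import incremental_estimate
from splineflux.synthetic import (builtin_protocol, sample_measurements,
                                  simulate_truth)

RECOVERY_N_TIME = 11


@pytest.fixture(scope="session")
def small_case():
    """(net, basis, kinetics, protocol) of the batch case study."""
    return builtin_protocol("small_low_noise")


@pytest.fixture(scope="session")
def small_truth(small_case):
    net, basis, kin, proto = small_case
    return simulate_truth(net, basis, kin, proto)


@pytest.fixture(scope="session")
def realistic_measurements(small_case, small_truth):
    net, basis, kin, proto = small_case
    proto_r = replace(proto, noise="relative")
    return sample_measurements(small_truth, proto_r, seed=3)


@pytest.fixture(scope="session")
def lownoise_recovery_run(small_case):
    """Full incremental run on low-noise data at the reduced grid, together
    with the truth used to generate it."""
    net, basis, kin, proto = small_case
    proto_r = replace(proto,
                      sampling_times=np.linspace(0.0, 20.0, RECOVERY_N_TIME))
    truth = simulate_truth(net, basis, kin, proto_r)
    ms = sample_measurements(truth, proto_r, seed=1)
    model = DynamicModel(net=net, basis=basis)
    fit = incremental_estimate(ms, model, proto_r.output_map)
    return {"net": net, "basis": basis, "truth": truth, "measurements": ms,
            "model": model, "fit": fit, "protocol": proto_r}
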