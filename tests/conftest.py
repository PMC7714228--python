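import numpy as np
import pytest

from emgsynergy import nmf, simulate
from emgsynergy.preprocess import preprocess


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


#: short blocks keep unit tests fast; the generator default mirrors the
#: full recording protocol (5 s movement / 3 s rest)
SMALL_PROTOCOL = simulate.Protocol(movement_duration=0.5, rest_duration=0.25)
TINY_PROTOCOL = simulate.Protocol(movement_duration=0.4, rest_duration=0.2)


@pytest.fixture
def small_protocol():
    return SMALL_PROTOCOL


def make_pool(k_true=3, n_electrodes=10, seed=0, noise_sd=0.1, carrier=True,
              protocol=SMALL_PROTOCOL):
    """Ground truth -> raw recording -> pooled envelope, in one call."""
    truth = simulate.make_ground_truth(n_electrodes, k_true, seed=seed,
                                       noise_sd=noise_sd, protocol=protocol)
    rec = simulate.synthesize(truth, seed=seed + 1, carrier=carrier)
    return truth, preprocess(rec)


def toy_model(W, H, E=None):
    """Assemble a SynergyModel from explicit factors (for typing tests)."""
    W = np.asarray(W, dtype=float)
    H = np.asarray(H, dtype=float)
    R = W @ H
    if E is None:
        E = R
    return nmf.SynergyModel(
        W=W, H=H, k=W.shape[1],
        global_vaf=nmf.vaf_global(E, R),
        local_vaf=nmf.vaf_local(E, R),
        seed=0, iterations_run=0,
    )
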