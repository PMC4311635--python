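import logging

import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

logging.getLogger("spikegc").setLevel(logging.ERROR)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_network(F, sig_mask=None, center=0.0, space="original"):
    """Hand-built pruned network for metric tests."""
    from spikegc.granger import GCNetwork

    F = np.asarray(F, dtype=float)
    n = F.shape[0]
    if sig_mask is None:
        sig_mask = F > 0
    return GCNetwork(
        node_ids=list(range(n)),
        F=np.where(sig_mask, F, 0.0),
        pvalues=None,
        sig_mask=np.asarray(sig_mask, dtype=bool),
        window_center=center,
        space_tag=space,
    )
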