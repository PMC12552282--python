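import numpy as np
import pytest

from ctiq import assess_roi, phantom_suite


@pytest.fixture(scope="session")
def suite():
    """The default 30-phantom fixture grid (sigma x correlation x blur)."""
    return phantom_suite(base_seed=0)


@pytest.fixture(scope="session")
def suite_by_params(suite):
    return {
        (t.spec.noise_sigma, t.spec.noise_corr_sigma, t.spec.edge_blur_sigma): t
        for t in suite
    }


@pytest.fixture(scope="session")
def suite_results(suite):
    """Full-pipeline assessment of every noisy phantom in the suite."""
    out = {}
    for truth in suite:
        s = truth.spec
        if s.noise_sigma == 0:
            continue
        out[(s.noise_sigma, s.noise_corr_sigma, s.edge_blur_sigma)] = assess_roi(truth.image)
    return out
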