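import numpy as np
import pytest

from phytospec import synthetic as syn


@pytest.fixture(scope="session")
def clean_study():
    """Default-size study without planted defects (shared, read-only)."""
    return syn.generate_study(
        syn.SyntheticConfig(seed=3, artifact_fraction=0.0)
    )


@pytest.fixture(scope="session")
def default_study():
    """Default study with the configured 10% planted defects."""
    return syn.generate_study(syn.SyntheticConfig(seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_valid_readings(rng, n):
    """Random PAM readings satisfying the yield ordering, as a dict of arrays."""
    fm = rng.uniform(0.3, 0.7, n)
    f0 = fm * rng.uniform(0.1, 0.5, n)
    f0p = f0 * rng.uniform(0.5, 1.0, n)
    fmp = f0p + (fm - f0p) * rng.uniform(0.05, 1.0, n)
    fs = f0p + (fmp - f0p) * rng.uniform(0.0, 0.999, n)
    return {"F0": f0, "Fm": fm, "Fs": fs, "Fm_prime": fmp, "F0_prime": f0p}
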