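"""Shared fixtures: small synthetic discs generated at test time."""

import numpy as np
import pytest

from discquant import SimConfig, simulate_disc


@pytest.fixture(scope="session")
def clean_disc():
    """Noise-free default-geometry disc with full ground truth."""
    cfg = SimConfig(seed=42, noise_sd=0.0)
    return simulate_disc(cfg)


@pytest.fixture(scope="session")
def noisy_disc():
    """Default disc at the study noise level."""
    cfg = SimConfig(seed=43)
    return simulate_disc(cfg)


@pytest.fixture(scope="session")
def small_disc_config():
    """Compact geometry used where many discs must be simulated."""
    return dict(
        shape=(10, 90, 90),
        pouch_semiaxes=(4.5, 34.0, 40.0),
        n_patches=1,
        target_coverage=0.35,
        channels=("gfp", "death"),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
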