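import numpy as np
import pytest

import sweatpk as sp


def random_rates(rng: np.random.Generator) -> sp.RateConstants:
    """In-bounds random draw of the eight rate constants."""
    return sp.RateConstants(
        k1=rng.uniform(0.01, 10.0),
        **{f"k{i}": rng.uniform(0.0, 0.2) for i in range(2, 9)},
    )


@pytest.fixture(scope="session")
def c2_design():
    return sp.DESIGNS["C2"]


@pytest.fixture(scope="session")
def noise_free_profile(c2_design):
    """One noise-free C.2 profile with duplicates and its ground truth."""
    rng = np.random.default_rng(7)
    truth = sp.sample_ground_truth(rng, c2_design)
    table, _ = sp.generate_profile(
        truth, c2_design, sp.NoiseModel(technical_cv=0.0), seed=1
    )
    return table, truth


@pytest.fixture(scope="session")
def noise_free_fit(noise_free_profile):
    """Multi-start fit of the noise-free profile (shared: it is slow)."""
    table, truth = noise_free_profile
    config = sp.FitConfig(n_starts=20, rng_seed=3, alphas=(2.0,))
    return sp.fit_profile(table, sp.PKConstants(), config), truth, table
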