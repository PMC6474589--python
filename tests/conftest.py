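import numpy as np
import pandas as pd
import pytest

import methclock as mc


@pytest.fixture
def toy_identity_clock():
    """Two-probe identity clock with a hand-checkable score."""
    return mc.ClockDefinition(
        name="toy", intercept=0.5, weights={"p1": 1.0, "p2": -0.5},
        transform="identity",
    )


@pytest.fixture
def toy_betas():
    return mc.BetaMatrix(pd.DataFrame(
        {"s1": [0.8, 0.4], "s2": [0.2, 0.6]}, index=["p1", "p2"]
    ))


@pytest.fixture(scope="session")
def noiseless_scenario():
    """Horvath-like platform-dropout scenario with zero measurement noise."""
    return mc.horvath_like_scenario(seed=11, n_samples=200, noise_sd=0.0)


@pytest.fixture(scope="session")
def noiseless_cohort(noiseless_scenario):
    return mc.generate_cohort(noiseless_scenario.spec)


def random_missing_frame(rng, n_probes, n_samples, missing_frac):
    """Beta frame with holes, always keeping at least one complete probe."""
    vals = rng.uniform(0.05, 0.95, size=(n_probes, n_samples))
    holes = rng.random((n_probes, n_samples)) < missing_frac
    holes[0, :] = False  # guarantee a complete row
    vals[holes] = np.nan
    ids = [f"cg{i:04d}" for i in range(n_probes)]
    samples = [f"s{j}" for j in range(n_samples)]
    return pd.DataFrame(vals, index=ids, columns=samples)
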