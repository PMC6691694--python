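import numpy as np
import pandas as pd
import pytest

from radnomics.cohort import PhantomParams, generate_tumor_phantom


@pytest.fixture(scope="session")
def small_params() -> PhantomParams:
    """A small, fast phantom geometry used across tests."""
    return PhantomParams(
        n_patients=10,
        grid_shape=(32, 32, 16),
        voxel_spacing=(0.9, 0.9, 5.0),
        tumor_radius_range=(5.0, 8.0),
        rng_seed=7,
    )


@pytest.fixture(scope="session")
def small_patient(small_params):
    """One deterministic phantom patient (pair, mask)."""
    return generate_tumor_phantom(small_params, 0, heterogeneity=0.6)


def simulate_survival(n, betas, x=None, seed=0, censor=(36.0, 68.0), lam0=0.01):
    """Plain exponential proportional-hazards survival simulator (test oracle

    for parameter recovery; independent of the cohort generator)."""
    rng = np.random.default_rng(seed)
    if x is None:
        x = rng.normal(size=(n, len(np.atleast_1d(betas))))
    x = np.asarray(x, dtype=float).reshape(n, -1)
    lp = x @ np.atleast_1d(betas)
    t_event = rng.exponential(1.0 / (lam0 * np.exp(lp)))
    t_cens = rng.uniform(*censor, size=n)
    event = t_event <= t_cens
    time = np.where(event, t_event, t_cens)
    df = pd.DataFrame({"time": time, "event": event.astype(int)})
    for j in range(x.shape[1]):
        df[f"x{j}"] = x[:, j]
    return df
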