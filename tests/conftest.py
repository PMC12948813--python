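import numpy as np
import pandas as pd
import pytest

import ergsurf as es


def make_bilinear_dataset(n_units=4, n_t=12, n_fs=6, beta0=5.0, noise=0.0, seed=0):
    """Noise-free (or noisy) data from a bilinear truth b0 + c1*t + c2*fs + c3*t*fs.

    A bilinear surface lies in the null space of second-order difference
    penalties in both directions, so a penalized fit reproduces it exactly
    at any smoothing level when noise is zero.
    """
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, 30.0, n_t)
    fs = np.linspace(12.0, 446.0, n_fs)
    rows = []
    for u in range(n_units):
        for f in fs:
            mu = beta0 + 0.15 * t - 0.004 * f + 0.0008 * t * f
            y = mu + (rng.normal(0, noise, n_t) if noise else 0.0)
            rows.append(pd.DataFrame({
                "subject_id": f"s{u:02d}",
                "eye": "right",
                "group": "g",
                "flash_td_s": f,
                "time_ms": t,
                "amplitude_uv": y,
            }))
    return es.WaveformDataset(pd.concat(rows, ignore_index=True))


@pytest.fixture(scope="session")
def bilinear_data():
    return make_bilinear_dataset()


@pytest.fixture(scope="session")
def small_spec():
    return es.ModelSpec(k_t=8, k_fs=5)


@pytest.fixture(scope="session")
def bilinear_fit(bilinear_data, small_spec):
    return es.fit_gam(bilinear_data, small_spec, group="g")


@pytest.fixture(scope="session")
def synthetic_fit():
    """Small but realistic synthetic ERG fit shared across surface tests."""
    design = es.DesignTable.balanced(8, groups=("control",))
    params = es.SyntheticParams(n_samples=40)
    data, truth = es.generate_dataset(design, params, seed=1)
    model = es.fit_gam(data, es.ModelSpec(k_t=12, k_fs=6), group="control")
    return model, truth, params
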