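import numpy as np
import pytest

from fmisovox import GridGeometry, PhantomConfig, generate_phantom


@pytest.fixture(scope="session")
def small_config():
    """A compact phantom (64x64x40 voxels, ~4k-voxel tumor) for fast tests."""
    return PhantomConfig(
        grid_shape=(64, 64, 40),
        tumor_center_mm=(32.0, 32.0, 40.0),
        tumor_radii_mm=(14.0, 13.0, 11.0),
        hypoxia_center_mm=(36.0, 32.0, 40.0),
        hypoxia_radii_mm=(6.0, 5.0, 4.0),
        muscle_centers_mm=((11.0, 11.0, 40.0), (11.0, 53.0, 40.0),
                           (53.0, 11.0, 40.0), (53.0, 53.0, 40.0)),
        seed=42,
    )


@pytest.fixture(scope="session")
def small_phantom(small_config):
    return generate_phantom(small_config)


def make_uniform_table(n, p_event, a=None, b=None, rng=None, tmr_lo=0.5, tmr_hi=2.5):
    """Voxel table with TMR ~ Uniform(tmr_lo, tmr_hi) and labels drawn either
    Bernoulli(p_event) (null) or from the logistic law expit(a + b * tmr)."""
    import pandas as pd
    from scipy.special import expit

    rng = rng or np.random.default_rng(0)
    tmr = rng.uniform(tmr_lo, tmr_hi, size=n)
    if a is None:
        p = np.full(n, p_event)
    else:
        p = expit(a + b * tmr)
    y = rng.random(n) < p
    return pd.DataFrame(
        {
            "patient_id": "sim",
            "i": np.arange(n),
            "j": 0,
            "k": 0,
            "tmr": tmr,
            "label": np.where(y, "ovl", "non_ovl"),
        }
    )
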