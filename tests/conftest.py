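import numpy as np
import pytest

from sedflux import CoreContext, SoluteProfile


@pytest.fixture
def baltic_context() -> CoreContext:
    """A core under the brackish, cold conditions of a deep Baltic basin."""
    return CoreContext(
        core_id="core-A",
        treatment="control",
        porosity=0.90,
        temperature_c=8.0,
        salinity=7.0,
        meiofauna_abundance=128.0,
        overlying_o2=280.0,
    )


@pytest.fixture
def linear_o2_profile() -> SoluteProfile:
    """O2 declining linearly at −200 μM/mm over the top 1.5 mm."""
    depths = np.arange(0.0, 1.6, 0.1)
    return SoluteProfile("O2", depths, 300.0 - 200.0 * depths, 100.0)


def ols_oracle(x, y):
    """Closed-form normal-equations least squares (slope, intercept)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xm, ym = x.mean(), y.mean()
    slope = np.sum((x - xm) * (y - ym)) / np.sum((x - xm) ** 2)
    return slope, ym - slope * xm
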