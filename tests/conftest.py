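import numpy as np
import pytest
from scipy import stats


@pytest.fixture
def grid49():
    """The default 49-level quantile grid, 0.02 ... 0.98."""
    return np.arange(1, 50) / 50.0


def normal_quantiles(taus, mean=0.0, sd=1.0):
    """Exact Gaussian quantile values on a grid of levels."""
    return stats.norm.ppf(taus, loc=mean, scale=sd)
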