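import numpy as np
import pytest
from hypothesis import settings

from iclvault import BiometryRecord, DEFAULT_COEFFICIENTS

settings.register_profile("ci", derandomize=True)
settings.load_profile("ci")


@pytest.fixture
def population_mean_record() -> BiometryRecord:
    """An eye at the validation-population mean biometry."""
    return BiometryRecord(sts_horizontal=11.54, sts_vertical=11.96, lens_thickness=3.67)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240715)


def record_with_prediction(target: float, size: float = 12.6) -> BiometryRecord:
    """Construct biometry whose predicted vault at ``size`` equals ``target``.

    Holds STS at population means and solves for the lens thickness, which
    must land inside its plausible range.
    """
    c = DEFAULT_COEFFICIENTS
    base = c.intercept + c.coef_size * size + c.coef_sts_h * 11.54 + c.coef_sts_v * 11.96
    lt = (target - base) / c.coef_lt
    return BiometryRecord(sts_horizontal=11.54, sts_vertical=11.96, lens_thickness=lt)
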