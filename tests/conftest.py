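import numpy as np
import pytest

from radiokinetics import I131
from radiokinetics import reference as ref
from radiokinetics.biokinetics import (
    TimeActivityCurve,
    TimeActivitySample,
    evaluate,
)


@pytest.fixture(scope="session")
def blood_q():
    """Published decay-corrected blood model q(t)=89.8e^-1.520t + 10.2e^-0.029t."""
    return ref.BLOOD_MODEL_BIOLOGICAL


@pytest.fixture(scope="session")
def blood_a():
    """Published effective blood model A(t)=89.8e^-1.524t + 10.2e^-0.033t."""
    return ref.BLOOD_MODEL_EFFECTIVE


@pytest.fixture(scope="session")
def organ_df_table():
    return ref.derived_organ_df_table()


def make_noise_free_curve(model, times, decay_corrected):
    vals = np.asarray(evaluate(model, times))
    return TimeActivityCurve(
        region=model.region,
        samples=[
            TimeActivitySample(time_h=float(t), value_pct_ia=float(v),
                               decay_corrected=decay_corrected)
            for t, v in zip(times, vals)
        ],
    )


@pytest.fixture(scope="session")
def blood_curve_q(blood_q):
    """12 noise-free samples of the decay-corrected blood model."""
    times = [0.25, 0.5, 1, 2, 3, 5, 8, 24, 48, 96, 120, 144]
    return make_noise_free_curve(blood_q, times, decay_corrected=True)


@pytest.fixture(scope="session")
def nuclide():
    return I131
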