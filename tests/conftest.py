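import numpy as np
import pytest
from hypothesis import settings

from maptrial.exposure import MAPObservation, MAPSeries

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def make_series(times, maps, doses=None, patient_id="P0001"):
    """Build a MAPSeries from parallel sequences (doses optional)."""
    if doses is None:
        doses = [None] * len(times)
    return MAPSeries(
        patient_id=patient_id,
        observations=tuple(
            MAPObservation(t=float(t), map=float(m), ne_dose=d)
            for t, m, d in zip(times, maps, doses)
        ),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


def random_series(rng, max_hours=120.0, pre_map=95.0):
    """A random 4-hourly-ish MAP series straddling the pre-illness MAP."""
    n = int(rng.integers(2, 31))
    times = np.cumsum(rng.uniform(0.5, 6.0, size=n))
    times = times[times <= max_hours]
    if times.size < 2:
        times = np.array([0.0, 4.0])
    maps = np.clip(rng.normal(pre_map, 18.0, size=times.size), 30.0, 175.0)
    return make_series(times, maps)
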