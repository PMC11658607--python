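import numpy as np
import pytest

from dyadcrqa.events import ACTORS, DyadRecord
from dyadcrqa.series import DEFAULT_ITEMS, OFF, CategoricalSeries


def make_series(values, labels=DEFAULT_ITEMS, rate=10.0, name=""):
    return CategoricalSeries(np.asarray(values, dtype=object), labels=labels,
                             rate_hz=rate, name=name)


def random_series(rng, n, labels=("A", "B", "C"), p_off=0.2, rate=10.0, name=""):
    pool = list(labels) + [OFF]
    probs = [(1 - p_off) / len(labels)] * len(labels) + [p_off]
    vals = rng.choice(pool, size=n, p=probs)
    return make_series(vals, labels=labels, rate=rate, name=name)


def make_record(turn_vals, gaze_t, gaze_u, point_t=None, point_u=None,
                labels=DEFAULT_ITEMS, rate=10.0, dyad_id="d0"):
    n = len(turn_vals)
    off = [OFF] * n
    return DyadRecord(
        dyad_id=dyad_id,
        gaze_trained=make_series(gaze_t, labels, rate, "gaze_trained"),
        gaze_untrained=make_series(gaze_u, labels, rate, "gaze_untrained"),
        point_trained=make_series(point_t or off, labels, rate, "point_trained"),
        point_untrained=make_series(point_u or off, labels, rate, "point_untrained"),
        turn=CategoricalSeries(np.asarray(turn_vals, dtype=object), labels=ACTORS,
                               rate_hz=rate, name="turn"),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_events_csv():
    return (
        "dyad_id,actor,track,category,onset_s,offset_s\n"
        "d1,trained,turn,trained,0.0,1.0\n"
        "d1,untrained,turn,untrained,1.0,2.0\n"
        "d1,trained,gaze,A,0.0,0.5\n"
        "d1,trained,gaze,B,0.5,1.2\n"
        "d1,untrained,gaze,A,0.2,0.9\n"
        "d1,trained,point,A,0.1,0.4\n"
    )
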