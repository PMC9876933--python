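import datetime as dt

import pytest

from hypnokit import Hypnogram, Stage


def make_hypnogram(tokens, start="07:00", kind="daytime"):
    """Build a hypnogram from stage tokens; 'AW*12' repeats a stage."""
    stages = []
    for tok in tokens:
        if "*" in tok:
            stage, n = tok.split("*")
            stages.extend([Stage(stage)] * int(n))
        else:
            stages.append(Stage(tok))
    h, m = (int(p) for p in start.split(":"))
    return Hypnogram(
        stages=tuple(stages),
        start_time=dt.time(h, m),
        lights_off=dt.time(19, 0),
        lights_on=dt.time(7, 0),
        kind=kind,
    )


@pytest.fixture
def hyp():
    return make_hypnogram
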