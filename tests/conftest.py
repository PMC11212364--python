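import pytest

from epgkit import CodeMap, GeneratorProfile, Mark, generate_recording, periods_from_marks
from epgkit.waveforms import D, PPD, TERMINAL_CODE


def build_recording(seq, code11=PPD, file_name="test.ana", treatment=1):
    """Build a Recording from [(label, duration), ...] with cumulative times."""
    cmap = CodeMap(code11=code11)
    marks, t = [], 0.0
    for label, dur in seq:
        marks.append(Mark(code=cmap.code(label), time=t))
        t += dur
    marks.append(Mark(code=TERMINAL_CODE, time=t))
    return periods_from_marks(marks, cmap, file_name=file_name, treatment=treatment)


@pytest.fixture
def build():
    return build_recording


@pytest.fixture
def aphid_recording():
    rec, _ = generate_recording(GeneratorProfile(seed=7, preset="aphid"))
    return rec


@pytest.fixture
def psyllid_recording():
    rec, _ = generate_recording(GeneratorProfile(seed=11, preset="psyllid"))
    return rec
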