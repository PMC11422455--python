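import numpy as np
import pytest

from rwakit import io_psg, rwa_core, synth

# Compact night used throughout the unit tests: 5 min REM flanked by NREM.
SHORT_BLOCKS = (("W", 60.0), ("S1", 60.0), ("S2", 120.0), ("REM", 300.0),
                ("S3", 60.0))
REM_SPAN = (240.0, 540.0)  # start/end of the REM block in SHORT_BLOCKS


@pytest.fixture
def short_blocks():
    return SHORT_BLOCKS


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def atonia_recording():
    """Quiet-REM recording: atonia floor only, no planted activity."""
    spec = synth.SynthSignalSpec(hypnogram_spec=SHORT_BLOCKS,
                                 target_occupancy=0.0, seed=7)
    sig, hyp, truth = synth.generate_signal(spec)
    return io_psg.PSGRecording(signals=[sig], hypnogram=hyp), truth


def score_spec(spec: synth.SynthSignalSpec,
               cfg: rwa_core.DetectionConfig | None = None):
    """Generate a synthetic recording and run the full scoring pipeline."""
    sig, hyp, truth = synth.generate_signal(spec)
    rec = io_psg.PSGRecording(signals=[sig], hypnogram=hyp)
    return rwa_core.score_recording(rec, cfg), truth
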