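import numpy as np
import pytest

from pursuitlab import AnalysisConfig, SimulationConfig, simulate_session
from pursuitlab.preprocess import preprocess_recording
from pursuitlab.report import classify_session

TARGET_FRAME_MS = 1000.0 / 29.97


@pytest.fixture(scope="session")
def cfg():
    return AnalysisConfig()


def quiet_sim_config(**overrides):
    """Simulation config with artifacts off unless a test asks for them."""
    base = dict(
        n_subjects=1,
        seed=0,
        noise_sd=0.0,
        jitter_sd=0.0,
        blink_rate=0.0,
        saccade_rate=0.0,
        target_dropout=0.0,
        plate_offset=(0.0, 0.0),
        latency_ms=150.0,
        gain=1.0,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def default_session():
    """One full-noise session under the study defaults, analysed once."""
    rec, truth = simulate_session(SimulationConfig(n_subjects=1, seed=11))
    synced = preprocess_recording(rec, AnalysisConfig())
    peak, threshold = classify_session(synced, AnalysisConfig())
    return {"rec": rec, "truth": truth, "synced": synced,
            "peak": peak, "threshold": threshold}


def eye_trace(t, x, y, pupil=None, **kw):
    from pursuitlab import EyeTrace

    t = np.asarray(t, float)
    pupil = np.full(len(t), 4.0) if pupil is None else np.asarray(pupil, float)
    return EyeTrace(t=t, x=np.asarray(x, float), y=np.asarray(y, float),
                    pupil=pupil, **kw)
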