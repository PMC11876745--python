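import numpy as np
import pytest

from sleepconn import resp, synth


def deterministic_params(rate_bpm: float = 60.0) -> dict:
    """Noise-free, jitter-free breathing parameters (strictly periodic trace)."""
    p = synth.RespGenParams(rate_bpm, 0.0, 0.0, noise_sd=0.0)
    return {synth.AS: p, synth.QS: p}


def pure_timeline(label: str, duration: float = 120.0) -> synth.StateTimeline:
    return synth.StateTimeline(((label, 0.0, duration),), duration)


@pytest.fixture(scope="session")
def qs_trace():
    """Band-passed quiet-sleep trace: 120 s of default QS breathing."""
    trace = synth.generate_respiration(pure_timeline("QS"), seed=7)
    return resp.bandpass(trace)


@pytest.fixture(scope="session")
def as_trace():
    """Band-passed active-sleep trace: 120 s of default AS breathing."""
    trace = synth.generate_respiration(pure_timeline("AS"), seed=7)
    return resp.bandpass(trace)


@pytest.fixture(scope="session")
def metronome_trace():
    """Band-passed deterministic 60 bpm trace (all variability off)."""
    trace = synth.generate_respiration(pure_timeline("QS"),
                                       deterministic_params(60.0), seed=0)
    return resp.bandpass(trace)


@pytest.fixture(scope="session")
def study_edges():
    """Small null study: 8 infants, 24 runs, 10 nodes, participant variance."""
    return synth.simulate_study_connectomes(
        n_infants=8, n_runs=24, n_qs_runs=8, n_qs_infants=4, n_nodes=10, seed=11)
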