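import numpy as np
import pytest

from orgephys import AnalysisConfig, StimulationProtocol


@pytest.fixture
def config() -> AnalysisConfig:
    return AnalysisConfig()


@pytest.fixture
def short_protocol() -> StimulationProtocol:
    """10 s baseline + 10 s stimulation with 500 ms pulses every 2 s."""
    return StimulationProtocol.periodic(10.0, 10.0, period=2.0,
                                        pulse_duration=0.5)


@pytest.fixture
def standard_protocol() -> StimulationProtocol:
    """The published protocol: 10 min baseline, then 500 ms pulses every
    10 s for 10 min."""
    return StimulationProtocol.periodic()


def greedy_match(true_times: np.ndarray, det_times: np.ndarray,
                 tol: float = 0.001) -> int:
    """Number of true spikes matched one-to-one by detections within tol."""
    det = np.sort(np.asarray(det_times))
    used = np.zeros(det.size, dtype=bool)
    hits = 0
    for t in np.sort(np.asarray(true_times)):
        if det.size == 0:
            break
        j = int(np.argmin(np.abs(det - t)))
        if abs(det[j] - t) <= tol and not used[j]:
            used[j] = True
            hits += 1
    return hits
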