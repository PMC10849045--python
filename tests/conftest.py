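import numpy as np
import pytest

from minidetect.recording import Recording
from minidetect.synth import SharpEventSpec, sharp_waveform

DT_MS = 0.1  # 10 kHz, the canonical sampling of the synthetic recordings


@pytest.fixture
def dt_ms() -> float:
    return DT_MS


def embed_events(waves: list[tuple[int, np.ndarray]], n_total: int, dt_ms: float = DT_MS) -> Recording:
    """Place waveforms at given onset sample indices on a zero baseline (summing overlaps)."""
    trace = np.zeros(n_total)
    for start, y in waves:
        end = min(n_total, start + y.size)
        trace[start:end] += y[: end - start]
    return Recording(sweeps=[trace], dt=dt_ms * 1e-3, unit_label="nA")


@pytest.fixture
def single_sharp_event():
    """One clean linear-rise/exponential-decay event (A=1, t_rise=2 ms, tau=10 ms)."""
    spec = SharpEventSpec(t_rise=2.0, amplitude=1.0, tau_decay=10.0)
    y, truth = sharp_waveform(spec, DT_MS)
    onset = 300
    rec = embed_events([(onset, y)], n_total=onset + y.size + 500)
    return rec, truth, onset, spec
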