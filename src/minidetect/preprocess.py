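"""Trace preprocessing: boxcar / Bessel filtering, baseline subtraction, averaging.

All operations return a new :class:`~minidetect.recording.Recording` of the
same shape; inputs are never mutated.
"""

from __future__ import annotations

from typing import Literal

import numpy as np
from scipy import signal

from .recording import Recording, TimeWindow

__all__ = ["boxcar_filter", "bessel_filter", "subtract_baseline", "average_sweeps"]


def _rebuild(recording: Recording, sweeps: list[np.ndarray]) -> Recording:
    return Recording(sweeps=sweeps, dt=recording.dt, unit_label=recording.unit_label, t0=recording.t0)


def boxcar_filter(recording: Recording, width: int) -> Recording:
    """Centered moving-average filter of odd ``width`` samples.

    Edges are reflect-padded so the output length equals the input length
    and baselines do not droop at the sweep ends.
    """
    if width % 2 == 0 or width < 1:
        raise ValueError(f"boxcar width must be odd and >= 1, got {width}")
    if width > recording.n_samples:
        raise ValueError("boxcar width exceeds sweep length")
    if width == 1:
        return _rebuild(recording, [s.copy() for s in recording.sweeps])
    h = width // 2
    kernel = np.full(width, 1.0 / width)
    out = []
    for s in recording.sweeps:
        padded = np.pad(s, h, mode="reflect")
        out.append(np.convolve(padded, kernel, mode="valid"))
    return _rebuild(recording, out)


def bessel_filter(recording: Recording, order: int, cutoff_hz: float) -> Recording:
    """Zero-phase low-pass Bessel filter (forward-backward, DC gain 1).

    The two passes preserve event onset and peak times at the cost of an
    effective doubling of the filter order.
    """
    nyquist = 0.5 / recording.dt
    if not 0 < cutoff_hz < nyquist:
        raise ValueError(f"cutoff must lie in (0, {nyquist:g}) Hz, got {cutoff_hz}")
    if not 1 <= order <= 10:
        raise ValueError("bessel order must be in [1, 10]")
    sos = signal.bessel(order, cutoff_hz, btype="low", fs=1.0 / recording.dt, output="sos", norm="mag")
    return _rebuild(recording, [signal.sosfiltfilt(sos, s) for s in recording.sweeps])


def subtract_baseline(
    recording: Recording,
    mode: Literal["whole_trace_mean", "window_mean", "fixed_value"],
    window: TimeWindow | None = None,
    value: float = 0.0,
) -> Recording:
    """Subtract one scalar per sweep: its mean, a window mean, or a fixed value."""
    out = []
    for i, s in enumerate(recording.sweeps):
        if mode == "whole_trace_mean":
            offset = s.mean()
        elif mode == "window_mean":
            if window is None:
                raise ValueError("window_mean mode requires a window")
            seg, _ = recording.slice(window, sweep_index=i)
            if seg.size == 0:
                raise ValueError("baseline window contains no samples")
            offset = seg.mean()
        elif mode == "fixed_value":
            offset = value
        else:
            raise ValueError(f"unknown baseline mode {mode!r}")
        out.append(s - offset)
    return _rebuild(recording, out)


def average_sweeps(recording: Recording) -> Recording:
    """Pointwise mean across sweeps (no time alignment is attempted)."""
    mean = np.mean(np.stack(recording.sweeps), axis=0)
    return _rebuild(recording, [mean])
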