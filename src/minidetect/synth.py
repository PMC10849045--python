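"""Synthetic recordings of miniature synaptic events with known ground truth.

Two event shapes are generated:

* a product of a rising and a decaying exponential,
  ``y(t) = A' (1 - exp(-t/tau1)) exp(-t/tau2)``, whose rounded peak mimics
  membrane-potential minis.  The scale ``A'`` is chosen per event so the
  curve's maximum equals the drawn target amplitude, since the maximum
  depends on both time constants;
* a sharper piecewise shape — linear ramp to ``A`` over ``t_rise`` followed
  by a single-exponential decay ``A exp(-(t - t_rise)/tau_decay)`` — which
  approximates voltage-clamp current events.

Ground-truth kinetics (10-90% rise time, time after the peak to decay to
1/e of the peak) are computed from the analytic curve itself, not from the
shape parameters, because both time constants of the biexponential shape
influence both quantities.

Events are separated by flat baseline spacers of uniformly random integer
length (default 100-500 samples, i.e. 10-50 ms at the default 10 kHz
sampling).  Noise models: a pure sine (default 0.02 units, 1 ms period),
correlated Gaussian noise formed by summing independent draws over an
11-sample window, and mains "hum" (default 0.2 units at 20 ms period,
i.e. 50 Hz).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .recording import Recording

__all__ = [
    "BiexpEventSpec",
    "SharpEventSpec",
    "GroundTruthEvent",
    "biexp_waveform",
    "sharp_waveform",
    "true_kinetics",
    "build_recording",
    "add_sine_noise",
    "add_correlated_noise",
    "add_hum",
    "biexp_sampler",
    "sharp_sampler",
    "truth_to_frame",
    "HUM_BENCH_GAUSS_SD",
]

# Correlated-noise sd for the hum benchmark: chosen so that a +-3 sd
# excursion of the 11-term summed noise is +-0.1 units (0.6 peak-to-peak
# together with the 0.2-amplitude hum).
HUM_BENCH_GAUSS_SD = 0.1 / (3.0 * math.sqrt(11.0))

_BISECT_TOL_MS = 1e-9


@dataclass(frozen=True)
class BiexpEventSpec:
    """Rise-times-decay product event; times in ms, amplitude in signal units."""

    tau1: float
    tau2: float
    amplitude: float

    @property
    def t_max(self) -> float:
        """Evaluation length, 5*(tau1 + tau2) ms: the tail is < exp(-5) ~ 1%."""
        return 5.0 * (self.tau1 + self.tau2)

    @property
    def peak_offset(self) -> float:
        """Closed-form time of the maximum, tau1 * ln(1 + tau2/tau1) ms."""
        return self.tau1 * math.log1p(self.tau2 / self.tau1)


@dataclass(frozen=True)
class SharpEventSpec:
    """Linear rise over ``t_rise`` ms to ``amplitude``, then exp decay with ``tau_decay`` ms."""

    t_rise: float
    amplitude: float
    tau_decay: float

    @property
    def t_max(self) -> float:
        return self.t_rise + 5.0 * self.tau_decay

    @property
    def peak_offset(self) -> float:
        return self.t_rise


EventSpec = BiexpEventSpec | SharpEventSpec


@dataclass(frozen=True)
class GroundTruthEvent:
    """Generator-side truth for one event (absolute times in seconds, kinetics in ms)."""

    onset_time: float
    peak_time: float
    amplitude: float
    rise_10_90: float
    tau_1e: float
    spec: EventSpec

    @property
    def shape(self) -> str:
        return "biexp" if isinstance(self.spec, BiexpEventSpec) else "sharp"


def _biexp_unit(t: np.ndarray | float, tau1: float, tau2: float):
    t = np.asarray(t, dtype=float)
    return (1.0 - np.exp(-t / tau1)) * np.exp(-t / tau2)


def true_kinetics(
    curve: Callable[[float], float],
    peak_time_ms: float,
    amplitude: float,
    t_hi_ms: float | None = None,
) -> tuple[float, float]:
    """10-90% rise time and 1/e decay time of an analytic event curve.

    ``curve`` maps time in ms from event onset to signal value, is 0 at
    t=0, rises to ``amplitude`` at ``peak_time_ms`` and decays after it.
    Crossings are found by bisection to 1e-9 ms.  Returns
    ``(rise_10_90_ms, tau_1e_ms)``; ``tau_1e`` is measured from the peak.
    """
    def _cross(level: float, lo: float, hi: float) -> float:
        return brentq(lambda t: curve(t) - level, lo, hi, xtol=_BISECT_TOL_MS)

    t10 = _cross(0.1 * amplitude, 0.0, peak_time_ms)
    t90 = _cross(0.9 * amplitude, t10, peak_time_ms)
    if t_hi_ms is None:
        t_hi_ms = peak_time_ms + max(peak_time_ms, 1.0)
        while curve(t_hi_ms) > amplitude / math.e:
            t_hi_ms = peak_time_ms + 2.0 * (t_hi_ms - peak_time_ms)
    t_1e = _cross(amplitude / math.e, peak_time_ms, t_hi_ms)
    return t90 - t10, t_1e - peak_time_ms


def biexp_waveform(spec: BiexpEventSpec, dt_ms: float) -> tuple[np.ndarray, GroundTruthEvent]:
    """Sampled biexponential event plus its analytic ground truth.

    The returned truth has ``onset_time = 0``; callers embedding the event
    in a trace shift the times.
    """
    if dt_ms <= 0:
        raise ValueError("dt_ms must be > 0")
    t_peak = spec.peak_offset
    unit_max = float(_biexp_unit(t_peak, spec.tau1, spec.tau2))
    scale = spec.amplitude / unit_max
    n = int(math.ceil(spec.t_max / dt_ms))
    t = np.arange(n) * dt_ms
    y = scale * _biexp_unit(t, spec.tau1, spec.tau2)
    rise, tau_1e = true_kinetics(
        lambda tt: scale * float(_biexp_unit(tt, spec.tau1, spec.tau2)),
        t_peak,
        spec.amplitude,
        t_hi_ms=spec.t_max * 4,
    )
    truth = GroundTruthEvent(
        onset_time=0.0,
        peak_time=t_peak * 1e-3,
        amplitude=spec.amplitude,
        rise_10_90=rise,
        tau_1e=tau_1e,
        spec=spec,
    )
    return y, truth


def sharp_waveform(spec: SharpEventSpec, dt_ms: float) -> tuple[np.ndarray, GroundTruthEvent]:
    """Sampled linear-rise/exponential-decay event plus exact ground truth."""
    if dt_ms <= 0:
        raise ValueError("dt_ms must be > 0")
    n = int(math.ceil(spec.t_max / dt_ms))
    t = np.arange(n) * dt_ms
    y = np.where(
        t <= spec.t_rise,
        spec.amplitude * t / spec.t_rise,
        spec.amplitude * np.exp(-(t - spec.t_rise) / spec.tau_decay),
    )
    truth = GroundTruthEvent(
        onset_time=0.0,
        peak_time=spec.t_rise * 1e-3,
        amplitude=spec.amplitude,
        rise_10_90=0.8 * spec.t_rise,
        tau_1e=spec.tau_decay,
        spec=spec,
    )
    return y, truth


def biexp_sampler(
    rng: np.random.Generator,
    tau1_range: tuple[float, float] = (2.0, 10.0),
    tau2_range: tuple[float, float] = (2.0, 15.0),
    amplitude_range: tuple[float, float] = (0.5, 2.5),
) -> BiexpEventSpec:
    """Default biexponential parameter draw: tau1~U(2,10), tau2~U(2,15), amp~U(0.5,2.5)."""
    return BiexpEventSpec(
        tau1=rng.uniform(*tau1_range),
        tau2=rng.uniform(*tau2_range),
        amplitude=rng.uniform(*amplitude_range),
    )


def sharp_sampler(
    rng: np.random.Generator,
    t_rise_range: tuple[float, float] = (0.5, 3.0),
    tau_decay_range: tuple[float, float] = (5.0, 25.0),
    amplitude_range: tuple[float, float] = (0.5, 2.5),
) -> SharpEventSpec:
    """Default sharp-event draw; decay range matches the mains-hum benchmark."""
    return SharpEventSpec(
        t_rise=rng.uniform(*t_rise_range),
        amplitude=rng.uniform(*amplitude_range),
        tau_decay=rng.uniform(*tau_decay_range),
    )


def build_recording(
    n_events: int,
    event_sampler: Callable[[np.random.Generator], EventSpec] = biexp_sampler,
    spacing_range_samples: tuple[int, int] = (100, 500),
    dt_ms: float = 0.1,
    seed: int | np.random.Generator = 0,
    unit_label: str = "nA",
) -> tuple[Recording, list[GroundTruthEvent]]:
    """Concatenate ``[spacer, event]`` segments into a noise-free recording.

    Spacer lengths are uniform random integers in ``spacing_range_samples``
    (closed range); a spacer also precedes the first event.  Deterministic
    for a fixed integer seed.  Returns the recording and the truth table in
    absolute time, sorted by onset.
    """
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lo, hi = spacing_range_samples
    segments: list[np.ndarray] = []
    truths: list[GroundTruthEvent] = []
    pos = 0
    dt_s = dt_ms * 1e-3
    for _ in range(n_events):
        spacer = int(rng.integers(lo, hi + 1))
        segments.append(np.zeros(spacer))
        pos += spacer
        spec = event_sampler(rng)
        if isinstance(spec, BiexpEventSpec):
            y, truth = biexp_waveform(spec, dt_ms)
        else:
            y, truth = sharp_waveform(spec, dt_ms)
        segments.append(y)
        onset = pos * dt_s
        truths.append(
            GroundTruthEvent(
                onset_time=onset,
                peak_time=onset + truth.peak_time,
                amplitude=truth.amplitude,
                rise_10_90=truth.rise_10_90,
                tau_1e=truth.tau_1e,
                spec=spec,
            )
        )
        pos += y.size
    # trailing baseline so the final decay is fully contained
    segments.append(np.zeros(lo))
    trace = np.concatenate(segments)
    rec = Recording(sweeps=[trace], dt=dt_s, unit_label=unit_label)
    return rec, truths


def _with_added(recording: Recording, terms: Sequence[np.ndarray]) -> Recording:
    return Recording(
        sweeps=[s + a for s, a in zip(recording.sweeps, terms)],
        dt=recording.dt,
        unit_label=recording.unit_label,
        t0=recording.t0,
    )


def add_sine_noise(recording: Recording, amplitude: float = 0.02, period_ms: float = 1.0) -> Recording:
    """Add ``amplitude * sin(2 pi t / period)`` to every sweep (t in ms)."""
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    t_ms = recording.times() * 1e3
    term = amplitude * np.sin(2.0 * np.pi * t_ms / period_ms)
    return _with_added(recording, [term] * recording.n_sweeps)


def add_correlated_noise(
    recording: Recording,
    gauss_sd: float = 0.02 / 5.0,
    sum_window: int = 11,
    seed: int | np.random.Generator = 0,
) -> Recording:
    """Add noise correlated over ``sum_window`` samples.

    Independent draws ``n_j ~ N(0, gauss_sd)`` are summed over a centered
    window: ``y_i += sum_{j=i-h}^{i+h} n_j`` with ``h = (sum_window-1)/2``.
    At the sweep edges the sum runs over existing indices only.  The
    interior noise term has sd ``sqrt(sum_window) * gauss_sd`` and lag-k
    autocorrelation ``(sum_window - k) / sum_window``.
    """
    if sum_window < 1 or sum_window % 2 == 0:
        raise ValueError("sum_window must be odd and >= 1")
    if gauss_sd < 0:
        raise ValueError("gauss_sd must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    kernel = np.ones(sum_window)
    terms = []
    for sweep in recording.sweeps:
        draws = rng.normal(0.0, gauss_sd, size=sweep.size)
        # zero padding outside the sweep == truncating the sum at the edges
        terms.append(np.convolve(draws, kernel, mode="same"))
    return _with_added(recording, terms)


def add_hum(recording: Recording, hum_amplitude: float = 0.2, hum_period_ms: float = 20.0) -> Recording:
    """Add mains hum: a sine of default 0.2 units at 20 ms period (50 Hz)."""
    return add_sine_noise(recording, amplitude=hum_amplitude, period_ms=hum_period_ms)


def truth_to_frame(truths: Sequence[GroundTruthEvent]) -> pd.DataFrame:
    """Ground-truth table with one row per event (times in s, kinetics in ms)."""
    rows = []
    for ev in truths:
        spec = ev.spec
        rows.append(
            {
                "onset_time_s": ev.onset_time,
                "peak_time_s": ev.peak_time,
                "amplitude": ev.amplitude,
                "rise_10_90_ms": ev.rise_10_90,
                "tau_1e_ms": ev.tau_1e,
                "shape": ev.shape,
                "tau1": getattr(spec, "tau1", np.nan),
                "tau2": getattr(spec, "tau2", np.nan),
                "t_rise": getattr(spec, "t_rise", np.nan),
                "tau_decay": getattr(spec, "tau_decay", np.nan),
            }
        )
    return pd.DataFrame(rows)
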