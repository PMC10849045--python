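"""Detection and measurement of miniature postsynaptic events.

The algorithm scans a sweep in half-overlapping windows (auto mode) or a
single user-centred window (manual mode) and takes the global extremum of
each window as a candidate peak.  From the peak it walks backward,
comparing each sample with a moving average of the preceding ``ma_window``
samples; the latest point strictly on the opposite side of that average
from the peak marks the sample just before the event, and the average
there is the baseline.  Amplitude, 10-90% rise time and half-width are
read off the trace with linear interpolation; the decay time constant
comes from a Levenberg-Marquardt fit of a single exponential
``B * exp(-t / tau)`` to the post-peak samples (or, optionally, from the
time to decay to 1/e of the amplitude).  Candidate peaks closer together
than a threshold can be split into compound events when a "valley" between
them returns toward baseline; the earlier event's fitted decay is then
subtracted to baseline the later one.  Events violating user amplitude /
rise / half-width / tau bounds are kept in the output with
``status="rejected"`` and the first violated criterion as the reason.

The public surface follows the model/results idiom:
``EventDetector(recording, params).fit()`` returns a
:class:`DetectionResult` holding the full event table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .recording import Recording

__all__ = [
    "DetectionParams",
    "DetectedEvent",
    "EventDetector",
    "DetectionResult",
    "scan_auto",
    "find_event_manual",
    "find_onset",
    "measure",
    "fit_decay",
    "resolve_compound",
    "apply_filters",
]

_FILTER_ORDER = ("amplitude", "rise", "halfwidth", "tau")


@dataclass(frozen=True)
class DetectionParams:
    """All user knobs of the event-detection algorithm.

    Times are in ms unless the name says otherwise; window sizes in
    samples.  ``direction`` is "positive" for events rising above the
    baseline (e.g. potentials), "negative" for inward currents.  Filter
    bounds left as ``None`` are not applied; an undefined measured value
    (e.g. a half-width that never returns to 50%) fails any bound set on
    that quantity.
    """

    direction: Literal["positive", "negative"] = "positive"
    auto_diameter_ms: float = 20.0
    search_radius_ms: float = 10.0
    ma_window: int = 100
    baseline_mode: Literal["moving_average", "fixed_left_window"] = "moving_average"
    fixed_offset_ms: float = 20.0
    fixed_window_ms: float = 2.0
    decay_method: Literal["lm_fit", "one_over_e"] = "lm_fit"
    decay_fit_max_ms: float | None = None  # None: 5x the 1/e estimate, else 50 ms
    compound_enabled: bool = False
    min_peak_separation_ms: float = 5.0
    valley_percent: float = 50.0
    min_amplitude: float | None = None
    max_amplitude: float | None = None
    min_rise_ms: float | None = None
    max_rise_ms: float | None = None
    min_halfwidth_ms: float | None = None
    max_halfwidth_ms: float | None = None
    min_tau_ms: float | None = None
    max_tau_ms: float | None = None

    def __post_init__(self) -> None:
        if self.auto_diameter_ms <= 0:
            raise ValueError("auto_diameter_ms must be > 0")
        if self.ma_window < 1:
            raise ValueError("ma_window must be >= 1")
        if not 0 < self.valley_percent <= 100:
            raise ValueError("valley_percent must be in (0, 100]")
        for name in ("amplitude", "rise_ms", "halfwidth_ms", "tau_ms"):
            lo = getattr(self, f"min_{name}")
            hi = getattr(self, f"max_{name}")
            if lo is not None and hi is not None and lo > hi:
                raise ValueError(f"min_{name} > max_{name}")

    @property
    def sign(self) -> float:
        return 1.0 if self.direction == "positive" else -1.0


@dataclass
class DetectedEvent:
    """One measured candidate event; rejected candidates carry the reason."""

    sweep_index: int
    onset_index: int
    onset_time_s: float
    peak_index: int
    peak_time_s: float
    baseline_value: float
    amplitude: float
    rise_10_90_ms: float
    halfwidth_ms: float
    tau_ms: float
    decay_fit_amplitude: float
    compound: bool = False
    status: Literal["accepted", "rejected"] = "accepted"
    reject_reason: str = ""
    baseline_warning: bool = False


# ---------------------------------------------------------------------------
# Measurement primitives.  All work on the *directed* trace: the raw sweep
# multiplied by the direction sign so events always point upward.
# ---------------------------------------------------------------------------


def find_onset(
    trace: np.ndarray,
    peak_index: int,
    params: DetectionParams,
    dt_ms: float,
) -> tuple[int, float, bool]:
    """Locate the event onset left of ``peak_index`` on a directed trace.

    Returns ``(onset_index, baseline_value, warning)`` where the baseline
    is the moving average at the crossing (or the fixed-window mean).  A
    run of samples exactly equal to the crossing sample is skipped forward
    so that degenerate, perfectly flat baselines place the onset at the
    first sample that departs from them; real noisy traces never tie
    exactly and are unaffected.
    """
    w = params.ma_window
    n = trace.size
    if peak_index <= 0 or peak_index >= n:
        raise ValueError("peak at trace edge; cannot measure onset")

    if params.baseline_mode == "fixed_left_window":
        j1 = peak_index - int(round(params.fixed_offset_ms / dt_ms))
        j0 = j1 - max(1, int(round(params.fixed_window_ms / dt_ms)))
        j0 = max(0, j0)
        if j1 <= j0:
            raise ValueError("fixed baseline window lies outside the trace")
        baseline = float(np.mean(trace[j0:j1]))
        seg = trace[:peak_index]
        below = np.flatnonzero(seg < baseline)
        if below.size:
            i_cross = int(below[-1])
            warn = False
        else:
            i_cross = j0
            warn = True
        onset = _skip_flat_run(trace, i_cross, peak_index)
        return onset, baseline, warn

    if peak_index <= w:
        raise ValueError(f"peak index {peak_index} <= ma_window {w}; no room for the baseline scan")

    # Backward block scan for the latest i in [w, peak-1] with
    # trace[i] strictly below its trailing moving average.
    cs = np.concatenate(([0.0], np.cumsum(trace[:peak_index])))
    hi = peak_index
    i_cross = -1
    block = 2048
    while hi > w:
        lo = max(w, hi - block)
        idx = np.arange(lo, hi)
        ma = (cs[idx] - cs[idx - w]) / w
        hit = np.flatnonzero(trace[idx] < ma)
        if hit.size:
            i_cross = int(idx[hit[-1]])
            baseline = float(ma[hit[-1]])
            break
        hi = lo
    if i_cross < 0:
        i_cross = w - 1
        baseline = float(np.mean(trace[:w]))
        warn = True
    else:
        warn = False
    onset = _skip_flat_run(trace, i_cross, peak_index)
    return onset, baseline, warn


def _skip_flat_run(trace: np.ndarray, i_cross: int, peak_index: int) -> int:
    """First sample after ``i_cross`` that departs from its exact value."""
    onset = i_cross + 1
    v = trace[i_cross] if i_cross >= 0 else trace[0]
    while onset < peak_index and trace[onset] == v:
        onset += 1
    # a crossing immediately before the peak (single-sample spike): keep
    # onset < peak so the candidate stays measurable (and filterable)
    return min(onset, peak_index - 1)


def _cross_before(trace: np.ndarray, lo: int, peak: int, level: float, dt_ms: float) -> float:
    """Time (ms) of the latest upward crossing of ``level`` before ``peak``."""
    seg = trace[lo : peak + 1]
    below = seg[:-1] < level
    above = seg[1:] >= level
    k = np.flatnonzero(below & above)
    if k.size == 0:
        # rising limb starts at/above the level; report the segment start
        return lo * dt_ms
    k = int(k[-1]) + lo
    frac = (level - trace[k]) / (trace[k + 1] - trace[k])
    return (k + frac) * dt_ms


def _cross_after(trace: np.ndarray, peak: int, stop: int, level: float, dt_ms: float) -> float:
    """Time (ms) of the first downward crossing of ``level`` after ``peak``; NaN if none."""
    seg = trace[peak:stop]
    if seg.size < 2:
        return math.nan
    above = seg[:-1] >= level
    below = seg[1:] < level
    k = np.flatnonzero(above & below)
    if k.size == 0:
        return math.nan
    k = int(k[0]) + peak
    frac = (trace[k] - level) / (trace[k] - trace[k + 1])
    return (k + frac) * dt_ms


def measure(
    trace: np.ndarray,
    onset_index: int,
    peak_index: int,
    baseline_value: float,
    dt_ms: float,
    stop_index: int | None = None,
) -> tuple[float, float, float]:
    """Amplitude, 10-90% rise time and half-width of one event (directed trace).

    Crossing times use linear interpolation between samples; the rise uses
    the latest crossings before the peak, the half-width pairs the 50%
    rise crossing with the first 50% crossing after the peak.  A decay that
    never returns to 50% before ``stop_index`` yields ``halfwidth = nan``.
    """
    if onset_index >= peak_index:
        raise ValueError("onset must precede peak")
    stop = trace.size if stop_index is None else stop_index
    amp = float(trace[peak_index] - baseline_value)
    if amp <= 0:
        return amp, math.nan, math.nan
    lo = max(0, onset_index - 1)
    t10 = _cross_before(trace, lo, peak_index, baseline_value + 0.1 * amp, dt_ms)
    t90 = _cross_before(trace, lo, peak_index, baseline_value + 0.9 * amp, dt_ms)
    t50r = _cross_before(trace, lo, peak_index, baseline_value + 0.5 * amp, dt_ms)
    t50d = _cross_after(trace, peak_index, stop, baseline_value + 0.5 * amp, dt_ms)
    rise = t90 - t10
    halfwidth = t50d - t50r if not math.isnan(t50d) else math.nan
    return amp, rise, halfwidth


def _one_over_e_time(y: np.ndarray, dt_ms: float) -> float:
    """Time for ``y`` (peak-anchored, baseline-subtracted) to fall to y[0]/e; NaN if never."""
    target = y[0] / math.e
    below = np.flatnonzero(y <= target)
    if below.size == 0 or below[0] == 0:
        return math.nan
    k = int(below[0])
    frac = (y[k - 1] - target) / (y[k - 1] - y[k])
    return (k - 1 + frac) * dt_ms


def fit_decay(
    trace: np.ndarray,
    peak_index: int,
    baseline_value: float,
    params: DetectionParams,
    dt_ms: float,
    stop_index: int | None = None,
) -> tuple[float, float]:
    """Decay time constant (ms) and fitted amplitude after the peak.

    ``lm_fit`` performs a two-parameter Levenberg-Marquardt least-squares
    fit of ``B * exp(-t/tau)`` to ``trace - baseline`` for t >= 0 from the
    peak (the baseline is not free); ``one_over_e`` reads off the
    interpolated time to fall to 1/e of the peak amplitude.  The fitted
    span ends at the earliest of ``stop_index``, the sweep end, and
    ``decay_fit_max_ms`` (default: five times the 1/e estimate, or 50 ms
    when the trace never reaches 1/e).  Returns ``(nan, nan)`` when fewer
    than 5 samples are available or the fit fails.
    """
    stop = trace.size if stop_index is None else min(stop_index, trace.size)
    y = trace[peak_index:stop] - baseline_value
    if y.size < 2 or y[0] <= 0:
        return math.nan, math.nan
    t_e = _one_over_e_time(y, dt_ms)
    span_ms = params.decay_fit_max_ms
    if span_ms is None:
        span_ms = 5.0 * t_e if not math.isnan(t_e) else 50.0
    n_fit = min(y.size, max(2, int(round(span_ms / dt_ms)) + 1))
    if params.decay_method == "one_over_e":
        return t_e, float(y[0])
    if n_fit < 5:
        return math.nan, math.nan
    t = np.arange(n_fit) * dt_ms
    p0 = (float(y[0]), t_e if not math.isnan(t_e) else span_ms / 5.0)
    try:
        popt, _ = curve_fit(
            lambda tt, b, tau: b * np.exp(-tt / tau),
            t,
            y[:n_fit],
            p0=p0,
            method="lm",
            maxfev=400,
        )
    except RuntimeError:
        return math.nan, math.nan
    b, tau = float(popt[0]), float(popt[1])
    if not (tau > 0 and np.isfinite(tau)):
        return math.nan, math.nan
    return tau, b


def resolve_compound(
    earlier: DetectedEvent,
    later_peak_index: int,
    trace: np.ndarray,
    params: DetectionParams,
    dt_ms: float,
) -> tuple[bool, int, float]:
    """Decide whether a close later peak is a separate (compound) event.

    The pair is split when some sample between the peaks comes closer to
    the earlier event's baseline than ``valley_percent`` of the earlier
    amplitude.  The deepest such valley point becomes the later onset, and
    the earlier event's fitted decay, extrapolated to the later peak, is
    added to the earlier baseline to baseline the later event.

    Returns ``(is_separate, later_onset_index, later_baseline_value)``;
    when not separate the later extremum belongs to the earlier decay.
    """
    ep = earlier.peak_index
    if later_peak_index <= ep + 1:
        return False, -1, math.nan
    between = trace[ep + 1 : later_peak_index]
    dist = np.abs(between - earlier.baseline_value)
    threshold = (params.valley_percent / 100.0) * earlier.amplitude
    if not np.any(dist < threshold):
        return False, -1, math.nan
    valley = ep + 1 + int(np.argmin(dist))
    tau, b = earlier.tau_ms, earlier.decay_fit_amplitude
    if math.isnan(tau) or math.isnan(b):
        tau, b = fit_decay(
            trace, ep, earlier.baseline_value,
            replace(params, decay_method="one_over_e"), dt_ms,
        )
        b = trace[ep] - earlier.baseline_value
    if math.isnan(tau):
        return False, -1, math.nan
    t_from_peak = (later_peak_index - ep) * dt_ms
    later_baseline = earlier.baseline_value + b * math.exp(-t_from_peak / tau)
    return True, valley, float(later_baseline)


def apply_filters(event: DetectedEvent, params: DetectionParams) -> DetectedEvent:
    """Set accept/reject status; checks run amplitude -> rise -> halfwidth -> tau."""
    values = {
        "amplitude": event.amplitude,
        "rise": event.rise_10_90_ms,
        "halfwidth": event.halfwidth_ms,
        "tau": event.tau_ms,
    }
    bounds = {
        "amplitude": (params.min_amplitude, params.max_amplitude),
        "rise": (params.min_rise_ms, params.max_rise_ms),
        "halfwidth": (params.min_halfwidth_ms, params.max_halfwidth_ms),
        "tau": (params.min_tau_ms, params.max_tau_ms),
    }
    # a candidate whose extremum lies below its own baseline is never an event
    if event.amplitude <= 0:
        event.status, event.reject_reason = "rejected", "amplitude"
        return event
    for name in _FILTER_ORDER:
        lo, hi = bounds[name]
        if lo is None and hi is None:
            continue
        v = values[name]
        if math.isnan(v) or (lo is not None and v < lo) or (hi is not None and v > hi):
            event.status, event.reject_reason = "rejected", name
            return event
    event.status, event.reject_reason = "accepted", ""
    return event


# ---------------------------------------------------------------------------
# Candidate collection and the full per-sweep pipeline
# ---------------------------------------------------------------------------


def _window_candidates(s: np.ndarray, diameter: int) -> list[int]:
    """Global extrema of half-overlapping windows, deduplicated.

    An extremum on a window's first/last sample is deferred to the window
    where it lies interior; extrema at the sweep edges are dropped (no
    room to measure).
    """
    n = s.size
    d = min(diameter, n)
    step = max(1, d // 2)
    found: set[int] = set()
    start = 0
    while start < n:
        win = s[start : start + d]
        if win.size == 0:
            break
        cand = start + int(np.argmax(win))
        interior = (cand != start) and (cand != start + win.size - 1)
        if interior and 0 < cand < n - 1:
            found.add(cand)
        if start + d >= n:
            break
        start += step
    return sorted(found)


def _measure_candidates(
    sweep: np.ndarray,
    candidates: list[int],
    params: DetectionParams,
    dt_ms: float,
    t0: float,
    sweep_index: int,
) -> list[DetectedEvent]:
    sgn = params.sign
    s = sweep * sgn
    n = s.size
    dt_s = dt_ms * 1e-3

    events: list[DetectedEvent] = []
    for peak in candidates:
        try:
            onset, baseline, warn = find_onset(s, peak, params, dt_ms)
        except ValueError:
            continue
        events.append(
            DetectedEvent(
                sweep_index=sweep_index,
                onset_index=onset,
                onset_time_s=t0 + onset * dt_s,
                peak_index=peak,
                peak_time_s=t0 + peak * dt_s,
                baseline_value=baseline,
                amplitude=math.nan,
                rise_10_90_ms=math.nan,
                halfwidth_ms=math.nan,
                tau_ms=math.nan,
                decay_fit_amplitude=math.nan,
                baseline_warning=warn,
            )
        )

    # a candidate whose backward scan walked past the previous candidate's
    # peak is the same event seen from a different scan window (a noise bump
    # riding the top or decay); keep the highest extremum of each group.
    # A genuinely separate later event never merges: its onset lies after
    # the earlier peak (that case is the compound path's business).
    events.sort(key=lambda e: e.peak_index)
    merged: list[DetectedEvent] = []
    for ev in events:
        if merged and ev.onset_index <= merged[-1].peak_index:
            if s[ev.peak_index] > s[merged[-1].peak_index]:
                merged[-1] = ev
        else:
            merged.append(ev)
    events = merged

    # amplitude and rise need nothing right of the peak; screening on them
    # first means sub-threshold noise candidates are rejected before they
    # can bound a neighbouring event's decay fit ("proceeds to the next
    # peak": rejected candidates are not analysed further)
    survivors: list[DetectedEvent] = []
    for ev in events:
        amp = float(s[ev.peak_index] - ev.baseline_value)
        ev.amplitude = amp
        if amp > 0:
            _, rise, _ = measure(s, ev.onset_index, ev.peak_index, ev.baseline_value, dt_ms, ev.peak_index + 2)
            ev.rise_10_90_ms = rise
        if _prescreen(ev, params):
            survivors.append(ev)

    # the next surviving candidate's onset bounds each decay
    for k, ev in enumerate(survivors):
        stop = survivors[k + 1].onset_index if k + 1 < len(survivors) else n
        stop = max(stop, ev.peak_index + 2)
        amp, rise, halfwidth = measure(s, ev.onset_index, ev.peak_index, ev.baseline_value, dt_ms, stop)
        tau, b = fit_decay(s, ev.peak_index, ev.baseline_value, params, dt_ms, stop)
        ev.rise_10_90_ms = rise
        ev.halfwidth_ms = halfwidth
        ev.tau_ms = tau
        ev.decay_fit_amplitude = b

    if params.compound_enabled:
        survivor_ids = {id(e) for e in survivors}
        kept = {id(e) for e in _resolve_compounds(s, survivors, params, dt_ms, t0)}
        events = [e for e in events if id(e) not in survivor_ids or id(e) in kept]

    for ev in events:
        apply_filters(ev, params)
        # report baseline in the original polarity
        ev.baseline_value *= sgn
    return events


def _prescreen(ev: DetectedEvent, params: DetectionParams) -> bool:
    """Amplitude/rise screening applied before any post-peak measurement."""
    if ev.amplitude <= 0:
        ev.status, ev.reject_reason = "rejected", "amplitude"
        return False
    lo, hi = params.min_amplitude, params.max_amplitude
    if (lo is not None and ev.amplitude < lo) or (hi is not None and ev.amplitude > hi):
        ev.status, ev.reject_reason = "rejected", "amplitude"
        return False
    lo, hi = params.min_rise_ms, params.max_rise_ms
    if (lo is not None or hi is not None) and (
        math.isnan(ev.rise_10_90_ms)
        or (lo is not None and ev.rise_10_90_ms < lo)
        or (hi is not None and ev.rise_10_90_ms > hi)
    ):
        ev.status, ev.reject_reason = "rejected", "rise"
        return False
    return True


def _resolve_compounds(
    s: np.ndarray,
    events: list[DetectedEvent],
    params: DetectionParams,
    dt_ms: float,
    t0: float,
) -> list[DetectedEvent]:
    """Split chains of close peaks into compound events.

    The pair decision (valley test, later onset) is :func:`resolve_compound`.
    Along a chain (e.g. an evoked train) the later baseline subtracts the
    fitted decay of *every* earlier chain member from the chain's root
    baseline: each earlier mini keeps decaying, so extrapolating only the
    immediately preceding event's scalar baseline would overestimate the
    level the later event rides on.
    """
    min_sep = int(round(params.min_peak_separation_ms / dt_ms))
    out: list[DetectedEvent] = []
    k = 0
    while k < len(events):
        ev = events[k]
        out.append(ev)
        chain = [ev]
        root_baseline = ev.baseline_value
        j = k + 1
        while j < len(events) and events[j].peak_index - out[-1].peak_index < min_sep:
            later = events[j]
            sep, onset, _ = resolve_compound(out[-1], later.peak_index, s, params, dt_ms)
            if sep:
                baseline = root_baseline
                for member in chain:
                    tau, b = member.tau_ms, member.decay_fit_amplitude
                    if math.isnan(tau) or math.isnan(b):
                        continue
                    dt_peaks = (later.peak_index - member.peak_index) * dt_ms
                    baseline += b * math.exp(-dt_peaks / tau)
                later.onset_index = onset
                later.onset_time_s = t0 + onset * dt_ms * 1e-3
                later.baseline_value = baseline
                stop = events[j + 1].onset_index if j + 1 < len(events) else s.size
                stop = max(stop, later.peak_index + 2)
                amp, rise, halfwidth = measure(s, onset, later.peak_index, baseline, dt_ms, stop)
                tau, b = fit_decay(s, later.peak_index, baseline, params, dt_ms, stop)
                later.amplitude = amp
                later.rise_10_90_ms = rise
                later.halfwidth_ms = halfwidth
                later.tau_ms = tau
                later.decay_fit_amplitude = b
                later.compound = True
                out[-1].compound = True
                out.append(later)
                chain.append(later)
            # else: the later extremum is part of the earlier decay; drop it
            j += 1
        k = j
    return out


def scan_auto(recording: Recording, params: DetectionParams) -> list[DetectedEvent]:
    """Automatic detection over every sweep; returns accepted and rejected events.

    Each sweep is scanned in windows of ``auto_diameter_ms`` advanced by
    half a window per step; the result is sorted by (sweep, peak time).
    """
    dt_ms = recording.dt * 1e3
    d = max(2, int(round(params.auto_diameter_ms / dt_ms)))
    all_events: list[DetectedEvent] = []
    for si, sweep in enumerate(recording.sweeps):
        s = sweep * params.sign
        candidates = _window_candidates(s, d)
        all_events.extend(_measure_candidates(sweep, candidates, params, dt_ms, recording.t0, si))
    return all_events


def find_event_manual(
    recording: Recording,
    center_time: float,
    params: DetectionParams,
    sweep_index: int = 0,
) -> DetectedEvent | None:
    """Measure the single event nearest ``center_time`` (seconds).

    Takes the global extremum within ``search_radius_ms`` of the centre
    and runs the same measurement path as the automatic scan; returns
    ``None`` when the search window is empty.
    """
    dt_ms = recording.dt * 1e3
    sweep = recording.sweeps[sweep_index]
    r = int(round(params.search_radius_ms / dt_ms))
    c = int(round((center_time - recording.t0) / recording.dt))
    lo, hi = max(0, c - r), min(sweep.size, c + r + 1)
    if hi <= lo:
        return None
    s = sweep * params.sign
    peak = lo + int(np.argmax(s[lo:hi]))
    if peak <= 0 or peak >= sweep.size - 1:
        return None
    events = _measure_candidates(sweep, [peak], params, dt_ms, recording.t0, sweep_index)
    return events[0] if events else None


# ---------------------------------------------------------------------------
# Model / results wrappers
# ---------------------------------------------------------------------------


class EventDetector:
    """Miniature-event detection model for one recording.

    Parameters
    ----------
    recording
        The trace(s) to analyse.
    params
        Detection parameters; defaults detect positive events with a
        10 ms moving-average baseline at 10 kHz sampling.

    ``fit()`` runs the automatic scan and returns a
    :class:`DetectionResult`.
    """

    def __init__(self, recording: Recording, params: DetectionParams | None = None):
        self.recording = recording
        self.params = params or DetectionParams()

    @classmethod
    def from_csv(cls, path, dt: float, params: DetectionParams | None = None,
                 unit_label: str = "") -> "EventDetector":
        from .recording import read_recording_csv

        return cls(read_recording_csv(path, dt=dt, unit_label=unit_label), params)

    def fit(self) -> "DetectionResult":
        events = scan_auto(self.recording, self.params)
        return DetectionResult(self, events)

    def find_at(self, center_time: float, sweep_index: int = 0) -> DetectedEvent | None:
        """Manual-mode search around one time point."""
        return find_event_manual(self.recording, center_time, self.params, sweep_index)


class DetectionResult:
    """Holds the detected event table and convenience accessors."""

    def __init__(self, model: EventDetector, events: list[DetectedEvent]):
        self.model = model
        self.events = events

    @property
    def accepted(self) -> list[DetectedEvent]:
        return [e for e in self.events if e.status == "accepted"]

    @property
    def n_accepted(self) -> int:
        return len(self.accepted)

    def to_frame(self, accepted_only: bool = False) -> pd.DataFrame:
        """Event table with the canonical CSV columns."""
        rows = [
            {
                "sweep": e.sweep_index,
                "onset_time_s": e.onset_time_s,
                "peak_time_s": e.peak_time_s,
                "baseline": e.baseline_value,
                "amplitude": e.amplitude,
                "rise_10_90_ms": e.rise_10_90_ms,
                "halfwidth_ms": e.halfwidth_ms,
                "tau_ms": e.tau_ms,
                "compound": e.compound,
                "status": e.status,
                "reject_reason": e.reject_reason,
            }
            for e in self.events
            if not (accepted_only and e.status != "accepted")
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "sweep", "onset_time_s", "peak_time_s", "baseline", "amplitude",
                "rise_10_90_ms", "halfwidth_ms", "tau_ms", "compound", "status",
                "reject_reason",
            ],
        )

    def summary(self) -> str:
        acc = self.accepted
        rej = [e for e in self.events if e.status == "rejected"]
        lines = [
            "Miniature event detection",
            "=" * 40,
            f"sweeps:            {self.model.recording.n_sweeps}",
            f"samples per sweep: {self.model.recording.n_samples}",
            f"dt:                {self.model.recording.dt * 1e3:g} ms",
            f"direction:         {self.model.params.direction}",
            f"candidates:        {len(self.events)}",
            f"accepted:          {len(acc)}",
            f"rejected:          {len(rej)}",
        ]
        if acc:
            amps = np.array([e.amplitude for e in acc])
            taus = np.array([e.tau_ms for e in acc])
            lines += [
                f"mean amplitude:    {amps.mean():.4g} {self.model.recording.unit_label}",
                f"mean tau:          {np.nanmean(taus):.4g} ms",
            ]
        return "\n".join(lines)
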