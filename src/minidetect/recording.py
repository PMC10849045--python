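"""Core recording container and CSV/ABF readers and writers.

A :class:`Recording` holds a uniformly sampled, possibly multi-sweep time
series (membrane current or potential).  Time values are never stored: the
time of sample ``i`` is ``t0 + i * dt``, generated on demand.  Indices are
0-based and all time windows in this package are half-open ``[start, end)``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Recording",
    "TimeWindow",
    "read_recording_csv",
    "write_recording_csv",
    "read_abf",
]


@dataclass(frozen=True)
class TimeWindow:
    """Half-open time interval ``[start, end)`` in seconds."""

    start: float
    end: float

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"TimeWindow requires start < end, got [{self.start}, {self.end})")


@dataclass
class Recording:
    """A uniformly sampled multi-sweep recording.

    Parameters
    ----------
    sweeps
        Ordered collection of equal-length 1-D sample arrays (e.g. current
        in nA or pA, potential in mV).
    dt
        Sampling interval in seconds per sample; strictly positive.
    unit_label
        Free-text unit of the samples (label only; never converted).
    t0
        Time of the first sample of every sweep, in seconds.
    """

    sweeps: list[np.ndarray]
    dt: float
    unit_label: str = ""
    t0: float = 0.0
    _n: int = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError(f"dt must be > 0, got {self.dt}")
        if len(self.sweeps) == 0:
            raise ValueError("Recording requires at least one sweep")
        self.sweeps = [np.asarray(s, dtype=float).ravel() for s in self.sweeps]
        lengths = {s.size for s in self.sweeps}
        if len(lengths) != 1:
            raise ValueError(f"all sweeps must have identical length, got lengths {sorted(lengths)}")
        self._n = self.sweeps[0].size
        if self._n < 2:
            raise ValueError("sweeps must contain at least 2 samples")

    @property
    def n_sweeps(self) -> int:
        return len(self.sweeps)

    @property
    def n_samples(self) -> int:
        """Samples per sweep."""
        return self._n

    @property
    def duration(self) -> float:
        """Time spanned by one sweep in seconds, ``(n_samples - 1) * dt``."""
        return (self._n - 1) * self.dt

    def times(self) -> np.ndarray:
        """Sample times in seconds, generated on demand."""
        return self.t0 + np.arange(self._n) * self.dt

    def slice(self, window: TimeWindow, sweep_index: int = 0) -> tuple[np.ndarray, int]:
        """Samples of one sweep whose times fall in ``[window.start, window.end)``.

        Returns
        -------
        samples, first_index
            The selected samples and the index of the first selected sample.
            An empty overlap yields an empty array (``first_index`` is the
            index the first sample would have had).
        """
        sweep = self.sweeps[sweep_index]
        # smallest i with t0 + i*dt >= start
        i0 = max(0, int(np.ceil((window.start - self.t0) / self.dt - 1e-12)))
        # smallest i with t0 + i*dt >= end (excluded)
        i1 = min(self._n, int(np.ceil((window.end - self.t0) / self.dt - 1e-12)))
        i1 = max(i1, i0)
        return sweep[i0:i1], i0


def read_recording_csv(path: str | Path, dt: float, unit_label: str = "") -> Recording:
    """Read a recording from CSV: one numeric column per sweep.

    An optional single header row is auto-detected (first row non-numeric).
    A two-column ``time,value`` file (first header cell ``time``) is also
    accepted; the time column is discarded and ``dt`` still comes from the
    argument, since CSV carries no sampling rate.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        rows = [r for r in csv.reader(fh) if r and any(c.strip() for c in r)]
    if not rows:
        raise ValueError(f"{path}: empty file")

    def _numeric(row: list[str]) -> bool:
        try:
            [float(c) for c in row]
            return True
        except ValueError:
            return False

    header: list[str] | None = None
    if not _numeric(rows[0]):
        header = [c.strip().lower() for c in rows[0]]
        rows = rows[1:]
        if not rows:
            raise ValueError(f"{path}: header but no data rows")

    drop_first = header is not None and header[0] == "time"

    width = len(rows[0])
    data = np.empty((len(rows), width), dtype=float)
    for i, row in enumerate(rows):
        if len(row) != width:
            raise ValueError(f"{path}: ragged row {i + 1}: expected {width} columns, got {len(row)}")
        try:
            data[i] = [float(c) for c in row]
        except ValueError as exc:
            raise ValueError(f"{path}: non-numeric cell in data row {i + 1}: {exc}") from None

    if drop_first:
        data = data[:, 1:]
        if data.shape[1] == 0:
            raise ValueError(f"{path}: 'time' column present but no value columns")
    return Recording(sweeps=[data[:, j].copy() for j in range(data.shape[1])], dt=dt, unit_label=unit_label)


def write_recording_csv(recording: Recording, path: str | Path) -> None:
    """Write one column per sweep at full float precision (repr round-trip)."""
    path = Path(path)
    cols = recording.sweeps
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        for i in range(recording.n_samples):
            writer.writerow([repr(float(c[i])) for c in cols])


def read_abf(path: str | Path, channel: int = 0) -> Recording:
    """Read one channel of an Axon Binary Format (v1/v2) file.

    Requires the optional ``pyabf`` dependency; ABF writing is unsupported.
    """
    try:
        import pyabf
    except ImportError as exc:  # pragma: no cover - depends on extras
        raise ImportError(
            "reading ABF files requires the optional dependency 'pyabf' "
            "(pip install minidetect[abf])"
        ) from exc
    abf = pyabf.ABF(str(path))
    if channel not in abf.channelList:
        raise ValueError(
            f"{path}: channel {channel} not present; available channels: {list(abf.channelList)}"
        )
    sweeps = []
    for sweep_number in abf.sweepList:
        abf.setSweep(sweep_number, channel=channel)
        sweeps.append(np.asarray(abf.sweepY, dtype=float).copy())
    unit = abf.adcUnits[channel] if channel < len(abf.adcUnits) else ""
    return Recording(sweeps=sweeps, dt=1.0 / abf.dataRate, unit_label=unit)
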