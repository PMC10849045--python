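"""Per-sweep extrema statistics for evoked responses."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .recording import Recording, TimeWindow

__all__ = ["EvokedSummary", "sweep_extrema"]


@dataclass
class EvokedSummary:
    """Minimum/maximum per sweep and their across-sweep mean and sample sd."""

    per_sweep_min: np.ndarray
    per_sweep_max: np.ndarray
    mean_min: float
    sd_min: float
    mean_max: float
    sd_max: float
    single_sweep: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sweep": np.arange(self.per_sweep_min.size),
             "min": self.per_sweep_min,
             "max": self.per_sweep_max}
        )


def sweep_extrema(recording: Recording, window: TimeWindow | None = None) -> EvokedSummary:
    """Min and max of each sweep (optionally within ``window``) plus summary stats.

    Standard deviations use the sample (N-1) denominator; a single sweep
    yields sd 0 with ``single_sweep`` flagged.
    """
    mins, maxs = [], []
    for i in range(recording.n_sweeps):
        if window is None:
            seg = recording.sweeps[i]
        else:
            seg, _ = recording.slice(window, sweep_index=i)
            if seg.size == 0:
                raise ValueError("window contains no samples")
        mins.append(seg.min())
        maxs.append(seg.max())
    mins = np.asarray(mins)
    maxs = np.asarray(maxs)
    single = recording.n_sweeps == 1
    return EvokedSummary(
        per_sweep_min=mins,
        per_sweep_max=maxs,
        mean_min=float(mins.mean()),
        sd_min=0.0 if single else float(mins.std(ddof=1)),
        mean_max=float(maxs.mean()),
        sd_max=0.0 if single else float(maxs.std(ddof=1)),
        single_sweep=single,
    )
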