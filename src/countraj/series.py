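"""Single-subject count series container.

A :class:`CountSeries` holds one subject's repeated count measurements at
strictly increasing observation times.  Missing days are represented by the
*absence* of rows, never by imputation: the spatial AR(1) working correlation
handles unequal gaps directly.  When per-observation exposure totals are
available (e.g. scheduled doses per subperiod) the model works on rates via
log-offsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["CountSeries"]


@dataclass(frozen=True)
class CountSeries:
    """Counts ``y`` observed at strictly increasing positive times ``t``.

    Parameters
    ----------
    times
        Strictly increasing, strictly positive observation times.
    counts
        Nonnegative integer counts, one per time.
    totals
        Optional positive exposure totals ``Y``; when present, offsets
        ``o = log(Y)`` convert the count model into a rate model and
        rates ``y' = y / Y`` are defined.
    """

    times: np.ndarray
    counts: np.ndarray
    totals: np.ndarray | None = None

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        counts = np.asarray(self.counts, dtype=float)
        if times.ndim != 1 or counts.ndim != 1 or times.size != counts.size:
            raise ValueError("times and counts must be 1-d arrays of equal length")
        if times.size < 1:
            raise ValueError("a series needs at least one observation")
        if np.any(times <= 0):
            raise ValueError("times must be strictly positive")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(counts < 0) or np.any(counts != np.round(counts)):
            raise ValueError("counts must be nonnegative integers")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "counts", counts)
        if self.totals is not None:
            totals = np.asarray(self.totals, dtype=float)
            if totals.shape != times.shape:
                raise ValueError("totals must match times in shape")
            if np.any(totals <= 0):
                raise ValueError("totals must be strictly positive")
            object.__setattr__(self, "totals", totals)

    @property
    def n(self) -> int:
        return self.times.size

    @property
    def offsets(self) -> np.ndarray:
        """Log-exposure offsets ``o = log(Y)``; zeros when no totals."""
        if self.totals is None:
            return np.zeros(self.n)
        return np.log(self.totals)

    @property
    def rates(self) -> np.ndarray:
        """Observed rates ``y' = y / Y``; requires totals."""
        if self.totals is None:
            raise ValueError("rates require totals")
        return self.counts / self.totals

    def subset(self, indices) -> "CountSeries":
        """Sub-series at the given sorted positional indices."""
        idx = np.asarray(indices, dtype=int)
        return CountSeries(
            times=self.times[idx],
            counts=self.counts[idx],
            totals=None if self.totals is None else self.totals[idx],
        )
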