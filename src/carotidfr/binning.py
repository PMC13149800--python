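"""Retrospective cardiac binning of continuously acquired readouts.

The free-running acquisition is ungated; pulse-oximeter trigger times are
used after the fact to sort readouts into non-overlapping cardiac phases.
The number of bins is the mean heartbeat duration divided by the bin
width (floored), so bins are duration-homogeneous; late-cycle readouts
beyond ``n_bins * width`` and readouts preceding the first trigger have
no well-defined phase and are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthdata import PhysioRecord

__all__ = ["BinAssignment", "mean_rr", "assign_bins"]

DISCARDED = -1


@dataclass
class BinAssignment:
    """Per-readout cardiac bin indices (``-1`` marks discarded readouts)."""

    bin_index: np.ndarray
    n_bins: int
    bin_width_ms: float
    mean_rr_ms: float

    def readouts_in_bin(self, b: int) -> np.ndarray:
        if not 0 <= b < self.n_bins:
            raise IndexError(f"bin {b} out of range [0, {self.n_bins})")
        return np.nonzero(self.bin_index == b)[0]

    def occupancy(self) -> np.ndarray:
        return np.bincount(self.bin_index[self.bin_index >= 0], minlength=self.n_bins)

    def to_frame(self, timestamps: np.ndarray) -> pd.DataFrame:
        """Audit table (readout_index, time_ms, bin)."""
        return pd.DataFrame(
            {
                "readout_index": np.arange(len(self.bin_index)),
                "time_ms": timestamps,
                "bin": self.bin_index,
            }
        )


def mean_rr(physio: PhysioRecord) -> float:
    """Arithmetic mean of successive trigger differences, in ms."""
    t = physio.trigger_times
    if len(t) < 2:
        raise ValueError("need at least 2 triggers to compute a mean RR interval")
    return float(np.mean(np.diff(t)))


def assign_bins(
    timestamps: np.ndarray, physio: PhysioRecord, bin_width_ms: float = 80.0
) -> BinAssignment:
    """Sort readouts into cardiac bins by offset from the preceding trigger.

    A readout at time ``t`` with preceding trigger ``tau`` falls in bin
    ``floor((t - tau) / bin_width_ms)``; bins at or beyond
    ``n_bins = floor(mean_rr / bin_width_ms)`` are discarded.
    """
    if bin_width_ms <= 0:
        raise ValueError("bin_width_ms must be positive")
    timestamps = np.asarray(timestamps, dtype=float)
    if np.any(np.diff(timestamps) < 0):
        raise ValueError("timestamps must be sorted")
    rr = mean_rr(physio)
    n_bins = int(np.floor(rr / bin_width_ms))
    if n_bins < 1:
        raise ValueError(
            f"bin width {bin_width_ms} ms is not smaller than the mean RR {rr:.1f} ms"
        )
    triggers = physio.trigger_times
    idx = np.searchsorted(triggers, timestamps, side="right") - 1
    offsets = timestamps - np.where(idx >= 0, triggers[np.clip(idx, 0, None)], 0.0)
    bins = np.floor(offsets / bin_width_ms).astype(np.int64)
    bins[(idx < 0) | (bins >= n_bins)] = DISCARDED
    return BinAssignment(
        bin_index=bins, n_bins=n_bins, bin_width_ms=float(bin_width_ms), mean_rr_ms=rr
    )
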