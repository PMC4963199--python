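"""Tidy time-course container shared by the simulator, generator, and fits."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Required tidy-CSV columns.
COLUMNS = ("time_s", "signal", "assay", "replicate")


@dataclass
class TimeCourse:
    """One assay's (time, signal) series.

    Times are in seconds, strictly increasing. ``condition`` distinguishes
    the IRES-programmed sample from the 80S-only control; ``meta`` carries
    provenance such as generator ground truth.
    """

    times: np.ndarray
    signal: np.ndarray
    assay: str
    replicate: int = 0
    condition: str = "ires"
    noise_sd: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.signal.shape:
            raise ValueError("times and signal must be 1-d arrays of equal length")
        if self.times.size and self.times[0] < 0:
            raise ValueError("times must be non-negative")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.times,
                "signal": self.signal,
                "assay": self.assay,
                "replicate": self.replicate,
                "condition": self.condition,
            }
        )


def to_frame(tcs: list[TimeCourse]) -> pd.DataFrame:
    """Concatenate time courses into one tidy frame."""
    if not tcs:
        return pd.DataFrame(columns=list(COLUMNS) + ["condition"])
    return pd.concat([tc.to_frame() for tc in tcs], ignore_index=True)
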