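"""Uniformly sampled scalar time series (LFP, MUA, rates, voltages)."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SignalSeries"]


@dataclass
class SignalSeries:
    """Samples at a fixed rate, with units and free-form channel metadata."""

    samples: np.ndarray
    fs_hz: float
    units: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("SignalSeries holds one scalar channel")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("SignalSeries samples must be finite")
        if self.fs_hz <= 0:
            raise ValueError("sampling rate must be > 0")

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.fs_hz

    @property
    def duration_ms(self) -> float:
        return self.samples.size * self.dt_ms

    def times_ms(self) -> np.ndarray:
        return np.arange(self.samples.size) * self.dt_ms

    def __len__(self) -> int:
        return self.samples.size
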