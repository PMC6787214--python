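"""Core container for a uniformly sampled single-lead ECG."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ECGSignal:
    """A uniformly sampled voltage series.

    Parameters
    ----------
    samples
        Voltage values, arbitrary units (raw ADC units, millivolts, or the
        unit interval after :func:`ecgpsr.preprocess.normalize`).
    fs
        Sampling rate in Hz.
    meta
        Free-form record metadata (record id, lead label, ...).
    """

    samples: np.ndarray
    fs: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("ECGSignal.samples must be one-dimensional")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.samples.size and not np.all(np.isfinite(self.samples)):
            raise ValueError("ECGSignal.samples must be finite")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(self.samples.size) / self.fs

    def copy_with(self, samples: np.ndarray) -> "ECGSignal":
        return ECGSignal(samples=np.asarray(samples, dtype=float),
                         fs=self.fs, meta=dict(self.meta))
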