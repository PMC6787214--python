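"""Denoising and normalization front end.

The pipeline's conditioning stage is a cascade of two zero-phase
Butterworth filters — a 1 Hz high-pass removing baseline wander and a
40 Hz low-pass removing muscle/powerline noise — followed by min-max
normalization of the whole record onto [0, 1]:

    x_n(t) = (x(t) - min x) / (max x - min x)

Zero-phase (forward-backward) application is used so that the filters do
not shift fiducial latencies.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .io import read_ecg  # noqa: F401  (re-exported: reading is part of the front end)
from .signal import ECGSignal

__all__ = ["read_ecg", "bandlimit", "normalize", "preprocess"]

DEFAULT_HP_HZ = 1.0
DEFAULT_LP_HZ = 40.0
DEFAULT_ORDER = 4


def bandlimit(ecg: ECGSignal,
              hp_hz: float = DEFAULT_HP_HZ,
              lp_hz: float = DEFAULT_LP_HZ,
              order: int = DEFAULT_ORDER) -> ECGSignal:
    """Apply the high-pass + low-pass Butterworth cascade, zero-phase.

    Both cutoffs must sit below the Nyquist frequency; output length and
    sampling rate equal the input's.
    """
    nyq = ecg.fs / 2.0
    if not 0 < hp_hz < lp_hz:
        raise ValueError(f"need 0 < hp_hz < lp_hz, got ({hp_hz}, {lp_hz})")
    if lp_hz >= nyq:
        raise ValueError(f"low-pass cutoff {lp_hz} Hz >= Nyquist {nyq} Hz")
    if order < 1:
        raise ValueError("filter order must be >= 1")
    x = ecg.samples
    if x.size == 0:
        return ecg.copy_with(x)
    sos_hp = sps.butter(order, hp_hz, btype="highpass", fs=ecg.fs, output="sos")
    sos_lp = sps.butter(order, lp_hz, btype="lowpass", fs=ecg.fs, output="sos")
    # generous reflection padding: the 1 Hz high-pass has a ~1 s impulse
    # response and the default padlen leaves visible end transients
    padlen = min(x.size - 1, int(3 * ecg.fs / hp_hz))
    y = sps.sosfiltfilt(sos_hp, x, padlen=padlen)
    y = sps.sosfiltfilt(sos_lp, y, padlen=min(x.size - 1, 3 * max(len(sos_lp) * 6, int(ecg.fs / lp_hz))))
    return ecg.copy_with(y)


def normalize(ecg: ECGSignal) -> ECGSignal:
    """Min-max normalize the record onto [0, 1].

    The record-wide minimum maps to 0 and the maximum to 1.  A constant
    record has no meaningful normalization and raises.
    """
    x = ecg.samples
    if x.size < 2:
        raise ValueError("need at least 2 samples to normalize")
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi == lo:
        raise ValueError("degenerate normalization: signal is constant")
    return ecg.copy_with((x - lo) / (hi - lo))


def preprocess(ecg: ECGSignal,
               hp_hz: float = DEFAULT_HP_HZ,
               lp_hz: float = DEFAULT_LP_HZ,
               order: int = DEFAULT_ORDER) -> ECGSignal:
    """Band-limit then normalize — the standard conditioning chain."""
    return normalize(bandlimit(ecg, hp_hz=hp_hz, lp_hz=lp_hz, order=order))
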