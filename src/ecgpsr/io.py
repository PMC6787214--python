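"""Reading and writing ECG records.

Two on-disk dialects are supported:

* CSV with a ``t,voltage`` header (time in seconds, one or more voltage
  columns), the format written by :func:`ecgpsr.synthetic.write_record_csv`.
* WFDB records (``.hea`` header + ``.dat`` signal file).  Only the common
  format-16 encoding (interleaved little-endian int16) is handled, which
  covers the PhysioNet records this pipeline targets.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from .signal import ECGSignal

__all__ = ["read_ecg", "read_csv_ecg", "read_wfdb_ecg", "write_wfdb_ecg"]

#: maximum relative deviation of the time step before a CSV is rejected
_MAX_DT_JITTER = 1e-3


def read_ecg(path, format: str | None = None, channel: int = 0) -> ECGSignal:
    """Read one channel of an ECG record as an :class:`ECGSignal`.

    ``format`` is ``"csv"`` or ``"wfdb"``; if omitted it is inferred from
    the file extension (``.hea``/``.dat`` -> wfdb, else csv).
    """
    path = Path(path)
    if format is None:
        format = "wfdb" if path.suffix in (".hea", ".dat") else "csv"
    if format == "csv":
        return read_csv_ecg(path, channel=channel)
    if format == "wfdb":
        return read_wfdb_ecg(path, channel=channel)
    raise ValueError(f"unknown format {format!r} (expected 'csv' or 'wfdb')")


def read_csv_ecg(path, channel: int = 0) -> ECGSignal:
    """Read a ``t,voltage`` CSV; fs is inferred from the time column.

    Raises if the time column is not uniform to within 0.1% of the median
    step (the downstream filters assume uniform sampling).
    """
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected a time column plus >= 1 voltage column")
    t = df.iloc[:, 0].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValueError(f"{path}: need at least 2 samples to infer fs")
    dt = np.diff(t)
    dt_med = float(np.median(dt))
    if dt_med <= 0:
        raise ValueError(f"{path}: time column must be strictly increasing")
    if np.max(np.abs(dt - dt_med)) > _MAX_DT_JITTER * dt_med:
        raise ValueError(f"{path}: non-uniform sampling in time column")
    n_channels = df.shape[1] - 1
    if not 0 <= channel < n_channels:
        raise ValueError(f"{path}: channel {channel} out of range "
                         f"(record has {n_channels})")
    v = df.iloc[:, 1 + channel].to_numpy(dtype=float)
    return ECGSignal(samples=v, fs=1.0 / dt_med,
                     meta={"path": str(path),
                           "lead": df.columns[1 + channel], "channel": channel})


def _parse_gain(token: str) -> tuple[float, float | None]:
    """Parse a WFDB gain token ``gain(baseline)/units`` -> (gain, baseline)."""
    m = re.match(r"([-+0-9.eE]+)(?:\(([-+0-9]+)\))?(?:/.*)?$", token)
    if not m:
        raise ValueError(f"cannot parse WFDB gain field {token!r}")
    gain = float(m.group(1))
    baseline = float(m.group(2)) if m.group(2) is not None else None
    return (gain if gain != 0 else 200.0), baseline


def read_wfdb_ecg(path, channel: int = 0) -> ECGSignal:
    """Read one channel of a WFDB format-16 record (``.hea`` + ``.dat``)."""
    path = Path(path)
    hea = path if path.suffix == ".hea" else path.with_suffix(".hea")
    if not hea.exists():
        raise FileNotFoundError(hea)
    lines = [ln for ln in hea.read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    head = lines[0].split()
    nsig = int(head[1])
    fs = float(head[2].split("/")[0]) if len(head) > 2 else 250.0
    nsamp = int(head[3]) if len(head) > 3 else None
    if not 0 <= channel < nsig:
        raise ValueError(f"{hea}: channel {channel} out of range (nsig={nsig})")

    sig_lines = lines[1:1 + nsig]
    specs = []
    for ln in sig_lines:
        f = ln.split()
        fmt = f[1].split("x")[0]
        if fmt != "16":
            raise ValueError(f"{hea}: unsupported WFDB format {fmt!r} "
                             "(only format 16 is handled)")
        gain, baseline = _parse_gain(f[2]) if len(f) > 2 else (200.0, None)
        adc_zero = float(f[4]) if len(f) > 4 else 0.0
        if baseline is None:
            baseline = adc_zero
        specs.append({"file": f[0], "gain": gain, "baseline": baseline})

    dat = hea.parent / specs[channel]["file"]
    raw = np.fromfile(dat, dtype="<i2")
    if nsig > 1:
        raw = raw[: (len(raw) // nsig) * nsig].reshape(-1, nsig)
        adc = raw[:, channel]
    else:
        adc = raw
    if nsamp is not None:
        adc = adc[:nsamp]
    spec = specs[channel]
    v = (adc.astype(float) - spec["baseline"]) / spec["gain"]
    return ECGSignal(samples=v, fs=fs,
                     meta={"path": str(hea), "channel": channel,
                           "record": head[0]})


def write_wfdb_ecg(signals: ECGSignal | list[ECGSignal], record_path,
                   gain: float = 2000.0) -> None:
    """Write channel(s) as a WFDB format-16 record (single .dat file)."""
    if isinstance(signals, ECGSignal):
        signals = [signals]
    record_path = Path(record_path)
    name = record_path.name
    fs = signals[0].fs
    n = min(len(s) for s in signals)
    adc = np.column_stack(
        [np.clip(np.round(s.samples[:n] * gain), -32768, 32767) for s in signals]
    ).astype("<i2")
    dat_name = f"{name}.dat"
    lines = [f"{name} {len(signals)} {fs:g} {n}"]
    for i, s in enumerate(signals):
        lead = s.meta.get("lead", f"ch{i}")
        lines.append(f"{dat_name} 16 {gain:g}(0)/mV 16 0 0 0 0 {lead}")
    record_path.with_suffix(".hea").write_text("\n".join(lines) + "\n")
    adc.tofile(record_path.parent / dat_name)
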