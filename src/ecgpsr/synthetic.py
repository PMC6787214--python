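"""Synthetic single-lead ECG with analytically known fiducial ground truth.

Each beat is a sum of smooth Gaussian bumps (one per wave: P; Q, R, S; T),
so every fiducial point has a closed-form location: a wave is defined to
start and end at +/-3 sigma of its bump.  Records are built as a block of
healthy beats followed by a block of unhealthy beats, emulating a subject
whose rhythm transitions from a normal regime into an arrhythmic one.

The unhealthy morphology regimes model, qualitatively, the feature-level
disturbances of common cardiovascular conditions:

``af_like``
    atrial-fibrillation-like: P wave suppressed, strongly irregular RR.
``bbb_like``
    bundle-branch-block-like: widened, notched (two-peaked) QRS.
``long_qt_like``
    prolonged QT with a widened T wave.

No claim of clinical fidelity is made; the regimes exist to give the
downstream phase-portrait statistics a controlled healthy/unhealthy
contrast with known per-beat labels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .signal import ECGSignal

__all__ = [
    "BeatSpec",
    "SyntheticRecord",
    "generate_record",
    "truth_feature_durations",
    "default_healthy_spec",
    "default_unhealthy_spec",
    "write_record_csv",
    "read_truth_json",
]

MORPHOLOGY_REGIMES = ("healthy", "af_like", "bbb_like", "long_qt_like")

#: Default per-wave peak heights (arbitrary units, R-normalized).
DEFAULT_AMPLITUDES = {"P": 0.15, "Q": -0.08, "R": 1.0, "S": -0.18, "T": 0.35}

# Fractions fixing wave geometry inside the intervals they define.
_P_FRACTION_OF_PR = 0.65     # P wave occupies the leading part of PR
_T_FRACTION_OF_JT = 0.60     # T width as fraction of (QT - QRS)
_T_FRACTION_OF_JT_WIDE = 0.75  # widened T for the long-QT regime


@dataclass(frozen=True)
class BeatSpec:
    """Target durations and morphology for one class of beats.

    Durations are in milliseconds: ``pr_ms`` (P onset to QRS onset),
    ``qrs_ms`` (QRS onset to offset), ``qt_ms`` (QRS onset to T offset)
    and ``rr_ms`` (beat-to-beat period).  ``duration_jitter`` is the
    relative standard deviation applied per beat to each duration and
    ``amplitude_jitter`` the one applied to each wave's peak height;
    ``rr_jitter`` overrides the duration jitter for the RR period (the
    af_like regime uses a much larger value).  Unhealthy presets carry
    substantially larger jitters than healthy beats — beat-to-beat
    variability of both timing and morphology is what makes arrhythmic
    phase portraits chaotic.
    """

    pr_ms: float = 160.0
    qrs_ms: float = 90.0
    qt_ms: float = 380.0
    rr_ms: float = 800.0
    amplitudes: dict = field(default_factory=lambda: dict(DEFAULT_AMPLITUDES))
    morphology_regime: str = "healthy"
    duration_jitter: float = 0.002
    amplitude_jitter: float = 0.001
    morphology_drift: float = 0.0
    ectopic_rate: float = 0.0
    ectopic_scale: float = 1.2
    p_variability: float = 0.0
    baseline_shift_sd: float = 0.0
    chaos_bumps: float = 0.0
    rr_jitter: Optional[float] = 0.005

    def __post_init__(self):
        for name in ("pr_ms", "qrs_ms", "qt_ms", "rr_ms"):
            if not getattr(self, name) > 0:
                raise ValueError(f"invariant violated: {name} must be > 0")
        if not self.qrs_ms < self.qt_ms:
            raise ValueError("invariant violated: qrs_ms < qt_ms")
        if not self.pr_ms + self.qt_ms < self.rr_ms:
            raise ValueError("invariant violated: pr_ms + qt_ms < rr_ms")
        if self.morphology_regime not in MORPHOLOGY_REGIMES:
            raise ValueError(
                f"invariant violated: morphology_regime must be one of "
                f"{MORPHOLOGY_REGIMES}, got {self.morphology_regime!r}")
        if self.duration_jitter < 0:
            raise ValueError("invariant violated: duration_jitter >= 0")
        if self.amplitude_jitter < 0:
            raise ValueError("invariant violated: amplitude_jitter >= 0")
        if self.morphology_drift < 0:
            raise ValueError("invariant violated: morphology_drift >= 0")
        if not 0 <= self.ectopic_rate <= 1:
            raise ValueError("invariant violated: 0 <= ectopic_rate <= 1")
        if self.p_variability < 0:
            raise ValueError("invariant violated: p_variability >= 0")
        if self.chaos_bumps < 0:
            raise ValueError("invariant violated: chaos_bumps >= 0")

    @property
    def effective_rr_jitter(self) -> float:
        if self.rr_jitter is not None:
            return self.rr_jitter
        return self.duration_jitter


def default_healthy_spec(**overrides) -> BeatSpec:
    """The default healthy-beat condition (normal adult intervals)."""
    return BeatSpec(**overrides)


def default_unhealthy_spec(regime: str = "long_qt_like", **overrides) -> BeatSpec:
    """A preset unhealthy-beat condition for the given morphology regime.

    Per-beat duration jitter is larger than for healthy beats, reflecting
    the beat-to-beat irregularity of arrhythmic rhythm.
    """
    presets = {
        "af_like": dict(amplitudes={**DEFAULT_AMPLITUDES, "P": 0.0},
                        duration_jitter=0.12, amplitude_jitter=0.15,
                        morphology_drift=0.30, ectopic_rate=0.35,
                        ectopic_scale=2.0, p_variability=0.8,
                        baseline_shift_sd=0.08, chaos_bumps=3.0,
                        rr_jitter=0.15),
        "bbb_like": dict(qrs_ms=140.0, qt_ms=420.0, duration_jitter=0.10,
                         amplitude_jitter=0.15, morphology_drift=0.30,
                         ectopic_rate=0.35, ectopic_scale=2.0,
                         p_variability=0.8, baseline_shift_sd=0.08,
                         chaos_bumps=3.0),
        "long_qt_like": dict(qt_ms=500.0, duration_jitter=0.10,
                             amplitude_jitter=0.15, morphology_drift=0.20,
                             ectopic_rate=0.35, ectopic_scale=2.0,
                             p_variability=0.8, baseline_shift_sd=0.08,
                             chaos_bumps=3.0),
    }
    if regime not in presets:
        raise ValueError(f"unknown unhealthy regime {regime!r}")
    kwargs = dict(presets[regime])
    kwargs["morphology_regime"] = regime
    kwargs.update(overrides)
    return BeatSpec(**kwargs)


@dataclass
class SyntheticRecord:
    """A generated record plus its per-beat fiducial ground truth.

    ``truth`` has one row per beat with integer sample-index columns
    ``p_on``, ``qrs_on``, ``r_peak``, ``qrs_off``, ``t_off`` and a string
    ``label`` column (``healthy``/``unhealthy``).
    """

    signal: ECGSignal
    truth: pd.DataFrame
    labels: np.ndarray

    @property
    def n_beats(self) -> int:
        return len(self.truth)


def _gauss(t: np.ndarray, center: float, sigma: float, amp: float) -> np.ndarray:
    if amp == 0.0 or sigma <= 0:
        return np.zeros_like(t)
    return amp * np.exp(-0.5 * ((t - center) / sigma) ** 2)


def _jittered(value: float, rel_sd: float, rng: np.random.Generator) -> float:
    if rel_sd == 0:
        return value
    # clip at +/-3 relative SD so durations can never go negative or absurd
    eps = float(np.clip(rng.normal(0.0, rel_sd), -3 * rel_sd, 3 * rel_sd))
    return value * (1.0 + eps)


def _beat_durations(spec: BeatSpec, rng: np.random.Generator):
    """Per-beat jittered (pr, qrs, qt, rr) in seconds, invariants enforced."""
    pr = _jittered(spec.pr_ms, spec.duration_jitter, rng) / 1000.0
    qrs = _jittered(spec.qrs_ms, spec.duration_jitter, rng) / 1000.0
    qt = _jittered(spec.qt_ms, spec.duration_jitter, rng) / 1000.0
    rr = _jittered(spec.rr_ms, spec.effective_rr_jitter, rng) / 1000.0
    qrs = min(qrs, 0.9 * qt)
    if pr + qt >= rr - 0.02:
        rr = pr + qt + 0.02
    return pr, qrs, qt, rr


def _render_beat(spec: BeatSpec, rng: np.random.Generator, fs: float,
                 morph_scale: float = 1.0):
    """One beat's samples plus fiducials (sample indices, beat-relative)."""
    pr, qrs, qt, rr = _beat_durations(spec, rng)
    n = int(round(rr * fs))
    lead_in = min(0.05, 0.5 * (rr - pr - qt))
    t = np.arange(n) / fs

    p_on_s = lead_in
    qrs_on_s = p_on_s + pr
    qrs_off_s = qrs_on_s + qrs
    t_off_s = qrs_on_s + qt

    # per-beat morphology variability: each wave's height is jittered
    # independently (arrhythmic beats vary in shape, not just timing), on
    # top of the slow AR(1) morphology drift carried in ``morph_scale``
    amps = {k: morph_scale * _jittered(v, spec.amplitude_jitter, rng)
            for k, v in spec.amplitudes.items()}
    if spec.p_variability > 0:
        # erratic atrial activity: the P wave waxes, wanes and vanishes
        amps["P"] = amps.get("P", 0.0) * max(
            0.0, 1.0 + rng.normal(0.0, spec.p_variability))
    shift = rng.normal(0.0, spec.baseline_shift_sd) if spec.baseline_shift_sd else 0.0
    x = np.zeros(n)

    # P wave: starts exactly at p_on, occupies the leading part of PR
    p_dur = _P_FRACTION_OF_PR * pr
    p_sigma = p_dur / 6.0
    p_center = p_on_s + p_dur / 2.0
    x += _gauss(t, p_center, p_sigma, amps.get("P", 0.0))

    # QRS complex: R bump spans [qrs_on, qrs_off] at +/-3 sigma
    r_center = 0.5 * (qrs_on_s + qrs_off_s)
    if spec.morphology_regime == "bbb_like":
        # notched QRS: two R bumps inside the widened complex; the notch
        # positions wander beat to beat (fragmented-QRS variability)
        f1 = float(np.clip(0.35 + rng.normal(0.0, 0.05), 0.22, 0.45))
        f2 = float(np.clip(0.65 + rng.normal(0.0, 0.05), 0.55, 0.78))
        for frac in (f1, f2):
            c = qrs_on_s + frac * qrs
            x += _gauss(t, c, qrs / 9.0, amps.get("R", 1.0))
        r_peak_s = qrs_on_s + f1 * qrs
    else:
        x += _gauss(t, r_center, qrs / 6.0, amps.get("R", 1.0))
        r_peak_s = r_center
    # narrow Q and S deflections kept well inside the complex
    x += _gauss(t, qrs_on_s + 0.20 * qrs, qrs / 18.0, amps.get("Q", 0.0))
    x += _gauss(t, qrs_on_s + 0.80 * qrs, qrs / 18.0, amps.get("S", 0.0))

    # T wave: ends exactly at t_off
    jt = qt - qrs
    t_frac = (_T_FRACTION_OF_JT_WIDE
              if spec.morphology_regime == "long_qt_like"
              else _T_FRACTION_OF_JT)
    t_dur = t_frac * jt
    t_sigma = t_dur / 6.0
    t_center = t_off_s - t_dur / 2.0
    x += _gauss(t, t_center, t_sigma, amps.get("T", 0.0))

    if spec.chaos_bumps > 0:
        # disorganized electrical activity (fibrillatory waves,
        # polymorphic repolarization): a random number of random-shape
        # deflections scattered through the beat, a fresh set each beat
        for _ in range(rng.poisson(spec.chaos_bumps)):
            c = rng.uniform(0.0, rr)
            w = rng.uniform(0.008, 0.040)
            a = (0.4 * float(np.exp(rng.normal(0.0, 0.7)))
                 * (1.0 if rng.random() < 0.5 else -1.0))
            x += _gauss(t, c, w / 2.0, a)
    if shift:
        # per-beat baseline displacement (respiration, electrode motion,
        # post-ectopic repolarization shifts): translates the whole loop
        # in phase space without changing its shape
        x += shift
    fid = {
        "p_on": int(round(p_on_s * fs)),
        "qrs_on": int(round(qrs_on_s * fs)),
        "r_peak": int(round(r_peak_s * fs)),
        "qrs_off": int(round(qrs_off_s * fs)),
        "t_off": int(round(t_off_s * fs)),
    }
    return x, fid


def generate_record(n_healthy: int,
                    n_unhealthy: int,
                    healthy_spec: Optional[BeatSpec] = None,
                    unhealthy_spec: Optional[BeatSpec] = None,
                    *,
                    unhealthy_regime: str = "long_qt_like",
                    fs: float = 1000.0,
                    noise_sd: float = 0.0,
                    wander_amp: float = 0.0,
                    wander_hz: float = 0.3,
                    seed: int = 0) -> SyntheticRecord:
    """Generate a healthy-block-then-unhealthy-block record.

    Parameters
    ----------
    n_healthy, n_unhealthy
        Beat counts of the two blocks (either may be 0).
    healthy_spec, unhealthy_spec
        Beat conditions; defaults are :func:`default_healthy_spec` and
        :func:`default_unhealthy_spec` for ``unhealthy_regime``.
    fs
        Sampling rate, Hz (default 1 kHz).
    noise_sd
        SD of additive white Gaussian noise, in units of the R amplitude
        scale (default 0 = noise-free).
    wander_amp
        Amplitude of a ``wander_hz`` sinusoidal baseline wander (default 0).
    seed
        Seed for all randomness; identical inputs + seed reproduce the
        record bit-for-bit.
    """
    if fs < 250:
        raise ValueError("fs must be >= 250 Hz")
    if n_healthy < 0 or n_unhealthy < 0:
        raise ValueError("beat counts must be >= 0")
    h_spec = healthy_spec if healthy_spec is not None else default_healthy_spec()
    u_spec = (unhealthy_spec if unhealthy_spec is not None
              else default_unhealthy_spec(unhealthy_regime))

    rng = np.random.default_rng(seed)
    chunks = []
    rows = []
    offset = 0
    plan = [("healthy", h_spec)] * n_healthy + [("unhealthy", u_spec)] * n_unhealthy
    # slow beat-to-beat morphology wandering (AR(1) on a log scale): the
    # sustained amplitude excursions of arrhythmic rhythm, as opposed to
    # the white per-beat jitter
    drift_state = 0.0
    for label, spec in plan:
        if spec.morphology_drift > 0:
            drift_state = float(np.clip(
                0.9 * drift_state + rng.normal(0.0, spec.morphology_drift),
                -0.5, 0.5))
            scale = float(np.exp(drift_state))
        else:
            drift_state = 0.0
            scale = 1.0
        # ectopic-like beats: occasional beats with grossly enlarged,
        # often discordant (inverted) deflections keep the window-to-window
        # composition of the phase portraits varying
        if spec.ectopic_rate and rng.random() < spec.ectopic_rate:
            scale *= spec.ectopic_scale
            if rng.random() < 0.5:
                # discordant ectopy: inverted, somewhat smaller deflections
                scale = -0.7 * scale
        x, fid = _render_beat(spec, rng, fs, morph_scale=scale)
        chunks.append(x)
        rows.append({k: v + offset for k, v in fid.items()} | {"label": label})
        offset += len(x)

    samples = np.concatenate(chunks) if chunks else np.zeros(0)
    if samples.size:
        if wander_amp:
            tt = np.arange(samples.size) / fs
            samples = samples + wander_amp * np.sin(2 * np.pi * wander_hz * tt)
        if noise_sd:
            samples = samples + rng.normal(0.0, noise_sd, samples.size)

    truth = pd.DataFrame(
        rows, columns=["p_on", "qrs_on", "r_peak", "qrs_off", "t_off", "label"])
    labels = truth["label"].to_numpy() if len(truth) else np.array([], dtype=object)
    sig = ECGSignal(samples=samples, fs=fs,
                    meta={"source": "synthetic", "seed": seed,
                          "n_healthy": n_healthy, "n_unhealthy": n_unhealthy,
                          "unhealthy_regime": u_spec.morphology_regime})
    return SyntheticRecord(signal=sig, truth=truth, labels=labels)


def truth_feature_durations(record: SyntheticRecord) -> pd.DataFrame:
    """Per-beat (pr_ms, qrs_ms, qt_ms, label) read back from the truth table.

    This is the oracle used to score fiducial/feature recovery.
    """
    if record.n_beats == 0:
        raise ValueError("record has no beats")
    fs = record.signal.fs
    t = record.truth
    ms = 1000.0 / fs
    return pd.DataFrame({
        "pr_ms": (t["qrs_on"] - t["p_on"]) * ms,
        "qrs_ms": (t["qrs_off"] - t["qrs_on"]) * ms,
        "qt_ms": (t["t_off"] - t["qrs_on"]) * ms,
        "label": t["label"],
    })


def write_record_csv(record: SyntheticRecord, csv_path, truth_path=None) -> None:
    """Write the signal as a (t,voltage) CSV plus a JSON truth sidecar."""
    csv_path = Path(csv_path)
    sig = record.signal
    df = pd.DataFrame({"t": sig.times, "voltage": sig.samples})
    df.to_csv(csv_path, index=False, float_format="%.9g")
    if truth_path is None:
        truth_path = csv_path.with_suffix(".truth.json")
    payload = {
        "fs": sig.fs,
        "beats": record.truth.to_dict(orient="records"),
    }
    Path(truth_path).write_text(json.dumps(payload, indent=1))


def read_truth_json(path) -> pd.DataFrame:
    payload = json.loads(Path(path).read_text())
    return pd.DataFrame(payload["beats"])
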