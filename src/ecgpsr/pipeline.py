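"""End-to-end pipeline wiring and cohort-level training/evaluation.

One record flows through: band-limit -> normalize -> beat delineation ->
feature slicing -> interval windows -> phase portraits -> box counts ->
sliding CV -> three-band classification, per feature kind (PR, QRS, QT).

For synthetic cohorts the generator's per-beat labels provide the
transition landmarks (a = last all-healthy CV window, b = first
all-unhealthy CV window) that threshold learning needs; on real data
those landmarks would come from annotation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .classify import (ClassDecision, LabeledCVTrace, PUBLISHED_THRESHOLDS,
                       ThresholdPair, classify_trace, learn_thresholds)
from .features import KINDS, detect_beats, extract_features, feature_durations
from .phase_space import box_count_series, make_interval_windows
from .preprocess import bandlimit, normalize
from .signal import ECGSignal
from .synthetic import SyntheticRecord
from .trends import CVTrace, sliding_stats, trace_to_frame

__all__ = ["PipelineConfig", "RecordResult", "run_pipeline",
           "labeled_traces", "learn_from_cohort", "evaluate_cohort"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Every knob of the pipeline, with the standard defaults."""

    fs: float = 1000.0
    hp_hz: float = 1.0
    lp_hz: float = 40.0
    filter_order: int = 4
    dwt_levels: int = 5
    w1: int = 20              # interval-window length (feature segments)
    stats_w: int = 20         # CV window length (box counts)
    delay_ms: float = 20.0
    grid_n: int = 100
    raster_mode: str = "line"
    thresholds: str | dict = "published"   # "published", "learn", or mapping
    train_fraction: float = 0.8
    edge_margin_s: float = 1.0   # discard beats inside the filter settling zone
    seed: int = 0

    def __post_init__(self):
        if self.raster_mode not in ("line", "point"):
            raise ValueError("raster_mode must be 'line' or 'point'")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")

    def resolve_thresholds(self) -> dict[str, ThresholdPair]:
        if self.thresholds == "published":
            return dict(PUBLISHED_THRESHOLDS)
        if isinstance(self.thresholds, dict):
            return {k: (v if isinstance(v, ThresholdPair)
                        else ThresholdPair(kind=k, **v))
                    for k, v in self.thresholds.items()}
        raise ValueError("thresholds unresolved: call learn_from_cohort "
                         "first when thresholds='learn'")


@dataclass
class RecordResult:
    """Everything the pipeline computed for one record and kind."""

    kind: str
    counts: np.ndarray
    trace: CVTrace
    window_decisions: list
    subject_decision: ClassDecision


def _trim_edge_beats(beats, n_samples: int, fs: float, margin_s: float):
    """Drop beats inside the settling margin of the zero-phase filters."""
    lo = margin_s * fs
    hi = n_samples - margin_s * fs
    kept = [b for b in beats if b.p_on >= lo and b.t_off <= hi]
    if len(kept) < len(beats):
        logger.info("trimmed %d edge beat(s)", len(beats) - len(kept))
    return kept


def _as_signal(inp) -> ECGSignal:
    if isinstance(inp, SyntheticRecord):
        return inp.signal
    if isinstance(inp, ECGSignal):
        return inp
    raise TypeError(f"cannot run pipeline on {type(inp).__name__}")


def analyze_record(inp, config: PipelineConfig,
                   out_dir=None) -> dict[str, RecordResult]:
    """Run the full chain on one record; returns one result per kind.

    ``out_dir`` persists every intermediate (features, counts, trends,
    decisions) as CSV/JSON.
    """
    sig = _as_signal(inp)
    if len(sig) < 2 or np.ptp(sig.samples) == 0:
        raise ValueError("no beats detected: empty or flat signal")
    ecg = normalize(bandlimit(sig, hp_hz=config.hp_hz, lp_hz=config.lp_hz,
                              order=config.filter_order))
    beats = detect_beats(ecg)
    beats = _trim_edge_beats(beats, len(ecg), ecg.fs, config.edge_margin_s)
    if not beats:
        raise ValueError("no beats detected")
    arrays = extract_features(ecg, beats)
    thresholds = config.resolve_thresholds()

    results: dict[str, RecordResult] = {}
    for kind in KINDS:
        windows = make_interval_windows(arrays[kind], w1=config.w1, step=1)
        if not windows:
            logger.warning("analyze_record: %s has %d segments < w1=%d; "
                           "skipped", kind, len(arrays[kind]), config.w1)
            continue
        counts = box_count_series(windows, delay_ms=config.delay_ms,
                                  grid_n=config.grid_n,
                                  mode=config.raster_mode)
        if counts.k < config.stats_w:
            logger.warning("analyze_record: %s has %d box counts < stats_w="
                           "%d; skipped", kind, counts.k, config.stats_w)
            continue
        trace = sliding_stats(counts, w=config.stats_w)
        wdec, subject = classify_trace(trace, thresholds[kind])
        results[kind] = RecordResult(kind=kind, counts=counts.counts,
                                     trace=trace, window_decisions=wdec,
                                     subject_decision=subject)

    if out_dir is not None:
        _persist(Path(out_dir), ecg, beats, arrays, results, thresholds)
    return results


def _persist(out_dir: Path, ecg, beats, arrays, results, thresholds) -> None:
    import pandas as pd

    out_dir.mkdir(parents=True, exist_ok=True)
    feature_durations(arrays).to_csv(out_dir / "features.csv", index=False)
    for kind, res in results.items():
        pd.DataFrame({"window_index": np.arange(res.counts.size),
                      "n_black": res.counts}
                     ).to_csv(out_dir / f"counts_{kind}.csv", index=False)
        trace_to_frame(res.trace).to_csv(out_dir / f"trend_{kind}.csv",
                                         index=False)
        pd.DataFrame({"window_index": np.arange(len(res.window_decisions)),
                      "cv": [d.cv for d in res.window_decisions],
                      "label": [d.label for d in res.window_decisions]}
                     ).to_csv(out_dir / f"decisions_{kind}.csv", index=False)
    (out_dir / "thresholds.json").write_text(json.dumps(
        {k: json.loads(v.to_json()) for k, v in thresholds.items()}, indent=1))
    report = {kind: {"subject": res.subject_decision.label,
                     "max_cv": float(np.max(res.trace.cvs)),
                     "n_windows": len(res.trace)}
              for kind, res in results.items()}
    (out_dir / "report.json").write_text(json.dumps(report, indent=1))


def run_pipeline(inp, config: Optional[PipelineConfig] = None, out_dir=None):
    """Public entry point: :func:`analyze_record` with default config."""
    return analyze_record(inp, config or PipelineConfig(), out_dir=out_dir)


# ---------------------------------------------------------------------------
# cohort training on synthetic records with known beat labels
# ---------------------------------------------------------------------------

def _beat_labels(record: SyntheticRecord, beats) -> np.ndarray:
    """Label each detected beat by its nearest ground-truth R peak."""
    truth_r = record.truth["r_peak"].to_numpy()
    truth_lab = record.truth["label"].to_numpy()
    det_r = np.array([b.r_peak for b in beats])
    idx = np.abs(truth_r[None, :] - det_r[:, None]).argmin(axis=1)
    return truth_lab[idx]


def _window_landmarks(beat_labels: np.ndarray, seg_beat_idx: Sequence[int],
                      w1: int, stats_w: int,
                      n_counts: int) -> Optional[tuple[int, int]]:
    """(a, b) for the CV trace: CV window m spans interval windows
    [m, m+stats_w), i.e. segments [m, m+stats_w+w1-1)."""
    labels = np.asarray(
        [beat_labels[i] for i in seg_beat_idx], dtype=object)
    span = stats_w + w1 - 1
    n_cv = n_counts - stats_w + 1
    if n_cv < 2:
        return None
    a = b = None
    for m in range(n_cv):
        window = labels[m: m + span]
        if np.all(window == "healthy"):
            a = m
        if b is None and np.all(window == "unhealthy"):
            b = m
    if a is None or b is None or not a < b:
        return None
    return a, b


def labeled_traces(record: SyntheticRecord, config: PipelineConfig,
                   patient_id: str = "") -> dict[str, LabeledCVTrace]:
    """CV traces of a transition record with (a, b) landmarks per kind.

    Kinds whose trace lacks both an all-healthy and an all-unhealthy
    window are omitted (with a warning).
    """
    sig = record.signal
    ecg = normalize(bandlimit(sig, hp_hz=config.hp_hz, lp_hz=config.lp_hz,
                              order=config.filter_order))
    beats = detect_beats(ecg)
    beats = _trim_edge_beats(beats, len(ecg), ecg.fs, config.edge_margin_s)
    if not beats:
        raise ValueError("no beats detected")
    arrays = extract_features(ecg, beats)
    beat_labels = _beat_labels(record, beats)

    out: dict[str, LabeledCVTrace] = {}
    for kind in KINDS:
        segs = arrays[kind]
        windows = make_interval_windows(segs, w1=config.w1, step=1)
        if not windows:
            continue
        counts = box_count_series(windows, delay_ms=config.delay_ms,
                                  grid_n=config.grid_n,
                                  mode=config.raster_mode)
        trace = sliding_stats(counts, w=config.stats_w)
        marks = _window_landmarks(beat_labels, [s.beat_index for s in segs],
                                  config.w1, config.stats_w, counts.k)
        if marks is None:
            logger.warning("labeled_traces: %s/%s has no clean transition "
                           "landmarks; omitted", patient_id, kind)
            continue
        out[kind] = LabeledCVTrace(trace=trace, a_index=marks[0],
                                   b_index=marks[1], patient_id=patient_id)
    return out


def learn_from_cohort(records: Sequence[SyntheticRecord],
                      config: PipelineConfig) -> dict[str, ThresholdPair]:
    """Learn per-kind threshold pairs from labeled transition records."""
    per_kind: dict[str, list[LabeledCVTrace]] = {k: [] for k in KINDS}
    for i, rec in enumerate(records):
        for kind, lt in labeled_traces(rec, config, patient_id=str(i)).items():
            per_kind[kind].append(lt)
    out = {}
    for kind in KINDS:
        if per_kind[kind]:
            out[kind] = learn_thresholds(per_kind[kind], kind)
    if not out:
        raise ValueError("no labeled traces available to learn from")
    return out


def _record_block_means(rec: SyntheticRecord,
                        config: PipelineConfig) -> dict[str, float]:
    """Per-kind mean CV of the record's evaluation block.

    For a transition record the block is the all-unhealthy window suffix
    (landmark ``b`` onward); for a healthy-only record it is the whole
    trace.  This per-block mean-CV summary is the statistic the cohort
    evaluation thresholds against.
    """
    has_unhealthy = "unhealthy" in set(rec.labels.tolist())
    out: dict[str, float] = {}
    if has_unhealthy:
        for kind, lt in labeled_traces(rec, config).items():
            out[kind] = float(np.mean(lt.trace.cvs[lt.b_index:]))
    else:
        for kind, res in analyze_record(rec, config).items():
            out[kind] = float(np.mean(res.trace.cvs))
    return out


def evaluate_cohort(records: Sequence[SyntheticRecord],
                    truth_positive: Sequence[bool],
                    thresholds: dict[str, ThresholdPair],
                    config: PipelineConfig):
    """Classify records against learned thresholds; tally the confusion.

    Each record is summarized per kind by its block mean CV
    (:func:`_record_block_means`) and predicted positive if any kind's
    summary reaches that kind's unhealthy threshold — the same
    block-level accounting the cohort statistics use.  Returns
    (ConfusionCounts, per-record predictions).
    """
    from .evaluation import ConfusionCounts

    preds = []
    for rec in records:
        means = _record_block_means(rec, config)
        pred = any(k in thresholds and v >= thresholds[k].th_final_min
                   for k, v in means.items())
        preds.append(pred)
    tp = sum(1 for p, t in zip(preds, truth_positive) if p and t)
    fp = sum(1 for p, t in zip(preds, truth_positive) if p and not t)
    tn = sum(1 for p, t in zip(preds, truth_positive) if not p and not t)
    fn = sum(1 for p, t in zip(preds, truth_positive) if not p and t)
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn), preds


DEFAULT_COHORT_REGIMES = ("long_qt_like", "bbb_like", "af_like")


def run_cohort_study(n_healthy: int = 20,
                     n_transition: int = 20,
                     config: Optional[PipelineConfig] = None,
                     seed: int = 0,
                     beats_healthy: int = 90,
                     beats_transition: tuple[int, int] = (45, 45)):
    """The full synthetic parameter-recovery study.

    Generates ``n_healthy`` healthy-only records and ``n_transition``
    healthy-then-unhealthy records (cycling through the unhealthy
    morphology regimes), learns per-kind thresholds on a stratified 80%
    split, and classifies the held-out records.  Returns a dict with the
    learned thresholds, held-out confusion counts, and the cohort's mean
    box counts over all-healthy vs all-unhealthy interval windows.
    """
    from .classify import split_train_validate
    from .synthetic import generate_record

    config = config or PipelineConfig()
    rng = np.random.default_rng(seed)
    records, labels = [], []
    for _ in range(n_healthy):
        records.append(generate_record(beats_healthy, 0,
                                       seed=int(rng.integers(2 ** 31))))
        labels.append(False)
    for i in range(n_transition):
        regime = DEFAULT_COHORT_REGIMES[i % len(DEFAULT_COHORT_REGIMES)]
        records.append(generate_record(*beats_transition,
                                       unhealthy_regime=regime,
                                       seed=int(rng.integers(2 ** 31))))
        labels.append(True)

    pairs = list(zip(records, labels))
    train, val = split_train_validate(
        pairs, [str(v) for v in labels], config.train_fraction,
        seed=int(rng.integers(2 ** 31)))
    thresholds = learn_from_cohort([r for r, pos in train if pos], config)
    confusion, preds = evaluate_cohort([r for r, _ in val],
                                       [pos for _, pos in val],
                                       thresholds, config)

    # direction of the box-count trend: unhealthy windows vs healthy ones
    h_counts, u_counts = [], []
    for rec, pos in val:
        if not pos:
            continue
        for kind, lt in labeled_traces(rec, config).items():
            h_counts.append(float(np.mean(lt.trace.means[: lt.a_index + 1])))
            u_counts.append(float(np.mean(lt.trace.means[lt.b_index:])))
    return {
        "thresholds": thresholds,
        "confusion": confusion,
        "predictions": preds,
        "mean_healthy_box_count": float(np.mean(h_counts)) if h_counts else np.nan,
        "mean_unhealthy_box_count": float(np.mean(u_counts)) if u_counts else np.nan,
    }
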