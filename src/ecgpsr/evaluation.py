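"""Diagnostic-accuracy measures and inferential statistics.

Covers the evaluation layer of the pipeline: the nine confusion-matrix
measures (Se, Sp, Acc, PPV, NPV, FPR, FDR, FNR, F1) expressed as
percentages, t-based confidence intervals for a mean, the one-tailed
paired t test of unhealthy-vs-healthy CV, and the equivalent
two-condition repeated-measures ANOVA (for which F equals the squared
paired t statistic).

Sample (n-1) standard deviations are used throughout this module, in
contrast to the population moments used inside trend windows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats as st

__all__ = [
    "ConfusionCounts",
    "DiagnosisMeasures",
    "HypothesisResult",
    "diagnosis_measures",
    "mean_ci",
    "paired_t_one_tailed",
    "rm_anova_two_conditions",
    "critical_value",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.p + self.n == 0:
            raise ValueError("all-zero confusion counts")

    @property
    def p(self) -> int:
        """Condition-positive total P = TP + FN."""
        return self.tp + self.fn

    @property
    def n(self) -> int:
        """Condition-negative total N = FP + TN."""
        return self.fp + self.tn


@dataclass(frozen=True)
class DiagnosisMeasures:
    """The nine measures, in percent; None where the denominator is zero."""

    se: Optional[float]
    sp: Optional[float]
    acc: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]
    fpr: Optional[float]
    fdr: Optional[float]
    fnr: Optional[float]
    f1: Optional[float]

    def as_dict(self) -> dict:
        return {k: getattr(self, k)
                for k in ("se", "sp", "acc", "ppv", "npv", "fpr", "fdr",
                          "fnr", "f1")}


def _pct(num: float, den: float) -> Optional[float]:
    return 100.0 * num / den if den > 0 else None


def diagnosis_measures(c: ConfusionCounts) -> DiagnosisMeasures:
    """All nine measures from the confusion counts, as percentages.

    Sensitivity Se = TP/(TP+FN), specificity Sp = TN/(FP+TN), accuracy
    Acc = (TP+TN)/(P+N), PPV = TP/(TP+FP), NPV = TN/(TN+FN),
    FPR = FP/(FP+TN), FDR = FP/(FP+TP), FNR = FN/(FN+TP), and
    F1 = 2TP/(2TP+FP+FN).  Measures with a zero denominator are reported
    as None rather than 0.
    """
    return DiagnosisMeasures(
        se=_pct(c.tp, c.p),
        sp=_pct(c.tn, c.n),
        acc=_pct(c.tp + c.tn, c.p + c.n),
        ppv=_pct(c.tp, c.tp + c.fp),
        npv=_pct(c.tn, c.tn + c.fn),
        fpr=_pct(c.fp, c.n),
        fdr=_pct(c.fp, c.fp + c.tp),
        fnr=_pct(c.fn, c.p),
        f1=_pct(2 * c.tp, 2 * c.tp + c.fp + c.fn),
    )


def mean_ci(mean: float, sd: float, n: int,
            level: float = 0.95) -> tuple[float, float]:
    """t-based confidence interval: mean +/- t_{(1+level)/2, n-1} sd/sqrt(n)."""
    if n < 2:
        raise ValueError("need n >= 2")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    half = st.t.ppf(0.5 * (1 + level), n - 1) * sd / np.sqrt(n)
    return (mean - half, mean + half)


@dataclass(frozen=True)
class HypothesisResult:
    statistic: float
    df: tuple
    p_value: float
    critical: float
    alpha: float

    @property
    def reject(self) -> bool:
        """Right-tailed decision: reject iff statistic > critical."""
        return self.statistic > self.critical


def paired_t_one_tailed(healthy, unhealthy,
                        alpha: float = 0.05) -> HypothesisResult:
    """Right-tailed paired t test of unhealthy CV > healthy CV.

    The statistic is computed on the per-patient differences
    (unhealthy - healthy) with df = n - 1.
    """
    h = np.asarray(healthy, dtype=float)
    u = np.asarray(unhealthy, dtype=float)
    if h.shape != u.shape or h.ndim != 1:
        raise ValueError("healthy/unhealthy must be equal-length 1-D arrays")
    n = h.size
    if n < 2:
        raise ValueError("need n >= 2 pairs")
    d = u - h
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance differences: t undefined")
    t = float(d.mean() / (sd / np.sqrt(n)))
    df = n - 1
    return HypothesisResult(statistic=t, df=(df,),
                            p_value=float(st.t.sf(t, df)),
                            critical=float(st.t.ppf(1 - alpha, df)),
                            alpha=alpha)


def rm_anova_two_conditions(healthy, unhealthy,
                            alpha: float = 0.05) -> HypothesisResult:
    """Repeated-measures ANOVA for the two-condition design.

    F = MS_condition / MS_error with df = (1, n-1); subject variance is
    removed by the within-subject design, so F equals the squared paired
    t statistic.
    """
    h = np.asarray(healthy, dtype=float)
    u = np.asarray(unhealthy, dtype=float)
    if h.shape != u.shape or h.ndim != 1:
        raise ValueError("healthy/unhealthy must be equal-length 1-D arrays")
    n = h.size
    if n < 2:
        raise ValueError("need n >= 2 subjects")
    data = np.stack([h, u])                   # conditions x subjects
    grand = data.mean()
    cond_means = data.mean(axis=1)
    subj_means = data.mean(axis=0)
    ss_cond = n * np.sum((cond_means - grand) ** 2)
    ss_subj = 2 * np.sum((subj_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_cond - ss_subj
    df_cond = 1
    df_err = n - 1
    ms_cond = ss_cond / df_cond
    ms_err = ss_err / df_err
    if ms_err == 0:
        raise ValueError("zero error variance: F undefined")
    f = float(ms_cond / ms_err)
    return HypothesisResult(statistic=f, df=(df_cond, df_err),
                            p_value=float(st.f.sf(f, df_cond, df_err)),
                            critical=float(st.f.ppf(1 - alpha, df_cond, df_err)),
                            alpha=alpha)


def critical_value(dist: str, alpha: float, df) -> float:
    """Upper-tail critical value of the t or F distribution at 1 - alpha."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if dist == "t":
        df = int(df if np.isscalar(df) else df[0])
        if df < 1:
            raise ValueError("t degrees of freedom must be >= 1")
        return float(st.t.ppf(1 - alpha, df))
    if dist == "f":
        try:
            d1, d2 = df
        except TypeError:
            raise ValueError("F distribution needs df = (d1, d2)") from None
        if d1 < 1 or d2 < 1:
            raise ValueError("F degrees of freedom must be >= 1")
        return float(st.f.ppf(1 - alpha, d1, d2))
    raise ValueError("dist must be 't' or 'f'")
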