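"""Cardiac-reserve indicators from S1/S2 timings and group comparison.

Two indicators are extracted per recording: the heart rate (HR, beats/min,
from the mean S1-to-S1 interval) and the ratio of diastolic to systolic
duration (D/S).  Systole runs from the S1 onset to the S2 onset within a
cycle; diastole from the S2 onset to the next cycle's S1 onset, so D/S
measures the fraction of the cycle available for diastolic myocardial
perfusion.  Groups are compared with a two-sample t-test (Welch by
default) on subject-level means, so subjects - not frames or recordings -
are the statistical units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import Recording
from .segmentation import (EnvelopeParams, detect_s2_onsets,
                           double_threshold_onsets, extract_envelope)


class InterleavingError(ValueError):
    """Raised when S1/S2 onsets do not alternate as cycles require."""


@dataclass
class CycleFeatures:
    """Per-recording cardiac-reserve features.

    ``systole`` / ``diastole`` are per-cycle durations in seconds (one
    entry per complete cycle with a detected S2); ``n_skipped`` counts
    cycles without a usable S2.
    """

    hr: float
    ds: float
    n_cycles: int
    systole: np.ndarray
    diastole: np.ndarray
    n_skipped: int = 0

    def __post_init__(self) -> None:
        if not self.hr > 0:
            raise ValueError("hr must be positive")
        if not self.ds > 0:
            raise ValueError("ds must be positive")


@dataclass
class GroupComparison:
    """Two-sample comparison of one feature between groups."""

    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    t: float
    p: float
    significant: bool
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (np.isnan(self.p) or 0.0 <= self.p <= 1.0):
            raise ValueError("p must lie in [0, 1]")


def cycle_intervals(s1_onsets, s2_onsets, fs: float) -> tuple[np.ndarray, np.ndarray, int]:
    """Per-cycle (systolic, diastolic) durations in seconds.

    For cycle ``i`` (between consecutive S1 onsets), systole is
    ``(s2_i - s1_i) / fs`` and diastole ``(s1_{i+1} - s2_i) / fs``.
    Cycles without an S2 are skipped and counted; a cycle containing more
    than one S2 onset raises :class:`InterleavingError` naming the cycle.

    Returns (systole array, diastole array, n_skipped).
    """
    s1 = np.asarray(s1_onsets, dtype=np.int64)
    s2 = np.asarray(s2_onsets, dtype=np.int64)
    if s1.size < 2:
        raise ValueError("need at least two S1 onsets to delimit a cycle")
    systole, diastole = [], []
    skipped = 0
    for i in range(s1.size - 1):
        inside = s2[(s2 > s1[i]) & (s2 < s1[i + 1])]
        if inside.size == 0:
            skipped += 1
            continue
        if inside.size > 1:
            raise InterleavingError(
                f"cycle {i} (S1 at {s1[i]}..{s1[i+1]}) contains "
                f"{inside.size} S2 onsets")
        systole.append((inside[0] - s1[i]) / fs)
        diastole.append((s1[i + 1] - inside[0]) / fs)
    return np.asarray(systole), np.asarray(diastole), skipped


def heart_rate(s1_onsets, fs: float) -> float:
    """Heart rate in beats/min: 60 over the mean S1-to-S1 interval."""
    s1 = np.asarray(s1_onsets, dtype=np.float64)
    if s1.size < 2:
        raise ValueError("need at least two S1 onsets to estimate heart rate")
    return 60.0 / float(np.mean(np.diff(s1)) / fs)


def ds_ratio(systole: np.ndarray, diastole: np.ndarray) -> float:
    """D/S ratio: mean diastolic duration over mean systolic duration."""
    systole = np.asarray(systole, dtype=np.float64)
    diastole = np.asarray(diastole, dtype=np.float64)
    if systole.size < 1 or diastole.size < 1:
        raise ValueError("need at least one complete cycle")
    mean_sys = float(systole.mean())
    if mean_sys <= 0:
        raise ValueError("mean systolic duration must be positive")
    return float(diastole.mean()) / mean_sys


def extract_cycle_features(rec: Recording, params: EnvelopeParams | None = None,
                           shannon: bool = True) -> CycleFeatures:
    """Full per-recording feature pipeline: envelope -> S1 -> S2 -> HR, D/S."""
    params = params or EnvelopeParams(fs=rec.fs)
    env = extract_envelope(rec.samples, params, shannon=shannon)
    s1 = double_threshold_onsets(env, params).s1_onsets
    s2, _ = detect_s2_onsets(env, s1, params)
    systole, diastole, skipped = cycle_intervals(s1, s2, rec.fs)
    return CycleFeatures(
        hr=heart_rate(s1, rec.fs),
        ds=ds_ratio(systole, diastole),
        n_cycles=systole.size,
        systole=systole,
        diastole=diastole,
        n_skipped=skipped,
    )


def group_ttest(values_a, values_b, equal_var: bool = False,
                alpha: float = 0.05) -> GroupComparison:
    """Two-sample t-test between groups (Welch by default).

    Degenerate inputs (both groups with zero variance) are flagged
    explicitly: equal constants give t = 0, p = 1; distinct constants an
    infinite t with p = 0.
    """
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two observations")
    if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
        if a.mean() == b.mean():
            t, p = 0.0, 1.0
        else:
            t = np.inf if a.mean() > b.mean() else -np.inf
            p = 0.0
        return GroupComparison(a.mean(), a.std(ddof=1), b.mean(), b.std(ddof=1),
                               t, p, significant=p < alpha, degenerate=True)
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return GroupComparison(
        mean_a=float(a.mean()), sd_a=float(a.std(ddof=1)),
        mean_b=float(b.mean()), sd_b=float(b.std(ddof=1)),
        t=float(res.statistic), p=float(res.pvalue),
        significant=bool(res.pvalue < alpha),
    )


def cohort_feature_table(manifest: pd.DataFrame,
                         params: EnvelopeParams | None = None,
                         shannon: bool = True) -> pd.DataFrame:
    """Per-recording HR and D/S for every row of a cohort manifest.

    Returns a DataFrame with columns
    (subject_id, group, time_node, hr, ds, n_cycles).
    """
    from .preprocess import WORKING_FS, read_wav, resample

    rows = []
    for row in manifest.itertuples(index=False):
        rec = read_wav(row.path, subject_id=row.subject_id, group=row.group,
                       time_node=row.time_node)
        if rec.fs != WORKING_FS:
            rec = resample(rec, WORKING_FS)
        feats = extract_cycle_features(rec, params, shannon=shannon)
        rows.append({
            "subject_id": row.subject_id, "group": row.group,
            "time_node": row.time_node, "hr": feats.hr, "ds": feats.ds,
            "n_cycles": feats.n_cycles,
        })
    return pd.DataFrame(rows)


def compare_groups(features: pd.DataFrame, feature: str = "hr",
                   by: str = "time_node",
                   equal_var: bool = False) -> pd.DataFrame:
    """Group comparison of a feature at every level of ``by``.

    Recordings are first averaged per subject (subjects are the
    statistical units), then the survival and sudden-death subject means
    are compared with :func:`group_ttest`.
    """
    out = []
    for level, chunk in features.groupby(by):
        per_subject = chunk.groupby(["subject_id", "group"], as_index=False)[feature].mean()
        a = per_subject.loc[per_subject.group == "survival", feature].to_numpy()
        b = per_subject.loc[per_subject.group == "sudden_death", feature].to_numpy()
        cmp = group_ttest(a, b, equal_var=equal_var)
        out.append({
            by: level, "feature": feature,
            "mean_survival": cmp.mean_a, "sd_survival": cmp.sd_a,
            "mean_sudden_death": cmp.mean_b, "sd_sudden_death": cmp.sd_b,
            "t": cmp.t, "p": cmp.p, "significant": cmp.significant,
        })
    return pd.DataFrame(out)
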