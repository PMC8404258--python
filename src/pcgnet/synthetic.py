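"""Synthetic rabbit phonocardiogram cohorts with ground-truth annotations.

The animal recordings behind the exercise sudden-death study are not
publicly available, so this module emulates their statistical structure:
S1/S2 bursts with energy well below 1 kHz, rabbit-range heart rates, a
diastolic/systolic duration ratio (D/S) controlled per group and time node,
and a cohort manifest of 10 surviving / 11 sudden-death subjects recorded
at four time nodes (A: pre-exercise ... D: after the third exhaustive
swimming bout).  Every recording comes with exact S1/S2 onset indices so
the segmentation and feature stages can be scored against ground truth.

Bursts are Gaussian-windowed sinusoids (sigma = duration / 6), the simplest
morphology whose windowed variance is unimodal; default carriers are
150 Hz (S1) and 250 Hz (S2).  The default cohort profile encodes the
group-level effects seen in exhaustive-swimming rabbits: survival heart
rate trends down across the protocol, sudden-death heart rate exceeds
survival at the later nodes, and sudden-death D/S drops below survival at
node D, with the two groups indistinguishable at node A.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import Recording, write_ground_truth, write_wav

GROUPS = ("survival", "sudden_death")
TIME_NODES = ("A", "B", "C", "D")

#: minimum plausible S1 duration (s); also the segmentation time-scale default
MIN_S1_DURATION = 0.02


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


@dataclass
class HeartCycleParams:
    """Morphological and timing parameters of one synthetic cardiac cycle.

    heart_rate : beats/min.
    ds_ratio : diastolic duration / systolic duration (dimensionless);
        systole runs from S1 onset to S2 onset, diastole from S2 onset to
        the next S1 onset.
    s1_freq, s2_freq : burst carrier frequencies, Hz (must stay below the
        1 kHz rabbit heart-sound band).
    s1_dur, s2_dur : burst durations, s.
    s1_amp, s2_amp : relative burst amplitudes; S2 is quieter than S1 at
        the apex.
    jitter_sd : cycle-to-cycle timing noise, s.
    """

    heart_rate: float = 240.0
    ds_ratio: float = 1.5
    s1_freq: float = 150.0
    s2_freq: float = 250.0
    s1_dur: float = 0.04
    s2_dur: float = 0.03
    s1_amp: float = 1.0
    s2_amp: float = 0.2
    jitter_sd: float = 0.005

    def __post_init__(self) -> None:
        if not self.heart_rate > 0:
            raise ValueError("heart_rate must be positive")
        if not self.ds_ratio > 0:
            raise ValueError("ds_ratio must be positive")
        if self.s1_dur < MIN_S1_DURATION:
            raise ValueError(f"s1_dur must be >= {MIN_S1_DURATION} s")
        if not (0 < self.s1_freq < 1000.0 and 0 < self.s2_freq < 1000.0):
            raise ValueError("burst carrier frequencies must lie in (0, 1000) Hz")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be nonnegative")

    @property
    def cycle_duration(self) -> float:
        """Nominal cycle length 60 / heart_rate, s."""
        return 60.0 / self.heart_rate


@dataclass
class GroundTruth:
    """Exact onset annotations for a synthetic recording.

    Onset indices are 0-based samples on the recording's own timeline;
    ``true_hr`` and ``true_ds`` are the realised values (after jitter),
    not the nominal parameters.
    """

    s1_onsets: np.ndarray
    s2_onsets: np.ndarray
    true_hr: float
    true_ds: float

    def __post_init__(self) -> None:
        self.s1_onsets = np.asarray(self.s1_onsets, dtype=np.int64)
        self.s2_onsets = np.asarray(self.s2_onsets, dtype=np.int64)
        for name, arr in (("s1_onsets", self.s1_onsets), ("s2_onsets", self.s2_onsets)):
            if arr.size > 1 and not np.all(np.diff(arr) > 0):
                raise ValueError(f"{name} must be strictly increasing")
        # S2 onsets must interleave: each cycle's S2 between consecutive S1s
        for i in range(min(len(self.s1_onsets) - 1, len(self.s2_onsets))):
            if not (self.s1_onsets[i] < self.s2_onsets[i] < self.s1_onsets[i + 1]):
                raise ValueError(f"S2 onset {i} does not interleave with S1 onsets")


def _burst(dur: float, freq: float, amp: float, fs: float, phase: float = 0.0) -> np.ndarray:
    """Gaussian-windowed sinusoid of length round(dur * fs) samples."""
    n = int(round(dur * fs))
    t = np.arange(n) / fs
    sigma = dur / 6.0
    window = np.exp(-0.5 * ((t - dur / 2.0) / sigma) ** 2)
    return amp * window * np.sin(2.0 * math.pi * freq * t + phase)


def _cycle(params: HeartCycleParams, fs: float,
           rng: np.random.Generator) -> tuple[np.ndarray, int]:
    """One cardiac cycle; returns (waveform, s2 onset sample)."""
    if fs < 2.0 * max(params.s1_freq, params.s2_freq):
        raise ValueError(
            f"fs={fs} Hz below Nyquist for carriers up to "
            f"{max(params.s1_freq, params.s2_freq)} Hz")
    cycle = params.cycle_duration
    if params.jitter_sd > 0:
        cycle += rng.normal(0.0, params.jitter_sd)
    if params.s1_dur + params.s2_dur >= cycle:
        raise ValueError(
            f"s1_dur + s2_dur = {params.s1_dur + params.s2_dur:.3f} s does not "
            f"fit in a {cycle:.3f} s cycle")
    n = int(round(cycle * fs))
    systole = cycle / (1.0 + params.ds_ratio)  # D/S = ds -> systole = cycle/(1+ds)
    s2_onset = int(round(systole * fs))
    if s2_onset + int(round(params.s2_dur * fs)) > n:
        raise ValueError("S2 burst does not fit inside the diastolic interval")
    wave = np.zeros(n)
    s1 = _burst(params.s1_dur, params.s1_freq, params.s1_amp, fs)
    s2 = _burst(params.s2_dur, params.s2_freq, params.s2_amp, fs)
    wave[:s1.size] += s1
    wave[s2_onset:s2_onset + s2.size] += s2
    return wave, s2_onset


def synth_cycle(params: HeartCycleParams, fs: float,
                rng_seed=0) -> tuple[np.ndarray, GroundTruth]:
    """Synthesize a single cardiac cycle.

    The S1 burst starts at sample 0; the S2 onset is placed so that
    diastole / systole equals ``params.ds_ratio``.  Returns the waveform
    and a single-cycle :class:`GroundTruth` whose realised HR reflects the
    jittered cycle length.
    """
    rng = _rng(rng_seed)
    wave, s2_onset = _cycle(params, fs, rng)
    realized = wave.size / fs
    systole = s2_onset / fs
    diastole = realized - systole
    truth = GroundTruth(
        s1_onsets=np.array([0]),
        s2_onsets=np.array([s2_onset]),
        true_hr=60.0 / realized,
        true_ds=diastole / systole,
    )
    return wave, truth


def synth_recording(params: HeartCycleParams, duration: float, fs: float = 2000.0,
                    noise_sd: float = 0.0, snr_db: float | None = None,
                    wander_amp: float = 0.0, wander_freq: float = 1.0,
                    rng_seed=0, subject_id: str | None = None,
                    group: str | None = None,
                    time_node: str | None = None) -> tuple[Recording, GroundTruth]:
    """Synthesize a multi-cycle recording with additive noise.

    Cycles are concatenated until ``duration`` is reached (the last cycle
    is truncated).  Noise is white Gaussian, either with explicit standard
    deviation ``noise_sd`` or derived from ``snr_db`` relative to the clean
    signal power (``snr_db`` wins when both are given).  An optional
    sinusoidal baseline wander (``wander_freq`` <= 5 Hz is sensible)
    emulates respiration/motion drift.

    The returned ground truth carries every onset index plus the realised
    mean heart rate and D/S ratio.
    """
    rng = _rng(rng_seed)
    if duration < 2.0 * params.cycle_duration:
        raise ValueError(
            f"duration {duration} s must cover at least two nominal cycles "
            f"({2 * params.cycle_duration:.3f} s)")
    n_total = int(round(duration * fs))
    pieces: list[np.ndarray] = []
    s1_onsets: list[int] = []
    s2_onsets: list[int] = []
    cursor = 0
    while cursor < n_total:
        wave, s2_rel = _cycle(params, fs, rng)
        s1_onsets.append(cursor)
        s2_onsets.append(cursor + s2_rel)
        pieces.append(wave)
        cursor += wave.size
    signal = np.concatenate(pieces)[:n_total]
    if signal.size < n_total:
        signal = np.pad(signal, (0, n_total - signal.size))
    s1 = np.array([i for i in s1_onsets if i < n_total], dtype=np.int64)
    s2 = np.array([i for i in s2_onsets if i < n_total], dtype=np.int64)

    # realised statistics from the kept onsets
    intervals = np.diff(s1) / fs
    true_hr = 60.0 / intervals.mean() if intervals.size else params.heart_rate
    n_complete = min(s1.size - 1, s2.size)
    if n_complete >= 1:
        sys_d = (s2[:n_complete] - s1[:n_complete]) / fs
        dia_d = (s1[1:n_complete + 1] - s2[:n_complete]) / fs
        true_ds = dia_d.mean() / sys_d.mean()
    else:
        true_ds = params.ds_ratio

    if snr_db is not None:
        p_sig = float(np.mean(signal ** 2))
        noise_sd = math.sqrt(p_sig / (10.0 ** (snr_db / 10.0)))
    if noise_sd > 0:
        signal = signal + rng.normal(0.0, noise_sd, size=signal.size)
    if wander_amp > 0:
        t = np.arange(n_total) / fs
        signal = signal + wander_amp * np.sin(
            2.0 * math.pi * wander_freq * t + rng.uniform(0, 2 * math.pi))

    rec = Recording(samples=signal, fs=fs, subject_id=subject_id,
                    group=group, time_node=time_node)
    truth = GroundTruth(s1_onsets=s1, s2_onsets=s2,
                        true_hr=float(true_hr), true_ds=float(true_ds))
    return rec, truth


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

@dataclass
class NodeProfile:
    """Group-level HR / D-S distribution at one time node."""
    hr_mean: float
    ds_mean: float


def default_node_profiles() -> dict[tuple[str, str], NodeProfile]:
    """Cohort profile emulating the exhaustive-swimming group effects.

    Node A is identical across groups (labels carry no signal before the
    protocol starts); separation grows monotonically to node D, where the
    sudden-death group shows markedly higher HR and lower D/S.
    """
    return {
        ("survival", "A"): NodeProfile(hr_mean=250.0, ds_mean=1.50),
        ("survival", "B"): NodeProfile(hr_mean=240.0, ds_mean=1.50),
        ("survival", "C"): NodeProfile(hr_mean=230.0, ds_mean=1.50),
        ("survival", "D"): NodeProfile(hr_mean=220.0, ds_mean=1.50),
        ("sudden_death", "A"): NodeProfile(hr_mean=250.0, ds_mean=1.50),
        ("sudden_death", "B"): NodeProfile(hr_mean=250.0, ds_mean=1.45),
        ("sudden_death", "C"): NodeProfile(hr_mean=256.0, ds_mean=1.35),
        ("sudden_death", "D"): NodeProfile(hr_mean=268.0, ds_mean=1.10),
    }


@dataclass
class CohortConfig:
    """Configuration of a synthetic cohort.

    ``n_survival`` / ``n_sudden_death`` default to the 10 / 11 animals of
    the emulated study.  ``subject_hr_sd`` and ``subject_ds_sd`` are
    between-subject random effects shared across a subject's nodes, which
    is what makes subject-exclusive cross-validation meaningfully harder
    than a frame-level shuffle.  Recording duration defaults to 6 s so a
    full default cohort stays around 200-250 heart-sound frames per class
    and per node.
    """

    n_survival: int = 10
    n_sudden_death: int = 11
    recordings_per_subject: int = 1
    duration: float = 6.0
    fs: float = 2000.0
    snr_db: float = 20.0
    subject_hr_sd: float = 8.0
    subject_ds_sd: float = 0.08
    jitter_sd: float = 0.005
    node_profiles: dict = field(default_factory=default_node_profiles)
    time_nodes: tuple = TIME_NODES
    base_params: HeartCycleParams = field(default_factory=HeartCycleParams)

    def __post_init__(self) -> None:
        if self.n_survival < 1 or self.n_sudden_death < 1:
            raise ValueError("both groups must contain at least one subject")
        if self.duration <= 0:
            raise ValueError("duration must be positive")


def synth_cohort(config: CohortConfig, out_dir: str | Path,
                 rng_seed=0) -> pd.DataFrame:
    """Generate a cohort of recordings on disk and return its manifest.

    Writes one WAV plus a ground-truth JSON sidecar per recording under
    ``out_dir`` and a ``manifest.csv`` with columns
    (subject_id, group, time_node, path, fs, n_recordings).
    """
    rng = _rng(rng_seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    subjects = (
        [("survival", f"sv{i:02d}") for i in range(config.n_survival)]
        + [("sudden_death", f"sd{i:02d}") for i in range(config.n_sudden_death)]
    )
    for group, subject_id in subjects:
        hr_offset = rng.normal(0.0, config.subject_hr_sd)
        ds_offset = rng.normal(0.0, config.subject_ds_sd)
        for node in config.time_nodes:
            profile = config.node_profiles[(group, node)]
            hr = max(profile.hr_mean + hr_offset, 120.0)
            ds = max(profile.ds_mean + ds_offset, 0.6)
            for r in range(config.recordings_per_subject):
                params = replace(config.base_params, heart_rate=hr, ds_ratio=ds,
                                 jitter_sd=config.jitter_sd)
                rec, truth = synth_recording(
                    params, config.duration, config.fs, snr_db=config.snr_db,
                    rng_seed=rng, subject_id=subject_id, group=group,
                    time_node=node)
                stem = f"{subject_id}_{node}_{r:02d}"
                wav_path = out_dir / f"{stem}.wav"
                write_wav(wav_path, rec)
                write_ground_truth(out_dir / f"{stem}.json",
                                   truth.s1_onsets, truth.s2_onsets,
                                   truth.true_hr, truth.true_ds)
                rows.append({
                    "subject_id": subject_id,
                    "group": group,
                    "time_node": node,
                    "path": str(wav_path),
                    "fs": config.fs,
                    "n_recordings": config.recordings_per_subject,
                })
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
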