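"""Heart-sound segmentation: windowed-variance envelope, Shannon energy,
double-threshold S1 onset detection and fixed-length frame extraction.

The characteristic envelope is the Viola-integral waveform: at every index
the variance of the signal over a window of half-width ``L_T = 0.5 * s * Fs``
samples, where ``s`` is the minimum S1 duration (0.02 s) and ``Fs`` the
working rate (2000 Hz).  The envelope is optionally passed through a
normalised Shannon-energy transform, which strongly suppresses the noise
floor (quadratic-in-energy attenuation of small values) before the double
threshold is applied: event runs are the regions above the low threshold
``L = b * M_env``; a run is kept as an S1 event only if its peak exceeds the
high threshold ``H = a * M_env`` (``M_env`` = mean envelope over the valid
range).  The S1 onset is the first sample of each kept run.

Frames of 1001 samples (0.5 s at 2000 Hz, inclusive endpoints) starting at
each S1 onset are the classifier input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .preprocess import Recording

#: default minimum S1 duration (s) used for the envelope time scale
DEFAULT_S = 0.02
#: default working sampling rate (Hz)
DEFAULT_FS = 2000.0
#: classifier frame length: 0.5 s at 2000 Hz with inclusive endpoints
FRAME_LEN = 1001


class SegmentationWarning(UserWarning):
    """Emitted when onset detection finds nothing above the high threshold."""


@dataclass
class EnvelopeParams:
    """Parameters of envelope extraction and double thresholding.

    s : minimum S1 duration (s); sets the window half-width.
    fs : sampling rate (Hz).
    a : high-threshold factor (sensible range 0.6 - 1.1).
    b : low-threshold factor (sensible range 0.01 - 0.03).

    Both factors multiply the mean of the envelope and can be adjusted per
    recording when the defaults mis-fire.
    """

    s: float = DEFAULT_S
    fs: float = DEFAULT_FS
    a: float = 0.8
    b: float = 0.02

    def __post_init__(self) -> None:
        if not 0 < self.b < self.a:
            raise ValueError(f"need 0 < b < a, got a={self.a}, b={self.b}")
        if self.s * self.fs < 2:
            raise ValueError("s * fs must be at least 2 samples")

    @property
    def L_T(self) -> int:
        return time_scale(self.s, self.fs)


@dataclass
class EnvelopeTrace:
    """A nonnegative envelope kept on the original signal timeline.

    ``values`` has the same length ``M`` as the source signal; indices
    outside the valid range ``[L_T, M - 1 - L_T]`` are zero-filled (the
    window does not fully overlap the signal there and the envelope is not
    defined).  Statistics (mean, thresholds) are computed over the valid
    range only.
    """

    values: np.ndarray
    L_T: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if np.any(self.values[self.valid_slice] < 0):
            raise ValueError("envelope values must be nonnegative")

    @property
    def M(self) -> int:
        return self.values.size

    @property
    def valid_slice(self) -> slice:
        return slice(self.L_T, self.M - self.L_T)

    @property
    def valid_values(self) -> np.ndarray:
        return self.values[self.valid_slice]


@dataclass
class OnsetSet:
    """Detected S1 onsets (0-based samples) plus the thresholds that produced them."""

    s1_onsets: np.ndarray
    H: float
    L: float
    m_env: float

    def __post_init__(self) -> None:
        self.s1_onsets = np.asarray(self.s1_onsets, dtype=np.int64)
        if self.s1_onsets.size > 1 and not np.all(np.diff(self.s1_onsets) > 0):
            raise ValueError("onsets must be strictly increasing")

    def __len__(self) -> int:
        return self.s1_onsets.size


@dataclass
class FrameSet:
    """Fixed-length heart-sound frames with their provenance.

    ``frames`` is (n_frames, frame_len); ``labels`` and ``subjects`` are
    parallel string arrays; ``onsets`` holds each frame's source S1 onset.
    """

    frames: np.ndarray
    labels: np.ndarray
    subjects: np.ndarray
    onsets: np.ndarray

    def __post_init__(self) -> None:
        self.frames = np.atleast_2d(np.asarray(self.frames, dtype=np.float64))
        self.labels = np.asarray(self.labels)
        self.subjects = np.asarray(self.subjects)
        self.onsets = np.asarray(self.onsets, dtype=np.int64)

    def __len__(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_len(self) -> int:
        return self.frames.shape[1]

    @staticmethod
    def concatenate(framesets: list["FrameSet"]) -> "FrameSet":
        framesets = [f for f in framesets if len(f) > 0]
        if not framesets:
            raise ValueError("no non-empty frame sets to concatenate")
        return FrameSet(
            frames=np.vstack([f.frames for f in framesets]),
            labels=np.concatenate([f.labels for f in framesets]),
            subjects=np.concatenate([f.subjects for f in framesets]),
            onsets=np.concatenate([f.onsets for f in framesets]),
        )

    def save_hdf5(self, path: str | Path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("frames", data=self.frames.astype(np.float32))
            f.create_dataset("labels", data=self.labels.astype("S"))
            f.create_dataset("subject_id", data=self.subjects.astype("S"))
            f.create_dataset("onset", data=self.onsets)

    @staticmethod
    def load_hdf5(path: str | Path) -> "FrameSet":
        import h5py

        with h5py.File(path, "r") as f:
            return FrameSet(
                frames=f["frames"][()].astype(np.float64),
                labels=f["labels"][()].astype("U"),
                subjects=f["subject_id"][()].astype("U"),
                onsets=f["onset"][()],
            )


# ---------------------------------------------------------------------------
# Envelope extraction
# ---------------------------------------------------------------------------

def time_scale(s: float, fs: float) -> int:
    """Window half-width in samples: ``L_T = 0.5 * s * fs`` (nearest integer)."""
    if not (s > 0 and fs > 0):
        raise ValueError("s and fs must be positive")
    L_T = int(round(0.5 * s * fs))
    if L_T < 1:
        raise ValueError(f"time scale 0.5*{s}*{fs} rounds below one sample")
    return L_T


def _check_length(x: np.ndarray, L_T: int) -> None:
    if x.size < 2 * L_T + 1:
        raise ValueError(
            f"signal of length {x.size} shorter than the window 2*{L_T}+1")


def moving_mean(x: np.ndarray, L_T: int) -> np.ndarray:
    """Centred moving average over windows of ``2*L_T + 1`` samples.

    Returns the valid-range values only (length ``len(x) - 2*L_T``),
    corresponding to indices ``m = L_T ... len(x)-1-L_T`` of the input.
    """
    x = np.asarray(x, dtype=np.float64)
    _check_length(x, L_T)
    kernel = np.full(2 * L_T + 1, 1.0 / (2 * L_T + 1))
    return np.convolve(x, kernel, mode="valid")


def viola_envelope(x: np.ndarray, L_T: int) -> EnvelopeTrace:
    """Characteristic envelope: windowed variance around each window's own mean.

    ``E(m) = mean_k (x[k] - xbar(m))**2`` over ``k in [m-L_T, m+L_T]``,
    computed as ``mean(x**2) - mean(x)**2`` per window.  Values are clipped
    at zero against floating-point cancellation and placed on the original
    timeline (zeros outside the valid range).
    """
    x = np.asarray(x, dtype=np.float64)
    _check_length(x, L_T)
    mean = moving_mean(x, L_T)
    mean_sq = moving_mean(x * x, L_T)
    env_valid = np.maximum(mean_sq - mean * mean, 0.0)
    values = np.zeros(x.size)
    values[L_T:x.size - L_T] = env_valid
    return EnvelopeTrace(values=values, L_T=L_T)


def shannon_normalize(env: EnvelopeTrace) -> EnvelopeTrace:
    """Normalised average Shannon energy of an envelope.

    The envelope is scaled to unit maximum, transformed with
    ``SE(v) = -v**2 * log(v**2)`` (natural log; ``SE(0) = 0``), smoothed
    with the same ``2*L_T + 1`` moving average, and rescaled to unit
    maximum.  Because ``SE`` behaves like ``v**2`` near zero this squares
    the envelope's already-quadratic noise attenuation, pushing the noise
    floor far below the low threshold while leaving burst lobes intact
    (lobe count is preserved).
    """
    v = env.valid_values
    peak = v.max() if v.size else 0.0
    if peak <= 0:
        raise ValueError("cannot Shannon-normalize an all-zero envelope")
    v = v / peak
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.where(v > 0, -(v ** 2) * np.log(v ** 2), 0.0)
    kernel = np.full(2 * env.L_T + 1, 1.0 / (2 * env.L_T + 1))
    se = np.convolve(se, kernel, mode="same")
    se = np.maximum(se, 0.0)
    se_peak = se.max()
    if se_peak > 0:
        se = se / se_peak
    values = np.zeros(env.M)
    values[env.valid_slice] = se
    return EnvelopeTrace(values=values, L_T=env.L_T)


def extract_envelope(x: np.ndarray, params: EnvelopeParams,
                     shannon: bool = True) -> EnvelopeTrace:
    """Convenience pipeline: Viola envelope, optionally Shannon-normalised."""
    env = viola_envelope(x, params.L_T)
    if shannon:
        env = shannon_normalize(env)
    return env


# ---------------------------------------------------------------------------
# Double-threshold onset detection
# ---------------------------------------------------------------------------

def _runs_above(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal [start, stop) runs of True in a boolean array."""
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2], edges[1::2]))


def double_threshold_onsets(env: EnvelopeTrace,
                            params: EnvelopeParams) -> OnsetSet:
    """Locate S1 onsets on an envelope with the double-threshold method.

    With ``M_env`` the mean envelope over the valid range, the high
    threshold is ``H = a * M_env`` and the low one ``L = b * M_env``.
    Candidate runs are the maximal regions where the envelope exceeds
    ``L``; runs whose peak exceeds ``H`` are kept as events, each onset
    being the run's first sample.  Events closer than ``s * fs`` samples
    are merged (the earlier onset wins).  An empty result triggers a
    warning, not an exception.
    """
    vals = env.values
    m_env = float(env.valid_values.mean())
    H = params.a * m_env
    L = params.b * m_env
    onsets: list[int] = []
    if m_env > 0:
        for start, stop in _runs_above(vals > L):
            if vals[start:stop].max() > H:
                onsets.append(int(start))
    min_gap = int(round(params.s * params.fs))
    merged: list[int] = []
    for onset in onsets:
        if merged and onset - merged[-1] < min_gap:
            continue
        merged.append(onset)
    if not merged:
        warnings.warn("no envelope run exceeded the high threshold; "
                      "empty onset set", SegmentationWarning, stacklevel=2)
    return OnsetSet(s1_onsets=np.array(merged, dtype=np.int64),
                    H=H, L=L, m_env=m_env)


def detect_s1_onsets(rec: Recording, params: EnvelopeParams | None = None,
                     shannon: bool = True) -> OnsetSet:
    """End-to-end S1 detection on a recording at the working rate."""
    params = params or EnvelopeParams()
    env = extract_envelope(rec.samples, params, shannon=shannon)
    return double_threshold_onsets(env, params)


def detect_s2_onsets(env: EnvelopeTrace, s1_onsets: np.ndarray,
                     params: EnvelopeParams | None = None) -> tuple[np.ndarray, int]:
    """Locate S2 onsets by re-thresholding each inter-S1 interval.

    For each pair of consecutive S1 onsets the search window opens where
    the S1 event's own envelope run decays below the global low threshold
    and closes ``s * fs`` samples before the next S1.  The window is
    re-thresholded against its local mean with the same (a, b) factors;
    the first qualifying run is taken as the S2 lobe (positional rule: the
    first lobe after S1 within the cycle) and the onset is placed where
    that lobe first exceeds ``b`` times its own peak, mirroring the global
    low-threshold rule so that S1 and S2 onsets share the same systematic
    rise-detection bias (which then cancels in duration differences).
    Cycles with no qualifying run are skipped and counted.

    Reliable S2 placement requires the Shannon-normalised envelope; on the
    raw windowed-variance envelope the low threshold sits below the noise
    floor at realistic SNR and most cycles are skipped.

    Returns (s2 onset array, number of skipped cycles).
    """
    params = params or EnvelopeParams()
    vals = env.values
    m_env = float(env.valid_values.mean())
    L_global = params.b * m_env
    tail = int(round(params.s * params.fs))
    s2_onsets: list[int] = []
    skipped = 0
    for i in range(len(s1_onsets) - 1):
        s1, s1_next = int(s1_onsets[i]), int(s1_onsets[i + 1])
        # window opens where the S1 lobe has decayed below the low threshold
        below = np.flatnonzero(vals[s1:s1_next] <= L_global)
        lo = s1 + int(below[0]) if below.size else s1 + tail
        hi = s1_next - tail
        if hi - lo < 2:
            skipped += 1
            continue
        window = vals[lo:hi]
        m_local = float(window.mean())
        if m_local <= 0:
            skipped += 1
            continue
        H = params.a * m_local
        L = params.b * m_local
        found = None
        for start, stop in _runs_above(window > L):
            if start == 0:
                continue  # still decaying S1 energy at the window edge
            peak = window[start:stop].max()
            if peak > H:
                # boundary refinement: onset where the lobe first exceeds
                # b * its own peak, mirroring the global low-threshold rule
                k = start + int(np.flatnonzero(window[start:stop] > params.b * peak)[0])
                found = lo + k
                break
        if found is None:
            skipped += 1
        else:
            s2_onsets.append(found)
    return np.array(s2_onsets, dtype=np.int64), skipped


# ---------------------------------------------------------------------------
# Frame extraction
# ---------------------------------------------------------------------------

def extract_frames(rec: Recording, onsets: OnsetSet | np.ndarray,
                   frame_len: int = FRAME_LEN,
                   standardize: bool = True) -> FrameSet:
    """Cut one frame per S1 onset: samples ``[onset, onset + frame_len - 1]``.

    Onsets whose frame would overrun the recording are dropped.  Frames
    are standardised to zero mean / unit variance individually (constant
    frames are left at zero), removing inter-subject gain differences.
    """
    onset_arr = onsets.s1_onsets if isinstance(onsets, OnsetSet) else np.asarray(onsets)
    x = rec.samples
    kept = [int(o) for o in onset_arr if o + frame_len <= x.size]
    if not kept:
        return FrameSet(frames=np.empty((0, frame_len)),
                        labels=np.empty(0, dtype="U16"),
                        subjects=np.empty(0, dtype="U16"),
                        onsets=np.empty(0, dtype=np.int64))
    frames = np.stack([x[o:o + frame_len] for o in kept])
    if standardize:
        mu = frames.mean(axis=1, keepdims=True)
        sd = frames.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        frames = (frames - mu) / sd
    n = len(kept)
    return FrameSet(
        frames=frames,
        labels=np.full(n, rec.group or "", dtype="U16"),
        subjects=np.full(n, rec.subject_id or "", dtype="U16"),
        onsets=np.array(kept, dtype=np.int64),
    )


def frames_from_manifest(manifest, params: EnvelopeParams | None = None,
                         frame_len: int = FRAME_LEN,
                         shannon: bool = True) -> FrameSet:
    """Segment every recording in a manifest into one pooled FrameSet."""
    from .preprocess import WORKING_FS, read_wav, resample

    params = params or EnvelopeParams()
    framesets = []
    for row in manifest.itertuples(index=False):
        rec = read_wav(row.path, subject_id=row.subject_id, group=row.group,
                       time_node=row.time_node)
        if rec.fs != WORKING_FS:
            rec = resample(rec, WORKING_FS)
        onsets = detect_s1_onsets(rec, params, shannon=shannon)
        fs = extract_frames(rec, onsets, frame_len=frame_len)
        if len(fs):
            framesets.append(fs)
    if not framesets:
        raise ValueError("segmentation produced no frames for the manifest")
    return FrameSet.concatenate(framesets)
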