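"""Waveform containers, WAV input/output, resampling and spectral inspection.

Rabbit phonocardiograms are acquired at a high rate (100 kHz in the original
hardware chain, band-passed 1 Hz - 10 kHz) while the heart-sound energy of
New Zealand rabbits sits below 1 kHz.  The working rate for everything
downstream is therefore 2000 Hz; this module provides the anti-aliased
rate conversion plus the FFT/STFT inspection used to verify that the band
of interest survives the conversion.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import get_window, resample_poly

logger = logging.getLogger("pcgnet")

#: working sampling rate (Hz) for segmentation and classification
WORKING_FS = 2000.0
#: upper edge (Hz) of the heart-sound band in New Zealand rabbits
HS_BAND_HZ = 1000.0


class ZeroEnergyError(ValueError):
    """Raised when a spectral quantity is undefined because the signal is silent."""


@dataclass
class Recording:
    """A single-channel phonocardiogram with its acquisition metadata.

    Parameters
    ----------
    samples : ndarray
        1-D real-valued waveform.
    fs : float
        Sampling rate in Hz (> 0).
    subject_id, group, time_node : str, optional
        Cohort metadata carried through the pipeline.  ``group`` is one of
        ``"survival"`` / ``"sudden_death"``; ``time_node`` one of A-D.
    """

    samples: np.ndarray
    fs: float
    subject_id: str | None = None
    group: str | None = None
    time_node: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D sequence")
        if not self.fs > 0:
            raise ValueError(f"fs must be positive, got {self.fs}")

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.samples.size / self.fs

    @property
    def n_samples(self) -> int:
        return self.samples.size


@dataclass
class Spectrogram:
    """Short-time Fourier magnitude of a recording.

    ``magnitude`` is (n_freqs, n_times), nonnegative; ``freqs`` spans
    [0, fs/2]; ``times`` holds the centre of each analysis window in
    seconds.  The window name, width and overlap that produced it are kept
    so the object is self-describing on disk.
    """

    magnitude: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    window: str
    width: int
    overlap: int

    def save_hdf5(self, path: str | Path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("magnitude", data=self.magnitude)
            f.create_dataset("freqs", data=self.freqs)
            f.create_dataset("times", data=self.times)
            f.attrs["window"] = self.window
            f.attrs["width"] = self.width
            f.attrs["overlap"] = self.overlap


# ---------------------------------------------------------------------------
# WAV + sidecar IO
# ---------------------------------------------------------------------------

def write_wav(path: str | Path, rec: Recording) -> None:
    """Write a recording as single-channel float32 WAV."""
    wavfile.write(str(path), int(round(rec.fs)), rec.samples.astype(np.float32))


def read_wav(path: str | Path, **meta: str | None) -> Recording:
    """Read a single-channel WAV file; integer PCM is rescaled to [-1, 1]."""
    fs, data = wavfile.read(str(path))
    if data.ndim > 1:
        data = data[:, 0]
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.float64) / float(np.iinfo(data.dtype).max)
    return Recording(samples=np.asarray(data, dtype=np.float64), fs=float(fs), **meta)


def write_ground_truth(path: str | Path, s1_onsets, s2_onsets, hr: float, ds: float) -> None:
    payload = {
        "s1_onsets": [int(i) for i in s1_onsets],
        "s2_onsets": [int(i) for i in s2_onsets],
        "hr": float(hr),
        "ds": float(ds),
    }
    Path(path).write_text(json.dumps(payload))


def read_ground_truth(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def resample(rec: Recording, target_fs: float) -> Recording:
    """Anti-aliased polyphase resampling of a recording.

    Frequency content below ``target_fs / 2`` is preserved; the output
    length is ``round(n * target_fs / fs)``.  Upsampling is permitted but
    logged, since the pipeline normally only ever reduces the rate.
    """
    if not target_fs > 0:
        raise ValueError("target_fs must be positive")
    if target_fs == rec.fs:
        return replace(rec, samples=rec.samples.copy())
    if target_fs > rec.fs:
        logger.warning(
            "upsampling %s from %.6g Hz to %.6g Hz (unusual for PCG)",
            rec.subject_id or "<recording>", rec.fs, target_fs,
        )
    ratio = Fraction(target_fs).limit_denominator(10**6) / Fraction(rec.fs).limit_denominator(10**6)
    out = resample_poly(rec.samples, ratio.numerator, ratio.denominator)
    n_target = int(round(rec.samples.size * target_fs / rec.fs))
    if out.size > n_target:
        out = out[:n_target]
    elif out.size < n_target:
        out = np.pad(out, (0, n_target - out.size))
    return replace(rec, samples=out, fs=float(target_fs))


# ---------------------------------------------------------------------------
# Spectral inspection
# ---------------------------------------------------------------------------

def spectrum(rec: Recording) -> tuple[np.ndarray, np.ndarray]:
    """One-sided magnitude spectrum of a recording.

    Returns ``(freqs, mags)`` with ``mags = |rfft(x)|`` (unnormalised
    magnitudes).  Signal energy can be recovered from them via Parseval:
    ``sum(x**2) == (2 * sum(mags**2) - mags[0]**2 - nyq**2) / n`` for even
    ``n``, which :func:`band_energy_fraction` exploits.
    """
    x = rec.samples
    mags = np.abs(np.fft.rfft(x))
    freqs = np.fft.rfftfreq(x.size, d=1.0 / rec.fs)
    return freqs, mags


def stft(rec: Recording, window: str = "hann", width: int = 2048,
         overlap: int = 1024) -> Spectrogram:
    """Short-time Fourier transform with no zero padding at the edges.

    The analysis hop is ``width - overlap`` and the number of time columns
    is ``floor((n - width) / hop) + 1`` exactly (only full windows are
    analysed).
    """
    x = rec.samples
    if width > x.size:
        raise ValueError(f"signal length {x.size} shorter than window width {width}")
    if not 0 <= overlap < width:
        raise ValueError("overlap must satisfy 0 <= overlap < width")
    hop = width - overlap
    n_cols = (x.size - width) // hop + 1
    win = get_window(window, width, fftbins=True)
    starts = np.arange(n_cols) * hop
    frames = np.lib.stride_tricks.sliding_window_view(x, width)[starts]
    mag = np.abs(np.fft.rfft(frames * win, axis=1)).T
    freqs = np.fft.rfftfreq(width, d=1.0 / rec.fs)
    times = (starts + width / 2) / rec.fs
    return Spectrogram(magnitude=mag, freqs=freqs, times=times,
                       window=window, width=width, overlap=overlap)


def band_energy_fraction(freqs: np.ndarray, mags: np.ndarray, f_cut: float) -> float:
    """Fraction of spectral energy strictly below ``f_cut``.

    Operates on the one-sided spectrum returned by :func:`spectrum`; the
    one-sided doubling cancels in the ratio except at DC/Nyquist, which is
    negligible for band-limited acoustic signals.

    Raises
    ------
    ZeroEnergyError
        If the signal has no energy (the fraction is undefined).
    ValueError
        If ``f_cut`` exceeds the spectrum's Nyquist frequency.
    """
    freqs = np.asarray(freqs, dtype=float)
    mags = np.asarray(mags, dtype=float)
    if f_cut > freqs[-1] * (1 + 1e-12):
        raise ValueError(f"f_cut {f_cut} Hz exceeds Nyquist {freqs[-1]} Hz")
    energy = mags ** 2
    total = float(energy.sum())
    if total == 0.0:
        raise ZeroEnergyError("band energy fraction undefined for an all-zero signal")
    return float(energy[freqs < f_cut].sum() / total)
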