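"""Short-time spectral analysis of temporal decomposition components.

The temporal (mode-3 / "frame") factor of a cine-loop decomposition
tracks speckle motion through the loop.  Disturbed flow through a
stenosis decorrelates speckle quickly, pushing power towards high
temporal frequencies across the whole recording; laminar flow keeps the
power low-frequency.  Recording artifacts (probe or patient movement)
instead appear as fleeting, high-energy bursts localised in time.  This
module computes spectrograms of such signals, summarises their
high-frequency content, and flags fleeting bursts.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import List

import h5py
import numpy as np
from scipy import signal as sps

__all__ = [
    "Spectrogram",
    "spectrogram",
    "high_frequency_ratio",
    "detect_transient_peaks",
    "save_spectrogram",
]

DEFAULT_WINDOW_LEN = 128
DEFAULT_OVERLAP = 64


@dataclass(frozen=True)
class Spectrogram:
    """Power distribution over frequency and time.

    ``power[f, t]`` is non-negative spectral power in frequency bin
    ``freqs[f]`` (Hz, 0 .. Nyquist) at time-bin centre ``times[t]``
    (seconds).
    """

    power: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    window_len: int
    overlap: int
    window: str
    fs: float

    @property
    def nyquist(self) -> float:
        return self.fs / 2.0


def spectrogram(
    x: np.ndarray,
    fs: float,
    window_len: int = DEFAULT_WINDOW_LEN,
    overlap: int = DEFAULT_OVERLAP,
    window: str = "hann",
) -> Spectrogram:
    """Magnitude-squared short-time Fourier transform of a real signal.

    Each window is mean-detrended before transforming: temporal factors
    of B-mode loops carry a large DC offset (overall image brightness)
    that would otherwise mask the flow frequencies.  Defaults are a
    128-sample Hann window with 50% overlap.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    if fs <= 0:
        raise ValueError("sampling rate must be positive")
    if not window_len > overlap >= 0:
        raise ValueError("need window_len > overlap >= 0")
    if len(x) < window_len:
        raise ValueError(
            f"signal of length {len(x)} is shorter than one window ({window_len})"
        )
    freqs, times, power = sps.spectrogram(
        x,
        fs=fs,
        window=window,
        nperseg=window_len,
        noverlap=overlap,
        detrend="constant",
        scaling="spectrum",
        mode="psd",
    )
    return Spectrogram(
        power=power, freqs=freqs, times=times,
        window_len=window_len, overlap=overlap, window=window, fs=float(fs),
    )


def high_frequency_ratio(S: Spectrogram, cutoff: float) -> float:
    """Fraction of total spectral power above ``cutoff`` Hz, in [0, 1].

    Operationalises the visual stenosis signature — persistently
    elevated high-frequency content — as a single scale-invariant
    number.  ``cutoff`` must lie strictly between 0 and Nyquist.
    """
    if not 0.0 < cutoff < S.nyquist:
        raise ValueError(f"cutoff must lie in (0, {S.nyquist}) Hz, got {cutoff}")
    total = float(S.power.sum())
    if total <= 0.0:
        raise ValueError("spectrogram has zero total power")
    high = float(S.power[S.freqs > cutoff, :].sum())
    return high / total


def detect_transient_peaks(
    S: Spectrogram, energy_factor: float = 5.0, max_span: int = 3
) -> List[int]:
    """Flag fleeting high-energy time bins (recording artifacts).

    A time bin is a candidate when its total power exceeds
    ``energy_factor`` times the median per-bin power.  Candidates are
    kept only if they belong to a run of at most ``max_span``
    consecutive flagged bins: a sustained elevation (as produced by
    genuine disturbed flow) is not an artifact and is not flagged.
    Returns the flagged time-bin indices, possibly empty.
    """
    if energy_factor <= 0:
        raise ValueError("energy_factor must be positive")
    if max_span < 1:
        raise ValueError("max_span must be >= 1")
    bin_power = S.power.sum(axis=0)
    med = float(np.median(bin_power))
    hot = bin_power > energy_factor * med
    flagged: List[int] = []
    i = 0
    n = len(hot)
    while i < n:
        if hot[i]:
            j = i
            while j < n and hot[j]:
                j += 1
            if j - i <= max_span:
                flagged.extend(range(i, j))
            i = j
        else:
            i += 1
    return flagged


def save_spectrogram(
    S: Spectrogram, path: os.PathLike | str, png: os.PathLike | str | None = None
) -> None:
    """Persist a spectrogram to HDF5, optionally rendering a log-power PNG."""
    with h5py.File(path, "w") as f:
        f.create_dataset("power", data=S.power)
        f.create_dataset("freqs", data=S.freqs)
        f.create_dataset("times", data=S.times)
        f.attrs.update(
            window_len=S.window_len, overlap=S.overlap, window=S.window, fs=S.fs
        )
    if png is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4))
        log_power = 10.0 * np.log10(S.power + 1e-20)
        mesh = ax.pcolormesh(S.times, S.freqs, log_power, cmap="viridis", shading="auto")
        fig.colorbar(mesh, ax=ax, label="power (dB)")
        ax.set_xlabel("time (s)")
        ax.set_ylabel("frequency (Hz)")
        fig.savefig(png, dpi=120)
        plt.close(fig)
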