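"""Synthetic B-mode-like speckle cine loops with known flow labels.

Real cine loops of fistula blood flow show a granular speckle pattern
whose temporal evolution encodes the flow regime: laminar flow advects
speckle coherently and decorrelates it slowly (low temporal
frequencies), while disturbed post-stenotic flow decorrelates the
pattern rapidly and with stronger pulsatile intensity modulation (high
temporal frequencies).  The generator reproduces exactly this
statistical structure — not ultrasound physics — via an advected,
exponentially decorrelating filtered-noise field with sinusoidal
intensity modulation:

* frame 0 is low-pass-filtered Gaussian noise (grain size in pixels);
* frame k+1 is frame k shifted by the advection speed and blended with
  fresh filtered noise so that temporal autocorrelation decays at the
  decorrelation rate;
* each frame is intensity-modulated by
  ``1 + depth * sin(2*pi*f_mod*k/frame_rate)`` and observed with
  additive Gaussian noise, clipped to [0, 1].

Optional extras emulate the two acquisition conditions studied: bright
surrounding-tissue clutter outside the lumen, animated by
label-independent acquisition dynamics (the full-frame condition), and
fleeting high-gain brightness transients (probe/patient movement
artifacts).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterator, List, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter

from .io_video import SITES, CineLoop

__all__ = [
    "FlowParams",
    "CohortConfig",
    "LAMINAR_PRESET",
    "DISTURBED_PRESET",
    "generate_speckle_video",
    "add_clutter",
    "inject_artifact",
    "iter_cohort",
    "generate_cohort",
    "mean_signal",
]

# Speckle contrast: SD of the zero-mean pattern around mid-gray.
_CONTRAST = 0.18


@dataclass(frozen=True)
class FlowParams:
    """Flow-regime parameters of one synthetic loop.

    ``advect_speed`` in pixels/frame, ``decorrelation_rate`` the
    per-frame fraction of the speckle pattern replaced by fresh noise,
    ``modulation_freq`` (Hz) and ``modulation_depth`` the pulsatile
    intensity modulation, ``speckle_grain`` the low-pass filter sigma in
    pixels, ``noise_sd`` additive observation noise in gray levels.
    """

    class_label: str
    advect_speed: float = 1.0
    decorrelation_rate: float = 0.02
    modulation_freq: float = 1.0
    modulation_depth: float = 0.2
    speckle_grain: float = 1.5
    noise_sd: float = 0.01

    def __post_init__(self) -> None:
        if self.class_label not in ("laminar", "disturbed"):
            raise ValueError("class_label must be 'laminar' or 'disturbed'")
        if not 0.0 <= self.decorrelation_rate <= 1.0:
            raise ValueError("decorrelation_rate must lie in [0, 1]")
        if not 0.0 <= self.modulation_depth <= 1.0:
            raise ValueError("modulation_depth must lie in [0, 1]")
        if self.modulation_freq < 0 or self.speckle_grain <= 0 or self.noise_sd < 0:
            raise ValueError("invalid flow parameters")


#: Healthy laminar flow: slow decorrelation, ~1 Hz pulse, shallow modulation.
LAMINAR_PRESET = FlowParams(
    class_label="laminar", advect_speed=1.0, decorrelation_rate=0.02,
    modulation_freq=1.0, modulation_depth=0.2,
)

#: Post-stenotic disturbed flow: fast decorrelation, strong 8 Hz modulation.
DISTURBED_PRESET = FlowParams(
    class_label="disturbed", advect_speed=1.0, decorrelation_rate=0.25,
    modulation_freq=8.0, modulation_depth=0.4,
)


@dataclass(frozen=True)
class CohortConfig:
    """Specification of a labelled synthetic cohort.

    Loops are generated at ``frame_shape`` with the flow confined to
    ``lumen`` (row0, col0, row1, col1); with ``clutter`` on, pixels
    outside the lumen become bright animated tissue texture (the
    full-frame condition).  Labels are 1 for disturbed, 0 for laminar;
    sites rotate round-robin within each class so stratified splitting
    is exercised.
    """

    n_videos: int = 60
    class_balance: float = 0.5
    frame_shape: Tuple[int, int] = (96, 96)
    n_frames: int = 600
    frame_rate: float = 60.0
    lumen: Tuple[int, int, int, int] = (38, 38, 58, 58)
    clutter: bool = False
    artifact_prob: float = 0.0
    seed: int = 0
    laminar: FlowParams = LAMINAR_PRESET
    disturbed: FlowParams = DISTURBED_PRESET

    def __post_init__(self) -> None:
        if self.n_videos < 4:
            raise ValueError("need at least 4 videos")
        n_pos = round(self.n_videos * self.class_balance)
        if n_pos < 1 or n_pos > self.n_videos - 1:
            raise ValueError("class_balance must leave at least one video per class")
        if self.n_frames < 1 or self.n_frames > 1000:
            raise ValueError("n_frames must lie in [1, 1000]")
        row0, col0, row1, col1 = self.lumen
        I, J = self.frame_shape
        if not (0 <= row0 < row1 <= I and 0 <= col0 < col1 <= J):
            raise ValueError(f"lumen {self.lumen} not inside frame {self.frame_shape}")
        if not 0.0 <= self.artifact_prob <= 1.0:
            raise ValueError("artifact_prob must lie in [0, 1]")
        if self.disturbed.decorrelation_rate <= self.laminar.decorrelation_rate:
            raise ValueError("disturbed preset must decorrelate faster than laminar")
        if self.disturbed.modulation_freq <= self.laminar.modulation_freq:
            raise ValueError("disturbed preset must modulate faster than laminar")

    @property
    def n_positive(self) -> int:
        return round(self.n_videos * self.class_balance)


def _filtered_noise(rng: np.random.Generator, shape: Tuple[int, int], grain: float) -> np.ndarray:
    """Unit-variance low-pass-filtered Gaussian field."""
    f = gaussian_filter(rng.standard_normal(shape), sigma=grain, mode="wrap")
    sd = f.std()
    return f / sd if sd > 0 else f


def generate_speckle_video(
    p: FlowParams,
    shape: Tuple[int, int] = (20, 20),
    n_frames: int = 600,
    frame_rate: float = 60.0,
    seed: int = 0,
    subject_id: str = "",
    site: str = "venous_outflow",
) -> CineLoop:
    """Generate one speckle loop under flow parameters ``p``.

    The speckle field follows an advected AR(1) process: with
    ``rho = 1 - decorrelation_rate``,
    ``s[k+1] = rho * shift(s[k]) + sqrt(1 - rho^2) * fresh`` keeps the
    field stationary with frame-lag correlation ``rho``.
    """
    if n_frames < 1 or frame_rate <= 0:
        raise ValueError("need n_frames >= 1 and frame_rate > 0")
    rng = np.random.default_rng(seed)
    I, J = shape
    rho = 1.0 - p.decorrelation_rate
    fresh_scale = np.sqrt(max(1.0 - rho * rho, 0.0))
    s = _filtered_noise(rng, (I, J), p.speckle_grain)
    frames = np.empty((I, J, n_frames))
    shift_accum = 0.0
    shifted = 0
    for k in range(n_frames):
        modulation = 1.0 + p.modulation_depth * np.sin(
            2.0 * np.pi * p.modulation_freq * k / frame_rate
        )
        img = (0.5 + _CONTRAST * s) * modulation
        if p.noise_sd > 0:
            img = img + rng.normal(0.0, p.noise_sd, size=(I, J))
        frames[:, :, k] = np.clip(img, 0.0, 1.0)
        # evolve the field for the next frame
        shift_accum += p.advect_speed
        step = int(round(shift_accum)) - shifted
        shifted += step
        advected = np.roll(s, step, axis=1) if step else s
        if fresh_scale > 0:
            s = rho * advected + fresh_scale * _filtered_noise(rng, (I, J), p.speckle_grain)
        else:
            s = advected
    return CineLoop(
        frames=frames, frame_rate=frame_rate, subject_id=subject_id, site=site
    )


def _smooth_drift(rng: np.random.Generator, n: int, fs: float,
                  bandwidth: float, rms: float) -> np.ndarray:
    """Zero-mean low-frequency displacement signal with the given RMS."""
    from scipy.ndimage import gaussian_filter1d

    sig = gaussian_filter1d(rng.standard_normal(n), sigma=fs / (2.0 * np.pi * bandwidth))
    sig -= sig.mean()
    sd = sig.std()
    return sig / sd * rms if sd > 0 else sig


def _bandpass_noise(rng: np.random.Generator, n: int, fs: float,
                    band: Tuple[float, float], rms: float) -> np.ndarray:
    """Zero-mean noise band-limited to ``band`` Hz with the given RMS."""
    spec = np.fft.rfft(rng.standard_normal(n))
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spec[(freqs < band[0]) | (freqs > band[1])] = 0.0
    sig = np.fft.irfft(spec, n)
    sd = sig.std()
    return sig / sd * rms if sd > 0 else sig


def add_clutter(
    loop: CineLoop,
    lumen: Tuple[int, int, int, int],
    seed: int = 0,
    drift_rms: float = 0.25,
    drift_bandwidth: float = 1.5,
    vibration_rms: float = 0.3,
    vibration_band: Tuple[float, float] = (4.0, 12.0),
    tremor_rms: float = 0.15,
    gain_noise_sd: float = 0.06,
    gain_band: Tuple[float, float] = (0.3, 24.0),
    ramp_gain_sd: float = 0.14,
    ramp_band: Tuple[float, float] = (0.3, 12.0),
    jitter_sd: float = 0.01,
) -> CineLoop:
    """Replace pixels outside ``lumen`` with bright surrounding-tissue texture.

    The clutter is a fixed bright texture animated by label-independent
    tissue dynamics: a slow sub-pixel drift (breathing / probe-pressure,
    ``drift_rms`` pixels RMS below ``drift_bandwidth`` Hz), a
    pulse-transmitted vibration (band-limited displacement noise,
    ``vibration_rms`` pixels RMS in ``vibration_band`` Hz — tissue next
    to a fistula shakes with the cardiac cycle and its harmonics), a
    broadband hand-tremor displacement (``tremor_rms`` pixels RMS, white
    across frames), and brightness fluctuations over ``gain_band`` Hz
    with a uniform profile (``gain_noise_sd``; probe-coupling
    variation) and with axial and lateral ramp profiles
    (``ramp_gain_sd`` each; breathing- and pulse-driven time-gain-
    compensation and beam-coupling variation), plus small per-pixel
    jitter.  Per pixel the clutter varies far less than the flow region,
    but its dynamics are bright, spatially coherent over most of the
    frame and occupy the same temporal-frequency band as the flow
    signature, so they dominate the leading components of a low-rank
    decomposition — the mechanism by which full-frame analysis loses the
    flow signal.  Pixels inside the lumen are untouched, so cropping to
    the lumen recovers the original flow loop exactly.
    """
    row0, col0, row1, col1 = lumen
    I, J, K = loop.shape
    if not (0 <= row0 < row1 <= I and 0 <= col0 < col1 <= J):
        raise ValueError(f"lumen {lumen} not inside frame {(I, J)}")
    rng = np.random.default_rng(seed)
    # tissue-motion and coupling strengths vary between recordings
    # (operator pressure, breathing depth, anatomy): each amplitude gets
    # a per-recording multiplier
    scale = {name: rng.uniform(0.7, 1.5)
             for name in ("drift", "vibration", "tremor")}
    drift_rms = drift_rms * scale["drift"]
    vibration_rms = vibration_rms * scale["vibration"]
    tremor_rms = tremor_rms * scale["tremor"]
    gain_noise_sd = gain_noise_sd * rng.uniform(0.9, 1.4)
    ramp_gain_sd = ramp_gain_sd * rng.uniform(0.9, 1.4)
    pad = int(np.ceil(3.0 * (drift_rms + vibration_rms + tremor_rms))) + 1
    # sharp speckle-like tissue texture: sub-pixel motion of a sharp
    # bright field is spatially coherent (it rides the texture gradient)
    # even though each pixel barely changes
    texture = 0.7 + 0.2 * _filtered_noise(rng, (I + 2 * pad, J + 2 * pad), 1.2)

    def displacement() -> np.ndarray:
        d = _smooth_drift(rng, K, loop.frame_rate, drift_bandwidth, drift_rms)
        d = d + _bandpass_noise(rng, K, loop.frame_rate, vibration_band, vibration_rms)
        if tremor_rms > 0:
            d = d + rng.normal(0.0, tremor_rms, size=K)
        return np.clip(d, -pad + 1, pad - 1)

    dy = displacement()
    dx = displacement()
    frames = np.empty((I, J, K))
    for k in range(K):
        iy, fy = int(np.floor(dy[k])), dy[k] - np.floor(dy[k])
        ix, fx = int(np.floor(dx[k])), dx[k] - np.floor(dx[k])
        y0, x0 = pad + iy, pad + ix
        # bilinear sample of the texture at sub-pixel offset (dy, dx)
        frames[:, :, k] = (
            (1 - fy) * (1 - fx) * texture[y0:y0 + I, x0:x0 + J]
            + (1 - fy) * fx * texture[y0:y0 + I, x0 + 1:x0 + 1 + J]
            + fy * (1 - fx) * texture[y0 + 1:y0 + 1 + I, x0:x0 + J]
            + fy * fx * texture[y0 + 1:y0 + 1 + I, x0 + 1:x0 + 1 + J]
        )
    if gain_noise_sd > 0:
        g_uniform = _bandpass_noise(rng, K, loop.frame_rate, gain_band, gain_noise_sd)
        frames = frames * (1.0 + g_uniform)
    if ramp_gain_sd > 0:
        g_axial = _bandpass_noise(rng, K, loop.frame_rate, ramp_band, ramp_gain_sd)
        g_lateral = _bandpass_noise(rng, K, loop.frame_rate, ramp_band, ramp_gain_sd)
        axial = np.linspace(0.0, 1.0, I)[:, None, None]
        lateral = np.linspace(0.0, 1.0, J)[None, :, None]
        frames = frames * (1.0 + axial * g_axial) * (1.0 + lateral * g_lateral)
    if jitter_sd > 0:
        frames += rng.normal(0.0, jitter_sd, size=(I, J, K))
    frames = np.clip(frames, 0.0, 1.0)
    frames[row0:row1, col0:col1, :] = loop.frames[row0:row1, col0:col1, :]
    return replace(loop, frames=frames)


def inject_artifact(
    loop: CineLoop, frame_index: int, span: int, gain: float
) -> CineLoop:
    """Apply a fleeting global brightness transient.

    Multiplies ``span`` consecutive frames starting at ``frame_index``
    by ``gain`` (clipped back to [0, 1]), emulating a probe or patient
    movement artifact.
    """
    if span < 1 or frame_index < 0 or frame_index + span > loop.n_frames:
        raise ValueError(
            f"artifact frames [{frame_index}, {frame_index + span}) outside "
            f"loop of {loop.n_frames} frames"
        )
    if gain <= 0:
        raise ValueError("gain must be positive")
    frames = loop.frames.copy()
    frames[:, :, frame_index:frame_index + span] = np.clip(
        frames[:, :, frame_index:frame_index + span] * gain, 0.0, 1.0
    )
    return replace(loop, frames=frames)


def iter_cohort(c: CohortConfig) -> Iterator[Tuple[CineLoop, int, str]]:
    """Yield ``(loop, label, site)`` triples one at a time (memory-friendly)."""
    rng = np.random.default_rng(c.seed)
    n = c.n_videos
    n_pos = c.n_positive
    labels = [1] * n_pos + [0] * (n - n_pos)
    # round-robin sites within each class keeps (site, label) strata even
    class_counter = {0: 0, 1: 0}
    vid_seeds = rng.integers(0, 2**31 - 1, size=n)
    artifact_draws = rng.random(size=n)
    artifact_rngs = rng.integers(0, 2**31 - 1, size=n)
    for i in range(n):
        label = labels[i]
        site = SITES[class_counter[label] % 3]
        class_counter[label] += 1
        params = c.disturbed if label == 1 else c.laminar
        loop = generate_speckle_video(
            params,
            shape=c.frame_shape,
            n_frames=c.n_frames,
            frame_rate=c.frame_rate,
            seed=int(vid_seeds[i]),
            subject_id=f"syn{i:03d}",
            site=site,
        )
        if c.artifact_prob > 0 and artifact_draws[i] < c.artifact_prob:
            # probe/patient movement transient: a fraction of a second
            art_rng = np.random.default_rng(int(artifact_rngs[i]))
            span = min(int(art_rng.integers(20, 61)), c.n_frames)
            start = int(art_rng.integers(0, max(c.n_frames - span, 1)))
            gain = float(art_rng.uniform(2.5, 4.0))
            loop = inject_artifact(loop, start, span, gain)
        if c.clutter:
            loop = add_clutter(loop, c.lumen, seed=int(vid_seeds[i]) ^ 0x5A5A)
        yield loop, label, site


def generate_cohort(c: CohortConfig) -> List[Tuple[CineLoop, int, str]]:
    """Materialise the full cohort as a list (see :func:`iter_cohort`)."""
    return list(iter_cohort(c))


def mean_signal(loop: CineLoop) -> np.ndarray:
    """Spatial-mean gray value per frame — a simple temporal flow signal."""
    return loop.frames.mean(axis=(0, 1))
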