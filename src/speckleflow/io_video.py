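"""Ingestion of B-mode ultrasound cine loops.

A cine loop is a short grayscale video clip recorded during duplex
ultrasound surveillance of an arteriovenous fistula.  Loops are loaded
from any container imageio can decode (a multi-frame TIFF/AVI/MP4 file,
or a directory of zero-pad-indexed PNG/TIFF frames), truncated to the
first ``max_frames`` frames, optionally cropped to a rectangular region
of interest around the vessel lumen, and exposed as third-order tensors
(rows x columns x frames) for decomposition.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Tuple

import imageio.v3 as iio
import numpy as np
import pandas as pd

__all__ = [
    "SITES",
    "CineLoop",
    "load_cine_loop",
    "write_cine_loop",
    "crop_roi",
    "as_tensor",
    "read_manifest",
]

#: Anatomical recording sites along the fistula.
SITES = ("arterial_inflow", "anastomosis", "venous_outflow")

#: Default ingestion frame cap: enough frames to cover at least one
#: cardiac cycle at clinical frame rates.
DEFAULT_MAX_FRAMES = 1000

# ITU-R BT.601 luminance weights for color -> gray conversion.
_BT601 = np.array([0.299, 0.587, 0.114])

_FRAME_EXTENSIONS = (".png", ".tif", ".tiff", ".jpg", ".jpeg", ".bmp")


class IngestionError(RuntimeError):
    """Raised when a cine-loop container cannot be decoded."""


@dataclass(frozen=True)
class CineLoop:
    """One grayscale cine loop with acquisition metadata.

    Parameters
    ----------
    frames
        Array of shape ``(I, J, K)`` — image rows x image columns x
        frame count — with gray values scaled to ``[0, 1]``.
    frame_rate
        Acquisition rate in frames per second.
    subject_id
        Opaque identifier of the recording.
    site
        One of :data:`SITES`.
    roi
        Optional ``(row0, col0, row1, col1)`` rectangle (0-based,
        half-open) recording the crop applied to this loop.
    """

    frames: np.ndarray
    frame_rate: float
    subject_id: str = ""
    site: str = "venous_outflow"
    roi: Optional[Tuple[int, int, int, int]] = None

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames)
        if frames.ndim != 3 or min(frames.shape) < 1:
            raise ValueError(f"frames must be a non-empty 3-D array, got shape {frames.shape}")
        if not np.all(np.isfinite(frames)):
            raise ValueError("frames contain non-finite values")
        if frames.min() < 0.0 or frames.max() > 1.0:
            raise ValueError("pixel values must lie in [0, 1]")
        if not self.frame_rate > 0:
            raise ValueError("frame_rate must be positive")
        if self.site not in SITES:
            raise ValueError(f"site must be one of {SITES}, got {self.site!r}")
        if self.roi is not None:
            # roi records crop provenance in pre-crop coordinates, so only
            # ordering is checked here; bounds are enforced by crop_roi
            # against the frame being cropped.
            row0, col0, row1, col1 = self.roi
            if not (0 <= row0 < row1 and 0 <= col0 < col1):
                raise ValueError(f"roi {self.roi} is not an ordered rectangle")
        object.__setattr__(self, "frames", frames)

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.frames.shape  # type: ignore[return-value]

    @property
    def n_frames(self) -> int:
        return self.frames.shape[2]


def _validate_rect(rect: Tuple[int, int, int, int], n_rows: int, n_cols: int) -> None:
    row0, col0, row1, col1 = rect
    if not (0 <= row0 < row1 <= n_rows and 0 <= col0 < col1 <= n_cols):
        raise ValueError(
            f"rectangle {rect} is not a valid half-open region inside a "
            f"{n_rows}x{n_cols} frame"
        )


def _to_unit_gray(frame: np.ndarray) -> np.ndarray:
    """Convert one decoded frame to float64 gray values in [0, 1]."""
    frame = np.asarray(frame)
    if frame.ndim == 3:
        if frame.shape[2] == 4:  # drop alpha
            frame = frame[:, :, :3]
        if frame.shape[2] == 3:
            frame = frame.astype(np.float64) @ _BT601
        elif frame.shape[2] == 1:
            frame = frame[:, :, 0]
        else:
            raise IngestionError(f"cannot interpret frame with {frame.shape[2]} channels")
    if frame.ndim != 2 or frame.size == 0:
        raise IngestionError("zero-area or non-2D frame")
    # Scale by the container's max code value so bit depth does not matter.
    if frame.dtype == np.uint8:
        return frame.astype(np.float64) / 255.0
    if frame.dtype == np.uint16:
        return frame.astype(np.float64) / 65535.0
    out = frame.astype(np.float64)
    if out.size and out.max() > 1.0:  # integer-coded floats (e.g. gray from uint8 RGB)
        out = out / 255.0
    return np.clip(out, 0.0, 1.0)


def _frames_from_directory(path: Path) -> list[np.ndarray]:
    files = sorted(
        f for f in path.iterdir() if f.suffix.lower() in _FRAME_EXTENSIONS
    )
    if not files:
        raise IngestionError(f"no frame images found in directory {path}")
    return [iio.imread(f) for f in files]


def _frames_from_file(path: Path) -> list[np.ndarray]:
    try:
        data = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - surface the codec failure
        raise IngestionError(f"could not decode cine loop {path}: {exc}") from exc
    data = np.asarray(data)
    if data.ndim == 2:
        return [data]
    if data.ndim == 3:
        # (K, I, J) frame stack, except a lone (I, J, 3|4) color frame
        if data.shape[-1] in (3, 4) and data.shape[0] > 4:
            return [data]
        return [data[k] for k in range(data.shape[0])]
    if data.ndim == 4:  # (K, I, J, C)
        return [data[k] for k in range(data.shape[0])]
    raise IngestionError(f"unsupported frame layout with shape {data.shape} in {path}")


def load_cine_loop(
    path: os.PathLike | str,
    max_frames: int = DEFAULT_MAX_FRAMES,
    frame_rate: float = 60.0,
    subject_id: str = "",
    site: str = "venous_outflow",
) -> CineLoop:
    """Load a cine loop and keep only its first ``max_frames`` frames.

    ``path`` may be a video/TIFF file or a directory of frame images
    named with zero-padded indices.  Color frames are converted to gray
    with BT.601 luminance weights and all values are rescaled to
    ``[0, 1]`` by the container's maximum code value.
    """
    if max_frames < 1:
        raise ValueError("max_frames must be >= 1")
    p = Path(path)
    if not p.exists():
        raise IngestionError(f"cine loop path does not exist: {p}")
    raw = _frames_from_directory(p) if p.is_dir() else _frames_from_file(p)
    if not raw:
        raise IngestionError(f"no frames decoded from {p}")
    raw = raw[:max_frames]
    gray = [_to_unit_gray(f) for f in raw]
    if len({g.shape for g in gray}) != 1:
        raise IngestionError(f"frames in {p} have inconsistent shapes")
    frames = np.stack(gray, axis=2)
    return CineLoop(frames=frames, frame_rate=frame_rate, subject_id=subject_id, site=site)


def write_cine_loop(loop: CineLoop, directory: os.PathLike | str) -> Path:
    """Write a loop as 16-bit grayscale PNG frames (frame_0000.png, ...).

    The inverse of :func:`load_cine_loop` on a directory, up to 16-bit
    quantization.  Returns the directory path.
    """
    out = Path(directory)
    out.mkdir(parents=True, exist_ok=True)
    coded = np.round(loop.frames * 65535.0).astype(np.uint16)
    for k in range(loop.n_frames):
        iio.imwrite(out / f"frame_{k:04d}.png", coded[:, :, k])
    return out


def crop_roi(loop: CineLoop, rect: Tuple[int, int, int, int]) -> CineLoop:
    """Crop all frames to rows ``[row0, row1)`` x cols ``[col0, col1)``.

    Metadata is preserved and the rectangle is recorded on the returned
    loop.  The rectangle uses 0-based half-open coordinates.
    """
    _validate_rect(tuple(rect), loop.frames.shape[0], loop.frames.shape[1])
    row0, col0, row1, col1 = rect
    return replace(loop, frames=loop.frames[row0:row1, col0:col1, :], roi=tuple(rect))


def as_tensor(loop: CineLoop) -> np.ndarray:
    """Expose the loop as a third-order tensor of shape ``(I, J, K)``.

    Mode 1 indexes image rows, mode 2 image columns, mode 3 frames.
    """
    return np.asarray(loop.frames, dtype=np.float64)


def read_manifest(path: os.PathLike | str) -> pd.DataFrame:
    """Read a dataset/ROI sidecar CSV.

    Expected columns: ``subject_id, site, path`` plus either ROI corners
    ``row0, col0, row1, col1`` and/or a ``label`` column (0/1, may be
    blank when DUS columns ``psv, volume_flow, diameter, waveform`` are
    given instead).
    """
    df = pd.read_csv(path)
    required = {"subject_id", "site", "path"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest is missing required columns: {sorted(missing)}")
    bad_sites = set(df["site"].unique()) - set(SITES)
    if bad_sites:
        raise ValueError(f"manifest contains unknown sites: {sorted(bad_sites)}")
    return df
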