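"""Labelled feature sequences for the stenosis classifier.

This module bridges decomposition output and classifier input: it
derives binary stenosis labels from duplex-ultrasound (DUS) criteria,
maps decompositions to per-mode factor sequences, builds stratified
train/validation/test splits, and z-score-normalizes and length-aligns
the sequences using statistics from the training set only.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, replace
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .decomposition import CPDecomposition, TuckerDecomposition
from .io_video import SITES

__all__ = [
    "DUSMeasurement",
    "FeatureSequences",
    "SplitSpec",
    "NormalizerState",
    "label_from_dus",
    "extract_features",
    "split_stratified",
    "fit_normalizer",
    "apply_normalizer",
    "save_split",
    "load_split",
    "save_normalizer",
    "load_normalizer",
]

WAVEFORMS = ("monophasic", "biphasic", "triphasic", "unknown")

# DUS stenosis thresholds (clinical criteria per recording site).
PSV_LOW = 50.0        # cm/s, venous outflow
PSV_HIGH = 400.0      # cm/s, all sites
DIAMETER_MIN = 3.5    # mm, venous outflow
VOLUME_FLOW_MIN = 300.0  # ml/min, arterial inflow

SD_FLOOR = 1e-8  # guards constant channels during z-scoring


class InsufficientDataError(ValueError):
    """Raised when no criterion-relevant DUS field is available."""


@dataclass(frozen=True)
class DUSMeasurement:
    """One duplex-ultrasound assessment at a fistula site.

    ``psv`` peak systolic velocity in cm/s, ``volume_flow`` in ml/min,
    ``diameter`` in mm (minimum recorded diameter when a range was
    measured), ``waveform`` the spectral Doppler waveform shape.
    """

    site: str
    psv: Optional[float] = None
    volume_flow: Optional[float] = None
    diameter: Optional[float] = None
    waveform: str = "unknown"

    def __post_init__(self) -> None:
        if self.site not in SITES:
            raise ValueError(f"site must be one of {SITES}, got {self.site!r}")
        if self.waveform not in WAVEFORMS:
            raise ValueError(f"waveform must be one of {WAVEFORMS}")
        for name in ("psv", "volume_flow", "diameter"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValueError(f"{name} must be positive when provided, got {v}")


def label_from_dus(m: DUSMeasurement) -> int:
    """Binary stenosis label from site-specific DUS criteria.

    Venous outflow: PSV < 50 or PSV > 400 cm/s, or diameter < 3.5 mm.
    Anastomosis: PSV > 400 cm/s.
    Arterial inflow: PSV > 400 cm/s, bi/triphasic waveform, or volume
    flow < 300 ml/min.

    A missing field simply cannot fire its criterion; if no
    criterion-relevant field is present at all the measurement is
    uninterpretable and :class:`InsufficientDataError` is raised.
    """
    psv, vf, dia, wf = m.psv, m.volume_flow, m.diameter, m.waveform
    if m.site == "venous_outflow":
        relevant = psv is not None or dia is not None
        fired = (
            (psv is not None and (psv < PSV_LOW or psv > PSV_HIGH))
            or (dia is not None and dia < DIAMETER_MIN)
        )
    elif m.site == "anastomosis":
        relevant = psv is not None
        fired = psv is not None and psv > PSV_HIGH
    else:  # arterial_inflow
        relevant = psv is not None or vf is not None or wf != "unknown"
        fired = (
            (psv is not None and psv > PSV_HIGH)
            or wf in ("biphasic", "triphasic")
            or (vf is not None and vf < VOLUME_FLOW_MIN)
        )
    if not relevant:
        raise InsufficientDataError(
            f"no criterion-relevant DUS field present for site {m.site}"
        )
    return int(fired)


@dataclass
class FeatureSequences:
    """The three per-mode factor sequences of one cine loop.

    ``seq_mode1``/``seq_mode2`` are spatial profiles (rows, columns) and
    ``seq_mode3`` the temporal profile, each ``(length, R)`` with the
    same number of channels ``R``.
    """

    seq_mode1: np.ndarray
    seq_mode2: np.ndarray
    seq_mode3: np.ndarray
    label: int
    site: str = "venous_outflow"
    subject_id: str = ""

    def __post_init__(self) -> None:
        seqs = (self.seq_mode1, self.seq_mode2, self.seq_mode3)
        channels = {s.shape[1] for s in seqs}
        if len(channels) != 1:
            raise ValueError(f"channel counts differ across modes: {channels}")
        for s in seqs:
            if not np.all(np.isfinite(s)):
                raise ValueError("feature sequences must be finite")
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label}")

    @property
    def n_channels(self) -> int:
        return self.seq_mode1.shape[1]

    @property
    def sequences(self) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        return (self.seq_mode1, self.seq_mode2, self.seq_mode3)


def extract_features(
    d: CPDecomposition | TuckerDecomposition,
    label: int,
    site: str = "venous_outflow",
    subject_id: str = "",
) -> FeatureSequences:
    """Map a decomposition to classifier input sequences.

    For a CPD the two spatial factors are used as-is (unit-norm columns)
    and the weights are folded into the temporal factor,
    ``seq_mode3 = C diag(lambda)``, so component scale information
    travels with the temporal signal.  For a Tucker decomposition the
    three orthonormal factors are used directly.
    """
    if isinstance(d, CPDecomposition):
        seq3 = d.factor_C * d.weights
    else:
        seq3 = np.asarray(d.factor_C, dtype=np.float64)
    return FeatureSequences(
        seq_mode1=np.asarray(d.factor_A, dtype=np.float64),
        seq_mode2=np.asarray(d.factor_B, dtype=np.float64),
        seq_mode3=np.asarray(seq3, dtype=np.float64),
        label=int(label), site=site, subject_id=subject_id,
    )


@dataclass(frozen=True)
class SplitSpec:
    """Disjoint train/validation/test id lists with their provenance."""

    train_ids: Tuple[str, ...]
    val_ids: Tuple[str, ...]
    test_ids: Tuple[str, ...]
    fractions: Tuple[float, float, float] = (0.6, 0.2, 0.2)
    seed: int = 0

    def __post_init__(self) -> None:
        all_ids = list(self.train_ids) + list(self.val_ids) + list(self.test_ids)
        if len(all_ids) != len(set(all_ids)):
            raise ValueError("split id lists overlap or repeat ids")


def _largest_remainder(n: int, fractions: Sequence[float]) -> List[int]:
    """Integer allotment of n items to |fractions| bins, largest remainder."""
    exact = [n * f for f in fractions]
    counts = [int(np.floor(e)) for e in exact]
    short = n - sum(counts)
    remainders = sorted(
        range(len(fractions)), key=lambda i: (-(exact[i] - counts[i]), i)
    )
    for i in remainders[:short]:
        counts[i] += 1
    return counts


def split_stratified(
    items: Iterable[Tuple[str, str, int]],
    fractions: Tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> SplitSpec:
    """Stratified 60/20/20 split by (site, label).

    Within each (site, label) stratum the items are shuffled by ``seed``
    and allotted to train/validation/test with largest-remainder
    rounding, so each stratum honours the global fractions to within one
    item.  Deterministic for fixed inputs and seed.
    """
    items = list(items)
    if not items:
        raise ValueError("cannot split an empty item list")
    if abs(sum(fractions) - 1.0) > 1e-9 or any(f < 0 for f in fractions):
        raise ValueError(f"fractions must be non-negative and sum to 1, got {fractions}")
    rng = np.random.default_rng(seed)
    strata: dict[Tuple[str, int], List[str]] = {}
    for subject_id, site, label in items:
        strata.setdefault((site, int(label)), []).append(subject_id)
    splits: Tuple[List[str], List[str], List[str]] = ([], [], [])
    for key in sorted(strata):
        ids = strata[key]
        order = rng.permutation(len(ids))
        shuffled = [ids[i] for i in order]
        counts = _largest_remainder(len(ids), fractions)
        start = 0
        for bin_idx, c in enumerate(counts):
            splits[bin_idx].extend(shuffled[start:start + c])
            start += c
    return SplitSpec(
        train_ids=tuple(splits[0]), val_ids=tuple(splits[1]),
        test_ids=tuple(splits[2]), fractions=tuple(fractions), seed=seed,
    )


@dataclass
class NormalizerState:
    """Training-set z-score statistics and target lengths per component.

    ``means[m]``/``sds[m]`` are per-channel statistics pooled over every
    step of every training sequence of component ``m``; ``lengths[m]``
    is the longest training length of that component, to which all
    sequences are padded or truncated.
    """

    means: Tuple[np.ndarray, np.ndarray, np.ndarray]
    sds: Tuple[np.ndarray, np.ndarray, np.ndarray]
    lengths: Tuple[int, int, int]


def fit_normalizer(train_features: Sequence[FeatureSequences]) -> NormalizerState:
    """Pool per-channel mean/SD and max length over the training set.

    Standard deviations of constant channels are floored at ``1e-8`` so
    degenerate inputs normalize to zero instead of blowing up.
    """
    if not train_features:
        raise ValueError("cannot fit a normalizer on an empty training set")
    means, sds, lengths = [], [], []
    for m in range(3):
        stacked = np.vstack([f.sequences[m] for f in train_features])
        means.append(stacked.mean(axis=0))
        sds.append(np.maximum(stacked.std(axis=0), SD_FLOOR))
        lengths.append(max(f.sequences[m].shape[0] for f in train_features))
    return NormalizerState(means=tuple(means), sds=tuple(sds), lengths=tuple(lengths))


def _align_length(seq: np.ndarray, target: int) -> np.ndarray:
    if seq.shape[0] >= target:
        return seq[:target]
    pad = np.zeros((target - seq.shape[0], seq.shape[1]))
    return np.vstack([seq, pad])


def apply_normalizer(f: FeatureSequences, s: NormalizerState) -> FeatureSequences:
    """Z-score with training statistics, then right-pad/truncate.

    Padding appends zero rows after normalization (i.e. at the training
    mean); truncation keeps the head of the sequence.
    """
    new_seqs = []
    for m in range(3):
        seq = f.sequences[m]
        if seq.shape[1] != len(s.means[m]):
            raise ValueError(
                f"component {m + 1} has {seq.shape[1]} channels, "
                f"normalizer expects {len(s.means[m])}"
            )
        z = (seq - s.means[m]) / s.sds[m]
        new_seqs.append(_align_length(z, s.lengths[m]))
    return replace(f, seq_mode1=new_seqs[0], seq_mode2=new_seqs[1], seq_mode3=new_seqs[2])


def save_split(split: SplitSpec, path: os.PathLike | str) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "train": list(split.train_ids),
                "val": list(split.val_ids),
                "test": list(split.test_ids),
                "fractions": list(split.fractions),
                "seed": split.seed,
            },
            fh, indent=2,
        )


def load_split(path: os.PathLike | str) -> SplitSpec:
    with open(path) as fh:
        d = json.load(fh)
    return SplitSpec(
        train_ids=tuple(d["train"]), val_ids=tuple(d["val"]),
        test_ids=tuple(d["test"]), fractions=tuple(d["fractions"]),
        seed=int(d["seed"]),
    )


def save_normalizer(s: NormalizerState, path: os.PathLike | str) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "means": [m.tolist() for m in s.means],
                "sds": [sd.tolist() for sd in s.sds],
                "lengths": list(s.lengths),
            },
            fh, indent=2,
        )


def load_normalizer(path: os.PathLike | str) -> NormalizerState:
    with open(path) as fh:
        d = json.load(fh)
    return NormalizerState(
        means=tuple(np.asarray(m) for m in d["means"]),
        sds=tuple(np.asarray(sd) for sd in d["sds"]),
        lengths=tuple(int(x) for x in d["lengths"]),
    )
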