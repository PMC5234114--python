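"""Audio I/O, sleep-stage annotations, stage-restricted extraction and framing.

The recordings this pipeline targets are single-channel room-microphone WAV
files stored at 8 kHz. Sleep stages come from a simple CSV export of the
clinical scoring (``subject_id,start_s,end_s,stage`` with AASM stage codes);
analysis is restricted to N2/N3 sleep, where breathing is regular and movement
noise minimal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.io import wavfile
from scipy.signal import resample_poly

from .errors import EmptyOutputError, FormatError, ValidationError

STAGES = frozenset({"W", "N1", "N2", "N3", "REM"})

#: peak integer value used when quantizing to/from 16-bit PCM
_PCM16 = 32767.0


@dataclass
class AudioSignal:
    """A mono waveform with its sample rate.

    samples are floats in [-1, 1]; duration is ``len(samples) / rate_hz``.
    """

    samples: np.ndarray
    rate_hz: int = 8000
    subject_id: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValidationError("AudioSignal samples must be one-dimensional")
        if self.rate_hz <= 0:
            raise ValidationError("rate_hz must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValidationError("AudioSignal samples must be finite")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.rate_hz

    def __len__(self) -> int:
        return len(self.samples)


@dataclass(frozen=True)
class StageInterval:
    """A scored sleep-stage interval, in seconds from recording start."""

    start_s: float
    end_s: float
    stage: str
    subject_id: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start_s < self.end_s):
            raise ValidationError(
                f"invalid interval [{self.start_s}, {self.end_s})"
            )
        if self.stage not in STAGES:
            raise ValidationError(f"unknown stage code {self.stage!r}")


@dataclass
class Frames:
    """Hanning-weighted analysis frames of a signal."""

    data: np.ndarray          # (n_frames, frame_len), window already applied
    rate_hz: int
    window_s: float
    hop_s: float
    window: np.ndarray = field(repr=False, default=None)  # the Hanning taper

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]


def read_wav(path: str | Path, target_rate_hz: int = 8000) -> AudioSignal:
    """Read a PCM WAV file as a mono float signal at ``target_rate_hz``.

    Multi-channel audio is averaged to mono; if the file's rate differs the
    signal is polyphase-resampled, giving ``ceil(n * up / down)`` samples.
    """
    if target_rate_hz <= 0:
        raise ValidationError("target_rate_hz must be positive")
    try:
        rate, data = wavfile.read(str(path))
    except FileNotFoundError:
        raise
    except Exception as exc:  # wavfile raises bare ValueError on junk input
        raise FormatError(f"cannot read {path!r} as a PCM WAV file: {exc}") from exc

    data = np.asarray(data)
    if data.dtype == np.int16:
        x = data / 32768.0
    elif data.dtype == np.int32:
        x = data / 2147483648.0
    elif data.dtype == np.uint8:
        x = (data.astype(np.float64) - 128.0) / 128.0
    else:  # float32/float64 WAV
        x = data.astype(np.float64)
    if x.ndim == 2:
        x = x.mean(axis=1)
    if rate != target_rate_hz:
        g = math.gcd(target_rate_hz, rate)
        x = resample_poly(x, target_rate_hz // g, rate // g)
    return AudioSignal(np.clip(x, -1.0, 1.0), target_rate_hz)


def write_wav(path: str | Path, signal: AudioSignal) -> None:
    """Write a signal as 16-bit PCM."""
    pcm = np.round(np.clip(signal.samples, -1.0, 1.0) * _PCM16).astype(np.int16)
    wavfile.write(str(path), signal.rate_hz, pcm)


def parse_stage_annotations(
    path: str | Path, subject_id: str | None = None
) -> list[StageInterval]:
    """Parse a stage-annotation CSV into sorted, validated intervals.

    The CSV must carry a header ``subject_id,start_s,end_s,stage``. Intervals
    of one subject must not overlap. If ``subject_id`` is given only that
    subject's rows are returned.
    """
    try:
        table = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        return []
    except (OSError, UnicodeDecodeError) as exc:
        raise FormatError(f"cannot read annotation file {path!r}: {exc}") from exc
    required = {"subject_id", "start_s", "end_s", "stage"}
    if not required.issubset(table.columns):
        raise ValidationError(
            f"annotation file {path!r} must have columns {sorted(required)}"
        )
    if subject_id is not None:
        table = table[table["subject_id"].astype(str) == str(subject_id)]
    intervals = [
        StageInterval(
            float(r.start_s), float(r.end_s), str(r.stage), str(r.subject_id)
        )
        for r in table.itertuples()
    ]
    intervals.sort(key=lambda iv: (iv.subject_id, iv.start_s))
    # overlap check per subject
    by_subject: dict[str | None, list[StageInterval]] = {}
    for iv in intervals:
        by_subject.setdefault(iv.subject_id, []).append(iv)
    for sid, ivs in by_subject.items():
        for a, b in zip(ivs, ivs[1:]):
            if b.start_s < a.end_s:
                raise ValidationError(
                    f"overlapping intervals for subject {sid!r}: "
                    f"[{a.start_s},{a.end_s}) and [{b.start_s},{b.end_s})"
                )
    return intervals


def extract_stage_segments(
    signal: AudioSignal,
    intervals: Sequence[StageInterval],
    keep: Iterable[str] = ("N2", "N3"),
) -> AudioSignal:
    """Concatenate, in temporal order, the spans whose stage is in ``keep``.

    Interval bounds map to half-open sample ranges
    ``[round(start_s * rate), round(end_s * rate))`` so adjacent intervals
    never double-count a sample.
    """
    keep = set(keep)
    unknown = keep - STAGES
    if unknown:
        raise ValidationError(f"unknown stage code(s) in keep set: {sorted(unknown)}")
    n = len(signal)
    pieces = []
    for iv in sorted(intervals, key=lambda iv: iv.start_s):
        if iv.stage not in keep:
            continue
        lo = int(round(iv.start_s * signal.rate_hz))
        hi = int(round(iv.end_s * signal.rate_hz))
        if hi > n:
            raise ValidationError(
                f"interval [{iv.start_s},{iv.end_s}) extends past the recording "
                f"({signal.duration_s:.2f} s)"
            )
        pieces.append(signal.samples[lo:hi])
    if not pieces:
        raise EmptyOutputError(
            f"no intervals with stage in {sorted(keep)}: nothing to analyze"
        )
    return AudioSignal(np.concatenate(pieces), signal.rate_hz, signal.subject_id)


def frame_signal(
    signal: AudioSignal, window_s: float = 0.5, overlap: float = 0.8
) -> Frames:
    """Slice a signal into Hanning-weighted frames.

    Frame count is ``floor((N - L) / H) + 1`` with ``L = round(window_s*rate)``
    samples per frame and hop ``H = round(L*(1-overlap))``; the trailing
    remainder is discarded so per-frame energy statistics stay unbiased.
    """
    if not (0 <= overlap < 1):
        raise ValidationError("overlap must be in [0, 1)")
    length = int(round(window_s * signal.rate_hz))
    if length < 2:
        raise ValidationError("window must span at least 2 samples")
    hop = int(round(length * (1.0 - overlap)))
    if hop < 1:
        raise ValidationError("hop is below one sample; reduce overlap")
    n = len(signal)
    if n < length:
        raise ValidationError(
            f"signal of {n} samples is shorter than one {length}-sample window"
        )
    n_frames = (n - length) // hop + 1
    idx = np.arange(length)[None, :] + hop * np.arange(n_frames)[:, None]
    window = np.hanning(length)
    return Frames(
        data=signal.samples[idx] * window,
        rate_hz=signal.rate_hz,
        window_s=length / signal.rate_hz,
        hop_s=hop / signal.rate_hz,
        window=window,
    )
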