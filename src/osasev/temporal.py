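"""Time-domain features: quantized energy levels and transition probabilities.

The intuition: as apnea frequency rises, silent intervals between breathing
sounds become more frequent and longer, so the *transitions* of a coarsely
quantized energy trace summarize severity. The pipeline is

1. frame energies (0.5 s Hanning frames, 80% overlap),
2. dynamic two-threshold quantization into level 1 (silence), level 2
   (ordinary breathing / simple snores) and level 3 (loud, obstruction-related
   snores), with an energy-proportion rule suppressing ripple artifacts,
3. silent runs longer than 20 s flanked by breathing are relabeled level 4 —
   the "OSA candidate" level (a >20 s respiratory arrest is the clinical
   hallmark of an apneic event),
4. a 4x4 matrix of consecutive-frame level transitions, normalized to
   probabilities: the 16 temporal features.

Thresholds are not fixed: every 60 s block the modal per-frame *peak* energy
is re-estimated from a log-energy histogram and the two thresholds track it as
fixed multiples, so slow gain drift or posture changes do not desynchronize
the quantizer.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .audio import AudioSignal, Frames, frame_signal
from .config import TemporalConfig
from .errors import ValidationError

#: energy levels, in order: silence, low (breathing), high (loud snore), OSA candidate
LEVELS = (1, 2, 3, 4)

_HIST_BINS = 64


@dataclass
class EnergyFrameSeries:
    """Per-frame energy descriptors aligned with a :class:`Frames` object."""

    energies: np.ndarray            # mean squared (Hanning-weighted) sample
    max_sample_energy: np.ndarray   # max squared (Hanning-weighted) sample
    fill_proportion: np.ndarray     # fraction of frame energy above the silence floor
    hop_s: float
    window_s: float

    def __post_init__(self) -> None:
        for arr in (self.energies, self.max_sample_energy, self.fill_proportion):
            if arr.shape != self.energies.shape:
                raise ValidationError("energy series arrays must be aligned")
        if np.any(self.energies < 0):
            raise ValidationError("energies must be non-negative")

    def __len__(self) -> int:
        return len(self.energies)


@dataclass
class ThresholdState:
    """Dynamic quantization thresholds tracking the modal peak energy.

    ``lower_thr = ratio_low * mode_estimate`` separates silence from
    breathing; ``upper_thr = ratio_high * mode_estimate`` separates breathing
    from loud snoring. ``mode_estimate`` is exponentially smoothed across
    blocks with weight ``smoothing`` on the previous value.
    """

    smoothing: float = 0.9
    ratio_low: float = 2.0
    ratio_high: float = 20.0
    mode_estimate: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.smoothing <= 1):
            raise ValidationError("smoothing must be in [0, 1]")
        if not (0 < self.ratio_low < self.ratio_high):
            raise ValidationError("need 0 < ratio_low < ratio_high")

    @property
    def lower_thr(self) -> float:
        if self.mode_estimate is None:
            raise ValidationError("thresholds undefined before the first update")
        return self.ratio_low * self.mode_estimate

    @property
    def upper_thr(self) -> float:
        if self.mode_estimate is None:
            raise ValidationError("thresholds undefined before the first update")
        return self.ratio_high * self.mode_estimate


@dataclass
class LevelSeries:
    """Per-frame quantized energy levels in {1, 2, 3, 4}."""

    levels: np.ndarray
    hop_s: float

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=np.int64)
        if not np.isin(self.levels, LEVELS).all():
            raise ValidationError("levels must be in {1, 2, 3, 4}")

    def __len__(self) -> int:
        return len(self.levels)


@dataclass
class TransitionMatrix:
    """4x4 level-transition probabilities; the 16 entries sum to one."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if self.probs.shape != (4, 4):
            raise ValidationError("transition matrix must be 4x4")
        if np.any(self.probs < 0):
            raise ValidationError("transition probabilities must be non-negative")


def compute_frame_energy(frames: Frames, silence_floor: float = 0.0) -> EnergyFrameSeries:
    """Per-frame mean energy, peak energy and energy-fill proportion.

    ``fill_proportion`` is the fraction of a frame's squared-sample energy
    contributed by samples whose squared value exceeds ``silence_floor``; an
    all-silent frame has fill 0. A frame holding a single click over silence
    therefore has high fill but is dominated by its peak — the proportion rule
    downstream uses this to reject ripple artifacts.
    """
    sq = frames.data**2
    energies = sq.mean(axis=1)
    peaks = sq.max(axis=1)
    total = sq.sum(axis=1)
    above = np.where(sq > silence_floor, sq, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore"):
        fill = np.where(total > 0, above / np.where(total > 0, total, 1.0), 0.0)
    return EnergyFrameSeries(
        energies=energies,
        max_sample_energy=peaks,
        fill_proportion=fill,
        hop_s=frames.hop_s,
        window_s=frames.window_s,
    )


def update_thresholds(state: ThresholdState, block: EnergyFrameSeries) -> ThresholdState:
    """Update the modal peak-energy estimate from one block of frames.

    The mode is the center of the modal bin of a 64-bin histogram of
    log10(peak energy) over the block's non-silent frames, mapped back to
    linear energy. The first update sets the estimate directly; later updates
    blend ``smoothing * old + (1 - smoothing) * new``. An all-zero block
    leaves the state unchanged (no mode is defined).
    """
    if len(block) == 0:
        raise ValidationError("threshold update requires a non-empty block")
    peaks = block.max_sample_energy[block.max_sample_energy > 0]
    if peaks.size == 0:
        return state
    logp = np.log10(peaks)
    lo, hi = logp.min(), logp.max()
    if hi - lo < 1e-12:
        mode = float(10.0 ** lo)
    else:
        counts, edges = np.histogram(logp, bins=_HIST_BINS, range=(lo, hi))
        b = int(np.argmax(counts))
        mode = float(10.0 ** ((edges[b] + edges[b + 1]) / 2.0))
    if state.mode_estimate is None:
        new_mode = mode
    else:
        new_mode = state.smoothing * state.mode_estimate + (1 - state.smoothing) * mode
    return replace(state, mode_estimate=new_mode)


def quantize_levels(
    e: EnergyFrameSeries, thr: ThresholdState, proportion_threshold: float = 0.5
) -> LevelSeries:
    """Quantize frames into levels 1-3.

    A frame is level 1 (silence) when its peak energy is at or below the lower
    threshold *or* its energy-fill proportion is below ``proportion_threshold``
    (the ripple-rejection rule); otherwise level 2 up to the upper threshold,
    level 3 above it. Bands are closed from above (ties map to the lower band).
    """
    lower, upper = thr.lower_thr, thr.upper_thr
    peaks = e.max_sample_energy
    levels = np.ones(len(e), dtype=np.int64)
    loud = (peaks > lower) & (e.fill_proportion >= proportion_threshold)
    levels[loud & (peaks <= upper)] = 2
    levels[loud & (peaks > upper)] = 3
    return LevelSeries(levels=levels, hop_s=e.hop_s)


def mark_osa_candidates(levels: LevelSeries, min_gap_s: float = 20.0) -> LevelSeries:
    """Relabel long, breathing-flanked silences as level 4 (OSA candidate).

    Every maximal run of level 1 lasting strictly more than ``min_gap_s``
    whose immediately preceding and following frames are both breathing levels
    (2 or 3, either order) is relabeled 4 in full. Runs touching either end of
    the recording are left alone — the rule requires both flanks.
    """
    lv = levels.levels
    if np.any(lv == 4):
        raise ValidationError("input already contains level 4")
    out = lv.copy()
    n = len(lv)
    i = 0
    while i < n:
        if lv[i] != 1:
            i += 1
            continue
        j = i
        while j < n and lv[j] == 1:
            j += 1
        run_s = (j - i) * levels.hop_s
        if (
            run_s > min_gap_s
            and i > 0
            and j < n
            and lv[i - 1] in (2, 3)
            and lv[j] in (2, 3)
        ):
            out[i:j] = 4
        i = j
    return LevelSeries(levels=out, hop_s=levels.hop_s)


def transition_counts(levels: LevelSeries) -> np.ndarray:
    """Raw 4x4 consecutive-pair counts (pooled across calls by addition)."""
    lv = levels.levels
    if len(lv) < 2:
        raise ValidationError("need at least 2 frames to count transitions")
    counts = np.zeros((4, 4), dtype=np.float64)
    np.add.at(counts, (lv[:-1] - 1, lv[1:] - 1), 1.0)
    return counts


def normalize_counts(counts: np.ndarray, row_normalize: bool = False) -> TransitionMatrix:
    """Turn pooled transition counts into a probability matrix."""
    if counts.sum() == 0:
        raise ValidationError("no transitions to normalize")
    if row_normalize:
        row_sums = counts.sum(axis=1, keepdims=True)
        probs = np.divide(counts, row_sums, out=np.zeros_like(counts), where=row_sums > 0)
    else:
        probs = counts / counts.sum()
    return TransitionMatrix(probs=probs)


def transition_matrix(levels: LevelSeries, row_normalize: bool = False) -> TransitionMatrix:
    """Accumulate consecutive-pair transition counts and normalize.

    By default normalization is global — the 16 entries sum to 1, so the
    (1,1) entry is the overall silence-dwell probability. ``row_normalize``
    switches to a row-stochastic (conditional) matrix.
    """
    return normalize_counts(transition_counts(levels), row_normalize)


def temporal_feature_vector(tm: TransitionMatrix) -> dict[str, float]:
    """The 16 named transition features, row-major: ``t_(i x j)`` = P(i -> j)."""
    return {
        f"t_({i} x {j})": float(tm.probs[i - 1, j - 1])
        for i in LEVELS
        for j in LEVELS
    }


def quantize_signal(frames: Frames, cfg: TemporalConfig) -> LevelSeries:
    """Blockwise dynamic quantization of a whole framed recording (levels 1-3).

    Thresholds are re-estimated every ``block_s`` of frames; each block's fill
    proportions use a silence floor of ``silence_floor_fraction * lower_thr``
    (per squared sample). Frames before any threshold is defined (all-zero
    leading blocks) are level 1.
    """
    base = compute_frame_energy(frames)
    n = len(base)
    per_block = max(1, int(round(cfg.block_s / frames.hop_s)))
    state = ThresholdState(
        smoothing=cfg.smoothing, ratio_low=cfg.ratio_low, ratio_high=cfg.ratio_high
    )
    levels = np.ones(n, dtype=np.int64)
    for start in range(0, n, per_block):
        sl = slice(start, min(start + per_block, n))
        block = EnergyFrameSeries(
            energies=base.energies[sl],
            max_sample_energy=base.max_sample_energy[sl],
            fill_proportion=base.fill_proportion[sl],
            hop_s=base.hop_s,
            window_s=base.window_s,
        )
        state = update_thresholds(state, block)
        if state.mode_estimate is None:
            continue  # nothing but silence so far
        floor = cfg.silence_floor_fraction * state.lower_thr
        block_e = EnergyFrameSeries(
            energies=base.energies[sl],
            max_sample_energy=base.max_sample_energy[sl],
            fill_proportion=_fill(frames.data[sl], floor),
            hop_s=base.hop_s,
            window_s=base.window_s,
        )
        levels[sl] = quantize_levels(block_e, state, cfg.proportion_threshold).levels
    return LevelSeries(levels=levels, hop_s=frames.hop_s)


def temporal_features(signal: AudioSignal, cfg: TemporalConfig) -> dict[str, float]:
    """Full time-domain pipeline: framing to the 16 transition features."""
    return temporal_features_segments([signal], cfg)


def temporal_features_segments(
    segments: list[AudioSignal], cfg: TemporalConfig
) -> dict[str, float]:
    """Transition features pooled over independently processed segments.

    Each segment gets its own framing, threshold adaptation and level-4
    marking; transition counts are summed across segments (no artificial
    pair spans a segment boundary) and normalized once.
    """
    counts = np.zeros((4, 4))
    for segment in segments:
        frames = frame_signal(segment, window_s=cfg.window_s, overlap=cfg.overlap)
        levels = quantize_signal(frames, cfg)
        levels = mark_osa_candidates(levels, min_gap_s=cfg.min_gap_s)
        counts += transition_counts(levels)
    tm = normalize_counts(counts, row_normalize=cfg.row_normalize)
    return temporal_feature_vector(tm)


def _fill(frame_data: np.ndarray, floor: float) -> np.ndarray:
    sq = frame_data**2
    total = sq.sum(axis=1)
    above = np.where(sq > floor, sq, 0.0).sum(axis=1)
    return np.where(total > 0, above / np.where(total > 0, total, 1.0), 0.0)
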