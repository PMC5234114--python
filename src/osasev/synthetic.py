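"""Synthetic sleep-breathing audio with controllable OSA severity.

No public corpus of full-night bedside breathing recordings with AHI labels
exists, so every pipeline stage is exercised on generated audio whose ground
truth is known by construction:

* breathing — band-passed noise amplitude-modulated once per breath cycle
  (a single inspiratory-dominant burst per period, so the envelope's
  fundamental cyclic frequency is exactly the breath rate);
* snoring — on a configurable fraction of breaths the burst carrier is a
  harmonic pulse train (fundamental ~80 Hz), louder than plain breathing;
  the periodic gating injects genuine second-order cyclostationarity at
  alpha = 1/breath_period;
* apneas — silent gaps with durations uniform in [15, 40] s inserted at a
  Poisson rate matching the target AHI, always flanked by breathing, so a
  known subset crosses the 20 s OSA-candidate threshold;
* background — stationary white noise plus 60 Hz mains hum (and harmonics)
  mixed at a configurable SNR against the breathing RMS.

The whole recording is annotated as stage N2. What this emulates — and what
it does not (real snore acoustics, position changes, arousals) — is discussed
in the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .audio import AudioSignal, StageInterval
from .errors import ValidationError
from .model import SEVERITIES, ahi_to_severity

_RATE = 8000

#: apnea gap duration range (s); straddles the 20 s candidate threshold
_GAP_RANGE = (15.0, 40.0)
_EDGE_MARGIN_S = 20.0    # breathing kept clear at both recording ends
_GAP_SPACING_S = 8.0     # minimum breathing between consecutive gaps

#: per-severity snore fractions for cohorts (snoring prevalence rises with severity)
_CLASS_SNORE_FRACTION = {"normal": 0.15, "mild": 0.35, "moderate": 0.5, "severe": 0.65}

#: target-AHI bands per severity class for cohort generation (events/hour)
CLASS_AHI_BANDS = {
    "normal": (0.0, 5.0),
    "mild": (5.0, 15.0),
    "moderate": (15.0, 30.0),
    "severe": (30.0, 60.0),
}


@dataclass(frozen=True)
class SyntheticSubjectSpec:
    """Generation parameters for one synthetic subject."""

    target_ahi: float
    breath_period_s: float = 4.0
    snore_fraction: float = 0.5
    snore_f0_hz: float = 80.0
    noise_snr_db: float = 15.0
    duration_min: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target_ahi < 0:
            raise ValidationError("target_ahi must be non-negative")
        if not (0 <= self.snore_fraction <= 1):
            raise ValidationError("snore_fraction must be in [0, 1]")
        if self.duration_min <= 0:
            raise ValidationError("duration_min must be positive")


@dataclass(frozen=True)
class Event:
    start_s: float
    end_s: float
    kind: str  # apnea | breath | snore


@dataclass
class CohortSubject:
    """One generated subject with its ground truth."""

    subject_id: str
    signal: AudioSignal
    intervals: list[StageInterval]
    events: list[Event]
    ahi: float
    severity: str
    spec: SyntheticSubjectSpec = field(repr=False, default=None)

    @property
    def apnea_count(self) -> int:
        return sum(1 for e in self.events if e.kind == "apnea")


def _breath_carrier(n: int, rng: np.random.Generator) -> np.ndarray:
    """Band-passed (300-1500 Hz) unit-RMS noise: the turbulent-flow carrier."""
    sos = sps.butter(4, [300, 1500], btype="bandpass", fs=_RATE, output="sos")
    x = sps.sosfilt(sos, rng.standard_normal(n))
    return x / max(np.sqrt(np.mean(x**2)), 1e-12)


def _snore_carrier(n: int, f0: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS harmonic pulse train: stacked harmonics with 1/k rolloff."""
    t = np.arange(n) / _RATE
    x = np.zeros(n)
    k = 1
    while k * f0 < 1500 and k <= 12:
        x += np.sin(2 * np.pi * k * f0 * t + rng.uniform(0, 2 * np.pi)) / k
        k += 1
    return x / max(np.sqrt(np.mean(x**2)), 1e-12)


def _place_apneas(
    duration_s: float, target_ahi: float, rng: np.random.Generator
) -> list[tuple[float, float]]:
    """Draw a Poisson number of non-overlapping gaps, breathing-flanked."""
    n_events = int(rng.poisson(target_ahi * duration_s / 3600.0))
    if n_events == 0:
        return []
    durations = rng.uniform(*_GAP_RANGE, size=n_events)
    occupied = durations.sum() + (n_events - 1) * _GAP_SPACING_S + 2 * _EDGE_MARGIN_S
    free = duration_s - occupied
    if free < 0:
        raise ValidationError(
            f"{n_events} apnea gaps totalling {durations.sum():.0f} s do not fit "
            f"in a {duration_s:.0f} s recording"
        )
    offsets = np.sort(rng.uniform(0, free, size=n_events))
    gaps = []
    cursor = _EDGE_MARGIN_S
    for i in range(n_events):
        start = cursor + offsets[i]
        gaps.append((float(start), float(start + durations[i])))
        cursor = start + durations[i] + _GAP_SPACING_S - offsets[i]
    return gaps


def synth_subject(
    spec: SyntheticSubjectSpec,
) -> tuple[AudioSignal, list[StageInterval], list[Event], float]:
    """Generate one subject: (audio, stage annotations, event log, realized AHI).

    Deterministic under the spec's seed. The realized AHI is the inserted
    apnea count per hour of recording; all gaps exceed the 10 s clinical
    minimum by construction.
    """
    rng = np.random.default_rng(spec.seed)
    duration_s = spec.duration_min * 60.0
    n = int(round(duration_s * _RATE))
    t = np.arange(n) / _RATE

    # one inspiratory-dominant burst per breath cycle: the envelope repeats at
    # the breath rate, so its fundamental cyclic frequency is 1/breath_period
    period = spec.breath_period_s
    burst_len = 0.45 * period
    phase = np.mod(t, period)
    envelope = np.where(
        phase < burst_len, np.sin(np.pi * phase / burst_len) ** 2, 0.0
    )

    breath_carrier = _breath_carrier(n, rng)
    snore_carrier = _snore_carrier(n, spec.snore_f0_hz, rng)

    n_cycles = int(np.ceil(duration_s / period))
    snoring_cycle = rng.random(n_cycles) < spec.snore_fraction
    cycle_idx = np.minimum((t // period).astype(int), n_cycles - 1)
    is_snore = snoring_cycle[cycle_idx]
    breath = envelope * np.where(is_snore, 1.6 * snore_carrier, breath_carrier)

    gaps = _place_apneas(duration_s, spec.target_ahi, rng)
    for start, end in gaps:
        breath[int(start * _RATE) : int(end * _RATE)] = 0.0

    active = np.abs(breath) > 0
    breath_rms = np.sqrt(np.mean(breath[active] ** 2)) if active.any() else 1.0
    bg = 0.85 * rng.standard_normal(n)
    for k, amp in ((60.0, 1.0), (120.0, 0.5), (180.0, 0.3)):
        bg += amp * 0.3 * np.sin(2 * np.pi * k * t + rng.uniform(0, 2 * np.pi))
    bg *= (breath_rms / 10 ** (spec.noise_snr_db / 20.0)) / np.sqrt(np.mean(bg**2))

    x = breath + bg
    peak = np.abs(x).max()
    if peak > 0.9:
        x *= 0.9 / peak

    events: list[Event] = [Event(s, e, "apnea") for s, e in gaps]
    for c in range(n_cycles):
        start = c * period
        end = min(start + burst_len, duration_s)
        if any(g0 < end and start < g1 for g0, g1 in gaps):
            continue
        events.append(Event(start, end, "snore" if snoring_cycle[c] else "breath"))
    events.sort(key=lambda e: e.start_s)

    realized_ahi = len(gaps) / (duration_s / 3600.0)
    signal = AudioSignal(x, _RATE)
    return signal, [StageInterval(0.0, duration_s, "N2")], events, realized_ahi


def breathing_with_gaps(
    gap_lengths_s: list[float], rate: int = 8000, seed: int = 0
) -> AudioSignal:
    """Breathing-burst audio with inserted silences of exact given lengths.

    A controlled construction for validating the silence-run rule: each 4 s
    cycle is a 2.2 s noise burst followed by a quiet phase, so quiet frames
    dominate the peak-energy histogram (the dynamic quantizer's operating
    assumption) while a silence run can be padded by at most one breath pause
    (~1.8 s) per side. Gap counting is exact when relabelable gaps exceed
    20 s plus the padding and short gaps stay below 20 s minus it.
    """
    rng = np.random.default_rng(seed)
    segments = []
    breath_s = 32.0  # multiple of the 4 s cycle
    for gap in list(gap_lengths_s) + [None]:
        n = int(breath_s * rate)
        t = np.arange(n) / rate
        phase = np.mod(t, 4.0)
        env = np.where(phase < 2.2, np.sin(np.pi * phase / 2.2) ** 2, 0.0)
        segments.append(env * 0.3 * rng.standard_normal(n))
        if gap is not None:
            segments.append(np.zeros(int(round(gap * rate))))
    x = np.concatenate(segments)
    x += 1e-4 * rng.standard_normal(len(x))  # faint sensor noise everywhere
    return AudioSignal(np.clip(x, -1, 1), rate)


def generate_cohort(
    n_per_class: int,
    duration_min: float = 10.0,
    seed: int = 0,
    breath_period_s: float = 4.0,
    noise_snr_db: float = 15.0,
) -> list[CohortSubject]:
    """Generate a labeled cohort with ``n_per_class`` subjects per severity.

    Target AHIs are drawn uniformly within each class band; a subject whose
    *realized* AHI falls outside its class band (Poisson event counts are
    discrete) is regenerated with a fresh derived seed until label and AHI
    agree. Snore fraction rises with severity class. Deterministic under
    ``seed``.
    """
    if n_per_class < 1:
        raise ValidationError("n_per_class must be >= 1")
    # realized AHI is quantized to one event per recording hour: a class band
    # must contain a multiple of that increment to be realizable at all
    increment = 3600.0 / (duration_min * 60.0)
    for severity, (lo, hi) in CLASS_AHI_BANDS.items():
        k0 = int(np.ceil(lo / increment))
        if severity != "severe" and k0 * increment >= hi:
            raise ValidationError(
                f"recordings of {duration_min:g} min quantize AHI to steps of "
                f"{increment:g}/h; the {severity!r} band [{lo}, {hi}) contains "
                "no realizable value — use longer recordings"
            )
    master = np.random.default_rng(seed)
    cohort: list[CohortSubject] = []
    for severity in SEVERITIES:
        lo, hi = CLASS_AHI_BANDS[severity]
        for i in range(n_per_class):
            for _attempt in range(50):
                spec = SyntheticSubjectSpec(
                    target_ahi=float(master.uniform(lo, hi)),
                    breath_period_s=breath_period_s,
                    snore_fraction=_CLASS_SNORE_FRACTION[severity],
                    noise_snr_db=noise_snr_db,
                    duration_min=duration_min,
                    seed=int(master.integers(0, 2**31 - 1)),
                )
                try:
                    sig, intervals, events, ahi = synth_subject(spec)
                except ValidationError:
                    continue  # gaps did not fit; redraw
                if ahi_to_severity(ahi) == severity:
                    break
            else:
                raise ValidationError(
                    f"could not realize severity {severity!r} in 50 attempts"
                )
            sid = f"{severity}_{i:02d}"
            sig.subject_id = sid
            cohort.append(
                CohortSubject(
                    subject_id=sid, signal=sig, intervals=intervals,
                    events=events, ahi=ahi, severity=severity, spec=spec,
                )
            )
    return cohort
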