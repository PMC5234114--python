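"""End-to-end orchestration: audio -> 709 features -> selection -> LOOCV report.

The per-subject feature vector concatenates the 16 temporal transition
probabilities (``t_*``) with the 693 cyclostationary statistics (``c_*``).
Because the NMF basis is shared across the cohort, extraction is two-phase:
every subject's masked mean CSD is computed first, the rank-45 basis is fit on
the stacked cohort, and each subject is then projected onto it.

A single pipeline seed fans out to per-stage seeds through a CRC-keyed
``SeedSequence`` derivation, so each stage is independently reproducible.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .audio import AudioSignal, StageInterval, extract_stage_segments
from .config import PipelineConfig
from .cyclo import (
    NMFBasis,
    fit_shared_basis,
    otsu_mask,
    project_activations,
    subject_running_mean,
    summarize_statistics,
)
from .denoise import denoise
from .errors import ValidationError
from .model import (
    BinaryMetrics,
    ConfusionMatrix,
    MetricsReport,
    SelectionResult,
    ahi_to_severity,
    binarize_confusion,
    compute_metrics,
    loocv_evaluate,
    select_features,
)
from .synthetic import CohortSubject, generate_cohort

logger = logging.getLogger(__name__)

FEATURE_META_COLUMNS = ("ahi", "severity")


def derive_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31, keyed by the stage name."""
    ss = np.random.SeedSequence([seed, zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class EvaluationReport:
    """Everything one evaluation run produces."""

    selection: SelectionResult | None
    confusion: ConfusionMatrix
    metrics: MetricsReport
    binary: BinaryMetrics
    config: dict
    seed: int


def prepare_signal(
    signal: AudioSignal,
    intervals: list[StageInterval],
    cfg: PipelineConfig,
) -> AudioSignal:
    """Denoise and restrict a recording to the kept sleep stages.

    Order (denoise before or after stage extraction) follows
    ``cfg.denoise_before_extract``; default is denoise-then-extract so the
    noise profile is estimated on the longest available stretch.
    """
    if cfg.denoise_before_extract:
        signal = denoise(signal, cfg.denoise)
        return extract_stage_segments(signal, intervals, keep=cfg.keep_stages)
    signal = extract_stage_segments(signal, intervals, keep=cfg.keep_stages)
    return denoise(signal, cfg.denoise)


def prepare_segments(
    signal: AudioSignal,
    intervals: list[StageInterval],
    cfg: PipelineConfig,
) -> list[AudioSignal]:
    """Prepared analysis segments per ``cfg.concat_segments``.

    With concatenation (default) the kept stages form one continuous signal;
    otherwise each kept interval is processed on its own, so no frame, level
    transition or CSD window spans the splice between non-adjacent stages.
    """
    if cfg.concat_segments:
        return [prepare_signal(signal, intervals, cfg)]
    if cfg.denoise_before_extract:
        signal = denoise(signal, cfg.denoise)
    segments = []
    for iv in sorted(intervals, key=lambda iv: iv.start_s):
        if iv.stage not in cfg.keep_stages:
            continue
        seg = extract_stage_segments(signal, [iv], keep=cfg.keep_stages)
        segments.append(seg if cfg.denoise_before_extract else denoise(seg, cfg.denoise))
    if not segments:
        raise ValidationError(
            f"no intervals with stage in {sorted(cfg.keep_stages)}: nothing to analyze"
        )
    return segments


def extract_cohort_features(
    subjects: list[tuple[str, AudioSignal, list[StageInterval], float]],
    cfg: PipelineConfig | None = None,
    basis: NMFBasis | None = None,
) -> tuple[pd.DataFrame, NMFBasis]:
    """Extract the 709-column feature table for a cohort.

    ``subjects`` holds (subject_id, signal, stage intervals, ahi). Subjects
    failing an individual stage are skipped with a logged reason; the run
    fails only if every subject fails. Returns the feature table (row per
    subject, ``t_*`` + ``c_*`` + ahi + severity) and the NMF basis used
    (fit here unless one is passed in).
    """
    from .temporal import temporal_features_segments  # local import avoids cycle

    cfg = cfg or PipelineConfig()
    rows: dict[str, dict[str, float]] = {}
    masked: dict[str, np.ndarray] = {}
    meta: dict[str, float] = {}
    for sid, signal, intervals, ahi in subjects:
        try:
            segments = prepare_segments(signal, intervals, cfg)
            t_feats = temporal_features_segments(segments, cfg.temporal)
            rms = None
            for segment in segments:
                rms = subject_running_mean(segment, cfg.csd, state=rms)
            masked[sid] = otsu_mask(rms.rms).masked
            rows[sid] = t_feats
            meta[sid] = float(ahi)
        except ValidationError as exc:
            logger.warning("subject %s skipped: %s", sid, exc)
    if not rows:
        raise ValidationError("feature extraction failed for every subject")

    if basis is None:
        basis = fit_shared_basis(
            list(masked.values()),
            rank=cfg.nmf.rank,
            seed=derive_seed(cfg.seed, "nmf"),
            max_iter=cfg.nmf.max_iter,
            tol=cfg.nmf.tol,
        )
    records = []
    for sid, t_feats in rows.items():
        H = project_activations(
            basis, masked[sid], max_iter=cfg.nmf.max_iter, tol=cfg.nmf.tol
        )
        c_feats = summarize_statistics(H, include_mean=cfg.nmf.include_mean)
        ahi = meta[sid]
        records.append(
            {"subject_id": sid, **t_feats, **c_feats,
             "ahi": ahi, "severity": ahi_to_severity(ahi)}
        )
    table = pd.DataFrame.from_records(records).set_index("subject_id")
    return table, basis


def split_features(table: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Split a feature table into (X, severity labels)."""
    feature_cols = [c for c in table.columns if c not in FEATURE_META_COLUMNS]
    return table[feature_cols], table["severity"].to_numpy()


def evaluate_features(
    table: pd.DataFrame, cfg: PipelineConfig | None = None
) -> EvaluationReport:
    """Feature selection + linear-SVM LOOCV + metric computation.

    Default protocol selects the feature subset once on the full cohort and
    reuses it in every LOOCV fold (the workflow behind the published-style
    numbers; optimistic). ``cfg.selection.nested`` switches to leakage-free
    per-fold selection.
    """
    cfg = cfg or PipelineConfig()
    X, y = split_features(table)
    if len(np.unique(y)) < 2:
        raise ValidationError("evaluation requires at least two classes")
    sel_seed = derive_seed(cfg.seed, "selection")
    if cfg.selection.nested:
        selection = None
        cm = loocv_evaluate(
            X, y, C=cfg.svm.C, nested=True,
            k=cfg.selection.k, folds=cfg.selection.folds, seed=sel_seed,
        )
    else:
        selection = select_features(
            X, y, k=cfg.selection.k, folds=cfg.selection.folds,
            seed=sel_seed, C=cfg.svm.C,
        )
        cm = loocv_evaluate(X[selection.selected], y, C=cfg.svm.C)
    return EvaluationReport(
        selection=selection,
        confusion=cm,
        metrics=compute_metrics(cm),
        binary=binarize_confusion(cm),
        config=cfg.to_dict(),
        seed=cfg.seed,
    )


def run_cohort_experiment(
    n_per_class: int = 5,
    duration_min: float = 10.0,
    seed: int = 0,
    cfg: PipelineConfig | None = None,
) -> tuple[EvaluationReport, pd.DataFrame, list[CohortSubject]]:
    """Full synthetic study: simulate -> extract -> select -> LOOCV."""
    cfg = cfg or PipelineConfig()
    cfg.seed = seed
    cohort = generate_cohort(
        n_per_class, duration_min=duration_min, seed=derive_seed(seed, "cohort")
    )
    subjects = [(s.subject_id, s.signal, s.intervals, s.ahi) for s in cohort]
    table, _ = extract_cohort_features(subjects, cfg)
    report = evaluate_features(table, cfg)
    return report, table, cohort
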