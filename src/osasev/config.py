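"""Pipeline configuration.

A single :class:`PipelineConfig` carries every tunable of the pipeline, grouped
by stage. It round-trips losslessly through YAML and rejects unknown keys, so a
config file is an auditable record of a run.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import yaml

from .errors import ValidationError


@dataclass
class DenoiseConfig:
    """Spectral-subtraction denoising parameters."""

    enabled: bool = True
    quantile: float = 0.1        # fraction of lowest-energy frames used for the noise profile
    oversubtraction: float = 1.0
    floor: float = 0.01          # spectral floor as a fraction of the noise magnitude
    nfft: int = 512


@dataclass
class TemporalConfig:
    """Energy framing, quantization and transition-matrix parameters."""

    window_s: float = 0.5
    overlap: float = 0.8
    ratio_low: float = 2.0       # lower threshold = ratio_low * modal peak energy
    ratio_high: float = 20.0
    block_s: float = 60.0        # threshold-update block length
    smoothing: float = 0.9       # EMA weight on the previous mode estimate
    min_gap_s: float = 20.0      # silence longer than this becomes the OSA-candidate level
    proportion_threshold: float = 0.5
    # per-sample silence floor relative to the lower threshold; ~half the modal
    # peak energy, so diffuse background excursions fail the proportion rule
    silence_floor_fraction: float = 0.25
    row_normalize: bool = False  # row-stochastic instead of global normalization


@dataclass
class CsdConfig:
    """Cyclic-spectral-density grid parameters (defaults give the 54 x 889 grid)."""

    window_s: float = 60.0
    n_f: int = 54
    n_alpha: int = 889


@dataclass
class NmfConfig:
    rank: int = 45
    max_iter: int = 500
    tol: float = 1e-6
    include_mean: bool = False   # optional eighth summary statistic per row/column


@dataclass
class SelectionConfig:
    k: int = 50                  # top-k single-feature ranks admitted to forward search
    folds: int = 5
    nested: bool = False         # re-select inside every LOOCV fold (leakage-free mode)


@dataclass
class SvmConfig:
    C: float = 1.0


@dataclass
class PipelineConfig:
    seed: int = 0
    keep_stages: tuple[str, ...] = ("N2", "N3")
    denoise_before_extract: bool = True
    concat_segments: bool = True
    denoise: DenoiseConfig = field(default_factory=DenoiseConfig)
    temporal: TemporalConfig = field(default_factory=TemporalConfig)
    csd: CsdConfig = field(default_factory=CsdConfig)
    nmf: NmfConfig = field(default_factory=NmfConfig)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    svm: SvmConfig = field(default_factory=SvmConfig)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["keep_stages"] = list(self.keep_stages)
        return d

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "PipelineConfig":
        return _build(cls, dict(data))

    def to_yaml(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValidationError(f"config file {path!r} is not a mapping")
        return cls.from_dict(data)


def _build(cls: type, data: dict[str, Any]):
    """Construct a (possibly nested) config dataclass, rejecting unknown keys."""
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ValidationError(
            f"unknown config key(s) for {cls.__name__}: {sorted(unknown)}"
        )
    kwargs: dict[str, Any] = {}
    for name, f in fields.items():
        if name not in data:
            continue
        value = data[name]
        if dataclasses.is_dataclass(f.type) or (
            isinstance(f.type, str) and f.type.endswith("Config")
        ):
            sub_cls = _SUBCONFIGS[name]
            if not isinstance(value, dict):
                raise ValidationError(f"config section {name!r} must be a mapping")
            kwargs[name] = _build(sub_cls, value)
        elif name == "keep_stages":
            kwargs[name] = tuple(value)
        else:
            kwargs[name] = value
    return cls(**kwargs)


_SUBCONFIGS = {
    "denoise": DenoiseConfig,
    "temporal": TemporalConfig,
    "csd": CsdConfig,
    "nmf": NmfConfig,
    "selection": SelectionConfig,
    "svm": SvmConfig,
}
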