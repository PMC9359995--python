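"""Run configuration: defaults mirroring the study's printed constants.

An empty override file reproduces the published analysis settings; the
config round-trips losslessly through YAML.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

from .classify import ClassifierThresholds
from .errors import ValidationError
from .metrics import MeasureParams
from .smlm import FilterMergeParams

__all__ = ["RunConfig", "load_config"]


@dataclass
class HistogramLimits:
    """Axis limits of the density histograms (radius nm, log10 density)."""

    radius_min_nm: float = 0.0
    radius_max_nm: float = 8000.0
    density_min_log10: float = -10.0
    density_max_log10: float = -5.0
    color_min: float = 1e-5
    color_max: float = 1e-3
    bins_1d: int = 50
    bins_2d_radius: int = 64
    bins_2d_density: int = 50


@dataclass
class SimulateConfig:
    """Synthetic-culture and localization-generator settings."""

    n_cells: int = 10
    fate_mix: tuple[float, float, float, float] = (0.6, 0.2, 0.1, 0.1)
    noise_sd: float = 0.01
    n_frames: int = 49
    frame_interval_min: float = 10.0
    n_molecules: int = 20000
    stages: tuple[int, ...] = (1, 2, 3, 4, 5)


@dataclass
class RunConfig:
    """All stage parameters of an end-to-end run plus the seed."""

    seed: int = 0
    measure: MeasureParams = field(default_factory=MeasureParams)
    classify: ClassifierThresholds = field(default_factory=ClassifierThresholds)
    filter_merge: FilterMergeParams = field(default_factory=FilterMergeParams)
    histogram: HistogramLimits = field(default_factory=HistogramLimits)
    simulate: SimulateConfig = field(default_factory=SimulateConfig)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data or {})
        kwargs: dict = {}
        for f in fields(cls):
            if f.name not in data:
                continue
            value = data.pop(f.name)
            if f.name == "seed":
                kwargs["seed"] = int(value)
                continue
            sub_cls = {
                "measure": MeasureParams,
                "classify": ClassifierThresholds,
                "filter_merge": FilterMergeParams,
                "histogram": HistogramLimits,
                "simulate": SimulateConfig,
            }[f.name]
            known = {sf.name for sf in fields(sub_cls)}
            unknown = set(value) - known
            if unknown:
                raise ValidationError(
                    f"unknown key(s) {sorted(unknown)} in config section {f.name!r}"
                )
            value = {
                k: tuple(v) if isinstance(v, list) else v for k, v in value.items()
            }
            kwargs[f.name] = sub_cls(**value)
        if data:
            raise ValidationError(f"unknown config section(s) {sorted(data)}")
        return cls(**kwargs)


def load_config(path=None, seed: int | None = None) -> RunConfig:
    """Load a YAML config (defaults for every key not overridden)."""
    data = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    cfg = RunConfig.from_dict(data)
    if seed is not None:
        cfg.seed = int(seed)
    return cfg
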