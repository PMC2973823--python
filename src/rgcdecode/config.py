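"""Run configuration: simulation + decoding parameters with field defaults.

Defaults follow the experimental protocol and decoder settings used
throughout the package: 66 ms flashes, 1.1–2.1 s inter-flash gaps,
0.07–0.7 µW/cm² intensities, 25 ms windows at 50% overlap, a 375 ms colour
filter, 250 ms (single-stage) / 125 ms (two-stage) onset filters, and the
±125 ms detection tolerance.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from rgcdecode.synthdata import DEFAULT_CLASS_FRACTIONS

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass
class RunConfig:
    # stimulus
    n_flashes: int = 500
    flash_duration: float = 66.0
    interflash_range: tuple[float, float] = (1100.0, 2100.0)
    intensity_range: tuple[float, float] = (0.07, 0.7)
    # population
    n_cells: int = 100
    class_fractions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_FRACTIONS)
    )
    # decoding grid
    window_length: float = 25.0
    overlap: float = 0.5
    # decoders
    colour_filter_length: float = 375.0
    onset_filter_length: float = 250.0
    two_stage_filter_length: float = 125.0
    detection_tolerance: float = 125.0
    naive_window: float = 250.0
    # sweep
    sweep_sizes: tuple[int, ...] = (1, 5, 10, 25, 50, 75, 100)
    n_subgroups: int = 50
    # reproducibility
    seed: int = 0


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    cfg = RunConfig()
    for k, v in data.items():
        if not hasattr(cfg, k):
            raise ValueError(f"unknown config key {k!r}")
        default = getattr(cfg, k)
        if isinstance(default, tuple):
            v = tuple(v)
        setattr(cfg, k, v)
    return cfg


def save_config(cfg: RunConfig, path: str | Path) -> None:
    data = asdict(cfg)
    for k, v in data.items():
        if isinstance(v, tuple):
            data[k] = list(v)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
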