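"""Run configuration: a flat, YAML-serialisable record of every knob.

The config is echoed into every output directory so a run can be
reproduced from its artifacts alone.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass
class RunConfig:
    # geometry
    crop_shape: tuple[int, int, int] | None = None  # derived from data when None
    keep_z: bool = False
    downsample: tuple[int, int, int] = (1, 4, 4)
    # networks
    base_filters_localizer: int = 8
    base_filters_segmenter: int = 8
    num_classes: int = 1
    # training
    learning_rate: float = 1e-4
    batch_size: int = 2
    max_epochs: int = 200
    patience: int = 10
    min_cases: int = 2
    seed: int = 0
    # behaviour switches
    loss_variant: str = "factor2"  # or "printed"
    hd_mode: str = "symmetric"  # or "directed"
    e2e_fusion: str = "multiply"  # or "concat"
    roi_source: str = "gcam"  # or "direct"
    roi_threshold_frac: float = 0.5
    # preprocessing
    use_clahe: bool = False
    clahe_clip_limit: float = 0.03
    clahe_tiles: tuple[int, int] = (8, 8)
    target_spacing: tuple[float, float, float] | None = None
    target_shape: tuple[int, int, int] | None = None

    def __post_init__(self):
        if self.crop_shape is not None:
            self.crop_shape = tuple(int(c) for c in self.crop_shape)
            div = self.pool_divisor()
            for c, d in zip(self.crop_shape, div):
                if c % 2 or c < 8 or c % d:
                    raise ValueError(
                        f"crop_shape {self.crop_shape} must be even, >= 8 and "
                        f"divisible by the pooling factor {div}"
                    )
        if self.loss_variant not in ("printed", "factor2"):
            raise ValueError(f"unknown loss_variant {self.loss_variant!r}")
        if self.hd_mode not in ("directed", "symmetric"):
            raise ValueError(f"unknown hd_mode {self.hd_mode!r}")
        if self.e2e_fusion not in ("multiply", "concat"):
            raise ValueError(f"unknown e2e_fusion {self.e2e_fusion!r}")
        if self.roi_source not in ("gcam", "direct"):
            raise ValueError(f"unknown roi_source {self.roi_source!r}")

    def pool_divisor(self) -> tuple[int, int, int]:
        """Cumulative pooling factor over the three encoder levels."""
        return (1 if self.keep_z else 8, 8, 8)

    def to_dict(self) -> dict:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d


_TUPLE_FIELDS = {
    "crop_shape",
    "downsample",
    "clahe_tiles",
    "target_spacing",
    "target_shape",
}


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for k in _TUPLE_FIELDS & set(raw):
        if raw[k] is not None:
            raw[k] = tuple(raw[k])
    return RunConfig(**raw)


def save_config(cfg: RunConfig, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
    return path
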