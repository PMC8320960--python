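"""Structured pipeline configuration with YAML round-trip.

Defaults reproduce the method's printed parameterisation: 30x30-px
background sub-regions, 5% percentile selections, a 10% low-contrast
fallback, the 9x9 centre-80 contrast-enhancement kernel, a 2x2 pre-clean
erosion, at least 3 MCs per 1 cm^2 block, enhancement weight 0.10 at 3
decomposition levels, and stratified 10-fold evaluation over seeds 1..10.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "load_config", "save_config"]


@dataclass
class PipelineConfig:
    # ROI cropping
    crop_margin_px: int = 20
    # enhancement
    enhance_weight: float = 0.10
    enhance_levels: int = 3
    wavelet: str = "db4"
    # probability image (A/B/C chain)
    subregion_px: int = 30
    top_fraction: float = 0.05
    fallback_fraction: float = 0.10
    smooth_step_px: int = 3
    # cluster rules
    min_per_block: int = 3
    block_side_px: int | None = None  # None -> derived from pixel spacing
    # feature selection
    stale_limit: int = 5
    # classification
    scheme: str = "10fold"
    n_folds: int = 10
    seeds: list[int] = field(default_factory=lambda: list(range(1, 11)))
    meta: str = "naive_bayes"

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def replace(self, **kw) -> "PipelineConfig":
        return replace(self, **kw)

    def hash(self) -> str:
        """Stable digest of the full configuration (for run manifests)."""
        canon = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        return PipelineConfig.from_dict(yaml.safe_load(fh) or {})


def save_config(config: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
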