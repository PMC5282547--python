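"""Run configuration: every tunable of the pipeline with validated defaults.

The configuration is deliberately flat so that a YAML file (or CLI flags)
can override any single knob, and so that the fully-resolved configuration
can be logged verbatim for provenance.  Unknown keys are rejected rather
than ignored.
"""
from __future__ import annotations

import dataclasses
import logging
import secrets
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Optional, Union

import yaml

logger = logging.getLogger("protflux")

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    # --- restricted permutation test ---
    permutation_iterations: int = 50_000  # iteration count of the flux null
    permutation_mode: str = "full_relabel"  # or "transposition"
    permutation_strict_ties: bool = False  # strict > instead of >= in the p-value
    permutation_plus_one: bool = False  # (b+1)/(B+1) correction

    # --- segmentation (green channel) ---
    min_area_px: int = 20
    max_area_px: int = 2000
    max_eccentricity: float = 0.95
    saturation_warn_fraction: float = 0.5

    # --- tracking ---
    max_disp_px: float = 15.0

    # --- per-cell decay fit QC ---
    min_timepoints: int = 5
    min_r2: float = 0.5
    subtract_background: bool = True  # fit on frame-median-subtracted traces

    # --- dose-response ---
    n_bootstrap: int = 300
    min_decline_fraction: float = 0.2  # required drop below top for identifiability

    # --- imaging defaults (configuration, not claims about the raw data) ---
    bit_depth: int = 16
    pixel_size_um: float = 0.65  # 20x objective

    # --- reproducibility ---
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.permutation_iterations < 1:
            raise ValueError("permutation_iterations must be >= 1")
        if self.permutation_mode not in ("full_relabel", "transposition"):
            raise ValueError(
                "permutation_mode must be 'full_relabel' or 'transposition'"
            )
        if self.min_area_px <= 0 or self.max_area_px < self.min_area_px:
            raise ValueError("need 0 < min_area_px <= max_area_px")
        if not 0 < self.max_eccentricity <= 1:
            raise ValueError("max_eccentricity must be in (0, 1]")
        if not 0 < self.saturation_warn_fraction <= 1:
            raise ValueError("saturation_warn_fraction must be in (0, 1]")
        if self.max_disp_px <= 0:
            raise ValueError("max_disp_px must be positive")
        if self.min_timepoints < 3:
            raise ValueError("min_timepoints must be >= 3 (2-parameter fit)")
        if not 0 <= self.min_r2 <= 1:
            raise ValueError("min_r2 must be in [0, 1]")
        if self.n_bootstrap < 1:
            raise ValueError("n_bootstrap must be >= 1")
        if not 0 <= self.min_decline_fraction < 1:
            raise ValueError("min_decline_fraction must be in [0, 1)")
        if self.bit_depth not in (8, 12, 16, 32):
            raise ValueError("bit_depth must be one of 8, 12, 16, 32")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.seed is not None and not 0 <= int(self.seed) < 2**32:
            raise ValueError("seed must be in [0, 2**32)")

    def resolve_seed(self) -> int:
        """Return the configured seed, drawing (and recording) one if absent."""
        if self.seed is None:
            self.seed = secrets.randbelow(2**31)
            logger.info("no seed configured; drew seed=%d", self.seed)
        return int(self.seed)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)

    def log_resolved(self) -> None:
        logger.info("resolved configuration: %s", self.as_dict())


def load_config(path: Union[str, Path, None] = None, **overrides) -> RunConfig:
    """Load a :class:`RunConfig` from a YAML file, applying defaults.

    Absent keys take their defaults; unknown keys raise ``ValueError``.  The
    fully-resolved configuration is echoed to the package logger so every
    run records its provenance.
    """
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError("configuration file must contain a mapping")
        data.update(loaded)
    data.update(overrides)

    known = {f.name for f in fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")

    cfg = RunConfig(**data)
    cfg.log_resolved()
    return cfg
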