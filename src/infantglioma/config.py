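"""Pipeline configuration.

Every calling threshold the pipeline applies lives here, with defaults set to
the published assay rules:

* hotspot positivity: MAF >= 1% in both duplicate runs, >= 50 fluorescent
  droplets per replicate;
* CDKN2A deletion: copy-number value strictly below 1.2;
* FGFR1 kinase-domain duplication: exon16/exon8 concentration ratio >= 1.125;
* fusion outliers: normalized count above Q3 + 3 x IQR of the batch.

Calling functions receive the relevant sub-config explicitly, so calls are
pure functions of (data, thresholds).
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import yaml


class ConfigurationError(ValueError):
    """Raised for invalid pipeline or simulation configuration."""


@dataclass
class DdpcrConfig:
    maf_threshold_pct: float = 1.0
    min_signal_droplets: int = 50
    cdkn2a_deleted_below: float = 1.2
    fgfr1_dup_ratio: float = 1.125
    droplet_volume_nl: float = 0.85  # vendor-standard droplet volume
    corrected_maf: bool = True  # MAF from Poisson-corrected lambdas, not raw fractions

    def validate(self) -> None:
        if self.maf_threshold_pct <= 0 or self.min_signal_droplets <= 0:
            raise ConfigurationError("hotspot thresholds must be positive")
        if self.cdkn2a_deleted_below <= 0 or self.fgfr1_dup_ratio <= 0:
            raise ConfigurationError("copy-number thresholds must be positive")
        if self.droplet_volume_nl <= 0:
            raise ConfigurationError("droplet volume must be positive")


@dataclass
class NanostringConfig:
    iqr_multiplier: float = 3.0
    min_batch_lanes: int = 8
    min_normalized_count: float = 50.0  # expression floor for an outlier call
    imbalance_z: float = 5.0
    imbalance_pseudocount: float = 1.0
    background_mode: str = "poisson"  # "poisson": mean + 2*sqrt(mean); "mean": mean only

    def validate(self) -> None:
        if self.iqr_multiplier <= 0 or self.min_batch_lanes <= 0:
            raise ConfigurationError("outlier parameters must be positive")
        if self.imbalance_z <= 0 or self.imbalance_pseudocount <= 0:
            raise ConfigurationError("imbalance parameters must be positive")
        if self.background_mode not in ("poisson", "mean"):
            raise ConfigurationError(f"unknown background_mode {self.background_mode!r}")


@dataclass
class IntegrationConfig:
    # precedence among simultaneously positive assays, most authoritative first
    tier1_precedence: tuple = ("snv_hotspot", "panel_fusion", "tag_imbalance", "fgfr1_tkd")
    tier2_precedence: tuple = ("targeted_rnaseq", "wts", "cnv")
    min_caller_support: int = 2
    breakpoint_tolerance_exons: int = 1

    def validate(self) -> None:
        if self.min_caller_support < 1:
            raise ConfigurationError("min_caller_support must be >= 1")
        if self.breakpoint_tolerance_exons < 0:
            raise ConfigurationError("breakpoint tolerance must be >= 0")


@dataclass
class SurvivalConfig:
    ci_transform: str = "log"  # "log" (R survival default) or "loglog"
    tie_handling: str = "efron"  # Efron is the only supported tie correction
    alpha: float = 0.05

    def validate(self) -> None:
        if self.ci_transform not in ("log", "loglog"):
            raise ConfigurationError(f"unknown ci_transform {self.ci_transform!r}")
        if self.tie_handling != "efron":
            raise ConfigurationError(f"unsupported tie_handling {self.tie_handling!r}")
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must lie in (0, 1)")


@dataclass
class PipelineConfig:
    ddpcr: DdpcrConfig = field(default_factory=DdpcrConfig)
    nanostring: NanostringConfig = field(default_factory=NanostringConfig)
    integration: IntegrationConfig = field(default_factory=IntegrationConfig)
    survival: SurvivalConfig = field(default_factory=SurvivalConfig)
    seed: int = 0

    def validate(self) -> "PipelineConfig":
        self.ddpcr.validate()
        self.nanostring.validate()
        self.integration.validate()
        self.survival.validate()
        return self

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, payload: dict) -> "PipelineConfig":
        cfg = cls()
        for section in ("ddpcr", "nanostring", "integration", "survival"):
            sub = payload.get(section, {})
            target = getattr(cfg, section)
            for key, value in sub.items():
                if not hasattr(target, key):
                    raise ConfigurationError(f"unknown key {section}.{key}")
                current = getattr(target, key)
                if isinstance(current, tuple):
                    value = tuple(value)
                setattr(target, key, value)
        cfg.seed = int(payload.get("seed", cfg.seed))
        return cfg.validate()


def load_config(path: Optional[str]) -> PipelineConfig:
    """Read a YAML pipeline configuration; ``None`` yields the defaults."""
    if path is None:
        return PipelineConfig().validate()
    with open(path) as handle:
        payload = yaml.safe_load(handle) or {}
    if not isinstance(payload, dict):
        raise ConfigurationError("configuration file must contain a mapping")
    return PipelineConfig.from_dict(payload)


def save_config(cfg: PipelineConfig, path: str) -> None:
    with open(path, "w") as handle:
        yaml.safe_dump(cfg.to_dict(), handle, sort_keys=False)
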