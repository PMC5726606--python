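"""Pipeline configuration: a strict, YAML-round-trippable parameter tree."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .tracking import TrackingParams


@dataclass(frozen=True)
class PhantomConfig:
    """Cohort generation settings (three-tract planted geometry)."""

    n_subjects: int = 12
    dispersion_deg: float = 10.0
    subject_jitter_mm: float = 1.0


@dataclass(frozen=True)
class StatsConfig:
    alpha: float = 0.05
    n_permutations_pairwise: int = 5000
    m_bonferroni: int | None = None      # default: T*(T-1) ordered pairs
    evidence_rule: str = "two_highest"
    n_permutations_overlap: int = 10_000
    m_overlap: int | None = None         # default: number of matrix cells
    fwhm_mm: float = 5.0


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a full phantom → overlap-matrix run needs.

    Serialises losslessly to/from YAML; unknown keys are rejected.
    """

    out_dir: str = "tractterm_out"
    rng_seed: int = 0
    hemisphere_split: bool = False
    write_global_profile: bool = True
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    tracking: TrackingParams = field(default_factory=lambda: TrackingParams(
        n_streamlines=1000))
    stats: StatsConfig = field(default_factory=StatsConfig)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        def build(klass, d, where):
            allowed = {f.name for f in fields(klass)}
            unknown = set(d) - allowed
            if unknown:
                raise ValueError(
                    f"unknown config keys in {where}: {sorted(unknown)}")
            return d

        data = dict(build(cls, data, "pipeline"))
        if "phantom" in data:
            data["phantom"] = PhantomConfig(
                **build(PhantomConfig, data["phantom"], "phantom"))
        if "tracking" in data:
            data["tracking"] = TrackingParams(
                **build(TrackingParams, data["tracking"], "tracking"))
        if "stats" in data:
            data["stats"] = StatsConfig(
                **build(StatsConfig, data["stats"], "stats"))
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)
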