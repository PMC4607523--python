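"""Pipeline configuration: every tunable constant in one validated object.

Defaults mirror the published scan parameters: 40 DIND flanking variants,
sentinel = dataset max + 20, 50 MAF classes, 100 DAF classes, 5 kb / 500 bp
DH windows, 25 kb gene flanks, 0.95 / 0.999 rank thresholds, 5th
percentile for gene-level and DH significance, 2,000 simulation iterations
on 20,000 bp regions, and 100 resamples of 8 genes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "load_config", "default_demography_dict"]


@dataclass
class PipelineConfig:
    populations: tuple[str, ...] = ("YRI", "CEU", "CHBJPT")

    # region definition
    flank_bp: int = 25_000  # per side; 50 kb combined

    # DH sliding windows
    dh_window: int = 5_000
    dh_step: int = 500
    dh_min_snps: int = 3
    dh_percentile: float = 5.0

    # empirical calibration
    maf_bins: int = 50
    daf_bins: int = 100
    min_bin_count: int = 1

    # DIND
    dind_flank_total: int = 40
    dind_sentinel_offset: float = 20.0
    dind_max_missing: float = 0.1

    # classification thresholds
    rank_outlier: float = 0.95
    rank_extreme: float = 0.999
    gene_level_percentile: float = 5.0

    # coalescent significance simulations
    sim_region_length: int = 20_000
    sim_iterations: int = 2_000
    mutation_rate: float = 1.2e-8
    recombination_rate: float = 1.0e-8

    # gene-set resampling
    resample_n: int = 100
    resample_set_size: int = 8

    seed: int | None = None

    def __post_init__(self) -> None:
        self.populations = tuple(self.populations)
        self.validate()

    def validate(self) -> None:
        if len(self.populations) < 1:
            raise ValueError("at least one population label required")
        positive = [
            "flank_bp", "dh_window", "dh_step", "maf_bins", "daf_bins",
            "dind_flank_total", "sim_region_length", "sim_iterations",
            "resample_n", "resample_set_size",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.dh_window < self.dh_step:
            raise ValueError("dh_window must be >= dh_step")
        if not (0.0 < self.rank_outlier < 1.0):
            raise ValueError("rank_outlier must be in (0, 1)")
        if not (self.rank_outlier <= self.rank_extreme < 1.0):
            raise ValueError("rank_extreme must be in [rank_outlier, 1)")
        if not (0.0 < self.gene_level_percentile < 50.0):
            raise ValueError("gene_level_percentile must be in (0, 50)")
        if not (0.0 < self.dh_percentile < 50.0):
            raise ValueError("dh_percentile must be in (0, 50)")
        if self.mutation_rate < 0 or self.recombination_rate < 0:
            raise ValueError("rates must be >= 0")
        if not (0.0 <= self.dind_max_missing <= 1.0):
            raise ValueError("dind_max_missing must be in [0, 1]")

    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["populations"] = list(self.populations)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=True)
        )


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load a flat YAML key-value config; defaults when path is None."""
    if path is None:
        return PipelineConfig()
    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise ValueError("config file must be a flat key-value mapping")
    return PipelineConfig.from_dict(data)


def default_demography_dict() -> dict:
    """The shipped three-population demography (editable YAML)."""
    path = Path(__file__).parent / "defaults" / "demography.yaml"
    return yaml.safe_load(path.read_text())
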