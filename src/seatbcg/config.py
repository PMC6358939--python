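"""Pipeline configuration: one flat key-value file drives every stage."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields

import yaml

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class PipelineConfig:
    """Resolved parameters for simulation, band, classifier and selection."""

    # simulation
    posture_id: int = 1
    duration: float = 60.0
    sample_rate: float = 30.0
    heart_rate: float = 77.0
    coupling_scale: float = 1.0
    noise_sd: float = 0.005
    subject_scale: float = 1.0
    waveform: str = "sine"
    seed: int = 0
    # filter band
    band_lo_bpm: float = 30.0
    band_hi_bpm: float = 120.0
    band_mode: str = "physical"
    band_margin_hz: float = 0.05
    # classifier
    n_hidden: int = 70
    train_size: int = 600
    n_subjects: int = 10
    n_groups: int = 20
    upsample: int = 16
    # selection
    threshold: float = 0.6
    lag_window_s: float = 0.8

    def __post_init__(self) -> None:
        if self.train_size < 1 or self.n_hidden < 1:
            raise ValueError("train_size and n_hidden must be >= 1")
        if self.n_subjects < 1 or self.n_groups < 1:
            raise ValueError("n_subjects and n_groups must be >= 1")
        if not 0 <= self.threshold <= 1:
            raise ValueError("threshold must lie in [0, 1]")
        if self.lag_window_s < 0:
            raise ValueError("lag_window_s must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def simulation_config(self, posture_id: int | None = None, seed: int | None = None):
        from .synthetic import SimulationConfig

        return SimulationConfig(
            posture_id=self.posture_id if posture_id is None else posture_id,
            duration=self.duration,
            sample_rate=self.sample_rate,
            heart_rate=self.heart_rate,
            coupling_scale=self.coupling_scale,
            noise_sd=self.noise_sd,
            subject_scale=self.subject_scale,
            waveform=self.waveform,
            seed=self.seed if seed is None else seed,
        )

    def band(self):
        from .extraction import bpm_to_band

        return bpm_to_band(
            self.band_lo_bpm, self.band_hi_bpm, mode=self.band_mode, margin=self.band_margin_hz
        )


def load_config(path: str | None) -> PipelineConfig:
    """Load a flat YAML/key-value config file; ``None`` gives the defaults."""
    if path is None:
        return PipelineConfig()
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a flat key-value mapping")
    return PipelineConfig.from_dict(data)
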