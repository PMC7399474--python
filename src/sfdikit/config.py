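"""Strict pipeline configuration (YAML).

Fail-fast validation: unknown keys are rejected and every module-level
invariant is checked at load time, because silent unit mistakes (mm vs cm)
are the dominant failure mode in this domain.  Units everywhere: spatial
frequencies in 1/mm at the sample plane, lengths in mm, wavelengths in nm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import yaml

__all__ = ["ConfigError", "PipelineConfig", "load_config"]


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    fx_list: list = field(default_factory=lambda: [0.0, 0.0333, 0.05, 0.1])
    phases_deg: list = field(default_factory=lambda: [0.0, 120.0, 240.0])
    bands: list = field(default_factory=lambda: ["BB", "GB", "GG", "GR", "RR"])
    pixel_pitch: float = 0.5  # mm per projected pixel
    seed: int = 0
    # reference phantom anchor properties at 625 nm, 1/mm
    reference_mus_prime: float = 1.0
    reference_mua: float = 0.05
    reference_scatter_exponent: float = 1.2
    # Monte Carlo table settings
    mc_photons: int = 1_000_000
    mc_g: float = 0.0
    mc_n: float = 1.4
    mc_max_path: float = 4000.0
    # inversion settings
    initial_mua: float = 0.1
    initial_mus_prime: float = 1.5
    bounds_mua: list = field(default_factory=lambda: [0.005, 0.5])
    bounds_mus_prime: list = field(default_factory=lambda: [0.3, 5.0])
    max_iter: int = 500
    # paths
    table_path: str = ""
    output_dir: str = "."

    def validate(self) -> None:
        if len(self.fx_list) < 2:
            raise ConfigError(
                "fx_list must contain at least two spatial frequencies "
                "(the inversion requires >= 2 fx)"
            )
        if any(f < 0 for f in self.fx_list):
            raise ConfigError("spatial frequencies must be >= 0 (units: 1/mm)")
        if sorted(self.fx_list) != list(self.fx_list):
            raise ConfigError("fx_list must be ascending")
        if list(self.phases_deg) != [0.0, 120.0, 240.0]:
            raise ConfigError("phases_deg must be [0, 120, 240]")
        if self.pixel_pitch <= 0:
            raise ConfigError("pixel_pitch must be > 0 (mm per pixel)")
        if max(self.fx_list) * self.pixel_pitch >= 0.5:
            raise ConfigError("fx_list violates the Nyquist limit for pixel_pitch")
        if not self.bands:
            raise ConfigError("at least one band is required")
        if self.reference_mus_prime <= 0 or self.reference_mua < 0:
            raise ConfigError("reference phantom properties out of range")
        if self.mc_photons < 1:
            raise ConfigError("mc_photons must be >= 1")
        if not (self.bounds_mua[0] <= self.initial_mua <= self.bounds_mua[1]):
            raise ConfigError("initial_mua outside bounds_mua")
        if not (
            self.bounds_mus_prime[0]
            <= self.initial_mus_prime
            <= self.bounds_mus_prime[1]
        ):
            raise ConfigError("initial_mus_prime outside bounds_mus_prime")


def load_config(path) -> PipelineConfig:
    """Load and validate a YAML config; unknown keys are an error.

    The config snapshot and its hash are logged so any run can be
    reproduced from the log alone.
    """
    import hashlib
    import logging

    with open(path, "rb") as fh:
        blob = fh.read()
    logging.getLogger(__name__).info(
        "config %s sha256=%s", path, hashlib.sha256(blob).hexdigest()
    )
    raw = yaml.safe_load(blob.decode()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    known = {f.name for f in fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(
            f"{path}: unknown config keys: {sorted(unknown)} "
            f"(known: {sorted(known)})"
        )
    cfg = PipelineConfig(**raw)
    cfg.validate()
    return cfg
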