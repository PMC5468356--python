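"""Run configuration: YAML loading, validation, defaults.

A run config has nested sections — scene, detector, split, network,
training — plus a global ``rng_seed``, ``output_dir`` and ``log_level``.
Defaults embed the published operating point (learning rate 0.01,
momentum 0.85, weight decay 0.005, batch 128, dropout 0.5, test interval
5000); an empty config therefore resolves to those values. Unknown keys
are rejected, and every offending key is reported at once.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .ndf.network import NetworkConfig
from .ndf.train import TrainConfig
from .patching import SplitPlan
from .seeds import SeedDetectionConfig
from .synthetic import SceneSpec

log = logging.getLogger(__name__)


@dataclass
class NetworkProfile:
    """YAML-facing network settings: a named architecture profile plus
    the knobs that do not change the layer topology."""

    profile: str = "full"  # full | small
    dropout_ratio: float = 0.5
    n_classes: int = 2

    def build(self) -> NetworkConfig:
        if self.profile == "full":
            cfg = NetworkConfig.full()
        elif self.profile == "small":
            cfg = NetworkConfig.small(dropout=self.dropout_ratio)
        else:
            raise ValueError(f"unknown network profile {self.profile!r}")
        cfg.dropout_ratio = self.dropout_ratio
        cfg.n_classes = self.n_classes
        return cfg


_SECTIONS = {
    "scene": SceneSpec,
    "detector": SeedDetectionConfig,
    "split": SplitPlan,
    "network": NetworkProfile,
    "training": TrainConfig,
}


@dataclass
class RunConfig:
    scene: SceneSpec = field(default_factory=SceneSpec)
    detector: SeedDetectionConfig = field(default_factory=SeedDetectionConfig)
    split: SplitPlan = field(default_factory=SplitPlan)
    network: NetworkProfile = field(default_factory=NetworkProfile)
    training: TrainConfig = field(default_factory=TrainConfig)
    rng_seed: int = 0
    output_dir: str = "out"
    log_level: str = "INFO"

    def resolved(self) -> dict:
        """Plain-dict echo of the fully resolved configuration."""
        return dataclasses.asdict(self)


def _build_section(cls, overrides: dict, errors: list, prefix: str):
    known = {f.name for f in dataclasses.fields(cls)}
    # YAML configs may say "rng_seed" for any section; map to the field.
    unknown = [k for k in overrides if k not in known]
    for k in unknown:
        errors.append(f"{prefix}.{k}")
    kwargs = {k: v for k, v in overrides.items() if k in known}
    if "nucleus_radius_range" in kwargs and kwargs["nucleus_radius_range"] is not None:
        kwargs["nucleus_radius_range"] = tuple(kwargs["nucleus_radius_range"])
    try:
        return cls(**kwargs)
    except (ValueError, TypeError) as exc:
        errors.append(f"{prefix}: {exc}")
        return cls()


def config_from_dict(data: dict | None) -> RunConfig:
    """Build a validated RunConfig from a nested dict, applying defaults
    and rejecting unknown keys (all offenders listed in one error)."""
    data = dict(data or {})
    errors: list[str] = []
    kwargs = {}
    top_known = {f.name for f in dataclasses.fields(RunConfig)}
    for key in list(data):
        if key not in top_known:
            errors.append(key)
    for name, cls in _SECTIONS.items():
        section = data.get(name) or {}
        if not isinstance(section, dict):
            errors.append(f"{name}: expected a mapping")
            section = {}
        kwargs[name] = _build_section(cls, section, errors, name)
    for scalar in ("rng_seed", "output_dir", "log_level"):
        if scalar in data:
            kwargs[scalar] = data[scalar]
    if errors:
        raise ValueError(
            "invalid configuration keys/values: " + "; ".join(sorted(errors))
        )
    cfg = RunConfig(**kwargs)
    log.info("resolved configuration: %s", cfg.resolved())
    return cfg


def load_config(path) -> RunConfig:
    """Load a YAML run configuration; an empty file gives all defaults."""
    with open(Path(path)) as fh:
        data = yaml.safe_load(fh)
    if data is not None and not isinstance(data, dict):
        raise ValueError(f"{path}: top level of a run config must be a mapping")
    return config_from_dict(data)
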