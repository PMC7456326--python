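"""Run configuration: defaults, YAML round trip, strict validation.

All defaults reproduce the modelled study conditions: the published kinetic
parameter table, pulling speeds {100, 400, 1600, 6400} nm/s, a 0.1 N/m
cantilever, 40 pN force-histogram bins and the documented analysis
thresholds. Every pipeline run writes a frozen copy of its effective
configuration next to its outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, fields, is_dataclass
from pathlib import Path

import yaml

from .elasticity import BellEvansParams, Environment, FRCParams
from .simulate import NetworkSpec, PullingProtocol, TransitionSpec

__all__ = [
    "TransitionConfig",
    "NetworkConfig",
    "ProtocolConfig",
    "AnalysisConfig",
    "FretConfig",
    "RunConfig",
    "ConfigError",
]


class ConfigError(ValueError):
    """Invalid configuration; the message names the offending key path."""


@dataclass
class TransitionConfig:
    k0: float
    dx: float
    delta_Lc: float = 0.0


@dataclass
class NetworkConfig:
    p_mode_a: float = 0.8
    base_Lc: float = 180.0
    persistence: float = 0.4
    rupture_p1: TransitionConfig = field(
        default_factory=lambda: TransitionConfig(4.70e-8, 0.178))
    xmod_unfold: TransitionConfig = field(
        default_factory=lambda: TransitionConfig(4.53e-5, 0.116, 37.0))
    rupture_p2: TransitionConfig = field(
        default_factory=lambda: TransitionConfig(7.43e-4, 0.277))
    rupture_p3: TransitionConfig = field(
        default_factory=lambda: TransitionConfig(2.79e-5, 0.366))
    fingerprint_step1: TransitionConfig = field(
        default_factory=lambda: TransitionConfig(3.0e-3, 0.45, 15.0))
    fingerprint_step2: TransitionConfig = field(
        default_factory=lambda: TransitionConfig(1.0e-3, 0.50, 17.0))
    n_fingerprints: int = 2

    def to_network(self) -> NetworkSpec:
        def tr(name: str, cfg: TransitionConfig, kind: str) -> TransitionSpec:
            return TransitionSpec(name, BellEvansParams(k0=cfg.k0, dx=cfg.dx),
                                  delta_Lc=cfg.delta_Lc, kind=kind)

        fingerprints = tuple(
            (
                tr(f"ddfln4_{i}_step1", self.fingerprint_step1, "unfolding"),
                tr(f"ddfln4_{i}_step2", self.fingerprint_step2, "unfolding"),
            )
            for i in range(self.n_fingerprints)
        )
        return NetworkSpec(
            rupture_p1=tr("rupture_P1", self.rupture_p1, "rupture"),
            xmod_unfold=tr("xmod_unfold", self.xmod_unfold, "unfolding"),
            rupture_p2=tr("rupture_P2", self.rupture_p2, "rupture"),
            rupture_p3=tr("rupture_P3", self.rupture_p3, "rupture"),
            fingerprints=fingerprints,
            p_mode_a=self.p_mode_a,
            base_Lc=self.base_Lc,
            persistence=self.persistence,
        )


@dataclass
class ProtocolConfig:
    speeds: tuple[float, ...] = (100.0, 400.0, 1600.0, 6400.0)
    n_curves: int = 1000
    spring_constant: float = 100.0
    extension_grid_step: float = 0.05
    max_head_height: float = 400.0

    def to_protocol(self, speed: float) -> PullingProtocol:
        return PullingProtocol(
            speed=speed,
            spring_constant=self.spring_constant,
            extension_grid_step=self.extension_grid_step,
            max_head_height=self.max_head_height,
        )


@dataclass
class AnalysisConfig:
    force_floor: float = 10.0
    frc_bond_length: float = 0.11
    frc_bond_angle: float = 41.0
    contour_bin_width: float = 1.0
    smooth_sigma_nm: float = 1.0
    min_separation_nm: float = 10.0
    fingerprint_total: float = 64.0
    fingerprint_tol: float = 6.0
    substep_window: tuple[float, float] = (11.0, 21.0)
    xmod_window: tuple[float, float] = (34.0, 42.0)
    p1_threshold: float = 350.0
    force_bin_width: float = 40.0
    min_events_per_speed: int = 20
    correct_xmod: bool = True

    def frc_params(self) -> FRCParams:
        return FRCParams(b=self.frc_bond_length, gamma=self.frc_bond_angle)


@dataclass
class FretConfig:
    alpha: float = 0.05
    delta: float = 0.10
    gamma_f: float = 1.0
    window_s: float = 500e-6
    min_photons_per_window: int = 4
    burst_threshold: int = 40
    stoichiometry_bounds: tuple[float, float] = (0.2, 0.8)
    efficiency_bin_width: float = 0.025
    background_rates: tuple[float, float, float] = (0.0, 0.0, 0.0)


@dataclass
class RunConfig:
    environment_kBT: float = 4.114
    temperature_K: float = 298.0
    network: NetworkConfig = field(default_factory=NetworkConfig)
    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    fret: FretConfig = field(default_factory=FretConfig)
    seed: int = 0
    save_curves: bool = True

    def environment(self) -> Environment:
        return Environment(kBT=self.environment_kBT,
                           temperature=self.temperature_K)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return _asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        return _from_dict(cls, data, path="")

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(data or {})

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _asdict(obj):
    if is_dataclass(obj):
        return {f.name: _asdict(getattr(obj, f.name)) for f in fields(obj)}
    if isinstance(obj, tuple):
        return [_asdict(v) for v in obj]
    return obj


def _from_dict(cls, data: dict, path: str):
    if not isinstance(data, dict):
        raise ConfigError(f"expected a mapping at {path or '<root>'}")
    valid = {f.name: f for f in fields(cls)}
    for key in data:
        if key not in valid:
            where = f"{path}.{key}" if path else key
            raise ConfigError(f"unknown configuration key: {where}")
    kwargs = {}
    for name, f in valid.items():
        if name not in data:
            continue
        value = data[name]
        sub = f"{path}.{name}" if path else name
        ftype = f.type if not isinstance(f.type, str) else None
        target = _dataclass_target(cls, name)
        if target is not None:
            kwargs[name] = _from_dict(target, value, sub)
        elif isinstance(value, list):
            kwargs[name] = tuple(value)
        else:
            kwargs[name] = value
    return cls(**kwargs)


def _dataclass_target(cls, name):
    default = cls().__getattribute__(name) if _constructible(cls) else None
    if is_dataclass(default):
        return type(default)
    return None


def _constructible(cls) -> bool:
    try:
        cls()
        return True
    except TypeError:
        return False
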