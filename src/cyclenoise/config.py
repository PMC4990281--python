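"""Run configuration: schema, YAML/JSON loading, and run manifests."""

from __future__ import annotations

import json
import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .models import BurstModel, DuplicationSchedule, PartitionModel
from .moments import ModelFlags
from .timing import ErlangMixture, erlang_mixture_from_target

__all__ = ["ConfigError", "RunConfig", "clock_from_spec", "load_config", "write_manifest"]


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


def clock_from_spec(spec: dict[str, Any]) -> ErlangMixture:
    """Build a phase-type clock from either explicit or target form.

    Explicit: ``{"orders": [...], "probs": [...], "rate_scale": k}``.
    Target:   ``{"mean": <T>, "cv2": CV_T^2}`` (minimal adjacent-order mixture).
    """
    if "orders" in spec:
        try:
            return ErlangMixture.from_dict(spec)
        except (KeyError, ValueError) as exc:
            raise ConfigError(f"bad explicit clock spec: {exc}") from exc
    if "mean" in spec and "cv2" in spec:
        try:
            return erlang_mixture_from_target(float(spec["mean"]), float(spec["cv2"]))
        except ValueError as exc:
            raise ConfigError(f"bad clock target spec: {exc}") from exc
    raise ConfigError(
        "clock spec needs either orders/probs/rate_scale or mean/cv2, "
        f"got keys {sorted(spec)}"
    )


@dataclass
class RunConfig:
    """Fully resolved run configuration with explicit defaults."""

    burst: BurstModel
    partition: PartitionModel
    clock: ErlangMixture | None = None
    duplication: DuplicationSchedule | None = None
    degradation: float | None = None
    burst_noise: bool = True
    partition_noise: bool = True
    cycles: int = 20_000
    burn_in: int = 50
    seed: int = 1
    raw: dict = field(default_factory=dict)

    @property
    def flags(self) -> ModelFlags:
        return ModelFlags(
            include_burst_noise=self.burst_noise,
            include_partition_noise=self.partition_noise,
            duplication=self.duplication,
            degradation=self.degradation,
        )

    def manifest_dict(self) -> dict:
        d: dict[str, Any] = {
            "burst": {
                "kx": self.burst.kx,
                "burst_mean": self.burst.burst_mean,
                "burst_second_moment": self.burst.burst_second_moment,
                "family": self.burst.burst_family,
            },
            "partition": {
                "alpha": self.partition.alpha,
                "variance_law": self.partition.variance_law,
            },
            "clock": self.clock.to_dict() if self.clock else None,
            "duplication": None,
            "degradation": self.degradation,
            "burst_noise": self.burst_noise,
            "partition_noise": self.partition_noise,
            "cycles": self.cycles,
            "burn_in": self.burn_in,
            "seed": self.seed,
        }
        if self.duplication is not None:
            d["duplication"] = {
                "f": self.duplication.f,
                "t1": self.duplication.t1_clock.to_dict(),
                "t2": self.duplication.t2_clock.to_dict(),
            }
        return d


_KNOWN_KEYS = {
    "burst",
    "partition",
    "clock",
    "duplication",
    "degradation",
    "model",
    "sim",
}


def _build_burst(spec: dict[str, Any]) -> BurstModel:
    family = spec.get("family", "geometric0")
    kx = float(spec.get("kx", 1.0))
    mean = float(spec.get("burst_mean", 1.0))
    if family == "geometric0":
        return BurstModel.geometric(kx, mean)
    if family == "geometric1":
        return BurstModel.geometric(kx, mean, shifted=True)
    if family == "point_mass":
        return BurstModel.point_mass(kx, mean)
    if family == "custom":
        if "burst_second_moment" not in spec:
            raise ConfigError("custom burst family requires burst_second_moment")
        return BurstModel(kx, mean, float(spec["burst_second_moment"]), "custom")
    raise ConfigError(f"unknown burst family {family!r}")


def parse_config(data: dict[str, Any]) -> RunConfig:
    unknown = set(data) - _KNOWN_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    try:
        burst = _build_burst(data.get("burst", {}))
        part_spec = data.get("partition", {})
        partition = PartitionModel(
            alpha=float(part_spec.get("alpha", 1.0)),
            variance_law=part_spec.get("variance_law", "proportional"),
        )
        clock = clock_from_spec(data["clock"]) if "clock" in data else None
        duplication = None
        if "duplication" in data and data["duplication"] is not None:
            dspec = data["duplication"]
            duplication = DuplicationSchedule(
                f=float(dspec.get("f", 2.0)),
                t1_clock=clock_from_spec(dspec["t1"]),
                t2_clock=clock_from_spec(dspec["t2"]),
            )
        model = data.get("model", {})
        sim = data.get("sim", {})
        return RunConfig(
            burst=burst,
            partition=partition,
            clock=clock,
            duplication=duplication,
            degradation=data.get("degradation"),
            burst_noise=bool(model.get("burst_noise", True)),
            partition_noise=bool(model.get("partition_noise", True)),
            cycles=int(sim.get("cycles", 20_000)),
            burn_in=int(sim.get("burn_in", 50)),
            seed=int(sim.get("seed", 1)),
            raw=data,
        )
    except (KeyError, TypeError, ValueError) as exc:
        if isinstance(exc, ConfigError):
            raise
        raise ConfigError(str(exc)) from exc


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML or JSON run configuration."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigError(f"config root must be a mapping, got {type(data).__name__}")
    return parse_config(data)


def write_manifest(path: str | Path, config: RunConfig, extra: dict | None = None) -> dict:
    """Write a JSON run manifest (config, seed, version, config hash)."""
    from . import __version__

    payload = config.manifest_dict()
    digest = hashlib.sha256(
        json.dumps(payload, sort_keys=True).encode()
    ).hexdigest()[:16]
    manifest = {
        "config": payload,
        "config_hash": digest,
        "seed": config.seed,
        "package_version": __version__,
    }
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
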