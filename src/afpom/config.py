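"""Run configuration: one schema-validated object ties all stages together.

Two shipped presets:

* ``paper_config()`` — full-scale study conditions: 500 LHS candidates, the
  8x256 calibration strip at the reference 0.01 cm spacing, 400x400 / 450x450
  planes, 1 us membrane step.  This preset needs substantial compute.
* ``desk_config()`` — the surrogate membrane model on reduced 100x100 planes
  (same physical areas) with a coarser grid spacing and a 0.1 ms step; runs a
  complete pipeline on one CPU in minutes and is the default for tests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .errors import ConfigurationError


@dataclass
class ProtocolConfig:
    n_s1: int = 3
    cl: float = 1000.0            # ms (1 Hz pacing)
    s2_coupling: float | None = None  # None -> adaptive APD90 + 10 ms
    amplitude: float = 2.0        # multiples of diastolic threshold
    duration: float = 3.0         # ms
    observation: float = 2000.0   # ms after S2


@dataclass
class StripConfig:
    n_beats: int = 15
    cl: float = 1000.0
    n_last: int = 5
    dx: float = 0.01              # cm


@dataclass
class MLConfig:
    train_frac: float = 0.8
    k: int = 5
    seed: int = 0
    n_estimators: int = 500
    max_depth: int = 7


@dataclass
class RunConfig:
    model: str = "ionic"                   # 'ionic' | 'surrogate'
    lhs_n: int = 500
    population_target: int | None = None   # keep drawing LHS batches until
                                           # this many profiles are accepted
    seed: int = 1234
    constraint_source: str = "synthetic"   # 'synthetic', 'synthetic-surrogate'
                                           # or a CSV path
    sizes: tuple[str, ...] = ("normal", "dilated")
    conditions: tuple[str, ...] = ("basal", "flecainide", "verapamil", "isoproterenol")
    plane_nodes: int | None = None         # None -> full 400/450 grids
    dt: float = 0.001                      # ms membrane/tissue step (1 us)
    dt_out: float = 1.0                    # ms storage step (1 kHz)
    D_baseline: float = 0.0055             # cm^2/ms, CV-calibrated
    agonist_law: str = "saturating"
    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    strip: StripConfig = field(default_factory=StripConfig)
    ml: MLConfig = field(default_factory=MLConfig)

    def __post_init__(self) -> None:
        if self.model not in ("ionic", "surrogate"):
            raise ConfigurationError(f"unknown model {self.model!r}")
        if self.lhs_n < 1:
            raise ConfigurationError("lhs_n must be >= 1")
        for s in self.sizes:
            if s not in ("normal", "dilated"):
                raise ConfigurationError(f"unknown size {s!r}")
        for c in self.conditions:
            if c not in ("basal", "flecainide", "verapamil", "isoproterenol"):
                raise ConfigurationError(f"unknown condition {c!r}")
        if not self.dt > 0 or not self.dt_out > 0:
            raise ConfigurationError("dt and dt_out must be > 0")

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key, sub in (("protocol", ProtocolConfig), ("strip", StripConfig),
                         ("ml", MLConfig)):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if "sizes" in d:
            d["sizes"] = tuple(d["sizes"])
        if "conditions" in d:
            d["conditions"] = tuple(d["conditions"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def paper_config() -> RunConfig:
    """Full-scale configuration (ionic model, full grids, 1 us step)."""
    return RunConfig()


def desk_config(n_profiles: int = 20, seed: int = 1234) -> RunConfig:
    """Reduced, surrogate-model configuration that runs on one CPU."""
    return RunConfig(
        model="surrogate",
        lhs_n=2 * n_profiles,
        population_target=n_profiles,
        seed=seed,
        constraint_source="synthetic-surrogate",
        plane_nodes=100,
        dt=0.1,
        protocol=ProtocolConfig(observation=800.0),
        strip=StripConfig(dx=0.04),
    )
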