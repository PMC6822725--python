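"""Run configuration: plain-text (YAML) key-value files for swimmers and runs.

A config has three blocks, all optional (missing keys take the documented
defaults):

``constants``
    the physical/physiological constants (see :class:`undulate.constants.Constants`);
``swimmer``
    the body mass plus the nine shape/motion parameters
    (DL, BL, c_d1, c_d2, c_b1, omega, e0, e1, e2);
``run``
    numerical settings: grid size, cycle-quadrature resolution, seed and
    the evolutionary budget (population size, generations).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .constants import Constants

__all__ = ["SwimmerSpec", "RunSettings", "RunConfig", "load_config", "save_config"]

PARAM_NAMES = ("DL", "BL", "c_d1", "c_d2", "c_b1", "omega", "e0", "e1", "e2")


@dataclass(frozen=True)
class SwimmerSpec:
    """Body mass and the nine shape/motion parameters of one swimmer."""

    mass: float = 1.0
    DL: float = 0.20
    BL: float = 0.15
    c_d1: float = 0.05
    c_d2: float = 0.02
    c_b1: float = 1.2
    omega: float = 8.0
    e0: float = 0.03
    e1: float = 0.03
    e2: float = 0.012

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError("swimmer mass must be positive")
        if self.omega <= 0:
            raise ValueError("omega must be positive")

    @property
    def params(self) -> tuple[float, ...]:
        """The 9-vector in canonical order (5 shape + 4 motion)."""
        return tuple(getattr(self, k) for k in PARAM_NAMES)


@dataclass(frozen=True)
class RunSettings:
    """Numerical resolution and optimization budget."""

    grid_n: int = 256
    n_quad: int = 1024
    seed: int = 0
    pop_size: int = 40
    generations: int = 60

    def __post_init__(self) -> None:
        if self.grid_n < 32:
            raise ValueError("grid_n must be at least 32")
        if self.n_quad < 64:
            raise ValueError("n_quad must be at least 64")
        if self.pop_size < 4:
            raise ValueError("pop_size must be at least 4")


@dataclass(frozen=True)
class RunConfig:
    constants: Constants = field(default_factory=Constants)
    swimmer: SwimmerSpec = field(default_factory=SwimmerSpec)
    run: RunSettings = field(default_factory=RunSettings)


def _build(cls, block: dict, name: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(block) - known
    if unknown:
        raise ValueError(f"unknown key(s) in {name!r} block: {sorted(unknown)}")
    return cls(**block)


def load_config(path: str | Path) -> RunConfig:
    """Read a YAML config; an empty file yields the full defaults.

    Unknown blocks or keys are rejected with a descriptive error, and the
    dataclass validators enforce positivity/size constraints.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    unknown = set(raw) - {"constants", "swimmer", "run"}
    if unknown:
        raise ValueError(f"unknown config block(s): {sorted(unknown)}")
    return RunConfig(
        constants=_build(Constants, raw.get("constants") or {}, "constants"),
        swimmer=_build(SwimmerSpec, raw.get("swimmer") or {}, "swimmer"),
        run=_build(RunSettings, raw.get("run") or {}, "run"),
    )


def save_config(cfg: RunConfig, path: str | Path) -> None:
    """Write a config as YAML; ``load_config`` round-trips it losslessly."""
    Path(path).write_text(
        yaml.safe_dump(
            {
                "constants": dataclasses.asdict(cfg.constants),
                "swimmer": dataclasses.asdict(cfg.swimmer),
                "run": dataclasses.asdict(cfg.run),
            },
            sort_keys=False,
        )
    )
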