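"""Run configuration: defaults, regime switches and YAML round-trip.

Printed model constants (cell counts, time constants, kernel widths,
adaptation range, conjunctive offset) are taken at face value; the
remaining strengths (recurrent, inhibition, input, theta scaling,
adaptation defaults, theta frequency) are calibrated defaults of this
implementation — see the methods note for how they were set.  All are
overridable from a config file or keyword arguments.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from .hd_network import HDParams
from .grid_network import GridParams

__all__ = [
    "RunConfig",
    "default_hd_params",
    "default_grid_params",
    "default_grid_modules",
]

#: Geometric series of grid spacings (m), dorsal to ventral, paired
#: with linearly increasing adaptation strength (0.7 dorsal rising
#: toward the ventral end of the printed 0.7-1.8 range).
MODULE_SPACINGS = (0.40, 0.56, 0.78, 1.10)
MODULE_ADAPTATION = (0.7, 0.9, 1.1, 1.3)


def default_hd_params(**overrides) -> HDParams:
    """Calibrated defaults of the HD ring attractor."""
    return HDParams(**overrides)


def default_grid_params(module: int = 0, **overrides) -> GridParams:
    """Calibrated defaults of grid module ``module`` (0 = most dorsal)."""
    base = dict(lambda_=MODULE_SPACINGS[module],
                m=MODULE_ADAPTATION[module])
    base.update(overrides)
    return GridParams(**base)


def default_grid_modules(n_modules: int = 4, **overrides):
    return [default_grid_params(i, **overrides) for i in range(n_modules)]


@dataclass
class RunConfig:
    """Complete, serializable description of one simulation run.

    ``trajectory`` is a mapping with a ``kind`` key (``straight_run``,
    ``rotation``, ``segments``, ``random_walk``) plus that generator's
    keyword arguments.  Regime switches: ``theta_hd`` / ``theta_grid``
    disable septal theta modulation per network (the Fig.-style septal
    inactivation regimes) without touching the stored parameter sets.
    """

    trajectory: dict = field(default_factory=lambda: {
        "kind": "straight_run", "speed": 0.5,
        "heading": float(np.deg2rad(45.0)), "duration": 10.0})
    hd: HDParams = field(default_factory=default_hd_params)
    grid_modules: list = field(default_factory=lambda:
                               [default_grid_params(0)])
    warmup: float = 0.5
    dt: float = 1e-3
    seed: int = 0
    theta_hd: bool = True
    theta_grid: bool = True

    def effective_hd(self) -> HDParams:
        return self.hd if self.theta_hd else self.hd.with_(abar=0.0)

    def effective_grids(self):
        if self.theta_grid:
            return list(self.grid_modules)
        return [g.with_(abar=0.0) for g in self.grid_modules]

    def build_trajectory(self):
        from . import trajectory as trj

        spec = dict(self.trajectory)
        kind = spec.pop("kind")
        spec.setdefault("dt", self.dt)
        makers = {
            "straight_run": trj.make_straight_run,
            "rotation": trj.make_rotation,
            "segments": trj.make_segments,
            "random_walk": trj.make_random_walk,
        }
        if kind not in makers:
            raise ValueError(f"unknown trajectory kind {kind!r}")
        if kind == "random_walk":
            spec.setdefault("seed", self.seed)
        return makers[kind](**spec)

    def to_dict(self) -> dict:
        return {
            "trajectory": dict(self.trajectory),
            "hd": asdict(self.hd),
            "grid_modules": [asdict(g) for g in self.grid_modules],
            "warmup": self.warmup,
            "dt": self.dt,
            "seed": self.seed,
            "theta_hd": self.theta_hd,
            "theta_grid": self.theta_grid,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "hd" in d:
            d["hd"] = HDParams(**d["hd"])
        if "grid_modules" in d:
            d["grid_modules"] = [GridParams(**g) for g in d["grid_modules"]]
        unknown = set(d) - {f.name for f in
                            cls.__dataclass_fields__.values()}
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**d)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
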