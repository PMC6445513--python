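"""Run configuration: optics, search space, detection parameters, I/O.

The serialized form mirrors the standard parameter table: optical keys
``u``, ``lambda``, ``INA``, ``r_max``, ``n``, ``theta``; search ranges
``dec_range``, ``d_range``, ``p_range`` as [min, step, max] triplets; and
detection parameters ``m``, ``c``, ``a``, ``t1``, ``t2``.  YAML or JSON is
chosen by file extension.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .extract import ExtractionConfig
from .match import MatchConstraints
from .model import OpticalConfig, ParameterGrid

__all__ = ["RunConfig"]


def _triplet(values: tuple[float, ...]) -> list[float]:
    if len(values) == 1:
        return [values[0], 1.0, values[0]]
    return [values[0], round(values[1] - values[0], 10), values[-1]]


@dataclass(frozen=True)
class RunConfig:
    """Everything a batch run needs; defaults are the standard table values."""

    optical: OpticalConfig = field(default_factory=OpticalConfig)
    grid: ParameterGrid = field(default_factory=ParameterGrid.default)
    m: int = 90
    c: float = 1.0
    constraints: MatchConstraints = field(default_factory=MatchConstraints)
    extraction: ExtractionConfig = field(default_factory=ExtractionConfig)
    magnitude_floor: float = 0.05
    e_modulus: float | None = None
    poisson: float | None = None
    input: str | None = None
    output: str | None = None
    save_line_image: bool = False
    save_correlation_map: bool = False
    overlay: bool = False
    seed: int = 0

    def to_dict(self) -> dict:
        cfg = {
            "u": self.optical.u,
            "lambda": self.optical.wavelength,
            "INA": self.optical.ina,
            "r_max": self.optical.r_max,
            "n": self.optical.n,
            "theta": self.optical.theta,
            "dec_range": _triplet(self.grid.dec_values),
            "d_range": _triplet(self.grid.d_values),
            "p_range": _triplet(self.grid.p_values),
            "m": self.m,
            "c": self.c,
            "a": self.constraints.a,
            "t1": self.extraction.t1,
            "t2": self.constraints.t2,
            "max_iterations": self.extraction.max_iterations,
            "magnitude_floor": self.magnitude_floor,
            "seed": self.seed,
        }
        if self.e_modulus is not None:
            cfg["E"] = self.e_modulus
        if self.poisson is not None:
            cfg["v"] = self.poisson
        io = {}
        if self.input is not None:
            io["input"] = self.input
        if self.output is not None:
            io["output"] = self.output
        for flag in ("save_line_image", "save_correlation_map", "overlay"):
            if getattr(self, flag):
                io[flag] = True
        if io:
            cfg["io"] = io
        return cfg

    @classmethod
    def from_dict(cls, cfg: dict) -> "RunConfig":
        optical = OpticalConfig(
            u=cfg.get("u", 0.067),
            wavelength=cfg.get("lambda", 0.53),
            ina=cfg.get("INA", 0.67),
            n=cfg.get("n", 1.332),
            theta=cfg.get("theta", math.pi),
            r_max=cfg.get("r_max", 100),
        )
        grid = ParameterGrid.from_ranges(
            cfg.get("d_range", [-0.45, 0.01, 0.0]),
            cfg.get("p_range", [10, 1, 30]),
            cfg.get("dec_range", [0, 1, 10]),
        )
        io = cfg.get("io", {})
        return cls(
            optical=optical,
            grid=grid,
            m=cfg.get("m", 90),
            c=cfg.get("c", 1.0),
            constraints=MatchConstraints(a=cfg.get("a", 0.05), t2=cfg.get("t2", 0.5)),
            extraction=ExtractionConfig(
                t1=cfg.get("t1", 0.9),
                r_max=cfg.get("r_max", 100),
                max_iterations=cfg.get("max_iterations", 100),
            ),
            magnitude_floor=cfg.get("magnitude_floor", 0.05),
            e_modulus=cfg.get("E"),
            poisson=cfg.get("v"),
            input=io.get("input"),
            output=io.get("output"),
            save_line_image=io.get("save_line_image", False),
            save_correlation_map=io.get("save_correlation_map", False),
            overlay=io.get("overlay", False),
            seed=cfg.get("seed", 0),
        )

    def to_file(self, path) -> None:
        path = Path(path)
        cfg = self.to_dict()
        with open(path, "w") as fh:
            if path.suffix == ".json":
                json.dump(cfg, fh, indent=1)
            else:
                yaml.safe_dump(cfg, fh, sort_keys=False)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            cfg = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
        return cls.from_dict(cfg)
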