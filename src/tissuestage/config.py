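"""Run configuration: schema, defaults, YAML round-trip.

A :class:`RunConfig` collects every constant of the model - tissue and
channel geometry, species transport, solver grid, landscape sweep, staging
and calibration - plus a random seed and output directory.  The shipped
paper-regime defaults live in ``data/paper_regime.yaml``; every constant is
flagged there as [paper] (printed in the source material for the model) or
[calibrated] (free constant fixed once by ``scripts/calibrate.py``).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .geometry import TissueParams
from .transport import SolverGrid, SpeciesParams

__all__ = ["StagingParams", "SweepParams", "RunConfig", "load_config", "paper_regime"]


@dataclass
class SweepParams:
    """Stiffness grid and landscape numerics."""

    Y_min: float = 2.0e3  # Pa
    Y_max: float = 150.0e3  # Pa
    n_Y: int = 200
    spacing: str = "log"  # "log" resolves the soft (healthy) flank densely
    n_periods: int = 10  # forcing protocol length (breathing periods)
    rel_smooth: float = 1.0e-3  # landscape spline smoothing (relative)

    def __post_init__(self) -> None:
        if not 0.0 < self.Y_min < self.Y_max:
            raise ValueError("need 0 < Y_min < Y_max")
        if self.n_Y < 5:
            raise ValueError("need at least 5 stiffness grid points")
        if self.spacing not in ("log", "linear"):
            raise ValueError(f"unknown grid spacing {self.spacing!r}")

    def grid_Y(self):
        import numpy as np

        if self.spacing == "log":
            return np.geomspace(self.Y_min, self.Y_max, self.n_Y)
        return np.linspace(self.Y_min, self.Y_max, self.n_Y)


@dataclass
class StagingParams:
    """Free-energy and staging constants."""

    Y_healthy: float = 5.0e3  # healthy anchor stiffness [Pa] [calibrated]
    Y_cancer: float = 45.5e3  # carcinogenic anchor stiffness [Pa] [paper]
    n_mol: float = 1.0  # moles per representative element [calibrated]
    c_k: float = 1.0  # tanh gain constant [calibrated]
    D_Y: float = 1.0  # stiffness-space diffusivity (unidentifiable; fixed)
    dG_r: float = 0.0  # reversible free-energy offset [J/mol]
    mode: str = "expansion"  # configurational free-energy mode
    drift: str = "driven"  # progression drift convention
    prominence_rel: float = 5.0e-5  # boundary-detection prominence
    stable_tol: float = 0.05  # dynamical-stability threshold

    def __post_init__(self) -> None:
        if self.mode not in ("expansion", "exact"):
            raise ValueError(f"unknown free-energy mode {self.mode!r}")
        if self.drift not in ("driven", "relaxational"):
            raise ValueError(f"unknown drift convention {self.drift!r}")
        if self.c_k <= 0.0 or self.D_Y <= 0.0:
            raise ValueError("c_k and D_Y must be positive")


@dataclass
class RunConfig:
    """Complete, serialisable model configuration."""

    tissue: TissueParams = field(
        default_factory=lambda: TissueParams(phi=0.0129, Y=5.0e3)
    )
    species: SpeciesParams = field(default_factory=SpeciesParams)
    grid: SolverGrid = field(default_factory=SolverGrid)
    sweep: SweepParams = field(default_factory=SweepParams)
    staging: StagingParams = field(default_factory=StagingParams)
    seed: int = 0
    outdir: str = "results"

    def to_dict(self) -> dict:
        return {
            "tissue": asdict(self.tissue),
            "species": asdict(self.species),
            "grid": asdict(self.grid),
            "sweep": asdict(self.sweep),
            "staging": asdict(self.staging),
            "seed": self.seed,
            "outdir": self.outdir,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {
            "tissue": TissueParams,
            "species": SpeciesParams,
            "grid": SolverGrid,
            "sweep": SweepParams,
            "staging": StagingParams,
        }
        kwargs = {}
        for key, val in d.items():
            if key in known:
                if not isinstance(val, dict):
                    raise TypeError(f"section {key!r} must be a mapping")
                kwargs[key] = known[key](**val)
            elif key in ("seed", "outdir"):
                kwargs[key] = val
            else:
                raise ValueError(f"unknown configuration section {key!r}")
        return cls(**kwargs)


def load_config(path: str | Path) -> RunConfig:
    """Parse a YAML configuration file into a validated RunConfig."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a YAML mapping")
    return RunConfig.from_dict(data)


def paper_regime() -> RunConfig:
    """The shipped paper-regime configuration (calibrated defaults)."""
    ref = importlib.resources.files("tissuestage").joinpath(
        "data/paper_regime.yaml"
    )
    data = yaml.safe_load(ref.read_text())
    return RunConfig.from_dict(data)
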