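"""Synthetic (porosity, stiffness) sample tables and the phi(Y) trend fit.

No public table of measured (phi, Y) pairs exists for pancreatic tissue;
the literature anchors used by the model are the carcinogenic averages
(phi = 0.0022, Y = 45.5 kPa).  The generator emulates per-stage clusters
along the hyperbolic trend phi(Y) = a / (1 + b Y): log-normal stiffness
scatter around a stage anchor and multiplicative porosity noise about the
trend.  Tables are tagged ``synthetic``; fitting the trend back from a
generated table recovers (a, b) - the parameter-recovery loop used in the
tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .staging import STAGE_LABELS

__all__ = ["SampleTable", "STAGE_ANCHORS", "generate_tissue_samples", "fit_phi_trend"]

# Per-stage stiffness anchors [Pa] along the shipped trend (a=0.0322,
# b=3e-4); healthy sits on the soft low-dissipation plateau, the
# carcinogenic anchor at the printed (0.0022, 45.5 kPa) average.
_TREND_A = 0.0322
_TREND_B = 3.0e-4
STAGE_ANCHORS: dict[str, float] = {
    "H": 5.0e3,
    "F0": 12.0e3,
    "F": 22.0e3,
    "T": 33.0e3,
    "C": 45.5e3,
    "T_C": 70.0e3,
    "RC": 110.0e3,
}


@dataclass
class SampleTable:
    """Rows of (sample_id, phi, Y_pa, stage_label) with provenance."""

    df: pd.DataFrame
    provenance: str = "synthetic"  # "measured" | "synthetic"

    def __post_init__(self) -> None:
        required = {"sample_id", "phi", "Y_pa"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValueError(f"sample table lacks columns {sorted(missing)}")
        if self.df["sample_id"].duplicated().any():
            raise ValueError("sample_id values must be unique")
        if len(self.df):
            if not ((self.df["phi"] > 0) & (self.df["phi"] < 1)).all():
                raise ValueError("porosity must lie in (0, 1)")
            if not (self.df["Y_pa"] > 0).all():
                raise ValueError("stiffness must be positive")

    def __len__(self) -> int:
        return len(self.df)

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, provenance: str = "measured") -> "SampleTable":
        return cls(pd.read_csv(path), provenance=provenance)


def _trend(Y, a, b):
    return a / (1.0 + b * np.asarray(Y, dtype=float))


def generate_tissue_samples(
    stage: str,
    n: int,
    seed: int,
    a: float = _TREND_A,
    b: float = _TREND_B,
    Y_spread: float = 0.10,
    phi_noise: float = 0.05,
) -> SampleTable:
    """Seeded draws of (phi, Y) pairs around a stage anchor on the trend.

    Stiffness is log-normal around the stage anchor (geometric spread
    ``Y_spread``); porosity is the trend value with multiplicative Gaussian
    noise ``phi_noise``.  Identical seeds give identical tables.
    """
    if stage not in STAGE_LABELS:
        raise ValueError(f"unknown stage label {stage!r}; choose from {STAGE_LABELS}")
    if n < 0:
        raise ValueError("n must be non-negative")
    rng = np.random.default_rng(seed)
    anchor = STAGE_ANCHORS[stage]
    Y = anchor * np.exp(rng.normal(0.0, Y_spread, size=n))
    phi = _trend(Y, a, b) * (1.0 + rng.normal(0.0, phi_noise, size=n))
    phi = np.clip(phi, 1.0e-6, 1.0 - 1.0e-6)
    df = pd.DataFrame(
        {
            "sample_id": [f"{stage}-{i:04d}" for i in range(n)],
            "phi": phi,
            "Y_pa": Y,
            "stage_label": stage,
        }
    )
    return SampleTable(df=df, provenance="synthetic")


def fit_phi_trend(table: SampleTable) -> tuple[float, float, np.ndarray]:
    """Least-squares fit of phi = a / (1 + b Y) to a sample table.

    Returns (a, b, residuals).  The starting point comes from the
    linearisation 1/phi = 1/a + (b/a) Y, which is exact for noise-free
    data; `curve_fit` then refines in the original (non-linear) metric.
    """
    Y = table.df["Y_pa"].to_numpy(dtype=float)
    phi = table.df["phi"].to_numpy(dtype=float)
    if len(np.unique(Y)) < 2:
        raise ValueError("trend fit needs at least 2 distinct stiffness values")
    # linearised start: 1/phi linear in Y
    coef = np.polyfit(Y, 1.0 / phi, 1)
    a0 = 1.0 / coef[1] if coef[1] > 0 else np.max(phi)
    b0 = max(coef[0] * a0, 1.0e-12)
    (a, b), _ = curve_fit(_trend, Y, phi, p0=(a0, b0), maxfev=10000)
    residuals = phi - _trend(Y, a, b)
    return float(a), float(b), residuals
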