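"""Non-equilibrium free energy and configuration probability over stiffness.

The free-energy change of holding the tissue at Young's modulus Y is

    dG(Y) = dG_r + dG_i(Y) + dG_c(Y),

with a reversible contribution dG_r (a constant offset by default - it
cancels in every ratio and current), the irreversible contribution
dG_i = E_d (lost work, the dissipated energy per mole), and the
configurational cost of sitting away from the dissipation-extremal
stiffness Y*,

    dG_c = |E_d(Y) - E_d(Y*)|            (exact form)
    dG_c = (dE_d/dY)^2 / (2 |d2E_d/dY2(Y*)|)   (quadratic expansion).

The probability of observing a configuration follows the Boltzmann weight
rho(Y) ~ exp(-dG / RT), normalised by trapezoidal quadrature over the
stiffness grid.  A ``paper_literal`` sign switch (+dG in the exponent) is
kept for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dissipation import EnergyLandscape
from .transport import R_GAS

__all__ = [
    "FreeEnergyLandscape",
    "DegenerateCurvatureError",
    "configurational_free_energy",
    "total_free_energy",
    "configuration_probability",
    "probability_ratio",
]


class DegenerateCurvatureError(ValueError):
    """Landscape curvature at Y* too small for the quadratic expansion."""


@dataclass
class FreeEnergyLandscape:
    """Free energy and configuration probability over the stiffness grid."""

    Y_grid: np.ndarray
    dG_r: np.ndarray  # reversible contribution [J/mol]
    dG_i: np.ndarray  # irreversible (dissipated) contribution [J/mol]
    dG_c: np.ndarray  # configurational contribution [J/mol]
    dG: np.ndarray  # total [J/mol]
    rho: np.ndarray  # probability density [1/Pa], unit mass on the grid
    T: float
    Y_star: float

    @property
    def beta(self) -> float:
        return 1.0 / (R_GAS * self.T)

    def rho_at(self, Y: float) -> float:
        """Interpolated probability density at stiffness ``Y``."""
        return float(np.interp(Y, self.Y_grid, self.rho))

    def dG_at(self, Y: float) -> float:
        return float(np.interp(Y, self.Y_grid, self.dG))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "Y": self.Y_grid,
                "dG_r": self.dG_r,
                "dG_i": self.dG_i,
                "dG_c": self.dG_c,
                "dG": self.dG,
                "rho": self.rho,
            }
        )


def configurational_free_energy(
    land: EnergyLandscape, mode: str = "expansion", curvature_eps: float = 1.0e-30
) -> np.ndarray:
    """Configurational cost dG_c(Y) of holding the tissue away from Y*.

    ``expansion`` (default) is the quadratic expansion around the extremum;
    it coincides with the exact form whenever E_d is exactly quadratic.
    """
    if mode == "exact":
        return np.abs(land.E_d_of_Y - land.E_d_star)
    if mode != "expansion":
        raise ValueError(f"unknown mode {mode!r}")
    curv = abs(land.d2_at_star)
    if curv < curvature_eps:
        raise DegenerateCurvatureError(
            f"|d2E_d/dY2(Y*)| = {curv:.3e} below {curvature_eps:.1e}; "
            "use mode='exact' for this landscape"
        )
    return 0.5 * land.dEdY**2 / curv


def total_free_energy(
    land: EnergyLandscape,
    dG_r: float | np.ndarray = 0.0,
    mode: str = "expansion",
    n_mol: float = 1.0,
    T: float = 310.0,
) -> FreeEnergyLandscape:
    """Assemble dG(Y) = dG_r + E_d/n_mol + dG_c/n_mol and its Boltzmann density.

    ``n_mol`` converts the per-element dissipated energy [J] into a molar
    quantity [J/mol]; it is part of the single global calibration.
    """
    Y = land.Y_grid
    dG_r_arr = np.broadcast_to(np.asarray(dG_r, dtype=float), Y.shape).copy()
    dG_i = land.E_d_of_Y / n_mol
    dG_c = configurational_free_energy(land, mode=mode) / n_mol
    dG = dG_r_arr + dG_i + dG_c
    rho = configuration_probability(dG, Y, T)
    return FreeEnergyLandscape(
        Y_grid=Y,
        dG_r=dG_r_arr,
        dG_i=dG_i,
        dG_c=dG_c,
        dG=dG,
        rho=rho,
        T=T,
        Y_star=land.Y_star,
    )


def configuration_probability(
    dG: np.ndarray, Y_grid: np.ndarray, T: float, sign: str = "boltzmann"
) -> np.ndarray:
    """Normalised configuration probability density over the stiffness grid.

    rho ~ exp(-dG/RT) (``sign="paper_literal"`` flips the exponent);
    overflow is guarded by subtracting the extremal dG before
    exponentiation, which cancels in the normalisation.
    """
    dG = np.asarray(dG, dtype=float)
    if not np.all(np.isfinite(dG)):
        raise ValueError("dG must be finite on the grid")
    beta = 1.0 / (R_GAS * T)
    if sign == "boltzmann":
        expo = -beta * (dG - np.min(dG))
    elif sign == "paper_literal":
        expo = beta * (dG - np.max(dG))
    else:
        raise ValueError(f"unknown sign convention {sign!r}")
    w = np.exp(expo)
    Z = np.trapezoid(w, Y_grid)
    return w / Z


def probability_ratio(dG1: float, dG2: float, T: float, sign: str = "boltzmann") -> float:
    """rho(Y1)/rho(Y2) = exp(-beta (dG(Y1) - dG(Y2))) (Boltzmann sign)."""
    beta = 1.0 / (R_GAS * T)
    s = -1.0 if sign == "boltzmann" else 1.0
    return float(np.exp(s * beta * (dG1 - dG2)))
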