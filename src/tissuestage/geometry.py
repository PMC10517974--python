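"""Intercellular channel geometry.

The interstitial space of the tissue is idealised as a periodically
constricted ("breathing") channel of half-width

    h(x, t) = A_h (sin(pi x / R_m - pi/2) + 1) |sin(f t)| + h0,

driven by an external periodic force of frequency ``f``.  The bottleneck
half-width ``h0`` follows from balancing the elastic energy of opening the
channel, ``Y (h0 - r0)^2 / (2 R_m)``, against the work ``C0 dP`` done by the
pressure difference the force induces in the capillary.  The amplitude
``A_h`` is slaved to the tissue porosity

    phi = (1 / R_m^3) * int_0^{R_m} h^2 dx,

evaluated at the forcing maximum ``|sin(f t)| = 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad

__all__ = [
    "TissueParams",
    "ChannelGeometry",
    "InfeasiblePorosityError",
    "bottleneck_width",
    "amplitude_from_porosity",
    "channel_halfwidth",
    "porosity_of_geometry",
    "build_geometry",
]


class InfeasiblePorosityError(ValueError):
    """Requested porosity is below the minimum the bottleneck allows."""


@dataclass
class TissueParams:
    """Physical parameters of one tissue configuration.

    Parameters
    ----------
    phi : float
        Porosity (extracellular volume fraction), 0 < phi < 1.
    Y : float
        Young's modulus [Pa].
    R_m : float
        Characteristic channel length [m] (four cell diameters).
    r0 : float
        Smallest capillary opening [m].
    C0 : float
        Force-to-pressure coupling volume [m^3].
    dP : float
        Pressure difference induced by the external force [Pa].
    f : float
        Forcing frequency [1/s]; the channel breathes with period pi/f.
    T : float
        Temperature [K].
    delta : float
        Tissue density [kg/m^3].
    Lambda : float
        Mechanical attenuation coefficient [Pa/m].
    lam : float
        Characteristic mechanical length, one cell diameter [m].
    a, b : float
        Constants of the porosity-stiffness trend phi(Y) = a/(1 + b Y).
    """

    phi: float
    Y: float
    R_m: float = 4.0e-5
    r0: float = 1.0e-7
    C0: float = 5.0e-10
    dP: float = 100.0
    f: float = 1.0
    T: float = 310.0
    delta: float = 1.0e3
    Lambda: float = 2.5e19
    lam: float = 1.0e-5
    a: float = 0.0322
    b: float = 3.0e-4

    def __post_init__(self) -> None:
        if not 0.0 < self.phi < 1.0:
            raise ValueError(f"porosity must lie in (0, 1), got {self.phi}")
        if self.Y <= 0.0:
            raise ValueError(f"Young's modulus must be positive, got {self.Y}")
        for name in ("R_m", "C0", "f", "T", "delta", "Lambda", "lam"):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"{name} must be strictly positive")
        if self.r0 < 0.0 or self.dP < 0.0:
            raise ValueError("r0 and dP must be non-negative")
        if self.r0 >= self.R_m:
            raise ValueError("r0 must be smaller than R_m")


@dataclass
class ChannelGeometry:
    """Breathing-channel geometry: amplitude, bottleneck and evaluator."""

    A_h: float
    h0: float
    R_m: float
    f: float
    mode: str = "self_consistent"

    def halfwidth(self, x, t):
        """Channel half-width h(x, t) [m]."""
        return channel_halfwidth(x, t, self.A_h, self.h0, self.R_m, self.f)

    def dhdx(self, x, t):
        """Spatial slope of the half-width (dimensionless)."""
        x = np.asarray(x, dtype=float)
        envelope = np.abs(np.sin(self.f * np.asarray(t, dtype=float)))
        return (
            self.A_h
            * (np.pi / self.R_m)
            * np.cos(np.pi * x / self.R_m - np.pi / 2.0)
            * envelope
        )


def bottleneck_width(Y: float, dP: float, C0: float, R_m: float, r0: float) -> float:
    """Bottleneck half-width h0 [m] from the elastic-energy balance.

    Equating the elastic energy of opening the channel by ``h0 - r0`` with
    the work done by the induced pressure difference gives

        h0 = sqrt(2 C0 R_m dP / Y) + r0.
    """
    if Y <= 0.0:
        raise ValueError(f"Young's modulus must be positive, got {Y}")
    if R_m <= 0.0:
        raise ValueError(f"R_m must be positive, got {R_m}")
    if r0 < 0.0 or dP < 0.0:
        raise ValueError("r0 and dP must be non-negative")
    return np.sqrt(2.0 * C0 * R_m * dP / Y) + r0


def amplitude_from_porosity(
    phi: float,
    R_m: float,
    h0: float,
    r0: float | None = None,
    mode: str = "self_consistent",
) -> float:
    """Channel amplitude A_h [m] consistent with porosity ``phi``.

    At the forcing maximum, the porosity integral over one channel period
    evaluates to ``phi R_m^2 = (3/2) A_h^2 + 2 A_h h0 + h0^2``; solving for
    the non-negative root gives

        A_h = sqrt((2/3) phi R_m^2 - (2/9) h0^2) - (2/3) h0.

    ``mode="paper_literal"`` replaces ``h0`` by the capillary opening ``r0``
    in this closed form (the small-forcing approximation h0 ~ r0); the two
    modes coincide exactly when ``dP = 0``.
    """
    if mode == "self_consistent":
        ref = h0
    elif mode == "paper_literal":
        if r0 is None:
            raise ValueError("paper_literal mode requires r0")
        ref = r0
    else:
        raise ValueError(f"unknown mode {mode!r}")
    radicand = (2.0 / 3.0) * phi * R_m**2 - (2.0 / 9.0) * ref**2
    if radicand < 0.0:
        phi_min = ref**2 / (3.0 * R_m**2)
        raise InfeasiblePorosityError(
            f"porosity {phi:.3e} infeasible for this bottleneck; "
            f"minimum feasible porosity is {phi_min:.3e}"
        )
    A_h = np.sqrt(radicand) - (2.0 / 3.0) * ref
    return max(A_h, 0.0)


def channel_halfwidth(x, t, A_h: float, h0: float, R_m: float, f: float):
    """Half-width h(x, t) = A_h (sin(pi x/R_m - pi/2) + 1)|sin(f t)| + h0."""
    x = np.asarray(x, dtype=float)
    t = np.asarray(t, dtype=float)
    shape = np.sin(np.pi * x / R_m - np.pi / 2.0) + 1.0
    return A_h * shape * np.abs(np.sin(f * t)) + h0


def porosity_of_geometry(geom: ChannelGeometry, R_m: float | None = None) -> float:
    """Porosity (1/R_m^3) int_0^{R_m} h^2 dx at the forcing maximum.

    Numerical-quadrature evaluation of the definition; serves as the
    independent check (and inverse) of :func:`amplitude_from_porosity`.
    """
    if R_m is None:
        R_m = geom.R_m
    t_max = np.pi / (2.0 * geom.f)  # |sin(f t)| = 1

    def integrand(x):
        return float(geom.halfwidth(x, t_max)) ** 2

    val, _ = quad(integrand, 0.0, R_m, limit=200)
    return val / R_m**3


def build_geometry(tp: TissueParams, mode: str = "self_consistent") -> ChannelGeometry:
    """Construct the channel geometry implied by a tissue parameter set."""
    h0 = bottleneck_width(tp.Y, tp.dP, tp.C0, tp.R_m, tp.r0)
    A_h = amplitude_from_porosity(tp.phi, tp.R_m, h0, r0=tp.r0, mode=mode)
    return ChannelGeometry(A_h=A_h, h0=h0, R_m=tp.R_m, f=tp.f, mode=mode)
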