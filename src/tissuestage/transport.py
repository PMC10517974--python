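"""Species transport in the breathing channel.

Solves the 1-D mass-conservation equation for a chemical species (drug,
glucose) in the constricted intercellular channel,

    dc/dt = -dJ/dx - k c - (D_a / h) (c - c_cell),
    J     = -(D / RT) c dmu/dx,
    mu    = RT ln c + RT ln (h / R_m)^2,

i.e. diffusion in the Fick-Jacobs entropic potential ``psi = ln (h/R_m)^2``
with first-order consumption and wall absorption.  The effective
diffusivity ``D = D0 / sqrt(1 + (dh/dx)^2)`` accounts for tortuosity.
The capillary feeds the channel mouth through a Robin condition
``J(0, t) = K (c* - c(0, t))`` and the far end is closed, ``J(L, t) = 0``.

Discretisation: conservative finite volumes with Scharfetter-Gummel
(exponential-fitting) face fluxes - exact for the Fick-Jacobs equilibrium
profile ``c ~ (h/R_m)^-2`` - and backward-Euler time stepping, which keeps
the scheme positivity-preserving for any time step.  Discrete mass balance
holds to solver accuracy at every step and is monitored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import solve_banded

from .geometry import ChannelGeometry, TissueParams, build_geometry

R_GAS = 8.314462618  # molar gas constant [J/mol K]

__all__ = [
    "R_GAS",
    "SpeciesParams",
    "SolverGrid",
    "TransportField",
    "TransportSolverError",
    "effective_diffusion",
    "chemical_potential",
    "solve_transport",
]


class TransportSolverError(RuntimeError):
    """The time integration produced NaN or significantly negative mass."""


@dataclass
class SpeciesParams:
    """Transport, uptake and boundary constants for one species.

    D0 : free diffusion coefficient [m^2/s]
    D_a : wall absorption coefficient [m/s]
    k : consumption rate constant [1/s]
    c_star : controlled capillary concentration c* [mol/m^3]
    K_ch : boundary (Robin) transport coefficient [m/s]; the single
        identifiable product of the boundary constant and chemical force
    c_cell : concentration inside cells / ECM [mol/m^3]
    dz_a : fugacity drop along the absorption flux [J/mol]
    dz_r : fugacity drop of the consumption reaction [J/mol]
    """

    D0: float = 7.0e-10
    D_a: float = 1.0e-7
    k: float = 0.05
    c_star: float = 5.0
    K_ch: float = 1.0e-5
    c_cell: float = 0.0
    dz_a: float = 500.0
    dz_r: float = 500.0

    def __post_init__(self) -> None:
        if self.D0 <= 0.0:
            raise ValueError("D0 must be positive")
        for name in ("D_a", "k", "K_ch", "c_star", "c_cell"):
            if getattr(self, name) < 0.0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class SolverGrid:
    """Numerical grid and horizon for the transport solve.

    L_factor : domain length in units of R_m (far boundary truncates
        J(inf, t) = 0); nx : spatial cells; steps_per_period : time steps
        per breathing period pi/f; n_periods_max : horizon in periods;
        tol_sigma : relative convergence tolerance for per-period entropy
        increments (used by the dissipation module).
    """

    L_factor: int = 4
    nx: int = 128
    steps_per_period: int = 64
    n_periods_max: int = 60
    tol_sigma: float = 1.0e-3

    def __post_init__(self) -> None:
        if self.nx < 16:
            raise ValueError("nx must be at least 16")
        if self.L_factor < 1:
            raise ValueError("domain must cover at least one channel period")
        if self.steps_per_period < 8:
            raise ValueError("need at least 8 time steps per forcing period")


@dataclass
class TransportField:
    """Space-time solution of the transport problem.

    Concentrations are stored densely (``c[ix, it]``); geometry-derived
    fields (h, D, J, mu, sinks) are reconstructed on demand from the stored
    forcing envelope so the container stays light.
    """

    x: np.ndarray  # cell centres [m]
    t: np.ndarray  # time levels [s]
    c: np.ndarray  # concentration [mol/m^3], shape (nx, nt)
    envelope: np.ndarray  # |sin(f t)| per time level
    geom: ChannelGeometry
    sp: SpeciesParams
    T: float
    dx: float
    mass_defect: float  # worst relative mass-balance defect per step
    influx: np.ndarray  # boundary influx K(c* - c(0,t)) [mol/m^2 s]

    @property
    def shape_x(self) -> np.ndarray:
        return np.sin(np.pi * self.x / self.geom.R_m - np.pi / 2.0) + 1.0

    def halfwidth(self) -> np.ndarray:
        """h(x, t) on the storage grid, shape (nx, nt)."""
        return (
            self.geom.A_h * np.outer(self.shape_x, self.envelope) + self.geom.h0
        )

    def dhdx(self) -> np.ndarray:
        slope = (
            self.geom.A_h
            * (np.pi / self.geom.R_m)
            * np.cos(np.pi * self.x / self.geom.R_m - np.pi / 2.0)
        )
        return np.outer(slope, self.envelope)

    def diffusivity(self) -> np.ndarray:
        return effective_diffusion(self.sp.D0, self.dhdx())

    def mu(self) -> np.ndarray:
        """Chemical potential [J/mol]; -inf where c = 0."""
        return chemical_potential(self.c, self.halfwidth(), self.geom.R_m, self.T)

    def flux(self) -> np.ndarray:
        """Diffusive flux J = -D (dc/dx + 2 c dln(h)/dx) at cell centres."""
        h = self.halfwidth()
        D = self.diffusivity()
        dcdx = np.gradient(self.c, self.x, axis=0)
        drift = 2.0 * self.c * self.dhdx() / h
        return -D * (dcdx + drift)

    def face_flux(self) -> np.ndarray:
        """Scharfetter-Gummel flux at interior faces, shape (nx-1, nt).

        This is the flux the conservative update actually used; entropy
        bookkeeping must use it (central differences overestimate the
        dissipation badly across steep entropic wells).
        """
        geom = self.geom
        x_f = 0.5 * (self.x[:-1] + self.x[1:])
        shape_f = np.sin(np.pi * x_f / geom.R_m - np.pi / 2.0) + 1.0
        slope_f = (
            geom.A_h * (np.pi / geom.R_m)
            * np.cos(np.pi * x_f / geom.R_m - np.pi / 2.0)
        )
        env = self.envelope[None, :]
        h_c = geom.A_h * np.outer(self.shape_x, self.envelope) + geom.h0
        D_f = self.sp.D0 / np.sqrt(1.0 + (slope_f[:, None] * env) ** 2)
        psi = 2.0 * np.log(h_c / geom.R_m)
        dpsi = np.diff(psi, axis=0)
        Bp = _bernoulli(dpsi)
        Bm = _bernoulli(-dpsi)
        return D_f / self.dx * (Bp * self.c[:-1, :] - Bm * self.c[1:, :])

    def absorption_flux(self) -> np.ndarray:
        """Absorption sink (D_a / h)(c - c_cell) [mol/m^3 s]."""
        return self.sp.D_a / self.halfwidth() * (self.c - self.sp.c_cell)

    def consumption_rate(self) -> np.ndarray:
        """Consumption sink k c [mol/m^3 s]."""
        return self.sp.k * self.c

    def to_dataframe(self, stride_t: int = 1, stride_x: int = 1) -> pd.DataFrame:
        """Tidy export with columns x, t, c, J, mu."""
        J = self.flux()
        mu = self.mu()
        ix = np.arange(0, len(self.x), stride_x)
        it = np.arange(0, len(self.t), stride_t)
        xx, tt = np.meshgrid(self.x[ix], self.t[it], indexing="ij")
        return pd.DataFrame(
            {
                "x": xx.ravel(),
                "t": tt.ravel(),
                "c": self.c[np.ix_(ix, it)].ravel(),
                "J": J[np.ix_(ix, it)].ravel(),
                "mu": mu[np.ix_(ix, it)].ravel(),
            }
        )


def effective_diffusion(D0: float, dhdx) -> np.ndarray | float:
    """Tortuosity-reduced diffusivity D = D0 / sqrt(1 + (dh/dx)^2)."""
    if D0 <= 0.0:
        raise ValueError("D0 must be positive")
    return D0 / np.sqrt(1.0 + np.square(dhdx))

def chemical_potential(c, h, R_m: float, T: float):
    """mu = RT ln c + RT ln (h/R_m)^2 (molar convention, J/mol).

    The entropic term penalises wide-to-narrow passages (Fick-Jacobs).
    Zero concentration maps to -inf; flux expressions avoid evaluating it.
    """
    c = np.asarray(c, dtype=float)
    with np.errstate(divide="ignore"):
        return R_GAS * T * (np.log(c) + 2.0 * np.log(np.asarray(h) / R_m))


def _bernoulli(z: np.ndarray) -> np.ndarray:
    """B(z) = z / (e^z - 1), series-continued through z = 0."""
    z = np.asarray(z, dtype=float)
    out = np.empty_like(z)
    small = np.abs(z) < 1.0e-10
    out[small] = 1.0 - 0.5 * z[small]
    zs = z[~small]
    out[~small] = zs / np.expm1(zs)
    return out


def solve_transport(
    tp: TissueParams,
    sp: SpeciesParams,
    grid: SolverGrid,
    geom: ChannelGeometry | None = None,
    c_init: np.ndarray | float = 0.0,
    freeze_envelope: float | None = None,
) -> TransportField:
    """Integrate the channel transport problem.

    Parameters
    ----------
    freeze_envelope : float, optional
        If given, the breathing envelope |sin(f t)| is pinned to this value
        (frozen geometry) - used for equilibrium and relaxation checks.
    c_init : initial concentration profile (default 0: drug arriving from
        the capillary).

    Returns a :class:`TransportField` sampled at every time step.
    """
    if geom is None:
        geom = build_geometry(tp)
    L = grid.L_factor * tp.R_m
    nx = grid.nx
    dx = L / nx
    x = (np.arange(nx) + 0.5) * dx
    x_faces = np.arange(1, nx) * dx

    period = np.pi / tp.f
    dt = period / grid.steps_per_period
    n_steps = grid.steps_per_period * grid.n_periods_max
    t = np.arange(n_steps + 1) * dt

    if freeze_envelope is None:
        envelope = np.abs(np.sin(tp.f * t))
    else:
        envelope = np.full_like(t, float(freeze_envelope))

    shape_c = np.sin(np.pi * x / tp.R_m - np.pi / 2.0) + 1.0
    shape_f = np.sin(np.pi * x_faces / tp.R_m - np.pi / 2.0) + 1.0
    slope_f = (
        geom.A_h * (np.pi / tp.R_m) * np.cos(np.pi * x_faces / tp.R_m - np.pi / 2.0)
    )

    c = np.empty((nx, n_steps + 1))
    c[:, 0] = np.broadcast_to(np.asarray(c_init, dtype=float), (nx,))
    if np.any(c[:, 0] < 0.0):
        raise ValueError("initial concentration must be non-negative")
    influx = np.empty(n_steps + 1)
    influx[0] = sp.K_ch * (sp.c_star - c[0, 0])

    ab = np.zeros((3, nx))
    rhs = np.empty(nx)
    worst_defect = 0.0
    cn = c[:, 0].copy()

    for n in range(1, n_steps + 1):
        env = envelope[n]
        h_c = geom.A_h * shape_c * env + geom.h0
        h_f = geom.A_h * shape_f * env + geom.h0
        D_f = sp.D0 / np.sqrt(1.0 + (slope_f * env) ** 2)
        # entropic potential difference across each interior face
        psi = 2.0 * np.log(h_c / tp.R_m)
        dpsi = np.diff(psi)
        Bp = _bernoulli(dpsi)  # multiplies left cell
        Bm = _bernoulli(-dpsi)  # multiplies right cell
        wf = D_f / dx  # face conductance [m/s]

        sink = sp.k + sp.D_a / h_c
        lam = dt / dx

        ab[:] = 0.0
        # diagonal
        diag = 1.0 + dt * sink
        diag[:-1] += lam * wf * Bp / 1.0  # outflow through right face
        diag[1:] += lam * wf * Bm
        # left Robin boundary: J_0 = K (c* - c_0)
        diag[0] += lam * sp.K_ch
        ab[1, :] = diag
        # superdiagonal (coeff of c_{i+1} in row i)
        ab[0, 1:] = -lam * wf * Bm
        # subdiagonal (coeff of c_{i-1} in row i)
        ab[2, :-1] = -lam * wf * Bp

        rhs[:] = cn + dt * sp.D_a / h_c * sp.c_cell
        rhs[0] += lam * sp.K_ch * sp.c_star

        cnew = solve_banded((1, 1), ab, rhs)

        if not np.all(np.isfinite(cnew)) or np.any(cnew < -1.0e-12 * max(sp.c_star, 1.0)):
            raise TransportSolverError(
                f"unstable solution at step {n} (t={t[n]:.3g} s): the "
                f"semi-implicit scheme requires dt resolving the forcing "
                f"period (dt={dt:.3g} s, period={period:.3g} s)"
            )
        cnew = np.maximum(cnew, 0.0)

        # discrete mass balance: dx * d(sum c) = dt * (influx - sinks)
        J_in = sp.K_ch * (sp.c_star - cnew[0])
        sinks = float(np.sum((sp.k * cnew + sp.D_a / h_c * (cnew - sp.c_cell)) * dx))
        dmass = float(np.sum(cnew - cn) * dx)
        scale = max(abs(dt * J_in), abs(dmass), dt * sinks, 1.0e-300)
        defect = abs(dmass - dt * (J_in - sinks)) / scale
        worst_defect = max(worst_defect, defect)

        c[:, n] = cnew
        influx[n] = J_in
        cn = cnew

    return TransportField(
        x=x,
        t=t,
        c=c,
        envelope=envelope,
        geom=geom,
        sp=sp,
        T=tp.T,
        dx=dx,
        mass_defect=worst_defect,
        influx=influx,
    )
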