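"""Entropy production, dissipated energy, and the stiffness landscape."""

from dataclasses import replace

import numpy as np
import pytest
from scipy.integrate import quad

from tissuestage.dissipation import (
    EnergyLandscape,
    mechanical_permittivity,
    porosity_from_young,
    sigma_chemical,
    sigma_mechanical,
    total_entropy,
)
from tissuestage.geometry import TissueParams, build_geometry
from tissuestage.transport import (
    R_GAS,
    SolverGrid,
    SpeciesParams,
    solve_transport,
)


class TestSigmaMechanical:
    def test_zero_force_is_silent(self, tissue):
        tp = replace(tissue, dP=0.0)
        t = np.linspace(0, 5, 50)
        assert np.all(sigma_mechanical(t, tp) == 0.0)

    def test_period_average_matches_quadrature(self, tissue):
        """<sigma_m> over one forcing period equals kappa dP^2 / (2 lam^2)."""
        kappa = mechanical_permittivity(tissue)
        period = 1.0 / tissue.f  # of sin(omega t), omega = 2 pi f
        val, _ = quad(lambda t: sigma_mechanical(t, tissue), 0, period, limit=200)
        analytic = kappa * (tissue.dP / tissue.lam) ** 2 / 2.0
        assert val / period == pytest.approx(analytic, rel=1e-9)

    def test_sqrt_stiffness_scaling(self, tissue):
        t = 0.21
        doubled = replace(tissue, Y=2 * tissue.Y)
        ratio = sigma_mechanical(t, doubled) / sigma_mechanical(t, tissue)
        assert ratio == pytest.approx(np.sqrt(2.0))


class TestSigmaChemical:
    def test_equilibrium_produces_nothing(self, tissue):
        """No forcing, no sinks: the entropy-production density vanishes."""
        grid = SolverGrid(nx=32, steps_per_period=16, n_periods_max=3, tol_sigma=1.0)
        sp = SpeciesParams(c_star=0.0, D_a=0.0, k=0.0)
        f = solve_transport(tissue, sp, grid)
        assert np.all(sigma_chemical(f, sp, tissue.T) == 0.0)

    def test_non_negative_everywhere(self, tissue, species, coarse_grid):
        f = solve_transport(tissue, species, coarse_grid)
        sig = sigma_chemical(f, species, tissue.T)
        assert np.all(sig >= 0.0)

    def test_free_relaxation_dissipates_free_energy(self, tissue):
        """Closed frozen channel: T Sigma_ch equals the free-energy drop.

        For an ideal mixture in the entropic potential, F = int c (mu - RT)
        dx decreases under pure diffusion exactly by the dissipated heat.
        The comparison starts after the (first-order-in-time) initial layer
        has been traversed, where the dynamics are resolved.
        """
        grid = SolverGrid(nx=64, steps_per_period=64, n_periods_max=30, tol_sigma=1.0)
        sp = SpeciesParams(D_a=0.0, k=0.0, K_ch=0.0)  # closed box
        geom = build_geometry(tissue)
        x = (np.arange(grid.nx) + 0.5) * (grid.L_factor * tissue.R_m / grid.nx)
        env = 0.999
        h = geom.halfwidth(x, np.pi / (2 * tissue.f)) * 0 + (
            geom.A_h * (np.sin(np.pi * x / tissue.R_m - np.pi / 2) + 1) * env
            + geom.h0
        )
        c_eq = (h[0] / h) ** 2
        c0 = c_eq * (1.0 + 0.5 * np.sin(2 * np.pi * x / (grid.L_factor * tissue.R_m)))
        f = solve_transport(tissue, sp, grid, c_init=c0, freeze_envelope=env)
        mu = f.mu()
        T = tissue.T
        F = np.sum(f.c * (mu - R_GAS * T), axis=0) * f.dx
        sig = sigma_chemical(f, sp, T)
        per_step = np.sum(sig, axis=0) * f.dx * T
        dt = f.t[1] - f.t[0]
        m = 32  # skip the unresolved initial layer
        heat = dt * np.sum(per_step[m + 1 :])
        drop = F[m] - F[-1]
        assert heat == pytest.approx(drop, rel=1e-2)


class TestTotalEntropy:
    def test_null_forcing_dissipates_nothing(self, tissue, coarse_grid):
        tp = replace(tissue, dP=0.0)
        sp = SpeciesParams(c_star=0.0, D_a=0.0, k=0.0)
        rec = total_entropy(tp, sp, coarse_grid, n_periods=4)
        assert rec.Sigma == 0.0 and rec.E_d == 0.0

    def test_components_sum_linearly(self, tissue, species, coarse_grid):
        rec = total_entropy(tissue, species, coarse_grid, n_periods=4)
        assert rec.Sigma == pytest.approx(rec.Sigma_ch + rec.Sigma_m, rel=1e-12)
        assert rec.E_d == pytest.approx(tissue.T * rec.Sigma, rel=1e-12)

    def test_second_law_across_parameter_box(self, coarse_grid, rng):
        """Sigma >= 0 for random configurations in the default box."""
        for _ in range(8):
            Y = float(rng.uniform(2e3, 150e3))
            tp = TissueParams(phi=float(porosity_from_young(Y, 0.0322, 3e-4)), Y=Y)
            sp = SpeciesParams(
                D_a=float(rng.uniform(0, 3e-7)),
                k=float(rng.uniform(0, 0.2)),
            )
            rec = total_entropy(tp, sp, coarse_grid, n_periods=4)
            assert rec.Sigma >= 0.0

    def test_mechanical_part_grows_linearly_with_protocol(self, tissue, species,
                                                          coarse_grid):
        recs = [total_entropy(tissue, species, coarse_grid, n_periods=n)
                for n in (3, 6)]
        assert recs[1].Sigma_m == pytest.approx(2.0 * recs[0].Sigma_m, rel=1e-6)

    def test_cancer_dissipates_more_than_healthy(self, coarse_grid):
        """E_d at the carcinogenic anchor exceeds the healthy anchor."""
        sp = SpeciesParams()
        healthy = TissueParams(phi=0.0129, Y=5.0e3)
        cancer = TissueParams(phi=0.0022, Y=45.5e3)
        grid = SolverGrid(nx=96, steps_per_period=48, n_periods_max=10, tol_sigma=1.0)
        E = [total_entropy(tp, sp, grid, n_periods=10).E_d for tp in (healthy, cancer)]
        assert E[1] > E[0]


class TestPorosityFromYoung:
    def test_intercept_and_monotonicity(self):
        assert porosity_from_young(0.0, 0.0322, 3e-4) == pytest.approx(0.0322)
        Y = np.linspace(0, 2e5, 50)
        phi = porosity_from_young(Y, 0.0322, 3e-4)
        assert np.all(np.diff(phi) < 0)

    def test_carcinogenic_anchor_on_shipped_trend(self):
        assert porosity_from_young(45.5e3, 0.0322, 3e-4) == pytest.approx(
            0.0022, rel=5e-3
        )

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            porosity_from_young(0.0, 1.5, 3e-4)


class TestEnergyLandscape:
    def test_injected_quadratic_maximum(self):
        Y = np.linspace(1e3, 1e5, 101)
        Y0 = 4.2e4
        E = -((Y - Y0) ** 2)
        land = EnergyLandscape.from_values(Y, E)
        assert land.Y_star == pytest.approx(Y0, rel=1e-6)
        assert not land.boundary_extremum

    def test_injected_quadratic_minimum_preferred(self):
        Y = np.linspace(1e3, 1e5, 101)
        Y0 = 3.0e4
        E = (Y - Y0) ** 2
        land = EnergyLandscape.from_values(Y, E)
        assert land.Y_star == pytest.approx(Y0, rel=1e-6)

    def test_monotone_landscape_flags_boundary(self):
        """Monotone dissipation: Y* falls back to the efficiency optimum."""
        Y = np.linspace(1e3, 1e5, 51)
        land = EnergyLandscape.from_values(Y, np.sqrt(Y))
        assert land.boundary_extremum
        assert land.Y_star == Y[0]

    def test_extremum_stable_under_grid_doubling(self):
        rng = np.random.default_rng(7)
        Y1 = np.linspace(1e3, 1e5, 100)
        Y2 = np.linspace(1e3, 1e5, 200)
        f = lambda Y: np.exp(-((Y - 3.7e4) / 2.5e4) ** 2) + 0.02 * np.sqrt(Y / 1e5)
        l1 = EnergyLandscape.from_values(Y1, f(Y1))
        l2 = EnergyLandscape.from_values(Y2, f(Y2))
        assert abs(l1.Y_star - l2.Y_star) < (Y1[1] - Y1[0])

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="5 grid points"):
            EnergyLandscape.from_values(np.array([1e3, 2e3, 3e3]), np.ones(3))
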