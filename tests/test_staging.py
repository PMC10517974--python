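"""Probability current, stage segmentation, transition probabilities."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tissuestage.free_energy import configuration_probability
from tissuestage.staging import (
    STAGE_LABELS,
    average_current,
    conditional_probabilities,
    probability_current,
    segment_stages,
    stage_transitions,
    transition_probability,
)
from tissuestage.transport import R_GAS

T = 310.0


class TestProbabilityCurrent:
    def test_boltzmann_density_carries_no_relaxational_current(self):
        """Detailed balance: rho ~ exp(-dG/RT) gives J = 0 (printed form)."""
        Y = np.linspace(2e3, 1.5e5, 400)
        dG = 2.0e3 * np.sin(2 * np.pi * Y / 1.0e5) + 1.0e-2 * Y
        rho = configuration_probability(dG, Y, T)
        J, _ = probability_current(rho, dG, Y, T=T, drift="relaxational")
        scale = np.max(np.abs(rho)) / (Y[-1] - Y[0])
        # one-sided end stencils carry O(h) error; the interior is O(h^2)
        assert np.max(np.abs(J[2:-2])) < 1e-3 * scale

    def test_uniform_density_flat_landscape(self):
        Y = np.linspace(0.0, 1.0, 101)
        rho = np.ones_like(Y)
        dG = np.zeros_like(Y)
        for drift in ("relaxational", "driven"):
            J, dJ = probability_current(rho, dG, Y, T=T, drift=drift)
            # nonuniform-stencil float residue only
            assert np.allclose(J, 0.0, atol=1e-10)
            assert np.allclose(dJ, 0.0, atol=1e-8)

    def test_driven_current_matches_closed_form(self):
        """For Boltzmann rho the driven current is 2 D beta rho dG'."""
        Y = np.linspace(2e3, 1.5e5, 2000)
        dG = 1.5e3 * (Y / 1.0e5) ** 2
        rho = configuration_probability(dG, Y, T)
        J, _ = probability_current(rho, dG, Y, D_Y=1.0, T=T, drift="driven")
        beta = 1.0 / (R_GAS * T)
        analytic = 2.0 * beta * rho * np.gradient(dG, Y)
        sel = slice(5, -5)
        assert J[sel] == pytest.approx(analytic[sel], rel=1e-4)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            probability_current(np.ones(5), np.ones(6), np.linspace(0, 1, 5))


class TestSegmentStages:
    def test_sinusoidal_current_boundaries_at_derivative_extrema(self):
        """J = sin(Y) on [0, 4 pi]: dJ/dY = cos has extrema at multiples of pi."""
        Y = np.linspace(0.0, 4 * np.pi, 2001)
        J = np.sin(Y)
        dJ = np.gradient(J, Y)
        model = segment_stages(J, dJ, Y, prominence_rel=0.05)
        expected = np.pi * np.arange(1, 4)
        assert len(model.boundaries) == 3
        assert model.boundaries == pytest.approx(expected, abs=2e-2)

    def test_merged_labels_keep_advanced_stages_reachable(self):
        Y = np.linspace(0.0, 2 * np.pi, 800)
        J = np.sin(Y)
        model = segment_stages(J, np.gradient(J, Y), Y, prominence_rel=0.05)
        assert model.merged
        assert model.labels[0] == "H"
        # every canonical label is carried by some interval
        for lab in STAGE_LABELS:
            assert model.stage_index(lab) >= 0

    def test_flat_current_single_stage(self):
        Y = np.linspace(0.0, 1.0, 100)
        model = segment_stages(np.zeros_like(Y), np.zeros_like(Y), Y)
        assert model.single_stage and len(model.labels) == 1


class TestAverageCurrent:
    def test_zero_and_constant_current(self):
        Y = np.linspace(0.0, 10.0, 101)
        assert average_current(np.zeros_like(Y), Y, 2.0, 7.0) == 0.0
        avg = average_current(np.full_like(Y, 3.0), Y, 2.0, 7.0)
        assert avg == pytest.approx(3.0 * 5.0)
        assert average_current(np.full_like(Y, 3.0), Y, 2.0, 7.0,
                               normalise=True) == pytest.approx(3.0)

    def test_linear_current_trapezoid_exact(self):
        Y = np.linspace(0.0, 10.0, 101)
        J = 2.0 * Y + 1.0
        # analytic integral of 2y+1 over [1, 9]: y^2+y | = 90-2 = 88
        assert average_current(J, Y, 1.0, 9.0) == pytest.approx(88.0, rel=1e-12)

    def test_empty_interval_rejected(self):
        Y = np.linspace(0.0, 1.0, 10)
        with pytest.raises(ValueError, match="empty"):
            average_current(np.ones_like(Y), Y, 0.5, 0.5)


class TestTransitionProbability:
    def test_half_at_zero_average_current(self):
        assert transition_probability(0.0, 12.3) == 0.5

    def test_tanh_limits(self):
        assert transition_probability(1e6, 1.0) == pytest.approx(1.0)
        assert transition_probability(-1e6, 1.0) == pytest.approx(0.0)

    def test_closed_form_three_quarters(self):
        """k <J> = (1/2) ln 3 lands exactly on W = 3/4."""
        assert transition_probability(0.5 * np.log(3.0), 1.0) == pytest.approx(0.75)

    @settings(deadline=None, max_examples=50)
    @given(st.floats(-2.0, 2.0), st.floats(-2.0, 2.0), st.floats(0.1, 3.0))
    def test_strictly_increasing_in_average_current(self, a, b, k):
        if abs(a - b) < 1e-9:
            return
        lo, hi = sorted((a, b))
        assert transition_probability(lo, k) < transition_probability(hi, k)

    def test_nonpositive_gain_rejected(self):
        with pytest.raises(ValueError):
            transition_probability(1.0, 0.0)


class TestConditionalProbabilities:
    def test_all_certain_transitions(self):
        P = conditional_probabilities(np.array([1.0, 1.0, 1.0]))
        assert P[0] == 0.0 and np.all(P[1:] == 1.0)

    def test_product_chain(self):
        P = conditional_probabilities(np.array([0.9, 0.8, 0.7]))
        assert P == pytest.approx([0.1, 0.9, 0.72, 0.504])

    def test_telescoping_identity(self):
        W = np.array([0.3, 0.95, 0.85, 0.6, 0.9])
        P = conditional_probabilities(W)
        for i in range(1, len(W)):
            assert P[i + 1] / P[i] == pytest.approx(W[i])

    def test_monotone_decay_beyond_first(self):
        W = np.array([0.4, 0.9, 0.99, 0.5])
        P = conditional_probabilities(W)
        assert np.all(np.diff(P[1:]) <= 0.0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            conditional_probabilities(np.array([]))
        with pytest.raises(ValueError):
            conditional_probabilities(np.array([1.2]))


class TestEquilibriumSanity:
    def test_boltzmann_density_gives_half_transitions(self):
        """Equilibrium density: with gains that saturate the driven current,
        the relaxational (detailed-balance) current still gives W ~ 0.5."""
        from dataclasses import replace as dc_replace

        Y = np.linspace(2e3, 1.5e5, 2000)
        dG = 1.0e3 * np.sin(2 * np.pi * Y / 7.0e4) + 2.0e-2 * Y
        rho = configuration_probability(dG, Y, T)
        Jd, dJd = probability_current(rho, dG, Y, T=T, drift="driven")
        model = segment_stages(Jd, dJd, Y, rho=rho, prominence_rel=0.02)
        if len(model.labels) < 2:
            pytest.skip("no boundaries detected")
        driven = stage_transitions(model, c_k=1.0)
        c_k = 3.0 / np.min(np.abs(driven.k_i * driven.avg_J))
        assert np.all(np.abs(stage_transitions(model, c_k=c_k).W - 0.5) > 0.3)
        # same physical gains, equilibrium current: every W collapses to 1/2
        Jr, _ = probability_current(rho, dG, Y, T=T, drift="relaxational")
        edges = model.stage_edges()
        for i, k_i in enumerate(driven.k_i):
            avg = average_current(Jr, Y, edges[i], edges[i + 2])
            W = transition_probability(avg, c_k * k_i)
            assert W == pytest.approx(0.5, abs=0.05)
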