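"""Tests for the coupled map lattice: diffusive and threshold coupling."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glycodyn import (
    CircleMapParams,
    LatticeConfig,
    LatticeState,
    classify_lattice,
    diffusive_step,
    phase_diagram,
    run_lattice,
    step,
    threshold_step,
)
from glycodyn.lattice import _transfer


def diffusive_config(size=3, kappa=1.0, epsilon=0.5, **kw):
    return LatticeConfig(size=size, kappa=kappa, coupling_mode="diffusive",
                         epsilon=epsilon, **kw)


def threshold_config(size=3, kappa=0.0, x_star=0.5, variant="conservative", **kw):
    return LatticeConfig(size=size, kappa=kappa, coupling_mode="threshold",
                         x_star=x_star, transfer_variant=variant, **kw)


class TestConfig:
    def test_diffusive_requires_epsilon(self):
        with pytest.raises(ValueError):
            LatticeConfig(size=4, kappa=1.0, coupling_mode="diffusive")

    def test_threshold_requires_x_star(self):
        with pytest.raises(ValueError):
            LatticeConfig(size=4, kappa=1.0, coupling_mode="threshold")

    @pytest.mark.parametrize("eps", [-0.1, 1.5])
    def test_epsilon_range(self, eps):
        with pytest.raises(ValueError):
            diffusive_config(epsilon=eps)


class TestDiffusiveStep:
    def test_zero_coupling_is_elementwise_map(self):
        x = np.array([0.1, 0.37, 0.82, 0.55])
        cfg = diffusive_config(size=4, kappa=2.3, epsilon=0.0)
        out = diffusive_step(LatticeState(x=x), cfg)
        expected = step(x, CircleMapParams(kappa=2.3))
        np.testing.assert_array_equal(out.x, expected)

    def test_homogeneous_zero_state_is_fixed(self):
        cfg = diffusive_config(size=5, kappa=3.0, epsilon=0.7)
        out = diffusive_step(LatticeState(x=np.zeros(5)), cfg)
        assert np.all(out.x == 0.0)

    def test_hand_computed_three_site_ring(self):
        cfg = diffusive_config(size=3, kappa=1.0, epsilon=0.5)
        out = diffusive_step(LatticeState(x=np.array([0.2, 0.4, 0.6])), cfg)
        f = [v + math.sin(2 * math.pi * v) / (2 * math.pi) for v in (0.2, 0.4, 0.6)]
        hand = [0.5 * f[i] + 0.25 * (f[(i + 1) % 3] + f[(i - 1) % 3]) for i in range(3)]
        np.testing.assert_allclose(out.x, hand, rtol=1e-15)

    def test_rotation_equivariance(self):
        """Rotating the state by one site commutes with the update (ring)."""
        rng = np.random.default_rng(7)
        x = rng.uniform(0, 1, size=8)
        cfg = diffusive_config(size=8, kappa=2.0, epsilon=0.3)
        a = diffusive_step(LatticeState(x=np.roll(x, 1)), cfg).x
        b = np.roll(diffusive_step(LatticeState(x=x), cfg).x, 1)
        np.testing.assert_allclose(a, b, rtol=1e-15)


class TestThresholdStep:
    def test_zeros_below_threshold_stay(self):
        out = threshold_step(LatticeState(x=np.zeros(3)), threshold_config(kappa=1.7))
        assert np.all(out.x == 0.0)

    def test_conservative_hand_example(self):
        out = threshold_step(LatticeState(x=np.array([0.6, 0.1, 0.1])),
                             threshold_config())
        np.testing.assert_allclose(out.x, [0.5, 0.2, 0.1], atol=1e-15)

    def test_literal_hand_example(self):
        out = threshold_step(LatticeState(x=np.array([0.6, 0.1, 0.1])),
                             threshold_config(variant="literal"))
        np.testing.assert_allclose(out.x, [0.6, 0.2, 0.1], atol=1e-15)

    @given(st.integers(min_value=0, max_value=1000))
    @settings(deadline=None, max_examples=25)
    def test_conservative_transfer_conserves_sum(self, seed):
        """The transfer phase leaves the lattice sum exactly unchanged."""
        rng = np.random.default_rng(seed)
        x = rng.uniform(0, 2, size=16)
        cfg = threshold_config(size=16, x_star=0.5)
        out = _transfer(x.copy(), cfg)
        assert out.sum() == pytest.approx(x.sum(), rel=1e-14)

    @given(st.integers(min_value=0, max_value=1000))
    @settings(deadline=None, max_examples=25)
    def test_literal_transfer_nondecreasing_sum(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.uniform(0, 2, size=16)
        cfg = threshold_config(size=16, x_star=0.5, variant="literal")
        assert _transfer(x.copy(), cfg).sum() >= x.sum()

    def test_open_boundary_discards_last_site_excess(self):
        cfg = threshold_config(size=3, variant="literal", boundary="open")
        out = threshold_step(LatticeState(x=np.array([0.1, 0.1, 0.9])), cfg)
        np.testing.assert_allclose(out.x, [0.1, 0.1, 0.9], atol=1e-15)

    def test_rotation_equivariance(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 1, size=8)
        cfg = threshold_config(size=8, kappa=1.2, x_star=0.4, variant="literal")
        a = threshold_step(LatticeState(x=np.roll(x, 1)), cfg).x
        b = np.roll(threshold_step(LatticeState(x=x), cfg).x, 1)
        np.testing.assert_allclose(a, b, rtol=1e-15)


class TestRunLattice:
    def test_blowup_case_diverges(self):
        """Literal transfers at x*=0.15, kappa=1.0 compound until blow-up."""
        cfg = threshold_config(size=64, kappa=1.0, x_star=0.15, variant="literal",
                               seed=0)
        run = run_lattice(cfg)
        assert run.divergent

    def test_frozen_when_map_off_and_threshold_high(self):
        cfg = threshold_config(size=8, kappa=0.0, x_star=2.0, seed=1)
        run = run_lattice(cfg, n_iter=50, transient=0)
        np.testing.assert_array_equal(run.states, np.tile(run.states[0], (51, 1)))

    def test_seed_fixes_trajectory_bitwise(self):
        cfg = threshold_config(size=16, kappa=2.6, x_star=0.5, seed=42)
        a = run_lattice(cfg, n_iter=500, transient=0)
        b = run_lattice(cfg, n_iter=500, transient=0)
        np.testing.assert_array_equal(a.states, b.states)

    def test_explicit_init_used(self):
        cfg = threshold_config(size=4, kappa=0.0, x_star=2.0)
        run = run_lattice(cfg, n_iter=10, transient=0, init=[0.1, 0.2, 0.3, 0.4])
        np.testing.assert_array_equal(run.states[0], [0.1, 0.2, 0.3, 0.4])


class TestClassifyLattice:
    def test_constant_series_is_fixed_point(self):
        cfg = threshold_config(size=4, kappa=0.0, x_star=2.0, seed=0)
        run = run_lattice(cfg, n_iter=300, transient=100)
        label = classify_lattice(run)
        assert label.kind == "fixed_point" and label.period == 1

    def test_homogeneous_conservative_cell_reduces_to_single_map_cycle(self):
        """With identical sites on a ring, conservative transfers cancel and
        the cell at threshold 0.5 shows the single-map 2-cycle."""
        cfg = threshold_config(size=64, kappa=2.6, x_star=0.5)
        run = run_lattice(cfg, init=np.full(64, 0.3))
        label = classify_lattice(run)
        assert label.kind == "cycle" and label.period == 2

    def test_divergent_flag_propagates(self):
        cfg = threshold_config(size=64, kappa=1.0, x_star=0.15, variant="literal",
                               seed=0)
        assert classify_lattice(run_lattice(cfg)).kind == "divergent"

    def test_insufficient_samples_rejected(self):
        cfg = threshold_config(size=4, kappa=0.0, x_star=2.0)
        run = run_lattice(cfg, n_iter=100, transient=50)
        with pytest.raises(ValueError):
            classify_lattice(run, max_period=64)


class TestPhaseDiagram:
    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            phase_diagram([], [1.0])

    def test_key_cells(self):
        """Blow-up at (0.15, 1.0); uncoupled stable maps give a fixed point."""
        pd_ = phase_diagram([0.15, 10.0], [1.0], n_iter=2000, transient=1800)
        assert pd_.kinds[0, 0] == "divergent"
        assert pd_.kinds[1, 0] == "fixed_point"

    def test_matches_run_lattice_classification(self):
        """The batch engine and the single-run path agree cell by cell."""
        xs, ks = [0.5, 10.0], [1.0, 2.6]
        pd_ = phase_diagram(xs, ks, n_iter=3000, transient=2800)
        for i, x_star in enumerate(xs):
            for j, kappa in enumerate(ks):
                cfg = threshold_config(size=64, kappa=kappa, x_star=x_star,
                                       variant="literal", seed=0)
                run = run_lattice(cfg, n_iter=3000, transient=2872)
                label = classify_lattice(run)
                assert pd_.kinds[i, j] == label.kind, (x_star, kappa)

    def test_long_format_export(self):
        pd_ = phase_diagram([0.5], [1.0], n_iter=500, transient=300)
        df = pd_.to_frame()
        assert list(df.columns) == ["x_star", "kappa", "label", "period"]
        assert len(df) == 1
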