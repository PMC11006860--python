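"""Solver tests: stencil, time steppers, boundary detection, subgrid, evolve."""

import numpy as np
import pytest

from phaseseg.fields import GridSpec, ImageField, PhaseField
from phaseseg.phantoms import PhantomSpec, generate_phantom
from phaseseg.potentials import PotentialSpec, bicubic_deriv, fitting_force
from phaseseg.region_stats import RegionMeans, compute_region_means, discrete_energy
from phaseseg.solver import (
    SolverParams,
    StabilityWarning,
    detect_boundary_cells,
    epsilon_m,
    evolve,
    laplacian,
    step_forward_euler,
    step_leapfrog,
    subgrid_refined_force,
)
from phaseseg.solver import _leapfrog_residual


def laplacian_oracle(v, h):
    """Ghost-cell double loop with explicit mirroring."""
    ny, nx = v.shape
    out = np.empty_like(v)

    def at(i, j):
        return v[min(max(i, 0), ny - 1), min(max(j, 0), nx - 1)]

    for i in range(ny):
        for j in range(nx):
            out[i, j] = (at(i, j + 1) + at(i, j - 1) + at(i + 1, j) + at(i - 1, j) - 4 * v[i, j]) / h**2
    return out


def catmull_rom_1d(p, s):
    """Through-point cubic through p[-1], p[0], p[1], p[2] at parameter s."""
    return 0.5 * (
        (2 * p[1])
        + (-p[0] + p[2]) * s
        + (2 * p[0] - 5 * p[1] + 4 * p[2] - p[3]) * s**2
        + (-p[0] + 3 * p[1] - 3 * p[2] + p[3]) * s**3
    )


class TestEpsilonM:
    def test_reference_values(self):
        assert epsilon_m(2, 1 / 256, 0.9) == pytest.approx(9.385e-4, rel=1e-3)
        assert epsilon_m(1, 1.0, 0.9) == pytest.approx(0.12013, rel=1e-3)

    def test_linear_in_m_and_h(self):
        assert epsilon_m(2, 0.01, 0.9) == pytest.approx(2 * epsilon_m(1, 0.01, 0.9), rel=1e-14)
        assert epsilon_m(1, 0.02, 0.9) == pytest.approx(2 * epsilon_m(1, 0.01, 0.9), rel=1e-14)

    def test_decreasing_in_rho(self):
        assert epsilon_m(1, 1.0, 0.9) < epsilon_m(1, 1.0, 0.45)

    @pytest.mark.parametrize("rho", [0.0, 1.0, -0.1, 1.5])
    def test_rho_domain(self, rho):
        with pytest.raises(ValueError):
            epsilon_m(1, 1.0, rho)


class TestLaplacian:
    def test_constant_field_is_zero(self, grid8):
        np.testing.assert_array_equal(laplacian(np.full(grid8.shape, 3.7), grid8.h), 0.0)

    def test_linear_field_zero_in_interior(self, grid8):
        x, _ = grid8.cell_centers()
        lap = laplacian(x, grid8.h)
        np.testing.assert_allclose(lap[1:-1, 1:-1], 0.0, atol=1e-9)

    def test_matches_ghost_cell_oracle(self, rng, grid8):
        v = rng.normal(size=grid8.shape)
        np.testing.assert_allclose(laplacian(v, grid8.h), laplacian_oracle(v, grid8.h), atol=1e-9)

    def test_conserves_mean(self, rng):
        grid = GridSpec.from_shape((32, 32))
        v = rng.normal(size=grid.shape)
        total = laplacian(v, grid.h).sum()
        assert abs(total) < 1e-10 * v.size / grid.h**2


class TestForwardEuler:
    def test_well_bottom_is_stationary(self, grid8):
        img = ImageField(np.full(grid8.shape, 0.5), grid8)
        phi = PhaseField(np.ones(grid8.shape), 1, grid8)
        means = RegionMeans(np.array([0.5]), np.array([1.0]))
        p = SolverParams(k_phases=1, lam=0.0, dt=1e-4, potential=PotentialSpec(mode="double_well")).resolve(grid8.h)
        out = step_forward_euler(phi, img, means, p)
        np.testing.assert_array_equal(out.values, phi.values)
        assert out.time_index == 1

    def test_matches_hand_computed_rhs(self):
        # single interior cell displaced on a flat field: scalar arithmetic oracle
        grid = GridSpec.from_shape((5, 5))
        phi_vals = np.zeros(grid.shape)
        phi_vals[2, 2] = 0.3
        img = ImageField(np.full(grid.shape, 0.1), grid)
        phi = PhaseField(phi_vals, 2, grid)
        means = RegionMeans(np.array([0.1, 0.9]), np.array([1.0, 1.0]))
        eps, lam, dt = 0.2, 2.0, 1e-5
        p = SolverParams(k_phases=2, epsilon=eps, lam=lam, dt=dt).resolve(grid.h)
        out = step_forward_euler(phi, img, means, p)
        deriv = 0.3**3 - 1.5 * 0.3**2 + 0.5 * 0.3
        lap = (0 + 0 + 0 + 0 - 4 * 0.3) / grid.h**2
        fit = fitting_force(0.3, np.array([0.1, 0.9]), 0.1, lam)
        expected = 0.3 + dt * (-deriv / eps**2 + lap - fit)
        assert out.values[2, 2] == pytest.approx(expected, rel=1e-12)
        # the four neighbors only feel the Laplacian of the bump
        assert out.values[2, 3] == pytest.approx(dt * 0.3 / grid.h**2, rel=1e-12)

    def test_small_dt_step_scales_linearly(self, rng, grid8):
        img = ImageField(rng.uniform(0, 1, grid8.shape), grid8)
        phi = PhaseField(rng.uniform(0, 2, grid8.shape), 2, grid8)
        means = compute_region_means(phi, img)
        p1 = SolverParams(k_phases=2, epsilon=0.1, lam=1.0, dt=1e-8).resolve(grid8.h)
        p2 = SolverParams(k_phases=2, epsilon=0.1, lam=1.0, dt=2e-8).resolve(grid8.h)
        d1 = step_forward_euler(phi, img, means, p1).values - phi.values
        d2 = step_forward_euler(phi, img, means, p2).values - phi.values
        np.testing.assert_allclose(d2, 2 * d1, rtol=1e-9)


class TestLeapfrog:
    def test_stationary_well_bottom(self, grid8):
        img = ImageField(np.full(grid8.shape, 0.5), grid8)
        phi = PhaseField(np.full(grid8.shape, 2.0), 1, grid8)
        means = RegionMeans(np.array([0.5]), np.array([1.0]))
        p = SolverParams(k_phases=1, epsilon=0.1, lam=0.0, dt=1e-5).resolve(grid8.h)
        out = step_leapfrog(phi, phi, img, means, p)
        np.testing.assert_allclose(out.values, phi.values, atol=1e-14)

    def test_converged_iterate_satisfies_printed_relation(self, rng):
        grid = GridSpec.from_shape((4, 4))
        img = ImageField(rng.uniform(0, 1, grid.shape), grid)
        prev = PhaseField(rng.uniform(0, 2, grid.shape), 2, grid)
        p = SolverParams(k_phases=2, epsilon=0.1, lam=5.0, dt=1e-5).resolve(grid.h)
        means = compute_region_means(prev, img)
        curr = step_forward_euler(prev, img, means, p)
        new = step_leapfrog(prev, curr, img, means, p)
        res = _leapfrog_residual(prev.values, curr.values, new.values, img, means, p)
        # per-cell residual: picard_tol plus the round-off floor eps·|phi|/(2 dt)
        floor = 8 * np.finfo(float).eps * max(1.0, np.max(np.abs(new.values))) / (2 * p.dt)
        assert np.max(np.abs(res)) < 1e-10 + floor

    def test_divergent_picard_raises(self, grid8, rng):
        # dt / eps^2 far beyond the contraction bound
        img = ImageField(rng.uniform(0, 1, grid8.shape), grid8)
        phi = PhaseField(rng.uniform(0, 2, grid8.shape), 2, grid8)
        means = compute_region_means(phi, img)
        p = SolverParams(k_phases=2, epsilon=1e-4, lam=0.0, dt=1e-3).resolve(grid8.h)
        with pytest.raises(RuntimeError, match="did not converge"):
            step_leapfrog(phi, phi, img, means, p)

    def test_agrees_with_euler_to_second_order(self, rng):
        # after the Euler bootstrap, one leapfrog step differs from a second
        # Euler step by O(dt^2): halving dt shrinks the gap ~4x per octave
        grid = GridSpec.from_shape((16, 16))
        img = ImageField(rng.uniform(0, 1, grid.shape), grid)
        phi0 = PhaseField(rng.uniform(0, 2, grid.shape), 2, grid)
        diffs = []
        for dt in [1e-4 / 2**j for j in range(4)]:
            p = SolverParams(k_phases=2, epsilon=0.1, lam=10.0, dt=dt).resolve(grid.h)
            means = compute_region_means(phi0, img)
            e1 = step_forward_euler(phi0, img, means, p)
            e2 = step_forward_euler(e1, img, means, p)
            lf = step_leapfrog(phi0, e1, img, means, p)
            diffs.append(np.linalg.norm(e2.values - lf.values))
        ratios = [diffs[i] / diffs[i + 1] for i in range(3)]
        assert all(3.0 <= r <= 5.0 for r in ratios)


class TestBoundaryDetection:
    def test_uniform_band_has_no_boundary(self, grid8):
        phi = PhaseField(np.full(grid8.shape, 0.2), 2, grid8)
        assert not detect_boundary_cells(phi).any()

    def test_vertical_step_flags_both_adjacent_columns(self, grid8):
        vals = np.zeros(grid8.shape)
        vals[:, 4:] = 1.0
        mask = detect_boundary_cells(PhaseField(vals, 2, grid8))
        expected = np.zeros(grid8.shape, dtype=bool)
        expected[:, 3:5] = True
        np.testing.assert_array_equal(mask, expected)

    def test_checkerboard_flags_everything(self, grid8):
        y, x = np.mgrid[0:8, 0:8]
        vals = ((x + y) % 2).astype(float)
        assert detect_boundary_cells(PhaseField(vals, 2, grid8)).all()

    def test_matches_neighbor_scan_oracle(self, rng, grid8):
        vals = rng.uniform(0, 2, grid8.shape)
        phi = PhaseField(vals, 2, grid8)
        mask = detect_boundary_cells(phi)
        oracle = np.zeros(grid8.shape, dtype=bool)
        for i in range(8):
            for j in range(8):
                for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    ii, jj = i + di, j + dj
                    if 0 <= ii < 8 and 0 <= jj < 8:
                        for level in (0.5, 1.5):
                            if (vals[i, j] - level) * (vals[ii, jj] - level) < 0:
                                oracle[i, j] = True
        np.testing.assert_array_equal(mask, oracle)


class TestSubgrid:
    def params(self, grid, **kw):
        base = dict(k_phases=2, epsilon=0.1, lam=0.0, subgrid_enabled=True, m=2)
        base.update(kw)
        return SolverParams(**base).resolve(grid.h)

    def test_all_false_mask_is_bit_identical_to_pointwise(self, rng, grid8):
        phi = PhaseField(rng.uniform(0, 2, grid8.shape), 2, grid8)
        p = self.params(grid8)
        out = subgrid_refined_force(phi, np.zeros(grid8.shape, dtype=bool), p)
        np.testing.assert_array_equal(out, bicubic_deriv(phi.values, p.potential))

    def test_constant_field_refines_exactly(self, grid8):
        phi = PhaseField(np.full(grid8.shape, 0.3), 2, grid8)
        p = self.params(grid8)
        out = subgrid_refined_force(phi, np.ones(grid8.shape, dtype=bool), p)
        np.testing.assert_allclose(out, bicubic_deriv(0.3), atol=1e-14)

    def test_linear_field_interpolant_averages_to_center(self, grid8):
        # the through-point bicubic reproduces linear fields; the symmetric
        # subcell offsets then average back to the cell-center value
        from phaseseg.solver import subgrid_interpolate

        x, y = grid8.cell_centers()
        phi = PhaseField(2.0 * x + 0.5 * y, 2, grid8)
        samples = subgrid_interpolate(phi, m=2)
        mean = sum(samples) / len(samples)
        np.testing.assert_allclose(mean[2:-2, 2:-2], phi.values[2:-2, 2:-2], atol=1e-8)

    def test_matches_brute_force_interpolation_oracle(self, rng, grid8):
        phi_vals = rng.uniform(0, 2, grid8.shape)
        phi = PhaseField(phi_vals, 2, grid8)
        p = self.params(grid8, m=2)
        mask = np.ones(grid8.shape, dtype=bool)
        got = subgrid_refined_force(phi, mask, p)

        padded = np.pad(phi_vals, 2, mode="symmetric")
        offsets = [-0.25, 0.25]
        want = np.zeros(grid8.shape)
        for i in range(8):
            for j in range(8):
                acc = 0.0
                for ty in offsets:
                    for tx in offsets:
                        iy, ix = int(np.floor(ty)), int(np.floor(tx))
                        sy, sx = ty - iy, tx - ix
                        rows = [
                            catmull_rom_1d(
                                padded[2 + i + iy + a - 1, 2 + j + ix - 1 : 2 + j + ix + 3], sx
                            )
                            for a in range(4)
                        ]
                        val = catmull_rom_1d(np.array(rows), sy)
                        acc += bicubic_deriv(float(val))
                want[i, j] = acc / 4.0
        np.testing.assert_allclose(got, want, atol=1e-10)

    def test_m_below_two_rejected(self):
        with pytest.raises(ValueError):
            SolverParams(k_phases=2, subgrid_enabled=True, m=1)


class TestEvolve:
    def test_zero_steps_returns_banded_initialization(self):
        img, truth = generate_phantom(PhantomSpec(shape="stripes", n=32, k_phases=3))
        res = evolve(img, SolverParams(k_phases=3, n_steps=0, dt=1e-7))
        np.testing.assert_allclose(res.phi_final.values, 3 * img.values)
        expected = np.clip(np.floor(3 * img.values + 0.5).astype(int), 0, 2)
        np.testing.assert_array_equal(res.labels, expected)
        assert len(res.energy_trace) == 1

    def test_noiseless_two_phase_recovery_small_grid(self):
        img, truth = generate_phantom(PhantomSpec(shape="disk", n=64, k_phases=2))
        res = evolve(img, SolverParams(k_phases=2, dt=1e-6, n_steps=10))
        assert (res.labels == truth).mean() >= 0.99

    def test_energy_trace_nonincreasing_frozen_means(self, rng):
        grid = GridSpec.from_shape((32, 32))
        img = ImageField(rng.uniform(0, 1, grid.shape), grid)
        p = SolverParams(
            k_phases=2, dt=1e-6, n_steps=20, update_means=False,
            potential=PotentialSpec(mode="double_well"),
        )
        res = evolve(img, p)
        assert np.all(np.diff(res.energy_trace) <= 1e-12)

    def test_stability_warning_above_cfl(self):
        img, _ = generate_phantom(PhantomSpec(shape="stripes", n=32, k_phases=2))
        with pytest.warns(StabilityWarning):
            evolve(img, SolverParams(k_phases=2, dt=1.0, n_steps=1, epsilon=10.0, lam=0.0))

    def test_masks_partition_domain(self):
        img, _ = generate_phantom(PhantomSpec(shape="stripes", n=32, k_phases=4))
        res = evolve(img, SolverParams(k_phases=4, dt=1e-7, n_steps=2))
        stack = np.stack(res.masks)
        assert (stack.sum(axis=0) == 1).all()
        for k in range(4):
            np.testing.assert_array_equal(res.masks[k], res.labels == k)
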