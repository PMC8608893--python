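"""Hybrid cell/ATP simulator: forces, field solver, scenarios."""

import numpy as np
import pytest

from microspacing import (
    ATPField,
    CellState,
    ModelParams,
    NumericsConfig,
    atp_step,
    cell_step,
    gradient_at,
    repulsion_force,
    run,
    wound_scenario,
)

TABLE = ModelParams()  # measured defaults


def static_cells(positions: np.ndarray) -> CellState:
    n = len(positions)
    return CellState(
        np.asarray(positions, float), np.zeros((n, 2)), np.full(n, np.inf)
    )


class TestRepulsionForce:
    def test_piecewise_linear(self):
        assert repulsion_force(45.0, TABLE) == 0.0
        assert repulsion_force(60.0, TABLE) == 0.0
        assert repulsion_force(0.0, TABLE) == pytest.approx(4.5)  # k·σ
        assert repulsion_force(25.0, TABLE) == pytest.approx(2.0)  # 0.1·(45−25)

    def test_vectorised(self):
        r = np.array([0.0, 25.0, 45.0, 100.0])
        assert np.allclose(repulsion_force(r, TABLE), [4.5, 2.0, 0.0, 0.0])


class TestGradientAt:
    def test_uniform_field_zero(self):
        field = ATPField(np.full((40, 40), 3.3), 5.0)
        g = gradient_at(field, np.array([[77.0, 102.0], [10.0, 10.0]]))
        assert np.allclose(g, 0.0)

    def test_linear_field_exact_interior(self):
        """Central differences are exact on a(x, y) = αx away from edges."""
        alpha = 0.02
        nx, dx = 40, 5.0
        x = np.arange(nx) * dx
        field = ATPField(np.tile(alpha * x[:, None], (1, nx)), dx)
        pos = np.array([[100.0, 100.0], [62.5, 87.0]])
        g = gradient_at(field, pos, boundary="no-flux")
        assert np.allclose(g[:, 0], alpha, rtol=1e-9)
        assert np.allclose(g[:, 1], 0.0, atol=1e-12)

    def test_refinement_second_order(self):
        """Halving dx shrinks the gradient error by about 4 (O(dx²))."""
        L = 400.0
        kx, ky = 2 * np.pi / L, 4 * np.pi / L
        pos = np.array([[133.0, 217.0], [55.5, 301.0]])
        exact = np.column_stack(
            [kx * np.cos(kx * pos[:, 0]) * np.sin(ky * pos[:, 1]),
             ky * np.sin(kx * pos[:, 0]) * np.cos(ky * pos[:, 1])]
        )
        errs = []
        for dx in (10.0, 5.0):
            n = int(L / dx)
            xs = np.arange(n) * dx
            a = np.sin(kx * xs[:, None]) * np.sin(ky * xs[None, :])
            g = gradient_at(ATPField(a, dx), pos)
            errs.append(np.max(np.abs(g - exact)))
        assert errs[1] < errs[0] / 3.0

    def test_outside_domain_rejected(self):
        field = ATPField(np.zeros((10, 10)), 5.0)
        with pytest.raises(ValueError, match="outside"):
            gradient_at(field, np.array([60.0, 10.0]), boundary="no-flux")


class TestAtpStep:
    def test_uniform_fixed_point(self):
        """a ≡ p/h is an exact fixed point of the cell-free field update."""
        a0 = TABLE.p_atp / TABLE.h
        field = ATPField(np.full((30, 30), a0), 5.0)
        out = atp_step(field, None, TABLE, dt=0.03)
        assert np.max(np.abs(out.a - a0)) < 1e-10 * a0

    def test_uniform_mode_follows_scalar_ode(self):
        """With b=0 the uniform mode reproduces the scalar Euler recursion
        bit-for-bit and tracks (p/h)(1 − e^{−ht}) with asymptote 8.5e−3 µM."""
        dt, n_steps = 0.03, 1000
        field = ATPField(np.zeros((20, 20)), 5.0)
        scalar = 0.0
        for _ in range(n_steps):
            field = atp_step(field, None, TABLE, dt)
            scalar = scalar + dt * (TABLE.p_atp - TABLE.h * scalar)
        assert np.all(field.a == scalar)
        t = dt * n_steps
        analytic = TABLE.p_atp / TABLE.h * (1.0 - np.exp(-TABLE.h * t))
        assert scalar == pytest.approx(analytic, rel=0.01)
        assert TABLE.p_atp / TABLE.h == pytest.approx(8.5e-3)

    def test_pure_diffusion_matches_heat_kernel(self):
        """A Gaussian bump spreads as σ²(t) = σ₀² + 2 d_a t (2% after 10 min)."""
        params = ModelParams(p_atp=0.0, h=0.0, b=0.0, d_a=180.0)
        L, dx = 800.0, 5.0
        n = int(L / dx)
        xs = np.arange(n) * dx
        xx, yy = np.meshgrid(xs, xs, indexing="ij")
        s0 = 20.0
        r2 = (xx - 400.0) ** 2 + (yy - 400.0) ** 2
        field = ATPField(np.exp(-r2 / (2 * s0**2)), dx)
        dt = 0.9 * dx**2 / (4 * params.d_a)
        t = 0.0
        while t < 10.0 - 1e-9:
            step = min(dt, 10.0 - t)
            field = atp_step(field, None, params, step)
            t += step
        s2 = s0**2 + 2 * params.d_a * 10.0
        analytic = (s0**2 / s2) * np.exp(-r2 / (2 * s2))
        assert np.max(np.abs(field.a - analytic)) < 0.02 * analytic.max()

    def test_point_sink_depletes_containing_node(self):
        field = ATPField(np.full((20, 20), 1.0), 5.0)
        cells = static_cells(np.array([[52.0, 48.0]]))  # node (10, 10)
        params = ModelParams(p_atp=0.0, h=0.0, d_a=0.0, b=0.5)
        out = atp_step(field, cells, params, dt=0.1)
        assert out.a[10, 10] == pytest.approx(1.0 - 0.05)
        assert np.sum(out.a < 1.0) == 1

    def test_clamped_at_zero(self):
        field = ATPField(np.full((10, 10), 1e-5), 5.0)
        cells = static_cells(np.array([[25.0, 25.0]]))
        out = atp_step(field, cells, ModelParams(p_atp=0.0, h=0.0, d_a=0.0, b=10.0), dt=1.0)
        assert out.a.min() == 0.0

    def test_stability_guard(self):
        field = ATPField(np.zeros((10, 10)), 5.0)
        with pytest.raises(ValueError, match="unstable"):
            atp_step(field, None, TABLE, dt=1.0)


class TestCellStep:
    def test_no_motility_no_motion(self):
        params = ModelParams(c=0.0, k=0.0, v=0.0)
        field = ATPField(np.full((40, 40), 1.0), 5.0)
        cells = static_cells(np.array([[10.0, 20.0], [100.0, 150.0]]))
        out = cell_step(cells, field, params, 0.05, np.random.default_rng(0))
        assert np.array_equal(out.positions, cells.positions)

    def test_two_cell_repulsion_matches_closed_form(self):
        """Separation follows d(t) = σ − (σ−d₀)e^{−2kt} within 1%."""
        params = ModelParams(c=0.0, v=0.0, k=0.1, sigma=45.0)
        field = ATPField(np.zeros((80, 80)), 5.0)
        d0 = 20.0
        cells = static_cells(np.array([[200.0 - d0 / 2, 200.0], [200.0 + d0 / 2, 200.0]]))
        dt = 0.01 / params.k
        t = 0.0
        for _ in range(200):
            cells = cell_step(cells, field, params, dt, np.random.default_rng(0), t)
            t += dt
        d_num = np.linalg.norm(cells.positions[1] - cells.positions[0])
        d_exact = params.sigma - (params.sigma - d0) * np.exp(-2 * params.k * t)
        assert d_num == pytest.approx(d_exact, rel=0.01)

    def test_chemotactic_drift_on_linear_field(self):
        """On a(x) = αx a lone cell drifts at c·α along the gradient."""
        alpha = 1e-3
        nx, dx = 80, 5.0
        xs = np.arange(nx) * dx
        field = ATPField(np.tile(alpha * xs[:, None], (1, nx)), dx)
        params = ModelParams(c=18.0, k=0.0, v=0.0)
        cells = static_cells(np.array([[150.0, 200.0]]))
        dt = 0.05
        for i in range(100):
            cells = cell_step(cells, field, params, dt, np.random.default_rng(0),
                              i * dt, boundary="no-flux")
        displacement = cells.positions[0, 0] - 150.0
        assert displacement == pytest.approx(params.c * alpha * 100 * dt, rel=1e-6)
        assert cells.positions[0, 1] == pytest.approx(200.0)


class TestRunScenarios:
    SMALL = dict(domain=(200.0, 200.0), n_cells=20, t_end=60.0, hsi_interval=30.0)

    def test_bit_reproducible(self):
        cfg = NumericsConfig(seed=5, **self.SMALL)
        r1 = run(TABLE, cfg)
        r2 = run(TABLE, cfg)
        assert np.array_equal(r1.final_pattern.points, r2.final_pattern.points)
        assert np.array_equal(r1.hsi_series, r2.hsi_series)
        assert np.array_equal(r1.final_field.a, r2.final_field.a)

    def test_motility_off_preserves_initial_pattern(self):
        params = ModelParams(c=0.0, k=0.0, v=0.0)
        cfg = NumericsConfig(seed=2, **self.SMALL)
        res = run(params, cfg)
        assert np.array_equal(res.snapshots[0][1].positions, res.final_pattern.points)

    def test_field_stays_finite_and_nonnegative(self):
        res = run(TABLE, NumericsConfig(seed=3, **self.SMALL))
        assert np.all(np.isfinite(res.final_field.a))
        assert res.final_field.a.min() >= 0.0

    def test_atp_dip_at_cells_is_small(self):
        """Per-cell uptake depresses the local field by under 5%."""
        params = ModelParams(c=0.0, k=0.0, v=0.0)  # static cells, live field
        cfg = NumericsConfig(seed=4, domain=(400.0, 400.0), n_cells=65,
                             t_end=30.0, hsi_interval=30.0)
        res = run(params, cfg)
        bulk = params.p_atp / params.h
        assert (bulk - res.final_field.a.min()) / bulk < 0.05

    def test_min_distance_floor_grows_with_sigma(self):
        """Pure-repulsion steady spacing increases with the repulsive radius."""
        floors = []
        for sigma in (20.0, 45.0, 70.0):
            params = ModelParams(c=0.0, v=0.0, k=0.1, sigma=sigma, d_a=0.0)
            cfg = NumericsConfig(seed=9, domain=(400.0, 400.0), n_cells=30,
                                 t_end=240.0, hsi_interval=240.0)
            res = run(params, cfg)
            pts = res.final_pattern.points
            diff = pts[:, None] - pts[None, :]
            diff -= 400.0 * np.rint(diff / 400.0)
            d = np.sqrt((diff**2).sum(-1))
            np.fill_diagonal(d, np.inf)
            floors.append(d.min())
        assert floors[0] < floors[1] < floors[2]


class TestWoundScenario:
    def test_cells_accumulate_at_wound(self):
        cfg = NumericsConfig(seed=1, domain=(200.0, 200.0), n_cells=20,
                             t_end=240.0, hsi_interval=60.0, boundary="wound-strip")
        res = wound_scenario(TABLE, cfg)
        frac = res.wound_fraction
        assert frac[-1, 1] > frac[0, 1]

    def test_no_gradient_without_wound_atp(self):
        params = ModelParams(a_w=0.0, c=18.0)
        cfg = NumericsConfig(seed=1, domain=(200.0, 200.0), n_cells=20,
                             t_end=240.0, hsi_interval=60.0, boundary="wound-strip")
        res = wound_scenario(params, cfg)
        # fraction fluctuates around the CSR expectation wound_width/Lx
        expected = cfg.wound_width / cfg.domain[0]
        assert abs(res.wound_fraction[-1, 1] - expected) < 0.35

    def test_cell_free_boundary_layer_length_scale(self):
        """Steady wound profile decays with length √(d_a/h) = 30 µm."""
        params = TABLE
        dx = 5.0
        nx, ny = 60, 20
        bulk = params.p_atp / params.h
        field = ATPField(np.full((nx, ny), bulk), dx)
        dt = 0.9 * dx**2 / (4 * params.d_a)
        for _ in range(int(60.0 / dt)):
            field.a[0, :] = params.a_w
            field = atp_step(field, None, params, dt, boundary="no-flux")
        field.a[0, :] = params.a_w
        profile = field.a[:, ny // 2] - bulk
        x = np.arange(nx) * dx
        sel = (x >= 10) & (x <= 90) & (profile > 0)
        slope = np.polyfit(x[sel], np.log(profile[sel]), 1)[0]
        assert -1.0 / slope == pytest.approx(np.sqrt(params.d_a / params.h), rel=0.1)
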