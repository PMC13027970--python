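"""Stokes solver: projection-step operations, boundary conditions,
conservation, symmetry, linearity, and the staggered-grid cross-check."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from poreflow.analytical import poiseuille_inlet_pressure
from poreflow.geometry import DomainSpec, NodeClass, build_mask, seal_membrane
from poreflow.solver import (
    ConfigurationError,
    FlowField,
    FluidProperties,
    InletSpec,
    SolverConfig,
    _Workspace,
    apply_boundary_conditions,
    momentum_sweep,
    pressure_poisson,
    solve_steady,
    velocity_correction,
)

from _oracle_mac import mac_inlet_pressure, mac_solve


def zero_field(mask) -> FlowField:
    z = np.zeros((mask.ny, mask.nx))
    return FlowField(z.copy(), z.copy(), z.copy())


# ---------------------------------------------------------------------------
# boundary conditions


class TestBoundaryConditions:
    def test_parabolic_inlet_profile(self, tiny_mask, inlet):
        field = apply_boundary_conditions(zero_field(tiny_mask), tiny_mask, inlet)
        spec = tiny_mask.spec
        h = spec.channel_height_lower_um
        # centreline of the lower inlet: 1.5x the mean speed
        j_half = spec.h_lower_steps // 2
        assert field.u[j_half, 0] == pytest.approx(1.5 * inlet.u_mean)
        # no-slip endpoints
        assert field.u[0, 0] == 0.0
        assert field.u[tiny_mask.j_interface_bottom, 0] == 0.0
        # upper inlet mirrored with negative sign
        j_up = tiny_mask.j_interface_top + spec.h_upper_steps // 2
        assert field.u[j_up, -1] == pytest.approx(-1.5 * inlet.u_mean)
        assert np.all(field.v[:, 0] == 0.0)
        # solid nodes are zero
        assert np.all(field.u[tiny_mask.is_solid] == 0.0)

    def test_inlet_profile_carries_mean_flux(self, tiny_mask, inlet):
        spec = tiny_mask.spec
        field = apply_boundary_conditions(zero_field(tiny_mask), tiny_mask, inlet)
        jb = tiny_mask.j_interface_bottom
        # Simpson is exact for the parabolic profile, so this checks the
        # profile itself rather than the quadrature rule
        from scipy.integrate import simpson

        q = simpson(field.u[: jb + 1, 0], dx=spec.dx_m)
        assert q == pytest.approx(inlet.u_mean * spec.channel_height_lower_m, rel=1e-6)

    def test_distorted_profile_rejected(self, tiny_mask):
        class Lopsided(InletSpec):
            def profile(self, y_local, h):
                return np.full_like(np.asarray(y_local, dtype=float), 2.0)

        with pytest.raises(ConfigurationError):
            apply_boundary_conditions(zero_field(tiny_mask), tiny_mask, Lopsided())


# ---------------------------------------------------------------------------
# projection-step operations


class TestMomentumSweep:
    def test_null_state_preserved(self, tiny_mask, props):
        """Zero pressure, zero velocity, zero inlets stay exactly zero."""
        field = zero_field(tiny_mask)
        out, ap = momentum_sweep(field, tiny_mask, props, SolverConfig())
        assert np.all(out.u == 0.0)
        assert np.all(out.v == 0.0)
        assert ap == pytest.approx(4.0 * props.nu / tiny_mask.dx_m**2)

    def test_sweeps_converge_to_discrete_poiseuille(self, props):
        """A duct with constant dp/dx relaxes to the tridiagonal solution.

        The oracle is a direct solve of the 1D viscous balance
        nu * d2u/dy2 = (1/rho) dp/dx with no-slip ends, discretised on the
        same nodes.
        """
        spec = DomainSpec(n_pores=1, dx_um=0.5)
        mask = seal_membrane(build_mask(spec))
        dx = spec.dx_m
        slope = -1.0e7  # Pa/m, towards +x flow
        field = zero_field(mask)
        xs = np.arange(mask.nx) * dx
        field.p[:, :] = slope * (xs - xs[-1])[None, :]

        # oracle: tridiagonal second-difference system on interior rows
        n_int = spec.h_lower_steps - 1
        A = (
            np.diag(np.full(n_int, -2.0))
            + np.diag(np.ones(n_int - 1), 1)
            + np.diag(np.ones(n_int - 1), -1)
        ) / dx**2
        rhs = np.full(n_int, slope / (props.rho * props.nu))
        u_oracle = np.linalg.solve(A, rhs)

        # impose the oracle profile at the inlet so the solution is x-uniform
        jb = mask.j_interface_bottom
        field.u[1:jb, 0] = u_oracle
        cfg = SolverConfig(momentum_solver="sor")
        out = field
        for _ in range(4000):
            out, ap = momentum_sweep(out, mask, props, cfg)
        mid_col = mask.nx // 2
        np.testing.assert_allclose(out.u[1:jb, mid_col], u_oracle, rtol=1e-4)

    def test_ap_uniform_on_square_grid(self, tiny_mask, props):
        _, ap = momentum_sweep(zero_field(tiny_mask), tiny_mask, props, SolverConfig())
        ws = _Workspace(tiny_mask, props, InletSpec(), SolverConfig())
        assert ap == ws.ap  # single scalar: identical at every interior node


class TestPressurePoisson:
    def test_divergence_free_gives_zero_correction(self, tiny_mask):
        dp = pressure_poisson(zero_field(tiny_mask), tiny_mask, ap=1.0e7, cfg=SolverConfig())
        assert np.max(np.abs(dp)) < 1e-12

    def test_matches_dense_oracle(self, tiny_mask, props):
        """The sparse solve equals a dense linear solve of the same stencil."""
        rng = np.random.default_rng(42)
        field = zero_field(tiny_mask)
        field.u = rng.normal(size=field.u.shape) * 0.1
        field.v = rng.normal(size=field.v.shape) * 0.1
        ws = _Workspace(tiny_mask, props, InletSpec(), SolverConfig())
        ap = ws.ap
        dp = pressure_poisson(field, tiny_mask, ap=ap, cfg=SolverConfig())

        div = ws.divergence(field.u, field.v)
        b = -ws.dx**2 * ap * div.ravel()[ws.fluid_flat]
        dense = np.linalg.solve(ws.p_matrix.toarray(), b)
        np.testing.assert_allclose(dp.ravel()[ws.fluid_flat], dense, rtol=1e-9, atol=1e-12)

    def test_outlet_correction_is_pinned_to_zero(self, tiny_mask, props):
        rng = np.random.default_rng(7)
        field = zero_field(tiny_mask)
        field.u = rng.normal(size=field.u.shape) * 0.1
        dp = pressure_poisson(field, tiny_mask, ap=1e7, cfg=SolverConfig())
        outlets = (tiny_mask.node_class == NodeClass.OUTLET_LOWER) | (
            tiny_mask.node_class == NodeClass.OUTLET_UPPER
        )
        assert np.all(dp[outlets] == 0.0)

    def test_sor_agrees_with_direct(self, tiny_mask, props):
        rng = np.random.default_rng(3)
        field = zero_field(tiny_mask)
        field.u = rng.normal(size=field.u.shape) * 0.1
        field.v = rng.normal(size=field.v.shape) * 0.1
        ap = 1.0e7
        dp_direct = pressure_poisson(field, tiny_mask, ap=ap, cfg=SolverConfig())
        dp_sor = pressure_poisson(
            field, tiny_mask, ap=ap, cfg=SolverConfig(pressure_solver="sor", relaxation_factor=1.7)
        )
        scale = np.max(np.abs(dp_direct))
        np.testing.assert_allclose(dp_sor, dp_direct, atol=1e-5 * scale)


class TestVelocityCorrection:
    def test_uniform_correction_changes_nothing(self, tiny_solution, tiny_mask):
        field, _ = tiny_solution
        dp = np.full((tiny_mask.ny, tiny_mask.nx), 123.4)
        out = velocity_correction(field, dp, ap=1e7, mask=tiny_mask)
        np.testing.assert_allclose(out.u, field.u, atol=1e-12)
        np.testing.assert_allclose(out.v, field.v, atol=1e-12)

    def test_linear_correction_shifts_u_by_slope_over_ap(self, tiny_mask):
        """dP linear in x: U' - s/Ap at interior fluid nodes (exact)."""
        ap = 2.0e7
        s = 5.0e8
        field = zero_field(tiny_mask)
        xs = np.arange(tiny_mask.nx) * tiny_mask.dx_m
        dp = np.tile(s * xs, (tiny_mask.ny, 1))
        out = velocity_correction(field, dp, ap=ap, mask=tiny_mask)
        ws = _Workspace(tiny_mask, FluidProperties(), InletSpec(), SolverConfig())
        # mirror ghosts flatten the linear field next to solid or inlet
        # x-neighbours; the exact central difference holds everywhere else
        sol = ws.is_solid
        east_bad = np.zeros_like(sol)
        west_bad = np.zeros_like(sol)
        east_bad[:, :-1] = sol[:, 1:] | ws.is_inlet[:, 1:]
        west_bad[:, 1:] = sol[:, :-1] | ws.is_inlet[:, :-1]
        interior = ws.fluid & ~east_bad & ~west_bad
        np.testing.assert_allclose(out.u[interior], -s / ap, rtol=1e-9)
        np.testing.assert_allclose(out.v[interior], 0.0, atol=1e-12)

    def test_projection_cycle_reduces_divergence(self, tiny_mask, props, inlet):
        """One full projection cycle shrinks the divergence of the sweep state."""
        cfg = SolverConfig(momentum_solver="sor")
        ws = _Workspace(tiny_mask, props, inlet, cfg)
        field = apply_boundary_conditions(zero_field(tiny_mask), tiny_mask, inlet)
        for _ in range(20):
            field, ap = momentum_sweep(field, tiny_mask, props, cfg)
        before = np.max(np.abs(ws.divergence(field.u, field.v)[ws.fluid]))
        dp = pressure_poisson(field, tiny_mask, ap=ap, cfg=cfg)
        corrected = velocity_correction(field, dp, ap=ap, mask=tiny_mask)
        after = np.max(np.abs(ws.divergence(corrected.u, corrected.v)[ws.fluid]))
        assert after < before


# ---------------------------------------------------------------------------
# steady solves


class TestSolveSteady:
    def test_sealed_channel_recovers_poiseuille(self, sealed_solution, props, inlet):
        spec, mask, field, report = sealed_solution
        assert report.converged
        p_in = float(np.max(field.p[1 : mask.j_interface_bottom, 0]))
        ref = poiseuille_inlet_pressure(
            props.mu, inlet.u_mean, spec.length_m, spec.channel_height_lower_m
        )
        assert p_in == pytest.approx(ref, rel=1e-8)
        # velocity is the undisturbed parabola everywhere in the channel
        j_half = spec.h_lower_steps // 2
        assert field.u[j_half, mask.nx // 2] == pytest.approx(1.5 * inlet.u_mean, rel=1e-8)
        assert np.max(np.abs(field.v)) < 1e-8 * inlet.u_mean

    def test_stokes_linearity_in_inlet_speed(self, tiny_spec, tiny_mask, props):
        f1, _ = solve_steady(tiny_spec, props, InletSpec(u_mean=1.0), mask=tiny_mask)
        f2, _ = solve_steady(tiny_spec, props, InletSpec(u_mean=2.0), mask=tiny_mask)
        np.testing.assert_allclose(f2.u, 2.0 * f1.u, rtol=1e-9, atol=1e-12)
        np.testing.assert_allclose(f2.v, 2.0 * f1.v, rtol=1e-9, atol=1e-12)
        np.testing.assert_allclose(f2.p, 2.0 * f1.p, rtol=1e-9, atol=1e-9)

    def test_pressure_scales_with_viscosity(self, tiny_spec, tiny_mask, inlet):
        f1, _ = solve_steady(tiny_spec, FluidProperties(mu=3e-4), inlet, mask=tiny_mask)
        f2, _ = solve_steady(tiny_spec, FluidProperties(mu=6e-4), inlet, mask=tiny_mask)
        np.testing.assert_allclose(f2.p, 2.0 * f1.p, rtol=1e-9, atol=1e-9)
        np.testing.assert_allclose(f2.u, f1.u, rtol=1e-9, atol=1e-12)

    def test_point_symmetry_of_countercurrent_field(self, two_pore_solution, inlet):
        """Equal channels and mirrored inlets: u(L-x, H-y) = -u(x, y) etc."""
        mask, field, report = two_pore_solution
        u, v, p = field.u, field.v, field.p
        umax, vmax, pmax = np.abs(u).max(), np.abs(v).max(), np.abs(p).max()
        assert np.max(np.abs(u + u[::-1, ::-1])) < 0.01 * umax
        assert np.max(np.abs(v + v[::-1, ::-1])) < 0.01 * vmax
        assert np.max(np.abs(p - p[::-1, ::-1])) < 0.01 * pmax

    def test_channel_mass_balance(self, two_pore_solution):
        """Inlet flux = outlet flux + net transmembrane flux, within 0.5%."""
        mask, field, _ = two_pore_solution
        spec = mask.spec
        dx = spec.dx_m
        jb = mask.j_interface_bottom
        q_in = np.trapezoid(field.u[: jb + 1, 0], dx=dx)
        q_out = np.trapezoid(field.u[: jb + 1, -1], dx=dx)
        q_mem = np.trapezoid(field.v[jb, :], dx=dx)
        assert abs(q_in - q_out - q_mem) < 0.005 * abs(q_in)

    def test_coupled_solution_is_projection_fixed_point(self, tiny_spec, tiny_mask, props, inlet):
        """Without stabilisation, one projection cycle leaves the coupled
        solution unchanged: both paths solve the same discrete system."""
        cfg = SolverConfig(pressure_stabilization=False)
        field, _ = solve_steady(tiny_spec, props, inlet, cfg, mask=tiny_mask)
        ws = _Workspace(tiny_mask, props, inlet, cfg)
        dp = pressure_poisson(field, tiny_mask, ap=ws.ap, cfg=cfg)
        pscale = np.abs(field.p).max() / props.rho
        assert np.max(np.abs(dp)) < 1e-8 * pscale
        corrected = velocity_correction(field, dp, ap=ws.ap, mask=tiny_mask)
        np.testing.assert_allclose(corrected.u, field.u, rtol=0, atol=1e-8 * inlet.u_max)

    def test_projection_method_approaches_coupled_solution(self, tiny_spec, tiny_mask, props, inlet):
        """The iterative projection loop drifts towards the coupled answer."""
        cfg = SolverConfig(
            method="projection",
            momentum_solver="sor",
            max_outer_iterations=1500,
        )
        f_proj, _ = solve_steady(tiny_spec, props, inlet, cfg, mask=tiny_mask)
        # the projection loop's fixed point is the unstabilised saddle system
        ref_cfg = SolverConfig(pressure_stabilization=False)
        f_ref, _ = solve_steady(tiny_spec, props, inlet, ref_cfg, mask=tiny_mask)
        # velocities agree closely; pressure (the slowest mode) within a few %
        assert np.max(np.abs(f_proj.u - f_ref.u)) < 0.02 * inlet.u_max
        jb = tiny_mask.j_interface_bottom
        p_proj = f_proj.p[1:jb, 0].max()
        p_ref = f_ref.p[1:jb, 0].max()
        assert p_proj == pytest.approx(p_ref, rel=0.05)

    def test_nonconvergence_reported_not_raised(self, tiny_spec, tiny_mask):
        cfg = SolverConfig(method="projection", momentum_solver="sor", max_outer_iterations=5)
        _, report = solve_steady(tiny_spec, cfg=cfg, mask=tiny_mask)
        assert not report.converged
        assert report.iterations == 5

    @settings(max_examples=5, deadline=None)
    @given(scale=st.floats(min_value=0.25, max_value=4.0))
    def test_linearity_property_under_scaling(self, scale, tiny_spec, tiny_mask, props):
        base, _ = solve_steady(tiny_spec, props, InletSpec(u_mean=1.0), mask=tiny_mask)
        scaled, _ = solve_steady(tiny_spec, props, InletSpec(u_mean=scale), mask=tiny_mask)
        np.testing.assert_allclose(scaled.u, scale * base.u, rtol=1e-8, atol=1e-11)
        np.testing.assert_allclose(scaled.p, scale * base.p, rtol=1e-8, atol=1e-8)


# ---------------------------------------------------------------------------
# independent-discretisation cross-check


class TestStaggeredOracle:
    def test_collocated_matches_mac_on_single_pore(self, tiny_spec, tiny_mask, props, inlet):
        """Two unrelated discretisations agree on the headline numbers."""
        field, _ = solve_steady(tiny_spec, props, inlet, mask=tiny_mask)
        jb = tiny_mask.j_interface_bottom
        p_in = float(field.p[1:jb, 0].max())
        jm = tiny_spec.h_lower_steps // 2
        u_mid = float(field.u[jm, tiny_spec.length_steps // 2])

        u_mac, v_mac, p_mac, _ = mac_solve(tiny_spec, mu=props.mu, rho=props.rho, u_mean=inlet.u_mean)
        p_in_mac = mac_inlet_pressure(tiny_spec, p_mac)
        ic = tiny_spec.length_steps // 2
        u_mid_mac = 0.5 * (u_mac[jm - 1, ic] + u_mac[jm, ic])

        assert p_in == pytest.approx(p_in_mac, rel=0.03)
        assert u_mid == pytest.approx(u_mid_mac, rel=0.03)

    def test_sealed_mac_matches_poiseuille(self, props, inlet):
        spec = DomainSpec(n_pores=1, dx_um=0.5)
        _, _, p_mac, _ = mac_solve(spec, sealed=True)
        ref = poiseuille_inlet_pressure(props.mu, inlet.u_mean, spec.length_m, spec.channel_height_lower_m)
        assert mac_inlet_pressure(spec, p_mac) == pytest.approx(ref, rel=0.02)
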