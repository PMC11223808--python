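"""Analytic propagators, Krylov matrix functions and the transition search."""

import numpy as np
import pytest
import sympy
from scipy.integrate import solve_bvp
from scipy.optimize import minimize

from enmpath import elastic_network as en
from enmpath import path_solver as ps
from enmpath.errors import NoCrossingError

from conftest import dense_wells, random_cloud


class TestScalarKernels:
    @pytest.mark.parametrize("x", [0.0, 0.5, 3.0, 50.0, 700.0])
    def test_boundary_values(self, x):
        assert ps.f_scalar(x, 0.0, 1.0) == 0.0
        assert ps.f_scalar(x, 1.0, 1.0) == pytest.approx(1.0, rel=1e-12)

    def test_zero_eigenvalue_limit_is_linear_interpolation(self):
        for t in (0.1, 0.4, 0.9):
            assert ps.f_scalar(0.0, t, 2.0) == pytest.approx(t / 2.0)

    def test_overflow_safe_matches_high_precision_sinh_ratio(self):
        # sinh(350) overflows float64; compare against 50-digit arithmetic
        x, t, t_s = 700.0, 0.5, 1.0
        exact = sympy.sinh(sympy.Rational(700) * sympy.Rational(1, 2)) / \
            sympy.sinh(sympy.Rational(700))
        exact = float(exact.evalf(50))
        assert ps.f_scalar(x, t, t_s) == pytest.approx(exact, rel=1e-12)

    def test_monotone_in_time(self):
        ts = np.linspace(0.0, 1.5, 40)
        for x in (0.0, 0.3, 10.0, 200.0):
            vals = [ps.f_scalar(x, t, 1.5) for t in ts]
            assert all(b >= a - 1e-15 for a, b in zip(vals, vals[1:]))

    def test_time_outside_interval_rejected(self):
        with pytest.raises(ValueError):
            ps.f_scalar(1.0, 2.0, 1.0)
        with pytest.raises(ValueError):
            ps.f_scalar(1.0, -0.1, 1.0)

    def test_velocity_kernel_zero_limit(self):
        assert ps.vel_scalar(0.0, 2.0) == pytest.approx(0.5)

    def test_velocity_kernel_asymptote(self):
        # x coth(x t) -> x for large x t
        assert ps.vel_scalar(500.0, 2.0) == pytest.approx(500.0, rel=1e-12)

    def test_velocity_kernel_is_time_derivative_of_f(self):
        rng = np.random.default_rng(0)
        t_s, h = 1.3, 1e-6
        for x in rng.uniform(0.01, 20.0, size=10):
            # backward difference at t = t_s (f is only defined on [0, t_s])
            dfdt = (ps.f_scalar(x, t_s, t_s) - ps.f_scalar(x, t_s - h, t_s)) / h
            assert ps.vel_scalar(x, t_s) == pytest.approx(dfdt, rel=1e-4)


@pytest.fixture(scope="module")
def small_operator():
    pts = random_cloud(10, box=9.0, seed=41)
    net = en.build_cutoff_network(pts, 9.0, 0.5)
    return en.assemble_hessian(net)


class TestMatrixFunctions:
    def test_eigenvector_is_exact_at_order_one(self, small_operator):
        w, P = small_operator.eigendecomposition()
        v = P[:, -1]
        lam = w[-1]
        fn = lambda x: ps.f_scalar(x, 0.3, 1.0)
        y = ps.apply_matrix_function(small_operator, fn, v, backend="krylov",
                                     m_max=1)
        assert np.allclose(y, fn(lam) * v, atol=1e-10)

    def test_full_order_krylov_equals_dense(self, small_operator):
        rng = np.random.default_rng(1)
        v = rng.normal(size=small_operator.dim)
        fn = lambda x: ps.f_scalar(x, 0.7, 1.0)
        yk = ps.apply_matrix_function(small_operator, fn, v, backend="krylov",
                                      m_max=small_operator.dim, tol=0.0)
        yd = ps.apply_matrix_function(small_operator, fn, v, backend="dense")
        assert np.linalg.norm(yk - yd) < 1e-10 * max(1, np.linalg.norm(yd))

    def test_krylov_converges_on_hundred_atom_network(self):
        pts = random_cloud(100, box=20.0, seed=42)
        net = en.build_cutoff_network(pts, 10.0, 0.2)
        H = en.assemble_hessian(net)
        rng = np.random.default_rng(2)
        v = rng.normal(size=H.dim)
        fn = lambda x: ps.f_scalar(x, 0.4, 1.0)
        yk = ps.apply_matrix_function(H, fn, v, backend="krylov", m_max=60)
        yd = ps.apply_matrix_function(H, fn, v, backend="dense")
        assert np.linalg.norm(yk - yd) < 1e-8 * np.linalg.norm(yd)

    def test_zero_vector_maps_to_zero(self, small_operator):
        y = ps.apply_matrix_function(small_operator, lambda x: x,
                                     np.zeros(small_operator.dim),
                                     backend="krylov")
        assert np.all(y == 0)

    def test_lanczos_recurrence_residual(self, small_operator):
        rng = np.random.default_rng(3)
        v = rng.normal(size=small_operator.dim)
        basis = ps.lanczos_extend(small_operator.matvec, v, 12)
        A_V = np.column_stack([small_operator.matvec(basis.V[:, j])
                               for j in range(basis.m)])
        T = basis.tridiagonal()
        resid = A_V - basis.V @ T
        expected = np.zeros_like(resid)
        expected[:, -1] = basis.beta_m * basis.v_next
        assert np.abs(resid - expected).max() < 1e-8
        # orthonormality under full reorthogonalization
        G = basis.V.T @ basis.V
        assert np.abs(G - np.eye(basis.m)).max() < 1e-10


class TestHalfTrajectory:
    def test_constant_when_boundary_equals_reference(self, small_operator):
        x0 = np.zeros(small_operator.dim)
        hp = ps.HalfPathModel(x0, small_operator, x0.copy(), 1.0)
        frames = ps.half_trajectory(hp, [0.0, 0.3, 1.0])
        assert np.all(frames == 0)

    def test_free_particle_is_straight_line(self):
        import scipy.sparse as sp
        H = en.HessianOperator(sp.csr_matrix((9, 9)))
        x0 = np.zeros(9)
        x1 = np.arange(9.0)
        hp = ps.HalfPathModel(x0, H, x1, 2.0)
        for t in (0.0, 0.5, 1.0, 2.0):
            assert np.allclose(hp.frame(t), (t / 2.0) * x1, atol=1e-12)

    def test_matches_numerical_bvp_integration(self, five_atom_pair):
        """Independent oracle: collocation solution of X'' = H^2 (X - X_A)."""
        xyz_a, xyz_b = five_atom_pair
        wellA, wellB, *_ = dense_wells(xyz_a, xyz_b, cutoff=30.0)
        X_A, HA = wellA
        X_ts = 0.5 * (X_A + wellB[0])
        t_s = 0.6
        Hd = HA.dense()
        H2 = Hd @ Hd

        def ode(t, y):
            X, V = y[:15], y[15:]
            return np.vstack([V, H2 @ (X - X_A[:, None])])

        def bc(ya, yb):
            return np.concatenate([ya[:15] - X_A, yb[:15] - X_ts])

        tgrid = np.linspace(0.0, t_s, 30)
        y0 = np.zeros((30, len(tgrid)))
        for i, t in enumerate(tgrid):
            y0[:15, i] = X_A + (t / t_s) * (X_ts - X_A)
        sol = solve_bvp(ode, bc, tgrid, y0, tol=1e-10, max_nodes=40000)
        assert sol.success

        hp = ps.HalfPathModel(X_A, HA, X_ts, t_s)
        for t in (0.15, 0.3, 0.45, 0.6):
            analytic = hp.frame(t)
            numeric = sol.sol(t)[:15]
            rms = np.sqrt(np.mean((analytic - numeric) ** 2))
            assert rms < 1e-6


class TestTransition:
    def test_symmetric_wells_give_exact_midpoint(self, five_atom_pair):
        xyz_a, _ = five_atom_pair
        shift = np.zeros_like(xyz_a)
        shift[:, 0] = 2.0
        xyz_b = xyz_a + shift  # same internal geometry: identical Hessians
        net = en.build_cutoff_network(xyz_a, 30.0, 0.3)
        HA = en.assemble_hessian(net)
        netb = en.build_cutoff_network(xyz_b, 30.0, 0.3)
        HB = en.assemble_hessian(netb)
        res = ps.solve_transition((xyz_a.ravel(), HA), (xyz_b.ravel(), HB),
                                  F=1.0, dE=0.0)
        assert res.t_A == pytest.approx(0.5, abs=1e-10)
        assert np.abs(res.X_ts - 0.5 * (xyz_a.ravel() + xyz_b.ravel())).max() \
            < 1e-10

    def test_impossible_offset_has_no_crossing(self, five_atom_pair):
        xyz_a, xyz_b = five_atom_pair
        wellA, wellB, *_ = dense_wells(xyz_a, xyz_b)
        # dE far above any energy either quadratic well reaches near the path
        with pytest.raises(NoCrossingError):
            ps.solve_transition(wellA, wellB, F=1.0, dE=1e6)

    def test_asymmetric_wells_continuity_and_oracle(self, five_atom_pair):
        """Stiff start well (k1 = 5 k2): residuals small, transition shifted
        toward the stiffer well, and X_ts agrees with direct minimization
        of the squared continuity violations over (t_A, X_ts)."""
        xyz_a, xyz_b = five_atom_pair
        wellA, wellB, *_ = dense_wells(xyz_a, xyz_b, k1=0.5, k2=0.1)
        res = ps.solve_transition(wellA, wellB, F=1.0, dE=0.0, tol_v=1e-4)
        assert res.velocity_residual < 1e-4
        X_A, HA = wellA
        X_B, HB = wellB
        cross = max(HA.quadratic_energy(X_B - X_A),
                    HB.quadratic_energy(X_A - X_B))
        assert abs(res.energy_gap) / cross < 1e-4
        # stiffer start well: crossing happens earlier in time
        assert res.t_A < 0.5


        def violations(params):
            t_A = params[0]
            X_ts = params[1:]
            if not 0.02 <= t_A <= 0.98:
                return 1e6
            vA = ps.apply_matrix_function(
                HA, lambda x: ps.vel_scalar(x, t_A), X_ts - X_A)
            vB = ps.apply_matrix_function(
                HB, lambda x: ps.vel_scalar(x, 1.0 - t_A), X_ts - X_B)
            gap = HB.quadratic_energy(X_ts - X_B) - HA.quadratic_energy(X_ts - X_A)
            return float(np.dot(vA + vB, vA + vB) + gap * gap)

        x0 = np.concatenate([[0.5], 0.5 * (X_A + X_B)])
        opt = minimize(violations, x0, method="Powell",
                       options={"xtol": 1e-10, "ftol": 1e-12, "maxiter": 200000})
        assert opt.fun < 1e-8
        assert opt.x[0] == pytest.approx(res.t_A, abs=5e-3)
        assert np.abs(opt.x[1:] - res.X_ts).max() < 5e-3

    def test_outer_iterations_are_reported(self, five_atom_pair):
        xyz_a, xyz_b = five_atom_pair
        wellA, wellB, *_ = dense_wells(xyz_a, xyz_b, k1=0.3, k2=0.1)
        res = ps.solve_transition(wellA, wellB)
        assert res.outer_iterations >= 3
        assert len(res.trace) == res.outer_iterations


class TestGeneratePath:
    def test_two_frames_are_exactly_the_endpoints(self, five_atom_pair):
        xyz_a, xyz_b = five_atom_pair
        wellA, wellB, *_ = dense_wells(xyz_a, xyz_b)
        traj = ps.generate_path(wellA, wellB, n_frames=2)
        assert np.array_equal(traj.frames[0], xyz_a.ravel())
        assert np.array_equal(traj.frames[-1], xyz_b.ravel())

    def test_identical_endpoints_constant_path(self, five_atom_pair):
        xyz_a, _ = five_atom_pair
        wellA, wellB, *_ = dense_wells(xyz_a, xyz_a.copy())
        traj = ps.generate_path(wellA, wellB, n_frames=7)
        assert np.all(traj.frames == traj.frames[0])
        assert np.all(traj.energies == 0.0)

    def test_transition_time_is_a_frame_and_energy_peaks_there(
            self, five_atom_pair):
        xyz_a, xyz_b = five_atom_pair
        wellA, wellB, *_ = dense_wells(xyz_a, xyz_b)
        traj = ps.generate_path(wellA, wellB, n_frames=41)
        assert traj.t_A in traj.times
        peak = np.argmax(traj.energies)
        assert traj.times[peak] == traj.t_A

    def test_dense_and_krylov_paths_agree(self):
        pts_a = random_cloud(60, box=16.0, seed=51)
        rng = np.random.default_rng(52)
        pts_b = pts_a + rng.normal(scale=0.6, size=pts_a.shape)
        wellA, wellB, *_ = dense_wells(pts_a, pts_b, cutoff=10.0)
        td = ps.generate_path(wellA, wellB, n_frames=11, backend="dense")
        tk = ps.generate_path(wellA, wellB, n_frames=11, backend="krylov")
        rms = np.sqrt(np.mean((td.frames - tk.frames) ** 2))
        assert rms < 1e-6

    def test_time_reversal_symmetry(self, five_atom_pair):
        """Swapping wells and negating dE reverses the trajectory."""
        xyz_a, xyz_b = five_atom_pair
        wellA, wellB, *_ = dense_wells(xyz_a, xyz_b, k1=0.4, k2=0.1)
        dE = 0.05
        fwd = ps.generate_path(wellA, wellB, dE=dE, n_frames=21)
        rev = ps.generate_path(wellB, wellA, dE=-dE, n_frames=21)
        assert np.abs(fwd.frames - rev.frames[::-1]).max() < 1e-6
        assert fwd.t_A == pytest.approx(1.0 - rev.t_A, abs=1e-6)
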