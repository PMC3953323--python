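"""Chart geometry: constraint Jacobians, implicit function theorem, metric
tensor, proposal densities and the change-of-variables utilities."""
import math

import numpy as np
import pytest

from loopmc.closure import Block, solve_planar, solve_spatial_6
from loopmc.fixtures import random_spatial_chain, spatial_seven_loop
from loopmc.kinematics import Chain, ExpandedState, forward_kinematics, planar_chain
from loopmc.manifold import (
    SingularChartError,
    block_chart_geometry,
    chart_jacobian,
    constraint_jacobians,
    default_weights,
    density_pushforward,
    implicit_chart_jacobian,
    log_det_g,
    manifold_dimension,
    metric_tensor,
    parallelotope_volume,
    proposal_density,
)
from loopmc.rigid import rotation_about_axis


def _closure_residual(chain, angles, block, target):
    """C(q): terminal block frame error as a 6-vector (for FD checks)."""
    frames = forward_kinematics(chain, angles)
    T = frames[block.start + block.size - 1]
    from loopmc.rigid import rotation_log

    e = np.empty(6)
    e[:3] = T[:3, 3] - target[:3, 3]
    e[3:] = rotation_log(T[:3, :3] @ target[:3, :3].T)
    return e


class TestConstraintJacobians:
    def test_matches_central_differences(self):
        """Analytic screw-axis columns agree with (C(q+eps) - C(q-eps))/2eps."""
        rng = np.random.default_rng(0)
        for _ in range(25):
            ch = random_spatial_chain(8, rng)
            q = rng.uniform(-np.pi, np.pi, 8)
            frames = forward_kinematics(ch, q)
            block = Block(0, 8, n_dependent=6)
            target = frames[7].copy()
            dC_dy, dC_dz = constraint_jacobians(ch, frames, block)
            J = np.hstack([dC_dy, dC_dz])
            eps = 1e-6
            for j in range(8):
                dq = np.zeros(8)
                dq[j] = eps
                fd = (
                    _closure_residual(ch, q + dq, block, target)
                    - _closure_residual(ch, q - dq, block, target)
                ) / (2 * eps)
                assert np.max(np.abs(J[:, j] - fd)) < 1e-5

    def test_planar_block_has_classic_form(self):
        """Planar revolute chain: rows are (x, y, orientation) and the
        orientation row is all ones."""
        ch = planar_chain([1.0, 1.0, 1.0, 1.0])
        q = np.array([0.3, -0.5, 0.8, 0.1])
        frames = forward_kinematics(ch, q)
        block = Block(0, 4, n_dependent=3)
        dC_dy, dC_dz = constraint_jacobians(ch, frames, block)
        J = np.hstack([dC_dy, dC_dz])
        np.testing.assert_allclose(J[2], 1.0, atol=1e-12)

    def test_deterministic(self):
        ch = planar_chain([1.0] * 4)
        q = np.array([0.1, 0.2, 0.3, 0.4])
        frames = forward_kinematics(ch, q)
        block = Block(0, 4, n_dependent=3)
        a = constraint_jacobians(ch, frames, block)
        b = constraint_jacobians(ch, frames, block)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])


class TestImplicitChartJacobian:
    def test_matches_ik_resolve_finite_differences(self):
        """Perturb y, re-solve the closure on the same branch, and compare
        delta-z / delta-y with the implicit-function-theorem value."""
        chain, state = spatial_seven_loop()
        block = Block(0, 7, n_dependent=6)
        frames = state.frames
        dC_dy, dC_dz = constraint_jacobians(chain, frames, block)
        dz_dy = implicit_chart_jacobian(dC_dy, dC_dz)
        eps = 1e-6
        target = np.asarray(chain.end_frame_constraint)
        zs = []
        for sgn in (1, -1):
            y = state.angles[0] + sgn * eps
            f1 = forward_kinematics(chain.subchain(0, 1, chain.base_frame), [y])
            dep = chain.subchain(1, 7, base_frame=f1[-1])
            sols = solve_spatial_6(dep, f1[-1], target, n_seeds=100,
                                   extra_seeds=state.angles[None, 1:])
            d = np.abs(np.arctan2(np.sin(sols.solutions - state.angles[1:]),
                                  np.cos(sols.solutions - state.angles[1:]))).max(axis=1)
            zs.append(sols.solutions[int(np.argmin(d))])
        fd = (zs[0] - zs[1]) / (2 * eps)
        assert np.max(np.abs(fd - dz_dy[:, 0])) < 1e-4

    def test_zero_independent_angles_gives_empty_matrix(self):
        dz = implicit_chart_jacobian(np.zeros((6, 0)), np.eye(6))
        assert dz.shape == (6, 0)

    def test_four_bar_coupler_sensitivity_matches_closed_form(self):
        """Planar 4-angle block: dz/dy matches the textbook loop-closure
        sensitivity obtained by differentiating the vector loop equations
        symbolically (solved independently with sympy)."""
        import sympy as sp

        L = [1.0, 1.4, 0.9, 1.2]
        ch = planar_chain(L)
        # generic closed configuration
        q = np.array([0.4, 0.7, -0.9, 0.3])
        frames = forward_kinematics(ch, q)
        block = Block(0, 4, n_dependent=3)
        dC_dy, dC_dz = constraint_jacobians(ch, frames, block)
        dz_dy = implicit_chart_jacobian(dC_dy, dC_dz)

        q1, q2, q3, q4 = sp.symbols("q1 q2 q3 q4")
        th = [q1, q1 + q2, q1 + q2 + q3, q1 + q2 + q3 + q4]
        x = L[0] + sum(Li * sp.cos(t) for Li, t in zip(L[1:], th[:3]))
        y = sum(Li * sp.sin(t) for Li, t in zip(L[1:], th[:3]))
        ori = th[3]
        C = sp.Matrix([x, y, ori])
        vars_z = sp.Matrix([q2, q3, q4])
        dC_dz_sym = C.jacobian(vars_z)
        dC_dy_sym = C.jacobian(sp.Matrix([q1]))
        subs = dict(zip([q1, q2, q3, q4], q))
        dz_sym = -(dC_dz_sym.subs(subs).inv() @ dC_dy_sym.subs(subs))
        np.testing.assert_allclose(dz_dy, np.array(dz_sym, dtype=float), atol=1e-8)


class TestChartJacobian:
    @staticmethod
    def _setup():
        chain, state = spatial_seven_loop()
        block = Block(0, 7, n_dependent=6)
        dC_dy, dC_dz = constraint_jacobians(chain, state.frames, block)
        dz_dy = implicit_chart_jacobian(dC_dy, dC_dz)
        return chain, state, block, dz_dy

    def test_top_block_is_identity(self):
        chain, state, block, dz_dy = self._setup()
        J = chart_jacobian(chain, state.frames, block, dz_dy)
        ni = block.n_independent
        np.testing.assert_array_equal(J[:ni], np.eye(ni))

    def test_zero_frame_weights_reduce_to_angle_space_metric(self):
        """W = 0 on all frame rows gives G = I + (dz/dy)^T (dz/dy)."""
        chain, state, block, dz_dy = self._setup()
        J = chart_jacobian(chain, state.frames, block, dz_dy)
        W = default_weights(block).copy()
        W[block.size:] = 0.0
        G = metric_tensor(J, W)
        expected = np.eye(block.n_independent) + dz_dy.T @ dz_dy
        np.testing.assert_allclose(G, expected, atol=1e-10)

    def test_frame_origin_rows_match_finite_differences(self):
        """Frame-origin rows of the chart agree with re-solved perturbed
        states along the manifold."""
        chain, state, block, dz_dy = self._setup()
        J = chart_jacobian(chain, state.frames, block, dz_dy)
        target = np.asarray(chain.end_frame_constraint)
        eps = 1e-6
        origins = []
        for sgn in (1, -1):
            y = state.angles[0] + sgn * eps
            f1 = forward_kinematics(chain.subchain(0, 1, chain.base_frame), [y])
            dep = chain.subchain(1, 7, base_frame=f1[-1])
            sols = solve_spatial_6(dep, f1[-1], target, n_seeds=60,
                                   extra_seeds=state.angles[None, 1:])
            d = np.abs(np.arctan2(np.sin(sols.solutions - state.angles[1:]),
                                  np.cos(sols.solutions - state.angles[1:]))).max(axis=1)
            z = sols.solutions[int(np.argmin(d))]
            fr = forward_kinematics(chain, np.concatenate([[y], z]))
            origins.append(fr[:6, :3, 3])
        fd = (origins[0] - origins[1]) / (2 * eps)  # (6 frames, 3)
        ni = block.n_independent
        for k in range(6):
            rows = J[block.size + 6 * k : block.size + 6 * k + 3, 0]
            assert np.max(np.abs(rows - fd[k])) < 1e-4


class TestProposalDensity:
    def test_linear_chart_halves_density(self):
        # f(y) = 2y: arc length doubles, so Q = P / 2
        assert proposal_density(1.0, 1, np.array([[4.0]])) == pytest.approx(0.5)

    def test_isometric_chart_preserves_density(self):
        assert proposal_density(0.7, 1, np.eye(3)) == pytest.approx(0.7)

    def test_solution_count_divides_density(self):
        assert proposal_density(1.0, 4, np.eye(2)) == pytest.approx(0.25)

    def test_singular_metric_rejected(self):
        with pytest.raises(SingularChartError):
            log_det_g(np.array([[1.0, 1.0], [1.0, 1.0]]))
        with pytest.raises(ValueError):
            proposal_density(1.0, 0, np.eye(1))


class TestDensityPushforward:
    def test_rigid_rotation_is_isometry(self):
        R = rotation_about_axis([0.3, 0.5, 0.8], 1.1)
        g = density_pushforward(lambda u: 0.42, lambda u: R @ u, [0.2, -0.4, 1.0])
        assert g == pytest.approx(0.42, rel=1e-6)

    def test_unit_circle_uniform_density(self):
        f = lambda u: np.array([math.cos(u[0]), math.sin(u[0])])
        g = density_pushforward(lambda u: 1.0 / (2 * math.pi), f, [0.7])
        assert g == pytest.approx(1.0 / (2 * math.pi), rel=1e-6)
        # line integral of g over the circle is 1
        assert g * 2 * math.pi == pytest.approx(1.0, rel=1e-6)

    def test_surface_integral_preserved_on_random_smooth_map(self):
        """Monte-Carlo surface integral of the pushforward over f(U) equals
        the integral of the source density over U."""
        A = np.array([[1.0, 0.3], [-0.2, 0.8], [0.5, -0.4]])

        def f(u):
            return A @ u + 0.1 * np.array([math.sin(u[0]), math.cos(u[1]), u[0] * u[1]])

        # source density: uniform on the unit square U = [0,1]^2
        g_u = lambda u: 1.0
        rng = np.random.default_rng(5)
        n = 4000
        us = rng.uniform(0, 1, (n, 2))
        # MC integral over the surface: sum g_v(f(u)) * area element / n
        total = 0.0
        for u in us:
            gv = density_pushforward(g_u, f, u)
            # area element sqrt(det G) via the same FD Jacobian route
            eps = 1e-6
            J = np.empty((3, 2))
            for k in range(2):
                du = np.zeros(2)
                du[k] = eps
                J[:, k] = (f(u + du) - f(u - du)) / (2 * eps)
            total += gv * math.sqrt(np.linalg.det(J.T @ J))
        assert total / n == pytest.approx(1.0, rel=1e-3)

    def test_rank_deficient_jacobian_raises(self):
        f = lambda u: np.array([u[0], u[0], u[0]]) * 0.0
        with pytest.raises(ValueError):
            density_pushforward(lambda u: 1.0, f, [0.3, 0.5])


class TestParallelotopeVolume:
    def test_orthonormal_pair_in_r3(self):
        assert parallelotope_volume([[1, 0, 0], [0, 1, 0]]) == pytest.approx(1.0)

    def test_single_vector_is_norm(self):
        assert parallelotope_volume([[3.0, 4.0]]) == pytest.approx(5.0)

    def test_matches_cross_product_magnitude(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            a, b = rng.normal(size=(2, 3))
            assert parallelotope_volume([a, b]) == pytest.approx(
                np.linalg.norm(np.cross(a, b)), abs=1e-10
            )

    def test_rank_deficient_gives_zero(self):
        assert parallelotope_volume([[1, 0, 0], [2, 0, 0]]) == pytest.approx(0.0, abs=1e-12)


class TestManifoldDimension:
    def test_spatial_block_dimensions(self):
        chain, state = spatial_seven_loop()
        assert manifold_dimension(chain, state.angles) == 1
        # spatial b = 6: zero-dimensional (finite solution set)
        rng = np.random.default_rng(7)
        free = random_spatial_chain(6, rng)
        q = rng.uniform(-np.pi, np.pi, 6)
        assert manifold_dimension(free, q, block=Block(0, 6, n_dependent=6)) == 0
        # spatial b = 8 (the protein default block) has a 2-D manifold
        free8 = random_spatial_chain(8, rng)
        q8 = rng.uniform(-np.pi, np.pi, 8)
        assert manifold_dimension(free8, q8, block=Block(0, 8, n_dependent=6)) == 2

    def test_planar_block_dimensions(self):
        rng = np.random.default_rng(8)
        for b, expected in ((3, 0), (4, 1), (5, 2)):
            ch = planar_chain(rng.uniform(0.6, 1.4, b))
            q = rng.uniform(-np.pi, np.pi, b)
            assert manifold_dimension(ch, q, block=Block(0, b, n_dependent=3)) == expected


class TestChartInvariance:
    def test_q_times_volume_element_is_chart_invariant(self):
        """On a planar 4-angle block, relabelling which angle is independent
        changes G but not Q times the manifold volume element, once the
        proposal density over the new chart variable is transformed
        accordingly.  Both chart metrics are obtained by finite differences
        on the W-weighted embedding (angles + varying frame origins), and
        chart A is cross-checked against the analytic metric."""
        from scipy.optimize import fsolve

        L = [1.0, 1.2, 0.8, 1.1]
        ch = planar_chain(L)
        q = np.array([0.5, 0.4, -0.7, 0.2])
        frames = forward_kinematics(ch, q)
        target = frames[-1].copy()

        def residual(qfull):
            fr = forward_kinematics(ch, qfull)
            T = fr[-1]
            return np.array([
                T[0, 3] - target[0, 3],
                T[1, 3] - target[1, 3],
                math.atan2(T[1, 0], T[0, 0]) - math.atan2(target[1, 0], target[0, 0]),
            ])

        def embed(qfull):
            fr = forward_kinematics(ch, qfull)
            # angles + origins of the intervening frames T_1..T_3 (the W
            # convention used by the sampler: angular rows carry weight 0)
            return np.concatenate([qfull, fr[:3, :2, 3].ravel()])

        def solve_chart(y_val, fixed_index):
            """Close the block with angle ``fixed_index`` held at y_val,
            starting from the current conformation (same branch)."""
            free = [j for j in range(4) if j != fixed_index]

            def res(v):
                qf = np.empty(4)
                qf[fixed_index] = y_val
                qf[free] = v
                return residual(qf)

            sol = fsolve(res, q[free], full_output=False, xtol=1e-13)
            qf = np.empty(4)
            qf[fixed_index] = y_val
            qf[free] = sol
            return qf

        eps = 1e-6

        def fd_metric(fixed_index):
            e_plus = embed(solve_chart(q[fixed_index] + eps, fixed_index))
            e_minus = embed(solve_chart(q[fixed_index] - eps, fixed_index))
            d = (e_plus - e_minus) / (2 * eps)
            return math.sqrt(float(d @ d)), (e_plus - e_minus) / (2 * eps)

        sqrtGA_fd, dA = fd_metric(0)
        sqrtGB_fd, dB = fd_metric(1)

        # analytic cross-check of chart A
        blockA = Block(0, 4, n_dependent=3)
        dCyA, dCzA = constraint_jacobians(ch, frames, blockA)
        dzA = implicit_chart_jacobian(dCyA, dCzA)
        GA = metric_tensor(chart_jacobian(ch, frames, blockA, dzA), default_weights(blockA))
        assert math.sqrt(GA[0, 0]) == pytest.approx(sqrtGA_fd, rel=1e-5)

        # dq1/dq2 along the manifold, from the chart-B finite difference
        dq1_dq2 = dB[0]
        # volume element invariance: sqrtGA |dq1| = sqrtGB |dq2|
        assert sqrtGA_fd * abs(dq1_dq2) == pytest.approx(sqrtGB_fd, rel=1e-4)

        # Q invariance once the proposal density is transformed consistently
        P_y1 = 0.37
        P_y2 = P_y1 * abs(dq1_dq2)
        assert P_y1 / sqrtGA_fd == pytest.approx(P_y2 / sqrtGB_fd, rel=1e-4)
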