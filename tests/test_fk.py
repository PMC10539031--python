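"""Membrane currents, anisotropic diffusion, stimulus, and time stepping."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from cardassim.fk import (
    FiberField,
    Grid3D,
    PARAMETER_SETS,
    StimulusModel,
    StochasticConfig,
    TissueState,
    default_parameters,
    diffusion_operator,
    reaction_currents,
    sample_time_scales,
    stability_limit,
    step,
    stimulus_current,
)


def _fields(grid, u, v, w):
    shape = grid.shape
    return np.full(shape, u), np.full(shape, v), np.full(shape, w)


class TestReactionCurrents:
    def test_threshold_and_zero_factors(self, grid5, params):
        p = params
        u, v, w = _fields(grid5, p.u_c, 0.7, 0.5)
        Ifi, Iso, Isi = reaction_currents(u, v, w, p)
        # at exactly u = u_c the fast inward current vanishes (strict threshold)
        assert np.all(Ifi == 0.0)
        u, v, w = _fields(grid5, 0.0, 1.0, 0.0)
        _, Iso, Isi = reaction_currents(u, v, w, p)
        assert np.all(Iso == 0.0)
        u, v, w = _fields(grid5, p.u_csi, 1.0, 0.0)
        assert np.all(reaction_currents(u, v, w, p)[2] == 0.0)

    def test_slow_inward_at_half_activation(self, grid5, params):
        # tanh(0) = 0 so the activation factor is exactly 1/2
        u, v, w = _fields(grid5, params.u_csi, 1.0, 1.0)
        _, _, Isi = reaction_currents(u, v, w, params)
        assert np.allclose(Isi, -1.0 / (2.0 * params.tau_si))

    def test_shape_mismatch_rejected(self, grid5, params):
        u = np.zeros(grid5.shape)
        with pytest.raises(ValueError):
            reaction_currents(u, u[:2], u, params)


def _dense_diffusion_matrix(grid, fib):
    """Independent first-principles assembly of the diffusion operator.

    Mirrored ghost nodes: index -1 maps to 1 and n maps to n - 2.
    """
    nz, ny, nx = grid.shape
    n = nz * ny * nx
    Dxx, Dyy, Dxy, Dzz = fib.tensors(grid)

    def refl(i, n):
        if i < 0:
            return -i
        if i >= n:
            return 2 * n - 2 - i
        return i

    def flat(k, j, i):
        return (refl(k, nz) * ny + refl(j, ny)) * nx + refl(i, nx)

    A = np.zeros((n, n))
    for k in range(nz):
        for j in range(ny):
            for i in range(nx):
                row = flat(k, j, i)
                cxx = Dxx[k] / grid.hx**2
                cyy = Dyy[k] / grid.hy**2
                czz = Dzz / grid.hz**2
                cxy = 2.0 * Dxy[k] / (4.0 * grid.hx * grid.hy)
                A[row, flat(k, j, i + 1)] += cxx
                A[row, flat(k, j, i - 1)] += cxx
                A[row, flat(k, j + 1, i)] += cyy
                A[row, flat(k, j - 1, i)] += cyy
                A[row, flat(k + 1, j, i)] += czz
                A[row, flat(k - 1, j, i)] += czz
                A[row, row] += -2.0 * (cxx + cyy + czz)
                A[row, flat(k, j + 1, i + 1)] += cxy
                A[row, flat(k, j - 1, i - 1)] += cxy
                A[row, flat(k, j + 1, i - 1)] -= cxy
                A[row, flat(k, j - 1, i + 1)] -= cxy
    return A


class TestDiffusion:
    def test_annihilates_constants(self, grid5, fiber):
        out = diffusion_operator(np.full(grid5.shape, 0.7), fiber, grid5)
        assert np.allclose(out, 0.0, atol=1e-13)

    def test_separable_stencil_without_rotation(self, grid5):
        fib = FiberField(theta0=0.0, delta_theta=0.0)
        rng = np.random.default_rng(0)
        u = rng.random(grid5.shape)
        out = diffusion_operator(u, fib, grid5)
        up = np.pad(u, 1, mode="reflect")
        h2 = grid5.hx**2
        expect = (
            fib.D_par * (up[1:-1, 1:-1, 2:] - 2 * u + up[1:-1, 1:-1, :-2]) / h2
            + fib.D_perp * (up[1:-1, 2:, 1:-1] - 2 * u + up[1:-1, :-2, 1:-1]) / h2
            + fib.D_perp * (up[2:, 1:-1, 1:-1] - 2 * u + up[:-2, 1:-1, 1:-1]) / h2
        )
        assert np.allclose(out, expect, atol=1e-15)

    def test_matches_dense_matrix_oracle(self, grid5, fiber, rng):
        A = _dense_diffusion_matrix(grid5, fiber)
        u = np.zeros(grid5.shape)
        u[2, 2, 2] = 1.0  # single interior perturbation
        assert np.allclose(
            diffusion_operator(u, fiber, grid5).ravel(), A @ u.ravel(), atol=1e-12
        )
        u = rng.random(grid5.shape)
        assert np.allclose(
            diffusion_operator(u, fiber, grid5).ravel(), A @ u.ravel(), atol=1e-12
        )

    def test_linearity(self, grid5, fiber, rng):
        a, b = rng.random(grid5.shape), rng.random(grid5.shape)
        lhs = diffusion_operator(2.0 * a - 3.0 * b, fiber, grid5)
        rhs = 2.0 * diffusion_operator(a, fiber, grid5) - 3.0 * diffusion_operator(
            b, fiber, grid5
        )
        assert np.allclose(lhs, rhs, atol=1e-13)

    def test_small_grid_rejected(self, fiber):
        with pytest.raises(ValueError):
            Grid3D(2, 5, 5)

    def test_tensor_invariants(self, grid5):
        fib = FiberField(theta0=0.3, delta_theta=2 * np.pi / 3)
        Dxx, Dyy, Dxy, Dzz = fib.tensors(grid5)
        assert np.allclose(Dxx + Dyy, fib.D_par + fib.D_perp)
        assert np.all(Dxx * Dyy - Dxy**2 > 0)
        assert Dzz == fib.D_perp


class TestStimulus:
    def test_off_phase_is_zero(self, grid5):
        s = StimulusModel(I0=0.1, period=118.0, t0=10.0, tau_on=10.0)
        assert np.all(stimulus_current(25.0, grid5, s) == 0.0)
        assert np.all(stimulus_current(0.0, grid5, s) == 0.0)

    def test_on_phase_amplitude_and_profile(self, grid5):
        s = StimulusModel(I0=0.1, t0=10.0, tau_on=10.0, x0=0.1, y0=0.1, kappa=5.0)
        field = stimulus_current(12.0, grid5, s)
        # default amplitude at the center
        assert field[0, 2, 2] == pytest.approx(0.1)
        # depth independence
        assert np.allclose(field[0], field[-1])
        # value I0/e at kappa^2 r^2 = 1
        r = 1.0 / s.kappa
        val = s.I0 * np.exp(-s.kappa**2 * r**2)
        assert val == pytest.approx(0.1 / np.e)

    def test_periodic_gate(self):
        s = StimulusModel(period=118.0, t0=10.0, tau_on=10.0)
        assert s.gate(10.0) == 1.0
        assert s.gate(19.999) == 1.0
        assert s.gate(20.0) == 0.0
        assert s.gate(10.0 + 118.0) == 1.0

    def test_explicit_onsets(self):
        s = StimulusModel(onsets=[5.0, 40.0], tau_on=2.0)
        assert s.gate(5.5) == 1.0
        assert s.gate(8.0) == 0.0
        assert s.gate(41.9) == 1.0


class TestTimeScaleSampling:
    def test_zero_sigma_is_identity(self, params, rng):
        assert sample_time_scales(params, 0.0, rng) == params

    def test_distribution_moments(self, params):
        rng = np.random.default_rng(7)
        n = 100_000
        draws = np.array(
            [sample_time_scales(params, 0.04, rng).tau_r for _ in range(n)]
        )
        se = 0.04 * params.tau_r / np.sqrt(n)
        assert abs(draws.mean() - params.tau_r) < 3 * se
        assert abs(draws.std() - 0.04 * params.tau_r) < 0.05 * 0.04 * params.tau_r

    def test_truncation_floor(self, params):
        rng = np.random.default_rng(3)
        draws = [sample_time_scales(params, 0.9, rng) for _ in range(500)]
        taus = np.array([d.tau_d for d in draws])
        assert np.all(taus >= 0.05 * params.tau_d - 1e-15)
        # with sigma_p = 0.9 the floor is hit
        assert np.any(taus == 0.05 * params.tau_d)

    def test_thresholds_untouched(self, params, rng):
        q = sample_time_scales(params, 0.3, rng)
        assert (q.u_c, q.u_v, q.u_csi, q.k_si) == (
            params.u_c, params.u_v, params.u_csi, params.k_si,
        )


class TestStep:
    def test_rest_state_nearly_invariant(self, grid5, fiber, params):
        # the slow-inward tanh tail gives a ~1e-9 drift per step, not zero
        s0 = TissueState.rest(grid5)
        s1 = step(s0, 0.1, params, fiber, grid5)
        assert np.all(np.abs(s1.u) < 1e-8)
        assert np.array_equal(s1.v, s0.v)
        assert np.array_equal(s1.w, s0.w)

    def test_rush_larsen_closed_form(self, grid5, fiber, params):
        s0 = TissueState.rest(grid5)
        s0.v[:] = 0.5
        s1 = step(s0, 0.1, params, fiber, grid5)
        # u = 0 < u_v: relaxation toward 1 with tau_v2^-
        expect = 1.0 + (0.5 - 1.0) * np.exp(-0.1 / params.tau_v2_minus)
        assert np.allclose(s1.v, expect, atol=1e-14)

    @pytest.mark.parametrize("name", sorted(PARAMETER_SETS))
    def test_gates_stay_in_unit_interval(self, grid5, fiber, name, rng):
        p = PARAMETER_SETS[name]
        state = TissueState(
            0.0, rng.uniform(0, 1, grid5.shape),
            rng.uniform(0, 1, grid5.shape), rng.uniform(0, 1, grid5.shape),
        )
        for _ in range(200):
            state = step(state, 0.1, p, FiberField(), grid5)
        assert np.all((state.v >= 0) & (state.v <= 1))
        assert np.all((state.w >= 0) & (state.w <= 1))

    def test_zero_noise_matches_deterministic_bitwise(self, grid5, fiber, params, rng):
        state = TissueState(0.0, np.full(grid5.shape, 0.3),
                            np.ones(grid5.shape), np.ones(grid5.shape))
        sto = StochasticConfig(sigma_u=0.0, sigma_p=0.0)
        a = step(state, 0.1, params, fiber, grid5)
        b = step(state, 0.1, params, fiber, grid5, sto=sto, rng=rng)
        assert np.array_equal(a.u, b.u)

    def test_unstable_dt_rejected(self, grid5, fiber, params):
        limit = stability_limit(fiber, grid5)
        with pytest.raises(ValueError):
            step(TissueState.rest(grid5), 2.0 * limit, params, fiber, grid5)

    def test_single_cell_against_stiff_ode_oracle(self, params):
        """A spatially uniform state has zero diffusion, so the step
        reduces to the single-cell membrane model; its action potential
        must match a high-accuracy generic ODE integration within 1% of
        the time spent above threshold."""
        p = params
        grid = Grid3D(3, 3, 3)
        fib = FiberField()

        def rhs(_, y):
            u, v, w = y
            above = 1.0 if u > p.u_c else 0.0
            below = 1.0 if u < p.u_c else 0.0
            Ifi = -v * above * (1 - u) * (u - p.u_c) / p.tau_d
            Iso = u * below / p.tau_o + above / p.tau_r
            Isi = -w * (1 + np.tanh(p.k_si * (u - p.u_csi))) / (2 * p.tau_si)
            tau_vm = p.tau_v1_minus if u > p.u_v else p.tau_v2_minus
            dv = below * (1 - v) / tau_vm - above * v / p.tau_v_plus
            dw = below * (1 - w) / p.tau_w_minus - above * w / p.tau_w_plus
            return [-(Ifi + Iso + Isi), dv, dw]

        t_eval = np.arange(0.0, 500.0, 0.1)
        sol = solve_ivp(rhs, (0, 500), [0.3, 1.0, 1.0], method="Radau",
                        t_eval=t_eval, rtol=1e-8, atol=1e-10, max_step=1.0)

        state = TissueState(
            0.0, np.full(grid.shape, 0.3), np.ones(grid.shape), np.ones(grid.shape)
        )
        trace = [0.3]
        for _ in range(len(t_eval) - 1):
            state = step(state, 0.1, p, fib, grid)
            trace.append(state.u[1, 1, 1])
        trace = np.asarray(trace)

        def time_above(u):  # both trajectories start above threshold
            below = np.nonzero(u < 0.1)[0]
            return t_eval[below[0]] if below.size else np.inf

        apd_ref = time_above(sol.y[0])
        apd = time_above(trace)
        assert np.isfinite(apd_ref)
        assert abs(apd - apd_ref) / apd_ref < 0.01
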