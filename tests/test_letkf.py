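"""LETKF analysis: taper, screening, local solves, and the grid sweep."""

import numpy as np
import pytest

from cardassim.fk import Grid3D, default_parameters
from cardassim.letkf import (
    AssimilationConfig,
    Ensemble,
    analysis_step,
    bound_state,
    gross_error_screen,
    initialize_ensemble,
    local_solve,
    localization_cutoff,
    localization_weight,
)
from cardassim.observations import ObservationSet


def _obs(grid, idx_xyz, values, etas, t=0.0):
    idx_xyz = np.atleast_2d(idx_xyz)
    return ObservationSet(
        t=t,
        x=idx_xyz[:, 0] * grid.hx,
        y=idx_xyz[:, 1] * grid.hy,
        z=idx_xyz[:, 2] * grid.hz,
        value=np.asarray(values, dtype=float),
        eta=np.asarray(etas, dtype=float),
        provenance=np.array(["surface"] * len(idx_xyz), dtype=object),
    )


def _random_ensemble(grid, M, rng, t=0.0):
    shape = (M,) + grid.shape
    return Ensemble(
        t,
        0.2 + 0.6 * rng.random(shape),
        0.2 + 0.6 * rng.random(shape),
        0.2 + 0.6 * rng.random(shape),
    )


class TestLocalizationTaper:
    def test_normalization_knot_and_cutoff(self):
        assert localization_weight(0.0, 6.0) == 1.0
        c = np.sqrt(10.0 / 3.0) * 6.0
        assert localization_weight(c, 6.0) == pytest.approx(5.0 / 24.0, abs=1e-12)
        # zero from 2c on; 21.91 grid units is already outside for sigma_o=6
        assert localization_weight(21.91, 6.0) == 0.0
        assert localization_cutoff(6.0) == pytest.approx(21.909, abs=5e-4)

    def test_monotone_and_bounded(self):
        r = np.linspace(0, 25, 500)
        w = localization_weight(r, 6.0)
        assert np.all(np.diff(w) <= 1e-12)
        assert np.all((w >= 0) & (w <= 1))


class TestGrossErrorScreen:
    def test_screening_rule(self):
        out, n = gross_error_screen([0.6, 0.3], [0.05, 0.05], 10.0)
        assert out[0] == 0.0 and out[1] == 0.3
        assert n == 1

    def test_saturation_multiplier(self):
        innov = np.linspace(-1, 1, 101)
        etas = np.full_like(innov, 0.05)
        _, n20 = gross_error_screen(innov, etas, 20.0)
        assert n20 == 0
        _, n19 = gross_error_screen(innov, etas, 19.0)
        assert n19 > 0


class TestLocalSolve:
    def test_no_observations_limit(self):
        wbar, Wa = local_solve(np.zeros((0, 4)), [], [], [], [], rho=1.05, M=4)
        assert np.all(wbar == 0)
        assert np.allclose(Wa, np.sqrt(1.05) * np.eye(4))

    def test_zero_obs_space_spread_gives_zero_gain(self):
        wbar, _ = local_solve(np.zeros((2, 3)), [0.5, 0.5], [0.9, 0.1],
                              [0.1, 0.1], [1.0, 1.0], rho=1.0, M=3)
        assert np.allclose(wbar, 0.0)

    def test_scalar_kalman_update(self):
        """Members {0, 1, 2} observing 2 with unit noise: the closed-form
        Kalman mean is xbar + P/(P+R) (y - xbar) = 1 + 1/2 = 1.5."""
        members = np.array([0.0, 1.0, 2.0])
        X = members - members.mean()
        wbar, Wa = local_solve(X[:, None].T, [members.mean()], [2.0],
                               [1.0], [1.0], rho=1.0, M=3)
        mean_a = members.mean() + X @ wbar
        assert mean_a == pytest.approx(1.5, abs=1e-12)
        # analysis variance matches P~ = (1/P + 1/R)^{-1} = 1/2
        Xa = X @ Wa
        assert Xa @ Xa / 2.0 == pytest.approx(0.5, abs=1e-12)

    def test_symmetric_transform(self, rng):
        Y = rng.standard_normal((5, 4))
        Y -= Y.mean(axis=1, keepdims=True)
        _, Wa = local_solve(Y, rng.random(5), rng.random(5),
                            np.full(5, 0.3), np.full(5, 0.8), rho=1.05, M=4)
        assert np.allclose(Wa, Wa.T, atol=1e-12)

    def test_monotone_influence_of_eta(self):
        members = np.array([0.0, 1.0, 2.0])
        X = members - 1.0
        gaps = []
        for eta in (0.5, 1.0, 2.0, 5.0, 50.0):
            wbar, _ = local_solve(X[:, None].T, [1.0], [2.0], [eta], [1.0],
                                  rho=1.0, M=3)
            gaps.append(abs(X @ wbar))
        assert all(a > b for a, b in zip(gaps, gaps[1:]))


class TestAnalysisStep:
    def test_matches_dense_etkf_oracle(self, rng):
        """With an effectively infinite localization scale every node sees
        every observation with unit weight, so the per-node solves must
        reproduce a single dense ensemble-transform update of the whole
        state."""
        grid = Grid3D(8, 3, 3)
        M = 4
        ens = _random_ensemble(grid, M, rng)
        cfg = AssimilationConfig(rho=1.05, sigma_o=1e6, sigma_g=1e9)
        obs = _obs(grid, [(1, 1, 1), (6, 1, 1)], [0.9, 0.1], [0.3, 0.4])

        # independent dense ETKF on the full stacked state
        n = grid.n_nodes
        xb = np.concatenate(
            [ens.u.reshape(M, n), ens.v.reshape(M, n), ens.w.reshape(M, n)], axis=1
        ).T  # (3n, M)
        xbar = xb.mean(axis=1)
        X = xb - xbar[:, None]
        flat = np.array([(1 * 3 + 1) * 8 + 1, (1 * 3 + 1) * 8 + 6])
        H = np.zeros((2, 3 * n))
        H[0, flat[0]] = 1.0
        H[1, flat[1]] = 1.0
        Y = H @ X
        Rinv = np.diag(1.0 / np.array([0.3, 0.4]) ** 2)
        C = (M - 1) * np.eye(M) / cfg.rho + Y.T @ Rinv @ Y
        evals, evecs = np.linalg.eigh(C)
        Pa = (evecs / evals) @ evecs.T
        wbar = Pa @ Y.T @ Rinv @ (np.array([0.9, 0.1]) - H @ xbar)
        Wa = (evecs * np.sqrt((M - 1) / evals)) @ evecs.T
        mean_oracle = xbar + X @ wbar
        dev_oracle = X @ Wa

        out = analysis_step(ens, obs, cfg, grid)
        mean_pkg = np.concatenate(
            [out.u.mean(axis=0).ravel(), out.v.mean(axis=0).ravel(),
             out.w.mean(axis=0).ravel()]
        )
        assert np.allclose(mean_pkg, mean_oracle, atol=1e-8)
        dev_pkg = np.concatenate(
            [out.u.reshape(M, n) - out.u.reshape(M, n).mean(axis=0),
             out.v.reshape(M, n) - out.v.reshape(M, n).mean(axis=0),
             out.w.reshape(M, n) - out.w.reshape(M, n).mean(axis=0)], axis=1
        ).T
        assert np.allclose(dev_pkg, dev_oracle, atol=1e-8)

    def test_vanishing_confidence_preserves_mean(self, rng):
        grid = Grid3D(5, 5, 4)
        ens = _random_ensemble(grid, 4, rng)
        cfg = AssimilationConfig(sigma_g=1e12)
        obs = _obs(grid, [(2, 2, 0)], [0.9], [1e6])
        out = analysis_step(ens, obs, cfg, grid)
        assert np.allclose(out.u.mean(axis=0), ens.u.mean(axis=0), atol=1e-6)

    def test_free_run_preserves_mean(self, rng):
        grid = Grid3D(5, 5, 4)
        ens = _random_ensemble(grid, 4, rng)  # strictly inside the bounds
        cfg = AssimilationConfig(free_run=True)
        out = analysis_step(ens, None, cfg, grid)
        assert np.allclose(out.u.mean(axis=0), ens.u.mean(axis=0), atol=1e-15)
        # deviations inflated by sqrt(rho)
        assert np.allclose(out.deviations("u"), np.sqrt(1.05) * ens.deviations("u"))

    def test_rho_one_no_observations_is_identity(self, rng):
        grid = Grid3D(5, 5, 4)
        ens = _random_ensemble(grid, 4, rng)
        cfg = AssimilationConfig(rho=1.0, free_run=True)
        out = analysis_step(ens, None, cfg, grid)
        assert np.array_equal(out.u, ens.u)
        assert np.array_equal(out.v, ens.v)

    def test_deviations_sum_to_zero(self, rng):
        grid = Grid3D(6, 6, 4)
        ens = _random_ensemble(grid, 5, rng)
        cfg = AssimilationConfig(sigma_o=3.0)
        obs = _obs(grid, [(1, 1, 0), (4, 4, 3), (2, 3, 0)],
                   [0.8, 0.3, 0.5], [0.05, 0.05, 0.05])
        out = analysis_step(ens, obs, cfg, grid)
        for name in ("u", "v", "w"):
            dev = out.deviations(name)
            assert np.allclose(dev.sum(axis=0), 0.0, atol=1e-10)

    def test_weak_coupling_leaves_gates_untouched(self, rng):
        grid = Grid3D(5, 5, 4)
        ens = _random_ensemble(grid, 4, rng)
        cfg = AssimilationConfig(coupling="weak")
        obs = _obs(grid, [(2, 2, 0)], [0.9], [0.05])
        out = analysis_step(ens, obs, cfg, grid)
        assert np.array_equal(out.v, ens.v)
        assert np.array_equal(out.w, ens.w)
        assert not np.array_equal(out.u, ens.u)

    def test_time_mismatch_rejected(self, rng):
        grid = Grid3D(5, 5, 4)
        ens = _random_ensemble(grid, 4, rng, t=10.0)
        obs = _obs(grid, [(2, 2, 0)], [0.9], [0.05], t=12.0)
        with pytest.raises(ValueError, match="time"):
            analysis_step(ens, obs, AssimilationConfig(), grid)


class TestBoundState:
    def test_clipping_rules(self, rng):
        grid = Grid3D(5, 5, 4)
        ens = _random_ensemble(grid, 3, rng)
        ens.u[0, 0, 0, 0] = 1.7
        ens.v[0, 0, 0, 1] = -0.2
        before = ens.u.copy()
        bound_state(ens, AssimilationConfig())
        assert ens.u[0, 0, 0, 0] == 1.5
        assert ens.v[0, 0, 0, 1] == 0.0
        # in-range entries untouched
        mask = before <= 1.5
        assert np.array_equal(ens.u[mask], before[mask])


class TestInitialization:
    def test_deterministic_and_spread_structure(self):
        grid = Grid3D(8, 8, 5)
        cfg = AssimilationConfig()
        p = default_parameters()
        a = initialize_ensemble(grid, 8, p, cfg, np.random.default_rng(42))
        b = initialize_ensemble(grid, 8, p, cfg, np.random.default_rng(42))
        assert np.array_equal(a.u, b.u)
        assert a.u.std() > 0
        assert np.all(a.v == 1.0) and np.all(a.w == 1.0)
        assert a.t == 0.0

    def test_zero_amplitude_gives_identical_rest_members(self):
        grid = Grid3D(8, 8, 5)
        ens = initialize_ensemble(grid, 4, default_parameters(),
                                  AssimilationConfig(), np.random.default_rng(0),
                                  amplitude=0.0)
        assert np.all(ens.u == 0.0)
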