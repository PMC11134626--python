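import numpy as np
import pytest
from scipy.linalg import subspace_angles
from scipy.optimize import minimize

from longenrich import (
    Hyperparams, SimConfig, admm_objective, constraint_residuals, enrich_all,
    eval_objective, fit, init_state, reweight, simulate_cohort, solve_sylvester,
    update_block, update_multipliers,
)
from longenrich.solver import (
    _multipliers_inplace, _sweep_inplace, standardize_cohort,
)


def _tiny_instance(seed=2):
    """n=3, d=4, r1=2, r2=2, c=1 instance with a generic perturbed state."""
    cfg = SimConfig(
        n=3, l=2, d_per_modality={"M": 4}, d_snp=6, K=2, c=1,
        r1_true=2, r2_true=2, active_group_count=2,
        noise_sd_imaging=0.3, noise_sd_snp=0.2, noise_sd_labels=0.1,
        visit_count_range=(4, 6), seed=seed,
    )
    cohort, _ = simulate_cohort(cfg)
    # moderate weights keep every restricted problem well-conditioned so the
    # generic numerical minimizer can resolve the same optimum
    hp = Hyperparams(r1=2, r2=2, gamma1=0.1, gamma2=0.3, gamma3=0.5,
                     gamma4=0.3, gamma5=0.2, gamma6=0.2, gamma7=0.2, seed=0)
    st = init_state(cohort, hp)
    rng = np.random.default_rng(seed + 1)
    st.H0 += 0.1 * rng.standard_normal(st.H0.shape)
    st.G1 += 0.1 * rng.standard_normal(st.G1.shape)
    st.G0 += 0.1 * rng.standard_normal(st.G0.shape)
    st.U += 0.1 * rng.standard_normal(st.U.shape)
    st.A = st.U + 0.01 * rng.standard_normal(st.A.shape)
    weights = reweight(st, cohort, hp.delta)
    return cohort, hp, st, weights


_BLOCKS = {
    "F": (lambda s: s.F, lambda s, v: setattr(s, "F", v)),
    "U": (lambda s: s.U, lambda s, v: setattr(s, "U", v)),
    "A": (lambda s: s.A, lambda s, v: setattr(s, "A", v)),
    "H1": (lambda s: s.H1, lambda s, v: setattr(s, "H1", v)),
    "G1": (lambda s: s.G1, lambda s, v: setattr(s, "G1", v)),
    "H0": (lambda s: s.H0, lambda s, v: setattr(s, "H0", v)),
    "G0": (lambda s: s.G0, lambda s, v: setattr(s, "G0", v)),
    "W_0": (lambda s: s.W[0], lambda s, v: s.W.__setitem__(0, v)),
    "W_2": (lambda s: s.W[2], lambda s, v: s.W.__setitem__(2, v)),
    "B_0": (lambda s: s.B[0], lambda s, v: s.B.__setitem__(0, v)),
    "B_1": (lambda s: s.B[1], lambda s, v: s.B.__setitem__(1, v)),
}


class TestInitState:
    def test_deterministic(self, small_sim, small_hp):
        cohort, _ = small_sim
        a = init_state(cohort, small_hp)
        b = init_state(cohort, small_hp)
        np.testing.assert_array_equal(a.H0, b.H0)
        np.testing.assert_array_equal(a.U, b.U)
        for wa, wb in zip(a.W, b.W):
            np.testing.assert_array_equal(wa, wb)

    def test_projections_orthonormal(self, small_sim, small_hp):
        cohort, _ = small_sim
        st = init_state(cohort, small_hp)
        for W in st.W:
            np.testing.assert_allclose(
                W.T @ W, np.eye(small_hp.r1), atol=1e-10)

    def test_labeled_scores_initialized_exactly(self, small_sim, small_hp):
        cohort, _ = small_sim
        st = init_state(cohort, small_hp)
        np.testing.assert_array_equal(
            st.F[:, :cohort.n_labeled], cohort.labels)
        np.testing.assert_array_equal(st.F[:, cohort.n_labeled:], 0.0)

    def test_copies_match(self, small_sim, small_hp):
        cohort, _ = small_sim
        st = init_state(cohort, small_hp)
        np.testing.assert_array_equal(st.A, st.U)
        for W, B in zip(st.W, st.B):
            np.testing.assert_array_equal(W, B)

    def test_r1_too_large_raises(self, small_sim):
        cohort, _ = small_sim
        with pytest.raises(ValueError):
            init_state(cohort, Hyperparams(r1=100, r2=2))


class TestUpdateBlock:
    @pytest.mark.parametrize("block", list(_BLOCKS))
    def test_stationary_and_nonincreasing(self, block):
        cohort, hp, st, w = _tiny_instance()
        before = admm_objective(st, cohort, hp, w)
        new = update_block(st, cohort, hp, w, block)
        after = admm_objective(new, cohort, hp, w)
        assert after <= before + 1e-10 * (1 + abs(before))

        get, setb = _BLOCKS[block]
        val = get(new)
        eps = 1e-6
        grad = np.zeros_like(val)
        for idx in np.ndindex(*val.shape):
            for s, sign in ((eps, 1.0), (-eps, -1.0)):
                probe = new.copy()
                b = get(probe).copy()
                b[idx] += s
                setb(probe, b)
                grad[idx] += sign * admm_objective(probe, cohort, hp, w)
        grad /= 2 * eps
        assert np.linalg.norm(grad) <= 1e-4 * (1 + np.linalg.norm(val))

    @pytest.mark.parametrize("block", list(_BLOCKS))
    def test_fixed_point(self, block):
        """Applying the same update twice leaves the block unchanged."""
        cohort, hp, st, w = _tiny_instance()
        once = update_block(st, cohort, hp, w, block)
        twice = update_block(once, cohort, hp, w, block)
        get = _BLOCKS[block][0]
        np.testing.assert_allclose(get(twice), get(once),
                                   atol=1e-8 * (1 + np.linalg.norm(get(once))))

    @pytest.mark.parametrize("block", list(_BLOCKS))
    def test_matches_numerical_minimizer(self, block):
        cohort, hp, st, w = _tiny_instance()
        get, setb = _BLOCKS[block]
        shape = get(st).shape

        def objective(flat):
            probe = st.copy()
            setb(probe, flat.reshape(shape))
            return admm_objective(probe, cohort, hp, w)

        res = minimize(objective, get(st).ravel(), method="L-BFGS-B",
                       options={"maxiter": 2000, "ftol": 1e-15, "gtol": 1e-12})
        ours = get(update_block(st, cohort, hp, w, block))
        np.testing.assert_allclose(ours, res.x.reshape(shape), atol=1e-5)

    def test_h1_least_squares_oracle(self):
        cohort, hp, st, w = _tiny_instance()
        # force D3 proportional to identity by zeroing the Z residual rows:
        # instead solve directly with whatever D3 (diagonal cancels exactly
        # when H1 is the only variable), so the LS oracle applies as-is
        new = update_block(st, cohort, hp, w, "H1")
        Z = enrich_all(cohort, st.W)
        oracle = Z @ st.G1.T @ np.linalg.inv(st.G1 @ st.G1.T)
        np.testing.assert_allclose(new.H1, oracle, atol=1e-6)

    def test_unknown_block_raises(self):
        cohort, hp, st, w = _tiny_instance()
        with pytest.raises(ValueError):
            update_block(st, cohort, hp, w, "Q")


class TestSolveSylvester:
    def test_scalar(self):
        X = solve_sylvester(np.array([[2.0]]), np.array([[3.0]]),
                            np.array([[10.0]]))
        np.testing.assert_allclose(X, [[2.0]])

    def test_q_zero_reduces_to_linear_solve(self):
        rng = np.random.default_rng(5)
        P = rng.standard_normal((4, 4)) + 4 * np.eye(4)
        R = rng.standard_normal((4, 3))
        X = solve_sylvester(P, np.zeros((3, 3)), R)
        np.testing.assert_allclose(X, np.linalg.solve(P, R), atol=1e-10)

    def test_random_residual(self):
        rng = np.random.default_rng(6)
        P = rng.standard_normal((5, 5)) + 5 * np.eye(5)
        Q = rng.standard_normal((3, 3)) + 5 * np.eye(3)
        R = rng.standard_normal((5, 3))
        X = solve_sylvester(P, Q, R)
        assert np.linalg.norm(P @ X + X @ Q - R) <= 1e-8 * np.linalg.norm(R)

    def test_spectral_overlap_raises(self):
        P = np.diag([1.0, 2.0])
        Q = np.diag([-2.0, 5.0])    # -2 is an eigenvalue of -Q... P has 2
        with pytest.raises(ValueError, match="eigenvalue"):
            solve_sylvester(P, Q, np.ones((2, 2)))


class TestUpdateMultipliers:
    def test_zero_residuals_keep_lambdas(self):
        cohort, hp, st, w = _tiny_instance()
        st.F[:, :cohort.n_labeled] = cohort.labels
        st.A = st.U.copy()
        for i in range(st.n):
            st.B[i] = st.W[i].copy()
            # make W_i^T B_i = I exactly
            Q, _ = np.linalg.qr(st.W[i])
            st.W[i] = Q[:, :st.r1]
            st.B[i] = st.W[i].copy()
        new = update_multipliers(st, hp, cohort)
        np.testing.assert_allclose(new.Lambda1, st.Lambda1, atol=1e-10)
        np.testing.assert_allclose(new.Lambda3, st.Lambda3, atol=1e-10)
        assert new.mu1 == pytest.approx(st.mu1 * hp.rho1)
        np.testing.assert_allclose(new.mu4, st.mu4 * hp.rho4)

    def test_rho_one_keeps_mus(self):
        cohort, hp, st, w = _tiny_instance()
        hp.rho1 = hp.rho2 = hp.rho3 = hp.rho4 = 1.0
        new = update_multipliers(st, hp, cohort)
        assert new.mu1 == st.mu1
        np.testing.assert_array_equal(new.mu2, st.mu2)

    def test_scalar_ascent_arithmetic(self):
        cohort, hp, st, w = _tiny_instance()
        st.mu3 = 2.0
        st.Lambda3 = np.zeros_like(st.Lambda3)
        st.A = st.U + 3.0 / np.sqrt(st.A.size) * np.ones_like(st.A)
        new = update_multipliers(st, hp, cohort)
        np.testing.assert_allclose(
            new.Lambda3, 2.0 * (st.A - st.U), atol=1e-12)

    def test_mu_capped(self):
        cohort, hp, st, w = _tiny_instance()
        st.mu1 = hp.mu_max
        new = update_multipliers(st, hp, cohort)
        assert new.mu1 == hp.mu_max


class TestFit:
    def test_descent_and_feasibility(self, small_sim, small_hp):
        cohort, _ = small_sim
        result = fit(cohort, small_hp)
        obj = np.array(result.objective_history)
        assert np.all(np.diff(obj) <= 1e-6 * (1 + np.abs(obj[1:])))
        assert np.isfinite(obj).all()
        res = result.residual_history[-1]
        assert max(res.values()) < 1e-3

    def test_z_equals_enrichment_of_final_state(self, small_sim, small_hp):
        cohort, _ = small_sim
        result = fit(cohort, small_hp, standardize=False)
        np.testing.assert_allclose(
            result.Z, enrich_all(cohort, result.state.W), atol=1e-12)

    def test_invalid_cohort_rejected(self, small_sim, small_hp):
        cohort, _ = small_sim
        cohort.histories[0] = np.empty((cohort.d, 0))
        with pytest.raises(ValueError, match="invalid cohort"):
            fit(cohort, small_hp)

    def test_decoupled_robust_pca_recovers_svd_subspace(self):
        cfg = SimConfig(
            n=6, l=4, d_per_modality={"M": 10}, d_snp=8, K=2, c=1,
            r1_true=3, r2_true=2, active_group_count=2,
            noise_sd_imaging=0.0, noise_sd_snp=0.0, noise_sd_labels=0.0,
            visit_count_range=(6, 8), seed=9,
        )
        cohort, _ = simulate_cohort(cfg)
        hp = Hyperparams(r1=3, r2=2, gamma1=1.0, gamma2=0, gamma3=0,
                         gamma4=0, gamma5=0, gamma6=0, gamma7=0,
                         max_outer=8, max_inner=50, tol_residual=1e-7, seed=0)
        result = fit(cohort, hp, standardize=False)
        for W, X in zip(result.state.W, cohort.histories):
            svd_basis = np.linalg.svd(X, full_matrices=False)[0][:, :3]
            assert subspace_angles(W, svd_basis).max() <= 1e-3

    def test_frozen_identity_weights_give_classical_pca(self):
        """With D2,i = I and the other terms off, the converged projector
        equals the top-r1 PCA projector."""
        cfg = SimConfig(
            n=8, l=6, d_per_modality={"M": 8}, d_snp=10, K=2, c=2,
            r1_true=3, r2_true=2, active_group_count=2,
            noise_sd_imaging=0.2, noise_sd_snp=0.1, noise_sd_labels=0.1,
            visit_count_range=(5, 7), seed=13,   # every history has rank >= r1
        )
        cohort, _ = simulate_cohort(cfg)
        hp = Hyperparams(r1=3, r2=2, gamma1=1.0, gamma2=0, gamma3=0,
                         gamma4=0, gamma5=0, gamma6=0, gamma7=0, seed=0)
        st = init_state(cohort, hp)
        w = reweight(st, cohort, hp.delta)
        for di in w.d2:
            di[:] = 1.0                      # freeze to identity
        for _ in range(300):
            _sweep_inplace(st, cohort, hp, w)
            _multipliers_inplace(st, hp, cohort)
        for W, X in zip(st.W, cohort.histories):
            P = W @ np.linalg.solve(W.T @ W, W.T)
            U3 = np.linalg.svd(X, full_matrices=False)[0][:, :3]
            assert np.linalg.norm(P - U3 @ U3.T) <= 1e-6

    def test_semi_supervision_labels_influence_predictions(self, small_sim, small_hp):
        cohort, _ = small_sim
        res_a = fit(cohort, small_hp)
        perturbed = cohort.copy()
        perturbed.labels = perturbed.labels + 1.0
        res_b = fit(perturbed, small_hp)
        l = cohort.n_labeled
        assert not np.allclose(res_a.state.F[:, l:], res_b.state.F[:, l:])

    def test_deterministic(self, small_sim, small_hp):
        cohort, _ = small_sim
        a = fit(cohort, small_hp)
        b = fit(cohort, small_hp)
        np.testing.assert_array_equal(a.Z, b.Z)
        assert a.objective_history == b.objective_history

    def test_standardization_recorded(self, small_sim, small_hp):
        cohort, _ = small_sim
        res = fit(cohort, small_hp, standardize=True)
        assert res.standardization is not None
        assert res.standardization["imaging_mean"].shape == (cohort.d,)
        res2 = fit(cohort, small_hp, standardize=False)
        assert res2.standardization is None


class TestInnerLoopProperties:
    def test_sweep_descends_admm_objective(self):
        cohort, hp, st, w = _tiny_instance()
        before = admm_objective(st, cohort, hp, w)
        _sweep_inplace(st, cohort, hp, w)
        after = admm_objective(st, cohort, hp, w)
        assert after <= before + 1e-10 * (1 + abs(before))

    def test_residuals_shrink_with_iterations(self, small_sim, small_hp):
        cohort, _ = small_sim
        std, _ = standardize_cohort(cohort)
        st = init_state(std, small_hp)
        w = reweight(st, std, small_hp.delta)
        _sweep_inplace(st, std, small_hp, w)
        _multipliers_inplace(st, small_hp, std)
        early = max(constraint_residuals(st, std).values())
        for _ in range(40):
            w = reweight(st, std, small_hp.delta)
            _sweep_inplace(st, std, small_hp, w)
            _multipliers_inplace(st, small_hp, std)
        late = max(constraint_residuals(st, std).values())
        assert late < early

    def test_w_step_cost_grows_with_dimension(self):
        """Loose monotone trend: doubling d increases W-step time."""
        import time

        times = []
        for dm in (8, 16):
            cfg = SimConfig(
                n=6, l=4, d_per_modality={"M": dm}, d_snp=8, K=2, c=1,
                r1_true=3, r2_true=2, active_group_count=2,
                visit_count_range=(4, 6), seed=3,
            )
            cohort, _ = simulate_cohort(cfg)
            hp = Hyperparams(r1=3, r2=2, seed=0)
            st = init_state(cohort, hp)
            w = reweight(st, cohort, hp.delta)
            t0 = time.perf_counter()
            for _ in range(30):
                for i in range(st.n):
                    update_block(st, cohort, hp, w, f"W_{i}")
            times.append(time.perf_counter() - t0)
        assert times[1] > times[0]

    def test_outer_fixed_point_tangency(self, small_sim, small_hp):
        """At the final iterate the delta->0 surrogate value approximates
        half the sum of the raw norm terms (IRLS tangency)."""
        from longenrich import eval_smoothed

        cohort, _ = small_sim
        result = fit(cohort, small_hp, standardize=False)
        st = result.state
        st.A = st.U.copy()
        for i in range(st.n):
            st.B[i] = st.W[i].copy()
        w = reweight(st, cohort, delta=1e-12)
        terms = eval_objective(st, cohort, small_hp)
        assert eval_smoothed(st, cohort, small_hp, w) == pytest.approx(
            0.5 * terms.total, rel=1e-5)
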