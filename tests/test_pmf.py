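"""Robust weighted factorization: solver correctness, diagnostics,
fingerprints, factor matching and bootstrap."""

import itertools

import numpy as np
import pandas as pd
import pytest

from streampulse.pmf import (
    BootstrapResult,
    PMFConfig,
    RobustPMF,
    bootstrap,
    detect_elbow,
    fingerprints,
    fit_multi,
    fit_single,
    match_factors,
    per_species_fit,
    q_expected,
    scan_factor_numbers,
)


def _random_instance(rng, n=30, m=5, p=2, noise=0.0):
    G = rng.uniform(0.1, 1.0, (n, p))
    F = rng.uniform(0.1, 1.0, (p, m))
    X = G @ F
    if noise:
        X = np.clip(X + rng.normal(0, noise, X.shape), 1e-9, None)
    return X, G, F


class TestQExpected:
    @pytest.mark.parametrize(
        "n,m,p,expected",
        [(2560, 14, 6, 20_396), (10, 4, 2, 12), (100, 10, 0, 1000)],
    )
    def test_arithmetic(self, n, m, p, expected):
        assert q_expected(n, m, p) == expected

    def test_overparameterized_rejected(self):
        with pytest.raises(ValueError, match="over-parameterized"):
            q_expected(10, 4, 3)  # 40 - 42 < 0


class TestFit:
    def test_noiseless_exact_factorization(self):
        rng = np.random.default_rng(0)
        X, _, _ = _random_instance(rng, n=40, m=6, p=3)
        U = np.ones_like(X)
        est = RobustPMF(n_components=3, n_runs=5, random_state=0).fit(X, U)
        assert est.q_robust_ / X.size < 1e-6
        C = est.contributions_ @ est.components_
        assert np.abs(C - X).max() / X.max() < 1e-3
        assert (est.components_ >= 0).all() and (est.contributions_ >= 0).all()

    def test_rank_one_recovers_profile_direction(self):
        rng = np.random.default_rng(1)
        g = rng.uniform(0.5, 2.0, 50)
        f = rng.uniform(0.5, 2.0, 7)
        X = np.outer(g, f)
        est = RobustPMF(n_components=1, n_runs=3, random_state=1).fit(
            X, np.ones_like(X)
        )
        prof = est.components_[0]
        cos = prof @ f / (np.linalg.norm(prof) * np.linalg.norm(f))
        assert cos > 0.9999

    def test_best_of_20_matches_brute_force_multistart(self):
        rng = np.random.default_rng(2)
        for _ in range(3):
            X, _, _ = _random_instance(rng, noise=0.05)
            U = np.full_like(X, 0.05)
            q20 = RobustPMF(n_components=2, n_runs=20, random_state=7).fit(X, U).q_robust_
            q200 = (
                RobustPMF(n_components=2, n_runs=200, random_state=900).fit(X, U).q_robust_
            )
            assert q20 <= q200 * 1.01

    def test_objective_descent_across_restarts_scales(self):
        """Scale ambiguity: multiplying U by a global constant scales Q by
        its inverse square but leaves the fit C unchanged."""
        rng = np.random.default_rng(3)
        X, _, _ = _random_instance(rng, noise=0.02)
        U = np.full_like(X, 0.05)
        # plain weighted fit: the robust cap is an absolute |e/u| threshold,
        # so only the unrobust objective is exactly scale-equivariant
        e1 = RobustPMF(n_components=2, n_runs=2, robust_passes=1, random_state=5).fit(X, U)
        e2 = RobustPMF(n_components=2, n_runs=2, robust_passes=1, random_state=5).fit(X, 2.0 * U)
        np.testing.assert_allclose(e1.q_true_, 4.0 * e2.q_true_, rtol=1e-6)
        C1 = e1.contributions_ @ e1.components_
        C2 = e2.contributions_ @ e2.components_
        np.testing.assert_allclose(C1, C2, rtol=1e-6)

    def test_seed_determinism(self):
        rng = np.random.default_rng(4)
        X, _, _ = _random_instance(rng, noise=0.02)
        U = np.full_like(X, 0.05)
        e1 = RobustPMF(n_components=2, n_runs=3, random_state=11).fit(X, U)
        e2 = RobustPMF(n_components=2, n_runs=3, random_state=11).fit(X, U)
        np.testing.assert_array_equal(e1.components_, e2.components_)
        np.testing.assert_array_equal(e1.contributions_, e2.contributions_)

    def test_robust_mode_caps_outlier_influence(self):
        rng = np.random.default_rng(5)
        X, G, F = _random_instance(rng, n=60, m=6, p=2)
        U = np.full_like(X, 0.02)
        X_spiked = X.copy()
        X_spiked[7, 3] += 5.0  # gross outlier, |e/u| >> 4
        est = RobustPMF(n_components=2, n_runs=3, random_state=0).fit(X_spiked, U)
        assert est.outlier_mask_[7, 3]
        assert est.q_robust_ < est.q_true_
        # the outlier cell is excluded, so the rest is still fit well
        resid = np.abs(est.contributions_ @ est.components_ - X)
        mask = np.ones_like(X, bool)
        mask[7, 3] = False
        assert resid[mask].max() < 0.05

    def test_invalid_inputs_rejected(self):
        X = np.abs(np.random.default_rng(0).normal(1, 0.1, (10, 4)))
        with pytest.raises(ValueError, match="uncertaint"):
            RobustPMF(n_components=2).fit(X, -np.ones_like(X))
        with pytest.raises(ValueError, match="n_components"):
            RobustPMF(n_components=4, n_runs=1).fit(X, np.ones_like(X))

    def test_transform_recovers_contributions(self):
        rng = np.random.default_rng(6)
        X, G, F = _random_instance(rng, n=40, m=6, p=2)
        est = RobustPMF(n_components=2, n_runs=3, random_state=2).fit(
            X, np.ones_like(X)
        )
        G_new = est.transform(X)
        np.testing.assert_allclose(G_new @ est.components_, X, atol=1e-4)


class TestFitMulti:
    def test_n_runs_one_equals_fit_single(self):
        rng = np.random.default_rng(7)
        X, _, _ = _random_instance(rng, noise=0.02)
        U = np.full_like(X, 0.05)
        m1 = fit_single(X, U, p=2, seed=3)
        m2, stab = fit_multi(X, U, p=2, cfg=PMFConfig(p=2, n_runs=1, seed=3))
        np.testing.assert_array_equal(m1.F.to_numpy(), m2.F.to_numpy())
        assert stab["relative_spread"] == 0.0

    def test_noiseless_runs_all_reach_zero(self):
        rng = np.random.default_rng(8)
        X, _, _ = _random_instance(rng, n=40, m=6, p=3)
        U = np.ones_like(X)
        model, stab = fit_multi(X, U, p=3, cfg=PMFConfig(p=3, n_runs=5, seed=0))
        assert (stab["q_robust_runs"] / X.size < 1e-6).all()


class TestScan:
    def test_noiseless_rank3_elbow(self):
        rng = np.random.default_rng(9)
        X, _, _ = _random_instance(rng, n=60, m=8, p=3)
        U = np.ones_like(X)
        scan = scan_factor_numbers(X, U, PMFConfig(n_runs=3, p_scan=(1, 6), seed=1))
        q = scan.set_index("p")["q_robust"]
        assert q[2] / q[3] > 1e6  # orders of magnitude drop up to p=3
        assert detect_elbow(scan) == 3

    def test_q_robust_nonincreasing_in_p(self):
        rng = np.random.default_rng(10)
        X, _, _ = _random_instance(rng, n=40, m=7, p=3, noise=0.05)
        U = np.full_like(X, 0.05)
        scan = scan_factor_numbers(X, U, PMFConfig(n_runs=4, p_scan=(1, 5), seed=2))
        q = scan["q_robust"].to_numpy()
        # nested model class: allow only multi-start noise violations
        assert (q[1:] <= q[:-1] * 1.01).all()


class TestFingerprints:
    def test_single_factor_is_all_100(self):
        F = pd.DataFrame([[3.0, 1.0, 2.0]], index=["F1"], columns=list("abc"))
        tab = fingerprints(F)
        assert (tab.percent.loc["F1"] == 100.0).all()

    def test_split_column_and_inclusive_cutoff(self):
        F = pd.DataFrame(
            [[3.0], [1.0]], index=["F1", "F2"], columns=["a"]
        )
        tab = fingerprints(F, cutoff_percent=25.0)
        np.testing.assert_allclose(tab.percent["a"], [75.0, 25.0])
        assert len(tab.filtered_pairs) == 2  # boundary 25% is kept

    def test_dominant_share_survives_filter(self):
        F = pd.DataFrame(
            [[99.0, 50.0], [1.0, 50.0]], index=["F1", "F2"], columns=["a", "b"]
        )
        tab = fingerprints(F)
        pairs = {(k, j) for k, j, _ in tab.filtered_pairs}
        assert ("F1", "a") in pairs and ("F2", "a") not in pairs

    def test_zero_profile_species_flagged(self):
        F = pd.DataFrame(
            [[1.0, 0.0], [1.0, 0.0]], index=["F1", "F2"], columns=["a", "b"]
        )
        tab = fingerprints(F)
        assert tab.undefined_species == ["b"]
        assert tab.percent["b"].isna().all()


class TestPerSpeciesFit:
    def test_perfect_fit_gives_one(self):
        rng = np.random.default_rng(11)
        X = rng.uniform(1, 10, (20, 4))
        r2, mean = per_species_fit(X, X)
        np.testing.assert_allclose(r2, 1.0)
        assert mean == 1.0

    def test_constant_prediction_gives_zero(self):
        rng = np.random.default_rng(12)
        X = rng.uniform(1, 10, (50, 3))
        C = np.tile(X.mean(axis=0), (50, 1))
        r2, _ = per_species_fit(C, X)
        np.testing.assert_allclose(r2, 0.0, atol=1e-12)

    def test_zero_variance_species_flagged_nan(self):
        X = np.column_stack([np.full(10, 5.0), np.arange(10.0)])
        C = X * 0.9
        r2, mean = per_species_fit(C, X)
        assert np.isnan(r2[0]) and np.isfinite(r2[1])
        assert np.isfinite(mean)


class TestMatchFactors:
    def test_permuted_scaled_truth_matches_exactly(self):
        rng = np.random.default_rng(13)
        F = rng.uniform(0, 1, (4, 9))
        perm_true = np.array([2, 0, 3, 1])
        F_est = F[perm_true] * rng.uniform(0.5, 5.0, (4, 1))
        perm, cos = match_factors(F_est, F)
        np.testing.assert_array_equal(perm, perm_true)
        np.testing.assert_allclose(cos, 1.0)

    def test_agrees_with_exhaustive_assignment(self):
        rng = np.random.default_rng(14)
        F = np.eye(5)[:, :5] + rng.uniform(0, 0.05, (5, 5))  # near-orthogonal
        F_est = F + rng.normal(0, 0.02, F.shape)
        perm, cos = match_factors(F_est, F)
        # brute force over all 5! permutations
        S = (F_est / np.linalg.norm(F_est, axis=1, keepdims=True)) @ (
            F / np.linalg.norm(F, axis=1, keepdims=True)
        ).T
        best = max(
            itertools.permutations(range(5)),
            key=lambda p: sum(S[i, p[i]] for i in range(5)),
        )
        np.testing.assert_array_equal(perm, np.array(best))

    def test_single_factor_identity(self):
        F = np.array([[1.0, 2.0, 3.0]])
        perm, cos = match_factors(F, F)
        assert perm[0] == 0 and cos[0] == pytest.approx(1.0)

    def test_partial_matching_with_unequal_counts(self):
        rng = np.random.default_rng(15)
        F_true = rng.uniform(0, 1, (3, 6))
        F_est = F_true[:2]
        perm, cos = match_factors(F_est, F_true)
        assert (perm >= 0).all() and len(perm) == 2
        perm2, cos2 = match_factors(F_true, F_est)
        assert (perm2 == -1).sum() == 1 and np.isnan(cos2).sum() == 1


class TestBootstrap:
    def _fitted(self, rng, noise=0.0):
        X, G, F = _random_instance(rng, n=60, m=6, p=2, noise=noise)
        U = np.full_like(X, max(noise, 0.05))
        cfg = PMFConfig(p=2, n_runs=3, seed=0, bootstrap_reps=20, bootstrap_block=10)
        model, _ = fit_multi(X, U, 2, cfg)
        return X, U, model, cfg

    def test_zero_reps_gives_empty_result(self):
        rng = np.random.default_rng(16)
        X, U, model, cfg = self._fitted(rng)
        cfg.bootstrap_reps = 0
        res = bootstrap(X, U, model, cfg)
        assert isinstance(res, BootstrapResult) and res.n_reps == 0

    def test_noiseless_input_fully_mapped_with_tight_intervals(self):
        rng = np.random.default_rng(17)
        X, U, model, cfg = self._fitted(rng, noise=0.0)
        res = bootstrap(X, U, model, cfg)
        assert (res.mapping_rate == 1.0).all()
        width = (res.profile_q75 - res.profile_q25).to_numpy()
        scale = model.F.to_numpy().max()
        assert width.max() / scale < 0.05

    def test_moderate_noise_mapping_rate(self):
        rng = np.random.default_rng(18)
        X, U, model, cfg = self._fitted(rng, noise=0.03)
        res = bootstrap(X, U, model, cfg)
        assert (res.mapping_rate >= 0.8).all()
        assert res.unmapped_fraction <= 0.2
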