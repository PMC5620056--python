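"""Scale-weight optimizer: kernels, alternating updates, selection rule."""

import numpy as np
import pytest
from scipy.linalg import solve_triangular

from discrn.features import extract_gabor
from discrn.learning import (
    DistanceKernels,
    NonDiscriminativeError,
    assemble_kernels,
    build_distance_kernels,
    learn_scale_weights,
    reformulation_objective,
    select_scales,
    snnls_bpp,
    solve_w,
    update_a,
)
from discrn.phantoms import generate_kernel_fixture
from discrn.types import Family, MultiScaleFeatureSet, ScaleGrid

import oracles


def _toy_sets(rng, n_pos=4, n_neg=3, S=3, d=5, slice_ids_pos=None, slice_ids_neg=None):
    grid = ScaleGrid(tuple(range(3, 3 + 2 * S, 2)))
    mk = lambda n, sid: MultiScaleFeatureSet(
        Family.HARALICK, grid, rng.normal(size=(n, S, d)),
        np.zeros((n, 2)), slice_ids=sid)
    return (mk(n_pos, slice_ids_pos), mk(n_neg, slice_ids_neg))


class TestKernelConstruction:
    def test_exhaustive_pair_counts(self, rng):
        pos, neg = _toy_sets(rng, n_pos=2, n_neg=1)
        k = build_distance_kernels(pos, neg, pairs_per_slice=10**6)
        assert k.H_p.shape[1] == 1  # one within-positive pair
        assert k.H_b.shape[1] == 2  # two positive x negative pairs

    def test_gram_matches_double_sum(self, rng):
        pos, neg = _toy_sets(rng, n_pos=5, n_neg=4)
        k = build_distance_kernels(pos, neg, pairs_per_slice=10**6)
        S_p = sum(np.outer(h, h) for h in k.H_p.T)
        S_b = sum(np.outer(h, h) for h in k.H_b.T)
        assert np.abs(k.S_p - S_p).max() < 1e-10
        assert np.abs(k.S_b - S_b).max() < 1e-10

    def test_cholesky_identity_and_psd(self, rng):
        pos, neg = _toy_sets(rng, n_pos=6, n_neg=5)
        k = build_distance_kernels(pos, neg)
        recon = k.R_p.T @ k.R_p - (k.S_p + k.ridge * np.eye(k.n_scales))
        assert np.abs(recon).max() < 1e-8
        assert np.all(np.linalg.eigvalsh(k.S_p) > -1e-10)
        assert np.all(np.linalg.eigvalsh(k.S_b) > -1e-10)

    def test_identical_positives_degenerate(self, rng):
        grid = ScaleGrid((3, 5, 7))
        desc = np.tile(rng.normal(size=(1, 3, 5)), (4, 1, 1))
        pos = MultiScaleFeatureSet(Family.GABOR, grid, desc, np.zeros((4, 2)))
        neg = MultiScaleFeatureSet(Family.GABOR, grid,
                                   rng.normal(size=(3, 3, 5)), np.zeros((3, 2)))
        k = build_distance_kernels(pos, neg)
        assert np.allclose(k.H_p, 0.0) and np.allclose(k.S_p, 0.0)
        assert np.all(np.isfinite(k.R_p))  # ridge keeps the factor defined

    def test_single_positive_per_slice_rejected(self, rng):
        pos, neg = _toy_sets(rng, n_pos=2, n_neg=2,
                             slice_ids_pos=[0, 1], slice_ids_neg=[0, 1])
        with pytest.raises(ValueError):
            build_distance_kernels(pos, neg)

    def test_per_slice_pairing_and_determinism(self, rng):
        pos, neg = _toy_sets(rng, n_pos=8, n_neg=8,
                             slice_ids_pos=[0] * 4 + [1] * 4,
                             slice_ids_neg=[0] * 4 + [1] * 4)
        k1 = build_distance_kernels(pos, neg, pairs_per_slice=3, seed=9)
        k2 = build_distance_kernels(pos, neg, pairs_per_slice=3, seed=9)
        assert np.array_equal(k1.H_p, k2.H_p) and np.array_equal(k1.H_b, k2.H_b)
        assert k1.H_p.shape[1] == 6 and k1.H_b.shape[1] == 6  # 3 per slice
        assert set(np.unique(k1.slice_ids_b)) == {0, 1}


def _identity_kernels(S_p_scale=1.0):
    S = 3
    return DistanceKernels(
        H_p=np.sqrt(S_p_scale) * np.eye(S), H_b=np.eye(S),
        S_p=S_p_scale * np.eye(S), S_b=np.eye(S),
        R_p=np.sqrt(S_p_scale) * np.eye(S), ridge=0.0,
    )


class TestUpdateA:
    def test_identity_kernels(self):
        a = update_a(_identity_kernels(), np.array([1.0, 0.0, 0.0]))
        np.testing.assert_allclose(a, [1.0, 0.0, 0.0], atol=1e-12)

    def test_scaled_whitening(self):
        # S_p = 4I so R_p = 2I; printed formula halves the coefficient
        a = update_a(_identity_kernels(4.0), np.array([1.0, 0.0, 0.0]))
        np.testing.assert_allclose(a, [0.5, 0.0, 0.0], atol=1e-12)

    def test_matches_triangular_solve_oracle(self, rng):
        for _ in range(100):
            S = int(rng.integers(2, 6))
            B = rng.normal(size=(S, S + 2))
            S_p = B @ B.T + 0.5 * np.eye(S)
            C = rng.normal(size=(S, S + 2))
            S_b = C @ C.T
            w = rng.uniform(0.1, 1.0, size=S)
            k = DistanceKernels(H_p=B, H_b=C, S_p=S_p, S_b=S_b,
                                R_p=np.linalg.cholesky(S_p).T, ridge=0.0)
            got = update_a(k, w)
            want = oracles.a_update_oracle(S_p, S_b, w)
            np.testing.assert_allclose(got, want, atol=1e-10)

    def test_zero_between_class_signal_raises(self):
        k = _identity_kernels()
        k.S_b = np.zeros((3, 3))
        with pytest.raises(NonDiscriminativeError):
            update_a(k, np.ones(3) / 3)


class TestSolveW:
    def test_scalar_closed_form(self, rng):
        # S = 1, no regularization: w = max(0, least-squares coefficient)
        for sign in (+1.0, -1.0):
            H_b = np.array([[1.0, 2.0, 3.0]])
            k = assemble_kernels(np.array([[1.0, 1.0]]), H_b)
            a = np.array([sign * 2.0])
            w = solve_w(k, a, alpha=0.0, eta=0.0)
            z = solve_triangular(k.R_p, a, lower=False)
            x = H_b[0]
            expected = max(0.0, float(x @ (x * z[0]) / (x @ x)))
            assert w[0] == pytest.approx(expected, abs=1e-8)

    def test_large_eta_gives_exact_zero(self, rng):
        k = generate_kernel_fixture(3, 1, 3.0, 50, seed=0)
        a = update_a(k, np.ones(3) / 3)
        z = solve_triangular(k.R_p, a, lower=False)
        grad0 = -2.0 * (k.S_b @ z)  # gradient at w = 0 without the l1 term
        eta = float(np.max(np.abs(grad0))) * 1.01
        w = solve_w(k, a, alpha=0.0, eta=eta)
        assert np.all(w == 0.0)

    def test_kkt_residual(self, rng):
        for seed in range(20):
            k = generate_kernel_fixture(4, 2, 2.0, 100, seed=seed)
            a = update_a(k, np.ones(4) / 4)
            w = solve_w(k, a)
            z = solve_triangular(k.R_p, a, lower=False)
            g = 2.0 * (k.S_b + 0.1 * np.eye(4)) @ w + 0.001 - 2.0 * k.S_b @ z
            assert np.all(g >= -1e-8)
            assert np.abs(w * g).max() < 1e-8

    def test_matches_enumeration_oracle(self, rng):
        for seed in range(50):
            r = np.random.default_rng(seed)
            S = int(r.integers(1, 4))
            H_p = np.abs(r.normal(1, 0.3, size=(S, 10)))
            H_b = np.abs(r.normal(1.5, 0.5, size=(S, 10)))
            k = assemble_kernels(H_p, H_b)
            a = r.normal(size=S)
            alpha, eta = 0.1, 0.001
            w = solve_w(k, a, alpha=alpha, eta=eta)
            z = solve_triangular(k.R_p, a, lower=False)
            Q = 2.0 * (k.S_b + alpha * np.eye(S))
            c = eta * np.ones(S) - 2.0 * k.S_b @ z
            _, best = oracles.nonneg_qp_enumeration_oracle(Q, c)
            got = 0.5 * w @ Q @ w + c @ w
            assert got <= best + 1e-6


class TestLearnScaleWeights:
    def test_planted_scale_recovery(self):
        hits = sum(
            np.argmax(learn_scale_weights(
                generate_kernel_fixture(3, 1, 5.0, 500, seed=s)).w) == 1
            for s in range(20)
        )
        assert hits >= 18

    def test_unit_norm_and_nonnegativity(self):
        sw = learn_scale_weights(generate_kernel_fixture(4, 0, 3.0, 200, seed=3))
        assert np.all(sw.w >= 0)
        assert np.linalg.norm(sw.w) == pytest.approx(1.0, abs=1e-12)
        assert np.argmax(sw.w) in sw.selected

    def test_permutation_equivariance(self):
        k = generate_kernel_fixture(3, 1, 4.0, 300, seed=7)
        perm = [2, 0, 1]
        kp = assemble_kernels(k.H_p[perm], k.H_b[perm])
        w = learn_scale_weights(k).w
        wp = learn_scale_weights(kp).w
        np.testing.assert_allclose(wp, w[perm], atol=1e-12)

    def test_objective_descent_with_normalized_a(self):
        for seed in range(10):
            k = generate_kernel_fixture(4, 2, 3.0, 400, seed=seed)
            sw = learn_scale_weights(k, normalize_a=True)
            h = np.asarray(sw.objective_history)
            if len(h) > 1:
                assert np.all(np.diff(h) <= 1e-9)

    def test_sparsity_path_near_monotone(self):
        violations = 0
        for seed in range(100):
            k = generate_kernel_fixture(5, 2, 2.0, 200, seed=seed)
            n_lo = int((learn_scale_weights(k, eta=0.001).w > 1e-10).sum())
            n_hi = int((learn_scale_weights(k, eta=0.05).w > 1e-10).sum())
            violations += n_hi > n_lo
        assert violations <= 5

    def test_exchangeable_scales_distribution(self):
        """gap = 1 makes scales exchangeable: no scale is preferred in
        distribution (the per-realization solution may still concentrate,
        since the whitened discriminant ratio is flat)."""
        ws = np.array([
            learn_scale_weights(generate_kernel_fixture(3, 1, 1.0, 500, seed=s)).w
            for s in range(60)
        ])
        mean_w = ws.mean(axis=0)
        assert mean_w.max() - mean_w.min() < 0.25
        assert len(np.unique(ws.argmax(axis=1))) == 3

    def test_uniform_fallback_when_nothing_discriminates(self):
        k = _identity_kernels()
        k.S_b = np.zeros((3, 3))
        k.H_b = np.zeros((3, 2))
        sw = learn_scale_weights(k)
        assert sw.fallback_uniform
        np.testing.assert_allclose(sw.w, np.full(3, 1 / np.sqrt(3)))

    def test_json_round_trip(self):
        sw = learn_scale_weights(generate_kernel_fixture(3, 2, 4.0, 200, seed=1),
                                 scale_sizes=(3, 5, 7))
        back = type(sw).from_json(sw.to_json(family="gabor"))
        np.testing.assert_allclose(back.w, sw.w)
        assert back.selected == sw.selected
        assert back.selected_sizes == sw.selected_sizes


class TestSelectScales:
    def test_threshold_rule(self):
        assert select_scales(np.array([0.5, 0.1, 0.4]), 0.3) == (0, 2)

    def test_uniform_selects_all(self):
        assert select_scales(np.ones(4) / 2.0, 0.99) == (0, 1, 2, 3)

    def test_monotone_in_sigma(self, rng):
        w = rng.uniform(size=6)
        prev = None
        for sigma in (0.9, 0.6, 0.3, 0.1):
            sel = set(select_scales(w, sigma))
            if prev is not None:
                assert prev <= sel
            prev = sel

    @pytest.mark.parametrize("sigma", [0.0, 1.0, -0.5])
    def test_invalid_sigma(self, sigma):
        with pytest.raises(ValueError):
            select_scales(np.array([1.0, 0.5]), sigma)

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            select_scales(np.zeros(3), 0.3)


class TestObjectiveConsistency:
    def test_reformulation_objective_matches_direct(self, rng):
        k = generate_kernel_fixture(3, 1, 3.0, 50, seed=2)
        a = update_a(k, np.ones(3) / 3)
        w = solve_w(k, a)
        got = reformulation_objective(k, a, w, alpha=0.1, eta=0.001)
        M = k.H_b.T @ np.linalg.inv(k.R_p)
        direct = (np.linalg.norm(M - np.outer(k.H_b.T @ w, a)) ** 2
                  + 0.1 * w @ w + 0.001 * np.abs(w).sum())
        assert got == pytest.approx(direct, rel=1e-10)
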