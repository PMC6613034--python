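"""MAP decomposition core: weights, energy, IRLS solve, baselines."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from virtdes.config import DecompositionConfig
from virtdes.decompose import (ExemplarSet, compute_prior_weights, energy,
                               initialize_solution, irls_step, map_decompose,
                               weighted_regression_baseline)
from virtdes.matching import CorrespondenceField


def identity_field(H, W):
    return CorrespondenceField(T=np.zeros((H, W, 2), np.int32),
                               cost=np.zeros((H, W)))


def random_small_field(rng, H, W, r=3):
    dy = rng.integers(-r, r + 1, size=(H, W))
    dx = rng.integers(-r, r + 1, size=(H, W))
    ys = np.arange(H)[:, None]
    xs = np.arange(W)[None, :]
    dy = np.clip(dy, -ys, H - 1 - ys)
    dx = np.clip(dx, -xs, W - 1 - xs)
    return CorrespondenceField(T=np.stack([dy, dx], -1).astype(np.int32),
                               cost=np.zeros((H, W)))


def make_exemplars(rng, H, W, M, fields=None):
    if fields is None:
        fields = [random_small_field(rng, H, W) for _ in range(M)]
    return ExemplarSet(S=[rng.standard_normal((H, W)) for _ in range(M)],
                       B=[rng.standard_normal((H, W)) for _ in range(M)],
                       fields=fields)


def energy_oracle(S, B, Y, ex, cfg):
    """Naive triple-loop evaluation of the decomposition energy."""
    p = cfg.patch_size
    p2 = p // 2
    H, W = Y.shape
    E = cfg.lambda_ * ((Y - S - B) ** 2).sum()
    for img, layers, eta in ((S, ex.S, cfg.eta_S), (B, ex.B, cfg.eta_B_)):
        for cy in range(p2, H - p2):
            for cx in range(p2, W - p2):
                vals = []
                for i in range(ex.M):
                    T = ex.fields[i].T
                    my = min(max(cy + T[cy, cx, 0], p2), H - 1 - p2)
                    mx = min(max(cx + T[cy, cx, 1], p2), W - 1 - p2)
                    e = 0.0
                    for oy in range(-p2, p2 + 1):
                        for ox in range(-p2, p2 + 1):
                            d = img[cy + oy, cx + ox] - \
                                layers[i][my + oy, mx + ox]
                            e += d * d
                    vals.append(-eta * e)
                m = max(vals)
                E += -(m + np.log(sum(np.exp(v - m) for v in vals)))
    return E


class TestPriorWeights:
    def test_softmax_of_hand_set_errors(self):
        e = np.array([0.0, 1.0, 2.0])
        w = np.exp(-e) / np.exp(-e).sum()
        # build M=3 exemplars whose patch errors are exactly (0, 1, 2)
        H = W = 3
        cur = np.zeros((H, W))
        imgs = [np.full((H, W), np.sqrt(v / 9.0)) for v in e]
        flds = [identity_field(H, W)] * 3
        got = compute_prior_weights(cur, imgs, flds, eta=1.0, patch_size=3)
        assert np.allclose(got[:, 0, 0], w, atol=1e-12)

    def test_equal_errors_give_uniform_weights(self, rng):
        H = W = 8
        cur = rng.standard_normal((H, W))
        img = rng.standard_normal((H, W))
        got = compute_prior_weights(cur, [img, img.copy(), img.copy()],
                                    [identity_field(H, W)] * 3,
                                    eta=0.7, patch_size=3)
        assert np.allclose(got, 1.0 / 3.0, atol=1e-12)

    def test_eta_limits(self, rng):
        H = W = 8
        cur = rng.standard_normal((H, W))
        imgs = [rng.standard_normal((H, W)) for _ in range(4)]
        flds = [identity_field(H, W)] * 4
        w0 = compute_prior_weights(cur, imgs, flds, eta=1e-12, patch_size=3)
        assert np.allclose(w0, 0.25, atol=1e-9)
        w1 = compute_prior_weights(cur, imgs, flds, eta=1e6, patch_size=3)
        assert np.allclose(w1.max(axis=0), 1.0, atol=1e-9)  # one-hot

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.floats(1e-4, 10.0))
    def test_weights_sum_to_one(self, seed, eta):
        rng = np.random.default_rng(seed)
        H = W = 7
        cur = rng.standard_normal((H, W))
        imgs = [rng.standard_normal((H, W)) for _ in range(3)]
        flds = [random_small_field(rng, H, W) for _ in range(3)]
        w = compute_prior_weights(cur, imgs, flds, eta=eta, patch_size=3)
        assert np.allclose(w.sum(axis=0), 1.0, atol=1e-12)


class TestEnergy:
    def test_zero_at_perfectly_explained_solution(self, rng):
        H = W = 10
        S = rng.standard_normal((H, W))
        B = rng.standard_normal((H, W))
        ex = ExemplarSet(S=[S.copy()], B=[B.copy()],
                         fields=[identity_field(H, W)])
        cfg = DecompositionConfig(M=1, patch_size=3)
        eb = energy(S, B, S + B, ex, cfg)
        assert eb.E_data == pytest.approx(0.0, abs=1e-20)
        assert abs(eb.E_prior_S) < 1e-12 and abs(eb.E_prior_B) < 1e-12

    def test_lambda_scales_data_term_exactly(self, rng):
        H = W = 8
        ex = make_exemplars(rng, H, W, 2)
        Y = rng.standard_normal((H, W))
        S = rng.standard_normal((H, W))
        B = rng.standard_normal((H, W))
        e1 = energy(S, B, Y, ex, DecompositionConfig(lambda_=1.0, M=2,
                                                     patch_size=3))
        e7 = energy(S, B, Y, ex, DecompositionConfig(lambda_=7.0, M=2,
                                                     patch_size=3))
        assert e7.E_data == pytest.approx(7.0 * e1.E_data, rel=1e-12)
        assert e7.E_prior_S == pytest.approx(e1.E_prior_S, rel=1e-12)

    def test_matches_triple_loop_oracle(self, rng):
        H = W = 8
        ex = make_exemplars(rng, H, W, 2)
        cfg = DecompositionConfig(lambda_=3.0, eta_S=0.2, M=2, patch_size=3)
        Y = rng.standard_normal((H, W))
        S = rng.standard_normal((H, W))
        B = rng.standard_normal((H, W))
        eb = energy(S, B, Y, ex, cfg)
        assert eb.E_total == pytest.approx(energy_oracle(S, B, Y, ex, cfg),
                                           abs=1e-9)
        assert eb.E_total == pytest.approx(
            eb.E_data + eb.E_prior_S + eb.E_prior_B, rel=1e-12)


class TestIrls:
    def test_surrogate_and_energy_decrease(self, rng):
        H = W = 12
        ex = make_exemplars(rng, H, W, 3)
        cfg = DecompositionConfig(lambda_=5.0, eta_S=0.3, M=3, patch_size=3)
        Y = rng.standard_normal((H, W))
        S0, B0 = initialize_solution(Y, ex, cfg)
        e0 = energy(S0, B0, Y, ex, cfg).E_total
        S1, B1 = irls_step(S0, B0, Y, ex, cfg)
        e1 = energy(S1, B1, Y, ex, cfg).E_total
        assert e1 <= e0 + 1e-9 * abs(e0)

    def test_large_lambda_forces_additivity(self, rng):
        H = W = 10
        ex = make_exemplars(rng, H, W, 2)
        Y = rng.standard_normal((H, W))
        cfg = DecompositionConfig(lambda_=1e9, eta_S=0.1, M=2, patch_size=3)
        S, B = initialize_solution(Y, ex, cfg)
        assert np.abs(Y - S - B).max() < 1e-6

    def test_scalar_system_matches_symbolic_inverse(self, rng):
        # patch 1, M = 1, identity field: per-pixel 2x2 solved by hand
        H = W = 6
        Sx = rng.standard_normal((H, W))
        Bx = rng.standard_normal((H, W))
        ex = ExemplarSet(S=[Sx], B=[Bx], fields=[identity_field(H, W)])
        cfg = DecompositionConfig(lambda_=2.0, eta_S=0.5, eta_B=0.8, M=1,
                                  patch_size=1)
        Y = rng.standard_normal((H, W))
        S, B = irls_step(rng.standard_normal((H, W)),
                         rng.standard_normal((H, W)), Y, ex, cfg)
        lam, aS, aB = 2.0, 0.5, 0.8
        det = (lam + aS) * (lam + aB) - lam * lam
        S_ref = ((lam + aB) * (lam * Y + aS * Sx) -
                 lam * (lam * Y + aB * Bx)) / det
        B_ref = ((lam + aS) * (lam * Y + aB * Bx) -
                 lam * (lam * Y + aS * Sx)) / det
        assert np.allclose(S, S_ref, atol=1e-12)
        assert np.allclose(B, B_ref, atol=1e-12)

    def test_update_matches_dense_quadratic_oracle(self, rng):
        from virtdes.decompose import _patch_errors, _softmax_weights

        H = W = 12
        M = 2
        p = 3
        p2 = 1
        ex = make_exemplars(rng, H, W, M)
        cfg = DecompositionConfig(lambda_=4.0, eta_S=0.25, M=M, patch_size=p)
        Y = rng.standard_normal((H, W))
        S0 = rng.standard_normal((H, W))
        B0 = rng.standard_normal((H, W))
        GS, GB = ex.gathered(p)
        wS = _softmax_weights(_patch_errors(S0, GS, p), cfg.eta_S)
        wB = _softmax_weights(_patch_errors(B0, GB, p), cfg.eta_B_)
        S1, B1 = irls_step(S0, B0, Y, ex, cfg)
        # dense normal equations of the quadratic surrogate
        N = H * W
        lam, aS, aB = cfg.lambda_, cfg.eta_S, cfg.eta_B_
        A = np.zeros((2 * N, 2 * N))
        b = np.zeros(2 * N)
        yflat = Y.ravel()
        for k in range(N):
            A[k, k] += lam
            A[N + k, N + k] += lam
            A[k, N + k] += lam
            A[N + k, k] += lam
            b[k] += lam * yflat[k]
            b[N + k] += lam * yflat[k]
        for w_all, G_all, eta, off in ((wS, GS, aS, 0), (wB, GB, aB, N)):
            for i in range(M):
                for cy in range(p2, H - p2):
                    for cx in range(p2, W - p2):
                        w = w_all[i, cy - p2, cx - p2]
                        for oy in range(-p2, p2 + 1):
                            for ox in range(-p2, p2 + 1):
                                k = (cy + oy) * W + (cx + ox)
                                A[off + k, off + k] += eta * w
                                b[off + k] += eta * w * \
                                    G_all[i, cy - p2, cx - p2, oy + p2,
                                          ox + p2]
        z = np.linalg.solve(A, b)
        assert np.abs(S1.ravel() - z[:N]).max() < 1e-6
        assert np.abs(B1.ravel() - z[N:]).max() < 1e-6


class TestMapDecompose:
    def test_energy_trace_monotone_nonincreasing(self, rng):
        H = W = 16
        ex = make_exemplars(rng, H, W, 3)
        cfg = DecompositionConfig(lambda_=5.0, eta_S=0.4, M=3, patch_size=3,
                                  irls_iters=8, tol=1e-12)
        Y = rng.standard_normal((H, W))
        _, _, trace = map_decompose(Y, ex, cfg)
        E = [t.E_total for t in trace]
        assert len(E) >= 2
        for a, b in zip(E, E[1:]):
            assert b <= a + 1e-9 * abs(a)

    def test_initialize_equals_single_exemplar_step(self, rng):
        H = W = 10
        ex = make_exemplars(rng, H, W, 1)
        cfg = DecompositionConfig(lambda_=3.0, eta_S=0.2, M=1, patch_size=3)
        Y = rng.standard_normal((H, W))
        S0, B0 = initialize_solution(Y, ex, cfg)
        # with M = 1 the weights are identically 1: any step reproduces it
        S1, B1 = irls_step(rng.standard_normal((H, W)),
                           rng.standard_normal((H, W)), Y, ex, cfg)
        assert np.allclose(S0, S1, atol=1e-12)
        assert np.allclose(B0, B1, atol=1e-12)


class TestBaseline:
    def test_single_exemplar_returns_patch_averaged_pullback(self, rng):
        from virtdes.decompose import _coverage, _gather, _scatter

        H = W = 10
        p = 3
        fld = random_small_field(rng, H, W)
        Sx = rng.standard_normal((H, W))
        Bx = rng.standard_normal((H, W))
        ex = ExemplarSet(S=[Sx], B=[Bx], fields=[fld])
        cfg = DecompositionConfig(M=1, patch_size=p)
        S, B = weighted_regression_baseline(rng.standard_normal((H, W)),
                                            ex, cfg)
        w = np.ones((1,) + _gather(Sx, fld, p).shape[:2])
        ref = _scatter(w, _gather(Sx, fld, p)[None], (H, W), p) / \
            _coverage((H, W), p)
        assert np.allclose(S, ref, atol=1e-12)

    def test_identical_exemplars_make_weights_irrelevant(self, rng):
        H = W = 10
        fld = random_small_field(rng, H, W)
        Sx = rng.standard_normal((H, W))
        Bx = rng.standard_normal((H, W))
        c1 = CorrespondenceField(T=fld.T.copy(),
                                 cost=np.zeros((H, W)))
        c2 = CorrespondenceField(T=fld.T.copy(),
                                 cost=rng.uniform(0, 5, (H, W)))
        ex = ExemplarSet(S=[Sx, Sx.copy()], B=[Bx, Bx.copy()],
                         fields=[c1, c2])
        cfg = DecompositionConfig(M=2, patch_size=3, eta_S=0.5)
        Y = rng.standard_normal((H, W))
        S, B = weighted_regression_baseline(Y, ex, cfg)
        ex1 = ExemplarSet(S=[Sx], B=[Bx], fields=[c1])
        S1, B1 = weighted_regression_baseline(Y, ex1,
                                              DecompositionConfig(
                                                  M=1, patch_size=3))
        assert np.allclose(S, S1, atol=1e-12)
        assert np.allclose(B, B1, atol=1e-12)
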