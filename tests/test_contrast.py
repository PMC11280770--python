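"""Proxy partition, sub-view contrastive loss, and nearest-proxy prediction."""

import numpy as np
import pytest

from ebdl.autodiff import Tensor
from ebdl.contrast import (ProxyBank, init_proxies, partition_proxies, predict,
                           predict_batch, scloss, scloss_batch)
from ebdl.representation import EmbeddingSet


def unit(v):
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


class TestPartition:
    def test_single_view_two_classes(self):
        bank = init_proxies(1, 2, 4, seed=0)
        part = partition_proxies(bank, 0, 0)
        assert part.same_view_same_class == (0, 0)
        assert part.same_view_other_classes == [(0, 1)]
        assert part.other_views_same_class == []
        assert part.excluded == []

    def test_two_views_three_classes_counts(self):
        bank = init_proxies(2, 3, 4, seed=0)
        part = partition_proxies(bank, 1, 2)
        assert len(part.same_view_other_classes) == 2
        assert len(part.other_views_same_class) == 1
        assert len(part.excluded) == 2
        groups = ([part.same_view_same_class] + part.same_view_other_classes
                  + part.other_views_same_class + part.excluded)
        assert sorted(groups) == [(i, c) for i in range(2) for c in range(3)]

    def test_degenerate_single_proxy(self):
        part = partition_proxies(init_proxies(1, 1, 4, seed=0), 0, 0)
        assert part.same_view_other_classes == [] and part.other_views_same_class == []


class TestSCLossValues:
    def test_aligned_embedding_with_orthogonal_negative(self):
        # z = p~, the one A-proxy orthogonal: -log(e / (e + e^0))
        z = EmbeddingSet(np.array([[1.0, 0, 0, 0]]))
        p = np.zeros((1, 2, 4))
        p[0, 0, 0] = 1.0
        p[0, 1, 1] = 1.0
        out = scloss(z, ProxyBank(p), 0)
        assert out.value == pytest.approx(-np.log(np.e / (np.e + 1)), abs=1e-12)
        assert out.per_view_terms == pytest.approx([out.value])

    def test_all_zero_similarities_give_log_two(self):
        z = EmbeddingSet(np.array([[0, 0, 1.0, 0]]))
        p = np.zeros((1, 2, 4))
        p[0, 0, 0] = 1.0
        p[0, 1, 1] = 1.0
        out = scloss(z, ProxyBank(p), 0)
        assert out.value == pytest.approx(np.log(2.0), abs=1e-12)

    def test_nonpositive_cross_view_proxy_contributes_exactly_one(self):
        # M=2: B-proxy with p.z = -0.6 must enter the denominator as e^0 = 1
        z = np.stack([unit([1, 0, 0, 0]), unit([0, 1, 0, 0])])
        p = np.zeros((2, 2, 4))
        p[0, 0] = unit([1, 0, 0, 0])       # view 0, class 0 (p~ of z0)
        p[0, 1] = unit([0, 0, 1, 0])       # view 0, class 1 (orthogonal)
        p[1, 0] = unit([-0.6, 0, 0.8, 0])  # view 1, class 0: z0 . p = -0.6
        p[1, 1] = unit([0, 0, 0, 1])
        out = scloss(EmbeddingSet(z), ProxyBank(p), 0)
        # view-0 term by hand: denominator e^1 + e^0 (A) + e^relu(-0.6)=1 (B)
        view0 = -np.log(np.e / (np.e + 1.0 + 1.0))
        assert out.per_view_terms[0] == pytest.approx(view0, abs=1e-12)

    def test_flat_region_of_clamped_cross_view_similarity(self):
        # moving a B-proxy while its similarity stays <= 0 leaves loss unchanged
        z = np.stack([unit([1, 0, 0, 0]), unit([0, 1, 0, 0])])
        base = np.zeros((2, 2, 4))
        base[0, 0] = unit([1, 0, 0, 0])
        base[0, 1] = unit([0, 0, 1, 0])
        base[1, 1] = unit([0, 0, 0, 1])
        losses = []
        for x in (-0.2, -0.5, -0.9):
            p = base.copy()
            p[1, 0] = unit([x, 0, np.sqrt(1 - x * x), 0])
            losses.append(scloss(EmbeddingSet(z), ProxyBank(p), 0).value)
        assert losses[0] == pytest.approx(losses[1], abs=1e-12)
        assert losses[1] == pytest.approx(losses[2], abs=1e-12)

    def test_loss_monotone_in_positive_and_negative_similarities(self):
        # raising p~.z lowers the loss; raising an A-proxy similarity raises it
        def loss_at(pos_angle, neg_overlap):
            z = EmbeddingSet(np.array([[1.0, 0, 0, 0]]))
            p = np.zeros((1, 2, 4))
            p[0, 0] = unit([np.cos(pos_angle), np.sin(pos_angle), 0, 0])
            p[0, 1] = unit([neg_overlap, 0, np.sqrt(1 - neg_overlap ** 2), 0])
            return scloss(z, ProxyBank(p), 0).value

        pos_sweep = [loss_at(a, 0.0) for a in (1.0, 0.6, 0.3, 0.0)]
        assert np.all(np.diff(pos_sweep) < 0)
        neg_sweep = [loss_at(0.0, x) for x in (0.0, 0.3, 0.6, 0.9)]
        assert np.all(np.diff(neg_sweep) > 0)

    def test_loss_nonnegative_on_random_instances(self, rng):
        for _ in range(20):
            m, c, l = rng.integers(1, 4), rng.integers(2, 5), 8
            bank = init_proxies(m, c, l, seed=int(rng.integers(1e6)))
            z = rng.normal(size=(m, l))
            z /= np.linalg.norm(z, axis=1, keepdims=True)
            out = scloss(EmbeddingSet(z), bank, int(rng.integers(c)))
            assert out.value >= 0
            assert out.value == pytest.approx(out.per_view_terms.mean())


class TestSCLossGradients:
    def test_gradients_match_central_differences(self, rng):
        for trial in range(4):
            m = int(rng.integers(1, 4))
            c = int(rng.integers(2, 5))
            l = int(rng.integers(3, 9))
            b = int(rng.integers(1, 4))
            z0 = rng.normal(size=(b, m, l))
            z0 /= np.linalg.norm(z0, axis=2, keepdims=True)
            p0 = rng.normal(size=(m, c, l))
            labels = rng.integers(0, c, size=b)
            z = Tensor(z0.copy())
            z.requires_grad = True
            bank = ProxyBank(p0.copy())
            loss, _ = scloss_batch(z, bank, labels)
            bank.zero_grad()
            loss.backward()

            def f():
                l_, _ = scloss_batch(Tensor(z.data), ProxyBank(bank.p.data.copy()),
                                     labels)
                return float(l_.data)

            for tensor in (z, bank.p):
                grad = tensor.grad
                flat_idx = [tuple(i) for i in
                            np.argwhere(np.ones_like(tensor.data))]
                sel = [flat_idx[k] for k in
                       rng.choice(len(flat_idx), size=min(6, len(flat_idx)),
                                  replace=False)]
                for idx in sel:
                    eps = 1e-6
                    tensor.data[idx] += eps
                    fp = f()
                    tensor.data[idx] -= 2 * eps
                    fm = f()
                    tensor.data[idx] += eps
                    num = (fp - fm) / (2 * eps)
                    assert grad[idx] == pytest.approx(num, rel=1e-5, abs=1e-8)


class TestPredict:
    def test_basis_aligned_prediction(self):
        p = np.zeros((1, 2, 4))
        p[0, 0, 0] = 1.0
        p[0, 1, 1] = 1.0
        z = EmbeddingSet(unit([0.9, 0.1, 0, 0])[None, :])
        assert predict(z, ProxyBank(p)) == 0

    def test_exact_tie_goes_to_lowest_class(self):
        p = np.zeros((1, 3, 4))
        p[0, 0, 0] = 1.0
        p[0, 1, 1] = 1.0
        p[0, 2, 2] = 1.0
        z = EmbeddingSet(unit([1.0, 0, 1.0, 0])[None, :])  # classes 0 and 2 tie
        assert predict(z, ProxyBank(p)) == 0

    def test_matches_bruteforce_enumeration(self, rng):
        for _ in range(30):
            m, c, l = int(rng.integers(1, 4)), int(rng.integers(2, 5)), 6
            bank = init_proxies(m, c, l, seed=int(rng.integers(1e6)))
            z = rng.normal(size=(m, l))
            z /= np.linalg.norm(z, axis=1, keepdims=True)
            pn = bank.normalized()
            best, best_sim = None, -np.inf
            for i in range(m):
                for k in range(c):
                    s = float(z[i] @ pn[i, k])
                    if s > best_sim:
                        best, best_sim = k, s
            assert predict(EmbeddingSet(z), bank) == best
            assert predict_batch(z[None], bank)[0] == best

    def test_single_view_reduces_to_nearest_centroid(self, rng):
        bank = init_proxies(1, 4, 8, seed=3)
        pn = bank.normalized()[0]
        for _ in range(20):
            z = rng.normal(size=(1, 8))
            z /= np.linalg.norm(z)
            dists = np.linalg.norm(pn - z, axis=1)
            assert predict(EmbeddingSet(z), bank) == int(np.argmin(dists))


class TestInitProxies:
    def test_seed_reproducibility_and_norms(self):
        a = init_proxies(3, 4, 128, seed=9)
        b = init_proxies(3, 4, 128, seed=9)
        assert np.array_equal(a.p.data, b.p.data)
        assert a.p.data.shape == (3, 4, 128)
        assert np.allclose(np.linalg.norm(a.p.data, axis=2), 1.0)

    def test_mismatched_embedding_rejected(self):
        bank = init_proxies(2, 2, 4, seed=0)
        z = EmbeddingSet(np.eye(3, 4))
        with pytest.raises(ValueError):
            predict(z, bank)
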