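"""Gated-attention MIL: forward contracts, analytic gradients, training."""

import numpy as np
import pytest

from necmil.bags import InstanceVector, PatientBag
from necmil.mil import (
    MILConfig,
    MILParams,
    _PARAM_NAMES,
    bag_loss_and_grads,
    cross_validate,
    embed,
    gated_attention,
    init_params,
    pool,
    predict_bag,
    train_mil,
)


def _small_params(n_features=6, seed=0, gated=True):
    cfg = MILConfig(hidden=7, embed_dim=5, attn_dim=4, gated=gated, seed=seed)
    return init_params(n_features, cfg, np.random.default_rng(seed)), cfg


def _make_bag(pid, X, days=None, label=0, onset=None):
    days = days if days is not None else list(range(1, len(X) + 1))
    return PatientBag(
        patient_id=pid,
        instances=[
            InstanceVector(pid, f"{pid}_s{i}", d, x) for i, (d, x) in enumerate(zip(days, X))
        ],
        label=label,
        onset_day=onset,
    )


class TestForwardContracts:
    def test_zero_weight_network_gives_zero_embedding(self):
        params, _ = _small_params()
        params.W1 = np.zeros_like(params.W1)
        params.W2 = np.zeros_like(params.W2)
        assert np.allclose(embed(np.ones(6), params), 0.0)

    def test_embedding_is_deterministic_and_seeded(self):
        a, _ = _small_params(seed=3)
        b, _ = _small_params(seed=3)
        x = np.random.default_rng(1).normal(size=6)
        assert np.array_equal(embed(x, a), embed(x, b))

    @pytest.mark.parametrize("k", [1, 2, 5, 17, 50])
    def test_attention_sums_to_one(self, k):
        params, _ = _small_params()
        H = np.random.default_rng(k).normal(size=(k, 5))
        a = gated_attention(H, params)
        assert a.shape == (k,)
        assert np.all(a >= 0)
        assert abs(a.sum() - 1.0) < 1e-6

    def test_singleton_bag_gets_full_attention(self):
        params, _ = _small_params()
        assert np.allclose(gated_attention(np.ones((1, 5)), params), [1.0])

    def test_identical_embeddings_get_uniform_attention(self):
        params, _ = _small_params()
        H = np.tile(np.random.default_rng(2).normal(size=5), (4, 1))
        assert np.allclose(gated_attention(H, params), 0.25, atol=1e-12)

    def test_pool_is_a_weighted_mean(self):
        H = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert np.allclose(pool(H, [0.3, 0.7]), [0.3, 0.7])
        assert np.allclose(pool(H[:1], [1.0]), H[0])

    def test_zero_classifier_gives_half_confidence(self):
        params, _ = _small_params()
        params.wc = np.zeros_like(params.wc)
        params.bc = 0.0
        X = np.random.default_rng(0).normal(size=(3, 6))
        assert predict_bag(X, params).confidence == pytest.approx(0.5)

    def test_confidence_monotone_in_classifier_logit(self):
        params, _ = _small_params()
        X = np.random.default_rng(0).normal(size=(3, 6))
        base = predict_bag(X, params).confidence
        params.bc += 1.0
        assert predict_bag(X, params).confidence > base

    def test_permutation_invariance(self):
        params, _ = _small_params()
        rng = np.random.default_rng(5)
        X = rng.normal(size=(6, 6))
        perm = rng.permutation(6)
        a = predict_bag(X, params)
        b = predict_bag(X[perm], params)
        assert a.confidence == pytest.approx(b.confidence, abs=1e-9)
        assert np.allclose(a.attention[perm], b.attention, atol=1e-9)

    def test_uniform_duplication_invariance(self):
        params, _ = _small_params()
        X = np.random.default_rng(6).normal(size=(4, 6))
        a = predict_bag(X, params)
        b = predict_bag(np.vstack([X, X]), params)
        assert a.confidence == pytest.approx(b.confidence, abs=1e-9)

    def test_empty_bag_is_an_error(self):
        params, _ = _small_params()
        with pytest.raises(ValueError):
            predict_bag(np.empty((0, 6)), params)

    def test_gate_forced_to_one_reduces_to_ungated_attention(self):
        """With the sigmoid gate forced to 1, the gated logit collapses to
        w^T tanh(V h)."""
        params, _ = _small_params(gated=True)
        H = np.random.default_rng(7).normal(size=(5, 5))
        ungated = MILParams(**{n: getattr(params, n) for n in _PARAM_NAMES}, gated=False)
        expected_logits = np.tanh(H @ params.V.T) @ params.w
        e = expected_logits - expected_logits.max()
        expected = np.exp(e) / np.exp(e).sum()
        assert np.allclose(gated_attention(H, ungated), expected, atol=1e-9)
        # and it differs from the gated version in general
        assert not np.allclose(gated_attention(H, params), expected)


class TestGradients:
    def test_analytic_gradients_match_finite_differences(self):
        rng = np.random.default_rng(0)
        params, _ = _small_params()
        mats = [rng.normal(size=(k, 6)) for k in (1, 3, 2)]
        y = np.array([1.0, 0.0, 1.0])
        wt = np.array([1.2, 0.8, 1.0])
        _, grads = bag_loss_and_grads(params, mats, y, wt)
        eps = 1e-6
        for name in _PARAM_NAMES:
            p = np.asarray(getattr(params, name), dtype=float)
            flat = p.reshape(-1) if p.ndim else None
            idxs = (
                [np.unravel_index(i, p.shape) for i in range(min(p.size, 12))]
                if p.ndim else [None]
            )
            for idx in idxs:
                orig = p[idx] if p.ndim else float(getattr(params, name))

                def setv(v):
                    if p.ndim:
                        p[idx] = v
                        setattr(params, name, p)
                    else:
                        setattr(params, name, float(v))

                setv(orig + eps)
                lp, _ = bag_loss_and_grads(params, mats, y, wt)
                setv(orig - eps)
                lm, _ = bag_loss_and_grads(params, mats, y, wt)
                setv(orig)
                num = (lp - lm) / (2 * eps)
                ana = np.asarray(grads[name])[idx] if p.ndim else float(grads[name])
                assert ana == pytest.approx(num, abs=1e-6, rel=1e-4), name


class TestTraining:
    def _separable_bags(self, n=24, seed=0):
        rng = np.random.default_rng(seed)
        bags = []
        for i in range(n):
            label = i % 2
            k = int(rng.integers(2, 5))
            X = rng.normal(size=(k, 6))
            if label:
                X[rng.integers(0, k)] += np.array([3.0, 3.0, 0, 0, 0, 0])
            bags.append(_make_bag(f"P{i}", X, label=label, onset=10 if label else None))
        return bags

    def test_training_reduces_loss_on_separable_bags(self):
        bags = self._separable_bags()
        cfg = MILConfig(hidden=16, embed_dim=8, attn_dim=4, max_epochs=60, patience=60)
        mats = [b.matrix() for b in bags]
        y = np.array([b.label for b in bags], dtype=float)
        params0 = init_params(6, cfg, np.random.default_rng(cfg.seed))
        loss0, _ = bag_loss_and_grads(params0, mats, y)
        params = train_mil(bags, config=cfg)
        loss1, _ = bag_loss_and_grads(params, mats, y)
        assert loss1 < loss0

    def test_same_seed_gives_identical_parameters(self):
        bags = self._separable_bags()
        cfg = MILConfig(hidden=16, embed_dim=8, attn_dim=4, max_epochs=20, patience=20)
        a = train_mil(bags, config=cfg, seed=5)
        b = train_mil(bags, config=cfg, seed=5)
        for n in _PARAM_NAMES:
            assert np.array_equal(np.asarray(getattr(a, n)), np.asarray(getattr(b, n)))

    def test_single_class_training_is_an_error(self):
        bags = [b for b in self._separable_bags() if b.label == 0]
        with pytest.raises(ValueError, match="both classes"):
            train_mil(bags)

    def test_cross_validate_stratifies_and_reproduces(self):
        bags = self._separable_bags(n=30)
        cfg = MILConfig(hidden=16, embed_dim=8, attn_dim=4, max_epochs=20, patience=20)
        df1, det1 = cross_validate(bags, n_trials=3, seed=2, config=cfg)
        df2, _ = cross_validate(bags, n_trials=3, seed=2, config=cfg)
        assert np.allclose(df1.roc_auc, df2.roc_auc)
        labels = np.array([b.label for b in bags])
        frac = labels.mean()
        for d in det1:
            te = labels[d["test_idx"]]
            assert abs(te.mean() - frac) <= 1.0 / len(te) + 1e-9
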