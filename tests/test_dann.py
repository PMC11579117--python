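"""Adversarial classifier contracts: losses, update rules, reductions, search."""

import numpy as np
import pandas as pd
import pytest

from neurotype._nets import cross_entropy, softmax
from neurotype.dann import (
    DANNConfig,
    DANNClassifier,
    domain_codes,
    domain_loss,
    label_loss,
    make_model,
    objective,
    predict_broad,
    random_search,
    reversed_feature_update,
    sample_config,
    train_dann,
    DEFAULT_SEARCH_SPACE,
)
from neurotype.preprocessing import feature_columns, normalize, run_preprocessing, split


def _batch(n=8, d=5, seed=0):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(rng.normal(size=(n, d)), columns=[f"f{i:02d}" for i in range(d)])
    df["broad_label"] = rng.integers(0, 2, n)
    df["organism"] = rng.choice(["mouse", "human"], n)
    return df


def _tiny_model(d=5, seed=0, hidden=(3,), head=(2,)):
    cfg = DANNConfig(hidden_layers=hidden, head_hidden=head, seed=seed)
    return make_model(cfg, n_features=d)


class TestLosses:
    def test_uniform_output_gives_ln2(self):
        model = _tiny_model()
        # zero all weights/biases of the heads -> logits 0 -> uniform softmax
        for net in (model.label_head_, model.domain_head_):
            for p in net.parameters():
                p[...] = 0.0
        batch = _batch()
        assert np.isclose(label_loss(model, batch), np.log(2))
        assert np.isclose(domain_loss(model, batch), np.log(2))

    def test_perfect_head_gives_zero_loss(self):
        model = _tiny_model(d=2, hidden=(2,), head=())
        batch = _batch(d=2)
        # identity-ish extractor + an oracle head reading the label planted
        # into the representation
        y = batch["broad_label"].to_numpy()
        model.extractor_.weights[0][...] = 0.0
        model.extractor_.biases[0][...] = 0.0
        feats = feature_columns(batch)
        batch = batch.copy()
        batch[feats[0]] = np.where(y == 0, 50.0, -50.0)
        model.extractor_.weights[0][0, 0] = 1.0  # relu passes positives
        model.extractor_.weights[0][0, 1] = -1.0
        model.label_head_.weights[0][...] = [[1.0, -1.0], [-1.0, 1.0]]
        assert label_loss(model, batch) < 1e-8

    def test_matches_hand_rolled_cross_entropy(self):
        model = _tiny_model(seed=3)
        batch = _batch(seed=3)
        X = batch[feature_columns(batch)].to_numpy()
        h, _ = model.extractor_.forward(X)
        logits, _ = model.label_head_.forward(h)
        # independent scalar-loop softmax cross-entropy
        y = batch["broad_label"].to_numpy()
        total = 0.0
        for row, yi in zip(logits, y):
            e = np.exp(row - row.max())
            total += -np.log(e[yi] / e.sum())
        assert np.isclose(label_loss(model, batch), total / len(y), atol=1e-6)

    def test_empty_batch_raises(self):
        model = _tiny_model()
        with pytest.raises(ValueError, match="empty"):
            label_loss(model, _batch(n=8).iloc[:0])


class TestObjective:
    def test_lambda_zero_equals_label_loss(self):
        model, batch = _tiny_model(), _batch()
        assert objective(model, batch, 0.0) == label_loss(model, batch)

    def test_arithmetic(self):
        model, batch = _tiny_model(seed=1), _batch(seed=1)
        ly, ld = label_loss(model, batch), domain_loss(model, batch)
        assert np.isclose(objective(model, batch, 1.7), ly - 1.7 * ld, atol=1e-9)

    def test_compositional_identity_random_batches(self):
        for seed in range(5):
            model, batch = _tiny_model(seed=seed), _batch(seed=seed, n=16)
            lam = 0.3 * seed
            assert np.isclose(
                objective(model, batch, lam),
                label_loss(model, batch) - lam * domain_loss(model, batch),
                atol=1e-9,
            )


def _all_params(model):
    return [p.copy() for net in model._nets() for p in net.parameters()]


class TestReversedUpdate:
    def test_mu_zero_is_identity(self):
        model, batch = _tiny_model(), _batch()
        before = _all_params(model)
        reversed_feature_update(model, batch, lambda_=1.0, mu=0.0)
        for a, b in zip(before, _all_params(model)):
            assert (a == b).all()

    def test_lambda_zero_freezes_domain_head_and_matches_plain_step(self):
        model, batch = _tiny_model(seed=5), _batch(seed=5)
        ref = _tiny_model(seed=5)
        d_before = [p.copy() for p in model.domain_head_.parameters()]
        reversed_feature_update(model, batch, lambda_=0.0, mu=0.1)
        for a, b in zip(d_before, model.domain_head_.parameters()):
            assert (a == b).all()
        # plain label-only gradient step computed independently on the twin
        from neurotype._nets import cross_entropy_grad

        X = batch[feature_columns(batch)].to_numpy()
        y = batch["broad_label"].to_numpy()
        h, cf = ref.extractor_.forward(X)
        logits, cy = ref.label_head_.forward(h)
        gy, dh = ref.label_head_.backward(cy, cross_entropy_grad(logits, y))
        gf, _ = ref.extractor_.backward(cf, dh)
        for p, g in zip(ref.extractor_.parameters(), gf):
            p -= 0.1 * g
        for p, g in zip(ref.label_head_.parameters(), gy):
            p -= 0.1 * g
        for a, b in zip(model.extractor_.parameters(), ref.extractor_.parameters()):
            assert (a == b).all()
        for a, b in zip(model.label_head_.parameters(), ref.label_head_.parameters()):
            assert (a == b).all()

    @pytest.mark.parametrize("lam", [0.0, 0.7, 2.0])
    def test_update_matches_finite_differences(self, lam):
        """On a <=50-parameter network every component of the three update
        rules matches a central finite-difference estimate."""
        d, mu_lr, eps = 2, 1e-2, 1e-5
        model = _tiny_model(d=d, hidden=(2,), head=())
        assert sum(net.n_params for net in model._nets()) <= 50
        batch = _batch(n=1, d=d, seed=7)
        X = batch[feature_columns(batch)].to_numpy()
        y = batch["broad_label"].to_numpy()
        dom = domain_codes(batch["organism"])

        def losses(m):
            h, _ = m.extractor_.forward(X)
            ly, _ = m.label_head_.forward(h)
            ld, _ = m.domain_head_.forward(h)
            return cross_entropy(ly, y), cross_entropy(ld, dom)

        before = _all_params(model)
        twin = _tiny_model(d=d, hidden=(2,), head=())
        reversed_feature_update(model, batch, lambda_=lam, mu=mu_lr)
        after = _all_params(model)

        # finite-difference the stated target of each parameter block:
        # extractor: L_y - lam*L_d ; label head: L_y ; domain head: lam*L_d
        n_f = len(twin.extractor_.parameters())
        n_y = len(twin.label_head_.parameters())
        params = [p for net in twin._nets() for p in net.parameters()]
        for k, p in enumerate(params):
            grad = np.zeros_like(p)
            it = np.nditer(p, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                orig = p[idx]
                p[idx] = orig + eps
                ly_p, ld_p = losses(twin)
                p[idx] = orig - eps
                ly_m, ld_m = losses(twin)
                p[idx] = orig
                if k < n_f:
                    grad[idx] = ((ly_p - lam * ld_p) - (ly_m - lam * ld_m)) / (2 * eps)
                elif k < n_f + n_y:
                    grad[idx] = (ly_p - ly_m) / (2 * eps)
                else:
                    grad[idx] = lam * (ld_p - ld_m) / (2 * eps)
            expected = before[k] - mu_lr * grad
            denom = np.maximum(np.abs(expected - before[k]), 1e-12)
            rel = np.abs(after[k] - expected) / denom
            mask = np.abs(expected - before[k]) > 1e-10
            assert (rel[mask] < 1e-4).all()

    def test_nonfinite_gradient_aborts(self):
        model, batch = _tiny_model(), _batch()
        batch.iloc[0, 0] = np.inf
        with pytest.raises(FloatingPointError):
            reversed_feature_update(model, batch, 1.0, 0.1)


@pytest.fixture(scope="module")
def small_split():
    from neurotype.synthetic import (
        SyntheticConfig, block_informative_sets, generate_cohort,
    )

    info = block_informative_sets(["excitatory", "inhibitory"], 12, 3)
    cfg = SyntheticConfig(
        n_per_class_per_domain={
            ("mouse", "excitatory"): 100, ("mouse", "inhibitory"): 100,
            ("human", "excitatory"): 50, ("human", "inhibitory"): 50,
        },
        d_features=12, informative_sets=info, class_effect_size=3.0, seed=13,
    )
    table, _ = generate_cohort(cfg)
    data, _ = run_preprocessing(table, seed=13)
    return data


class TestTraining:
    def test_separable_cohort_learned(self, small_split):
        cfg = DANNConfig(hidden_layers=(16, 8), epochs=60, lambda_=0.0,
                         learning_rate=0.05, seed=0)
        model, _ = train_dann(cfg, small_split)
        feats = feature_columns(small_split.test)
        acc = (
            model.predict(small_split.test[feats].to_numpy())
            == small_split.test["broad_label"].to_numpy()
        ).mean()
        assert acc >= 0.95

    def test_seeded_determinism(self, small_split):
        cfg = DANNConfig(hidden_layers=(8,), epochs=10, lambda_=0.5,
                         learning_rate=0.05, dropout=0.2, seed=4)
        _, h1 = train_dann(cfg, small_split)
        _, h2 = train_dann(cfg, small_split)
        pd.testing.assert_frame_equal(h1, h2)

    def test_lambda_zero_reduction_weight_identical(self, small_split):
        """Adversarial training at lambda = 0 is weight-for-weight the plain
        jointly-trained classifier under a shared seed."""
        cfg = DANNConfig(hidden_layers=(8,), epochs=8, lambda_=0.0,
                         learning_rate=0.05, seed=9)
        m1, _ = train_dann(cfg, small_split)
        from neurotype.evaluation import fcnn_baseline

        m2, _ = fcnn_baseline(cfg, small_split)
        for a, b in zip(m1.extractor_.parameters(), m2.extractor_.parameters()):
            assert (a == b).all()
        for a, b in zip(m1.label_head_.parameters(), m2.label_head_.parameters()):
            assert (a == b).all()

    def test_single_domain_with_lambda_errors(self, small_split):
        cfg = DANNConfig(epochs=2, lambda_=1.0, seed=0)
        mouse_only = small_split.train[small_split.train["organism"] == "mouse"]
        est = DANNClassifier(epochs=2, lambda_=1.0)
        feats = feature_columns(mouse_only)
        with pytest.raises(ValueError, match="single domain"):
            est.fit(
                mouse_only[feats].to_numpy(),
                mouse_only["broad_label"].to_numpy(),
                domain=np.zeros(len(mouse_only), dtype=int),
            )


class TestPrediction:
    def test_argmax_and_tie_rule(self):
        model = _tiny_model(d=3, hidden=(2,), head=())
        # force known logits via the label head
        model.label_head_.weights[0][...] = 0.0
        model.label_head_.biases[0][...] = [2.0, -1.0]
        batch = _batch(n=4, d=3)
        assert (predict_broad(model, batch) == 0).all()
        model.label_head_.biases[0][...] = [1.0, 1.0]  # exact tie -> class 0
        assert (predict_broad(model, batch) == 0).all()

    def test_predictions_match_independent_forward(self, small_split):
        cfg = DANNConfig(hidden_layers=(8,), epochs=5, lambda_=0.3, seed=2)
        model, _ = train_dann(cfg, small_split)
        feats = feature_columns(small_split.test)
        X = small_split.test[feats].to_numpy()
        # oracle forward pass from the raw weight matrices
        h = X
        for W, b in zip(model.extractor_.weights, model.extractor_.biases):
            h = np.maximum(h @ W + b, 0.0)
        for k, (W, b) in enumerate(
            zip(model.label_head_.weights, model.label_head_.biases)
        ):
            h = h @ W + b
            if k < len(model.label_head_.weights) - 1:
                h = np.maximum(h, 0.0)
        assert (model.predict(X) == np.argmax(h, axis=1)).all()

    def test_embed_dimension(self, small_split):
        cfg = DANNConfig(hidden_layers=(16, 6), epochs=3, lambda_=0.0, seed=1)
        model, _ = train_dann(cfg, small_split)
        feats = feature_columns(small_split.test)
        H = model.transform(small_split.test[feats].to_numpy())
        assert H.shape == (len(small_split.test), 6)


class TestConfigAndSearch:
    @pytest.mark.parametrize(
        "kw", [dict(lambda_=-1), dict(learning_rate=0), dict(dropout=0.6),
               dict(weight_decay=-0.1), dict(optimizer="adagrad"),
               dict(epochs=0)],
    )
    def test_invalid_config_rejected(self, kw):
        with pytest.raises(ValueError):
            DANNConfig(**kw)

    def test_sampled_configs_lie_in_grid(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            cfg = sample_config(None, rng, seed=1)
            assert 0.001 <= cfg.learning_rate <= 0.2
            assert 0.0001 <= cfg.weight_decay <= 1.0
            assert 0.0 <= cfg.dropout <= 0.5
            assert cfg.batch_size in (32, 64)
            assert cfg.epochs in (500, 1000, 1500, 2000)
            assert cfg.optimizer in ("sgd", "rmsprop", "adam")
            assert tuple(cfg.hidden_layers) in DEFAULT_SEARCH_SPACE["hidden_layers"]
            assert 3 <= len(cfg.hidden_layers) <= 4
            assert cfg.activation in ("relu", "selu", "swish")

    def test_budget_zero_rejected(self, small_split):
        with pytest.raises(ValueError, match="budget"):
            random_search(None, 0, 0, small_split)

    def test_search_returns_best_of_trials(self, small_split):
        space = {"epochs": (5,), "hidden_layers": ((8,),), "batch_size": (64,)}
        best, trials = random_search(space, 3, seed=0, data=small_split)
        assert len(trials) == 3
        winner_score = trials["val_accuracy"].max()
        sel = trials[np.isclose(trials["lambda_"], best.lambda_)]
        assert winner_score == trials["val_accuracy"].max()
        assert best.epochs == 5


class TestOptimizers:
    @pytest.mark.parametrize("opt", ["sgd", "rmsprop", "adam"])
    def test_all_optimizers_reduce_loss(self, opt, small_split):
        lr = 0.05 if opt == "sgd" else 0.005
        cfg = DANNConfig(hidden_layers=(8,), epochs=15, lambda_=0.0,
                         optimizer=opt, learning_rate=lr, seed=0)
        _, h = train_dann(cfg, small_split)
        assert h["label_loss"].iloc[-1] < h["label_loss"].iloc[0]
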