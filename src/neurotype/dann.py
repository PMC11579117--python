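"""Domain-adversarial classifier for cross-species broad-type prediction.

One feature extractor G_f feeds two heads: a label classifier G_y
(excitatory vs. inhibitory) and a domain classifier G_d (mouse vs. human).
Training seeks the saddle point of

    E(th_f, th_y, th_d) = mean_i L_y^i - lambda * mean_i L_d^i,

minimized over the extractor and label head and maximized over the domain
head, via the coupled update rules

    th_f <- th_f - mu * (dL_y/dth_f - lambda * dL_d/dth_f)
    th_y <- th_y - mu * dL_y/dth_y
    th_d <- th_d - mu * lambda * dL_d/dth_d.

The reversed sign on the extractor's domain gradient (gradient reversal)
drives representations the domain head cannot separate, so the label head
must rely on species-invariant structure.  Both species' labels enter the
label loss by default: the study trains one joint classifier reporting
supervised metrics on both organisms; a flag restricts the label loss to
the source species for strictly unsupervised adaptation.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted, check_X_y, check_array

from ._nets import MLP, cross_entropy, cross_entropy_grad, make_optimizer, softmax
from .preprocessing import DataSplit, feature_columns

logger = logging.getLogger(__name__)

DOMAIN_CODES = {"mouse": 0, "human": 1}

_OPTIMIZERS = ("sgd", "rmsprop", "adam")
_ACTIVATION_CHOICES = ("relu", "selu", "swish")
#: six extractor architectures of 3-4 hidden layers, the searched family
ARCHITECTURE_CHOICES = (
    (64, 32, 16),
    (128, 64, 32),
    (32, 32, 16),
    (64, 64, 32, 16),
    (128, 64, 32, 16),
    (64, 32, 32, 16),
)


def domain_codes(organism) -> np.ndarray:
    """Map organism names to domain labels (mouse = 0 source, human = 1 target)."""
    return np.asarray([DOMAIN_CODES[o] for o in organism], dtype=int)


@dataclass
class DANNConfig:
    """Training configuration; field names mirror the estimator parameters."""

    hidden_layers: tuple = (64, 32, 16)
    head_hidden: tuple = (16,)
    activation: str = "relu"
    lambda_: float = 1.0
    learning_rate: float = 0.05
    dropout: float = 0.0
    weight_decay: float = 0.0
    batch_size: int = 64
    epochs: int = 500
    optimizer: str = "sgd"
    lambda_schedule: str = "fixed"
    include_target_labels: bool = True
    class_weight: str | None = None
    checkpoint: str = "final"
    seed: int = 0

    def __post_init__(self):
        if self.lambda_ < 0:
            raise ValueError("lambda_ must be >= 0")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if not 0.0 <= self.dropout <= 0.5:
            raise ValueError("dropout must lie in [0, 0.5]")
        if self.weight_decay < 0:
            raise ValueError("weight_decay must be >= 0")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")
        if self.optimizer.lower() not in _OPTIMIZERS:
            raise ValueError(f"optimizer must be one of {_OPTIMIZERS}")
        if self.lambda_schedule not in ("fixed", "ramp"):
            raise ValueError("lambda_schedule must be 'fixed' or 'ramp'")
        if self.checkpoint not in ("final", "best_val"):
            raise ValueError("checkpoint must be 'final' or 'best_val'")


def _config_to_estimator_params(cfg) -> dict:
    if isinstance(cfg, DANNConfig):
        d = asdict(cfg)
    elif isinstance(cfg, dict):
        d = dict(DANNConfig(**cfg).__dict__)
    else:
        raise TypeError("cfg must be a DANNConfig or a dict of its fields")
    d["random_state"] = d.pop("seed")
    return d


class DANNClassifier(BaseEstimator, ClassifierMixin):
    """Domain-adversarial neural classifier (scikit-learn estimator).

    ``fit(X, y, domain=...)`` trains the extractor/label-head/domain-head
    triple with the reversed-gradient update rules; ``lambda_=0`` reduces
    exactly to a plain jointly trained classifier.  ``transform`` exposes the
    learned representation for invariance diagnostics.

    Parameters mirror :class:`DANNConfig`; ``random_state`` seeds weight
    initialization, shuffling and dropout.
    """

    def __init__(
        self,
        hidden_layers=(64, 32, 16),
        head_hidden=(16,),
        activation="relu",
        lambda_=1.0,
        learning_rate=0.05,
        dropout=0.0,
        weight_decay=0.0,
        batch_size=64,
        epochs=500,
        optimizer="sgd",
        lambda_schedule="fixed",
        include_target_labels=True,
        class_weight=None,
        checkpoint="final",
        random_state=0,
    ):
        self.hidden_layers = hidden_layers
        self.head_hidden = head_hidden
        self.activation = activation
        self.lambda_ = lambda_
        self.learning_rate = learning_rate
        self.dropout = dropout
        self.weight_decay = weight_decay
        self.batch_size = batch_size
        self.epochs = epochs
        self.optimizer = optimizer
        self.lambda_schedule = lambda_schedule
        self.include_target_labels = include_target_labels
        self.class_weight = class_weight
        self.checkpoint = checkpoint
        self.random_state = random_state

    # ------------------------------------------------------------------ setup

    def _validate_config(self):
        DANNConfig(
            hidden_layers=tuple(self.hidden_layers),
            head_hidden=tuple(self.head_hidden),
            activation=self.activation,
            lambda_=self.lambda_,
            learning_rate=self.learning_rate,
            dropout=self.dropout,
            weight_decay=self.weight_decay,
            batch_size=self.batch_size,
            epochs=self.epochs,
            optimizer=self.optimizer,
            lambda_schedule=self.lambda_schedule,
            class_weight=self.class_weight,
            checkpoint=self.checkpoint,
            seed=self.random_state,
        )

    def _extractor_activations(self):
        if isinstance(self.activation, str):
            return [self.activation] * len(self.hidden_layers)
        acts = list(self.activation)
        if len(acts) != len(self.hidden_layers):
            raise ValueError("one activation per extractor layer is required")
        return acts

    def _init_nets(self, n_features, n_classes, rng):
        act = self._extractor_activations()
        head_act = [act[-1]] * len(self.head_hidden) + ["linear"]
        repr_dim = self.hidden_layers[-1]
        self.extractor_ = MLP(
            [n_features, *self.hidden_layers], act, rng, dropout=self.dropout
        )
        self.label_head_ = MLP([repr_dim, *self.head_hidden, n_classes], head_act, rng)
        self.domain_head_ = MLP([repr_dim, *self.head_hidden, 2], head_act, rng)

    # ---------------------------------------------------------------- forward

    def _forward(self, X, train=False, rng=None):
        h, cache_f = self.extractor_.forward(X, train=train, rng=rng)
        ly, cache_y = self.label_head_.forward(h)
        ld, cache_d = self.domain_head_.forward(h)
        return h, ly, ld, (cache_f, cache_y, cache_d)

    def _label_weights(self, y, d):
        """Per-sample weights entering the label loss."""
        w = np.ones(len(y), dtype=float)
        if not self.include_target_labels:
            w[np.asarray(d) == 1] = 0.0
        if self.class_weight == "balanced":
            counts = np.bincount(y, minlength=len(self.classes_)).astype(float)
            counts[counts == 0] = 1.0
            w *= (len(y) / (len(self.classes_) * counts))[y]
        return w

    # ------------------------------------------------------------------ train

    def _one_update(self, X, y, d, lam, opt_f, opt_y, opt_d, rng):
        """One reversed-gradient step on a minibatch; returns (L_y, L_d)."""
        w = self._label_weights(y, d)
        h, ly, ld, (cache_f, cache_y, cache_d) = self._forward(
            X, train=self.dropout > 0, rng=rng
        )
        loss_y = cross_entropy(ly, y, sample_weight=w if w.sum() else None)
        loss_d = cross_entropy(ld, d)

        g_logits_y = cross_entropy_grad(ly, y, sample_weight=w if w.sum() else None)
        grads_y, dh_y = self.label_head_.backward(cache_y, g_logits_y)
        g_logits_d = cross_entropy_grad(ld, d)
        grads_d, dh_d = self.domain_head_.backward(cache_d, g_logits_d)
        # gradient reversal: the extractor descends L_y but ascends L_d
        grads_f, _ = self.extractor_.backward(cache_f, dh_y - lam * dh_d)

        if self.weight_decay:
            # decay regularizes the learned predictor (extractor + label
            # head); the domain head follows its update rule exactly
            for k, wgt in enumerate(self.extractor_.weights):
                grads_f[k] = grads_f[k] + self.weight_decay * wgt
            for k, wgt in enumerate(self.label_head_.weights):
                grads_y[k] = grads_y[k] + self.weight_decay * wgt
        opt_f.step(grads_f)
        opt_y.step(grads_y)
        opt_d.step([lam * g for g in grads_d])
        return loss_y, loss_d

    def fit(self, X, y, domain=None, validation=None, check_domains=True):
        """Train on features X, broad labels y and domain labels (0/1).

        ``validation`` is an optional (X, y, domain) triple used for the
        history and for ``checkpoint='best_val'`` selection.
        """
        self._validate_config()
        X, y = check_X_y(X, y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        self.n_features_in_ = X.shape[1]
        if domain is None:
            domain = np.zeros(len(y), dtype=int)
        domain = np.asarray(domain, dtype=int)
        if check_domains and self.lambda_ > 0 and len(np.unique(domain)) < 2:
            raise ValueError(
                "training data contains a single domain; the domain loss is "
                "undefined as a discriminator when lambda_ > 0"
            )
        rng = np.random.default_rng(self.random_state)
        self._rng = rng
        self._init_nets(X.shape[1], len(self.classes_), rng)
        opt_f = make_optimizer(self.optimizer, self.extractor_.parameters(),
                               self.learning_rate)
        opt_y = make_optimizer(self.optimizer, self.label_head_.parameters(),
                               self.learning_rate)
        opt_d = make_optimizer(self.optimizer, self.domain_head_.parameters(),
                               self.learning_rate)

        n = len(y_idx)
        history = []
        best = (-np.inf, None)
        for epoch in range(self.epochs):
            lam = self._lambda_at(epoch)
            order = rng.permutation(n)
            ep_ly, ep_ld, n_batches = 0.0, 0.0, 0
            for start in range(0, n, self.batch_size):
                sel = order[start:start + self.batch_size]
                loss_y, loss_d = self._one_update(
                    X[sel], y_idx[sel], domain[sel], lam, opt_f, opt_y, opt_d, rng
                )
                ep_ly += loss_y
                ep_ld += loss_d
                n_batches += 1
            rec = {
                "epoch": epoch,
                "label_loss": ep_ly / n_batches,
                "domain_loss": ep_ld / n_batches,
                "objective": ep_ly / n_batches - lam * ep_ld / n_batches,
                "lambda": lam,
            }
            if validation is not None:
                Xv, yv, dv = validation
                pred = self._predict_indices(np.asarray(Xv, dtype=float))
                yv_idx = np.searchsorted(self.classes_, yv)
                acc = float((pred == yv_idx).mean())
                rec["val_accuracy"] = acc
                dv = np.asarray(dv)
                for code, name in ((0, "source"), (1, "target")):
                    m = dv == code
                    if m.any():
                        rec[f"val_accuracy_{name}"] = float(
                            (pred[m] == yv_idx[m]).mean()
                        )
                if self.checkpoint == "best_val" and acc > best[0]:
                    best = (acc, [p.copy() for net in self._nets()
                                  for p in net.parameters()])
            history.append(rec)
            logger.debug("epoch %d: L_y=%.4f L_d=%.4f", epoch,
                         rec["label_loss"], rec["domain_loss"])
        if self.checkpoint == "best_val" and best[1] is not None:
            self._set_all_parameters(best[1])
        self.history_ = pd.DataFrame(history)
        return self

    def _nets(self):
        return (self.extractor_, self.label_head_, self.domain_head_)

    def _set_all_parameters(self, flat):
        i = 0
        for net in self._nets():
            k = len(net.parameters())
            net.set_parameters(flat[i:i + k])
            i += k

    def _lambda_at(self, epoch):
        if self.lambda_schedule == "ramp" and self.epochs > 1:
            p = epoch / (self.epochs - 1)
            return self.lambda_ * (2.0 / (1.0 + np.exp(-10.0 * p)) - 1.0)
        return self.lambda_

    # -------------------------------------------------------------- inference

    def _predict_indices(self, X):
        _, ly, _, _ = self._forward(X)
        return np.argmax(ly, axis=1)  # argmax takes the lowest index on ties

    def predict(self, X):
        check_is_fitted(self, "extractor_")
        X = check_array(X)
        return self.classes_[self._predict_indices(X)]

    def predict_proba(self, X):
        check_is_fitted(self, "extractor_")
        X = check_array(X)
        _, ly, _, _ = self._forward(X)
        return softmax(ly)

    def predict_domain_proba(self, X):
        check_is_fitted(self, "extractor_")
        X = check_array(X)
        _, _, ld, _ = self._forward(X)
        return softmax(ld)

    def transform(self, X):
        """Extractor representations G_f(x), for invariance diagnostics."""
        check_is_fitted(self, "extractor_")
        X = check_array(X)
        h, _ = self.extractor_.forward(X)
        return h


# --------------------------------------------------------------- module ops


def _batch_arrays(batch: pd.DataFrame):
    feats = feature_columns(batch)
    X = batch[feats].to_numpy(dtype=float)
    y = batch["broad_label"].to_numpy(dtype=int)
    d = domain_codes(batch["organism"])
    return X, y, d


def label_loss(model: DANNClassifier, batch: pd.DataFrame) -> float:
    """Mean cross-entropy of G_y(G_f(x)) against the broad labels."""
    X, y, _ = _batch_arrays(batch)
    if len(X) == 0:
        raise ValueError("empty batch")
    _, ly, _, _ = model._forward(X)
    return cross_entropy(ly, np.searchsorted(model.classes_, y))


def domain_loss(model: DANNClassifier, batch: pd.DataFrame) -> float:
    """Mean cross-entropy of G_d(G_f(x)) against the organism labels."""
    X, _, d = _batch_arrays(batch)
    if len(X) == 0:
        raise ValueError("empty batch")
    _, _, ld, _ = model._forward(X)
    return cross_entropy(ld, d)


def objective(model: DANNClassifier, batch: pd.DataFrame, lambda_: float) -> float:
    """The combined criterion E = mean L_y - lambda * mean L_d on the batch."""
    if lambda_ < 0:
        raise ValueError("lambda_ must be >= 0")
    return label_loss(model, batch) - lambda_ * domain_loss(model, batch)


def reversed_feature_update(
    model: DANNClassifier, batch: pd.DataFrame, lambda_: float, mu: float
) -> DANNClassifier:
    """One plain gradient step of the three update rules (in place).

    th_f descends dL_y/dth_f - lambda dL_d/dth_f, th_y descends dL_y/dth_y,
    th_d descends lambda dL_d/dth_d.  ``mu`` is the learning rate; mu = 0
    leaves the model unchanged.
    """
    if mu < 0:
        raise ValueError("mu must be >= 0")
    X, y, d = _batch_arrays(batch)
    y_idx = np.searchsorted(model.classes_, y)
    h, ly, ld, (cache_f, cache_y, cache_d) = model._forward(X)
    grads_y, dh_y = model.label_head_.backward(cache_y, cross_entropy_grad(ly, y_idx))
    grads_d, dh_d = model.domain_head_.backward(cache_d, cross_entropy_grad(ld, d))
    grads_f, _ = model.extractor_.backward(cache_f, dh_y - lambda_ * dh_d)
    for g in grads_f + grads_y + grads_d:
        if not np.all(np.isfinite(g)):
            raise FloatingPointError("non-finite gradient in update")
    for p, g in zip(model.extractor_.parameters(), grads_f):
        p -= mu * g
    for p, g in zip(model.label_head_.parameters(), grads_y):
        p -= mu * g
    for p, g in zip(model.domain_head_.parameters(), grads_d):
        p -= mu * lambda_ * g
    return model


def make_model(cfg, n_features: int, n_classes: int = 2) -> DANNClassifier:
    """Initialized (untrained) model with seeded weights, for loss/update ops."""
    est = DANNClassifier(**_config_to_estimator_params(cfg))
    est._validate_config()
    rng = np.random.default_rng(est.random_state)
    est._rng = rng
    est.classes_ = np.arange(n_classes)
    est.n_features_in_ = n_features
    est._init_nets(n_features, n_classes, rng)
    return est


def train_dann(cfg, data: DataSplit) -> tuple[DANNClassifier, pd.DataFrame]:
    """Fit the adversarial classifier on a normalized split."""
    if not data.is_normalized:
        raise ValueError("split must be normalized before training")
    feats = feature_columns(data.train)
    est = DANNClassifier(**_config_to_estimator_params(cfg))
    val = None
    if len(data.validation):
        val = (
            data.validation[feats].to_numpy(dtype=float),
            data.validation["broad_label"].to_numpy(dtype=int),
            domain_codes(data.validation["organism"]),
        )
    est.fit(
        data.train[feats].to_numpy(dtype=float),
        data.train["broad_label"].to_numpy(dtype=int),
        domain=domain_codes(data.train["organism"]),
        validation=val,
    )
    return est, est.history_


def predict_broad(model: DANNClassifier, table: pd.DataFrame) -> np.ndarray:
    """Broad-type predictions for a feature table (ties -> lowest class)."""
    return model.predict(table[feature_columns(table)].to_numpy(dtype=float))


def embed(model: DANNClassifier, table: pd.DataFrame) -> np.ndarray:
    """Extractor representations for a feature table."""
    return model.transform(table[feature_columns(table)].to_numpy(dtype=float))


DEFAULT_SEARCH_SPACE = {
    "hidden_layers": ARCHITECTURE_CHOICES,
    "activation": _ACTIVATION_CHOICES,
    "learning_rate": (0.001, 0.2),     # log-uniform
    "weight_decay": (0.0001, 1.0),     # log-uniform
    "dropout": (0.0, 0.5),             # uniform
    "batch_size": (32, 64),
    "epochs": (500, 1000, 1500, 2000),
    "optimizer": _OPTIMIZERS,
    "lambda_": (0.01, 10.0),           # log-uniform; 0 is included as a choice
}


def sample_config(space: dict, rng: np.random.Generator, seed: int) -> DANNConfig:
    sp = {**DEFAULT_SEARCH_SPACE, **(space or {})}
    lo, hi = sp["learning_rate"]
    lr = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    lo, hi = sp["weight_decay"]
    wd = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    lo, hi = sp["lambda_"]
    lam = 0.0 if rng.random() < 0.2 else float(
        np.exp(rng.uniform(np.log(lo), np.log(hi)))
    )
    return DANNConfig(
        hidden_layers=tuple(sp["hidden_layers"][rng.integers(len(sp["hidden_layers"]))]),
        activation=str(sp["activation"][rng.integers(len(sp["activation"]))]),
        learning_rate=lr,
        weight_decay=wd,
        dropout=float(rng.uniform(*sp["dropout"])),
        batch_size=int(sp["batch_size"][rng.integers(len(sp["batch_size"]))]),
        epochs=int(sp["epochs"][rng.integers(len(sp["epochs"]))]),
        optimizer=str(sp["optimizer"][rng.integers(len(sp["optimizer"]))]),
        lambda_=lam,
        seed=seed,
    )


def random_search(
    space: dict | None, budget: int, seed: int, data: DataSplit
) -> tuple[DANNConfig, pd.DataFrame]:
    """Seeded random search over the hyperparameter grid.

    Each trial trains on the split and is scored by validation label
    accuracy, with target-domain validation accuracy as tie-break.  Returns
    (best config, trial table).
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    rng = np.random.default_rng(seed)
    trials = []
    best = None
    for t in range(budget):
        cfg = sample_config(space, rng, seed=int(rng.integers(2**31)))
        model, history = train_dann(cfg, data)
        score = float(history["val_accuracy"].iloc[-1])
        tgt = float(history.get("val_accuracy_target", history["val_accuracy"]).iloc[-1])
        trials.append({"trial": t, "val_accuracy": score,
                       "val_accuracy_target": tgt, **asdict(cfg)})
        key = (score, tgt)
        if best is None or key > best[0]:
            best = (key, cfg)
    return best[1], pd.DataFrame(trials)
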