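"""Locally sparse gated classifier for interpretable subclass prediction.

Two networks are trained in tandem: a gating network psi that maps each
sample x to gate parameters mu = psi(x | Omega), and a prediction network
f_theta that classifies the gated features x * z.  Each gate is the clipped
Gaussian relaxation of a Bernoulli switch,

    z_d = max(0, min(1, 0.5 + mu_d + eps_d)),   eps_d ~ N(0, sigma^2),

with sigma fixed during training and 0 at inference, so inference is
deterministic and z is then a hard-thresholded function of mu alone.  The
loss is cross-entropy on the gated prediction plus the regularizer

    R(z) = lambda1 * ||z||_0 + lambda2 * sum_j K_ij ||z_i - z_j||^2.

The non-differentiable ||z||_0 is replaced by its exact expectation under
the gate noise, sum_d Phi((mu_d + 0.5) / sigma) with Phi the standard
normal CDF — the standard relaxation in the stochastic-gates literature —
which is smooth in mu.  The inference-time gate matrix (samples x features)
is the interpretability surface: a near-zero entry means that feature was
muted for that cell.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist
from scipy.stats import norm
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from ._nets import MLP, cross_entropy, cross_entropy_grad, make_optimizer, softmax
from .preprocessing import DataSplit, feature_columns

logger = logging.getLogger(__name__)


@dataclass
class LSPINConfig:
    """Defaults are the study's fitted configuration: prediction net 41->40->
    20->5, gating net 3x50, tanh throughout, lambda1 = 0.01047, lambda2 = 0,
    sigma = 0.5, learning rate 0.0599, 1000 epochs, SGD."""

    gating_layers: tuple = (50, 50, 50)
    prediction_layers: tuple = (40, 20)
    activation: str = "tanh"
    sigma: float = 0.5
    lambda1: float = 0.01047
    lambda2: float = 0.0
    kernel: str = "rbf"
    learning_rate: float = 0.0599
    epochs: int = 1000
    batch_size: int = 64
    optimizer: str = "sgd"
    seed: int = 0

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("lambda1 and lambda2 must be >= 0")
        if self.learning_rate <= 0 or self.epochs < 1 or self.batch_size < 1:
            raise ValueError("learning_rate, epochs and batch_size must be positive")


# ------------------------------------------------------------------ gate ops


def gate(mu_vec, eps_vec) -> np.ndarray:
    """Stochastic-gate threshold: z = max(0, min(1, 0.5 + mu + eps))."""
    mu_vec = np.asarray(mu_vec, dtype=float)
    eps_vec = np.asarray(eps_vec, dtype=float)
    if mu_vec.shape != eps_vec.shape:
        raise ValueError(
            f"mu and eps shapes differ: {mu_vec.shape} vs {eps_vec.shape}"
        )
    return np.clip(0.5 + mu_vec + eps_vec, 0.0, 1.0)


def sample_noise(sigma: float, shape, rng: np.random.Generator) -> np.ndarray:
    """Gate noise eps ~ N(0, sigma^2); identically zero when sigma = 0."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return np.zeros(shape)
    return rng.normal(0.0, sigma, size=shape)


def sparsity_penalty(mu_batch, sigma: float, lambda1: float) -> float:
    """Expected open-gate count surrogate, batch-averaged.

    E[||z||_0] under the gate noise equals sum_d Phi((mu_d + 0.5) / sigma)
    (the probability each gate exceeds 0), so the penalty is
    lambda1 * mean_i sum_d Phi((mu_d^(i) + 0.5) / sigma).
    """
    if lambda1 == 0:
        return 0.0
    mu_batch = np.atleast_2d(np.asarray(mu_batch, dtype=float))
    return float(lambda1 * norm.cdf((mu_batch + 0.5) / sigma).sum(axis=1).mean())


def _sparsity_grad(mu_batch, sigma, lambda1):
    n = mu_batch.shape[0]
    return lambda1 * norm.pdf((mu_batch + 0.5) / sigma) / sigma / n


def rbf_kernel(X, bandwidth: float | None = None) -> np.ndarray:
    """RBF kernel on input features with median-heuristic bandwidth."""
    X = np.asarray(X, dtype=float)
    sq = ((X[:, None, :] - X[None, :, :]) ** 2).sum(-1)
    if bandwidth is None:
        d = pdist(X)
        med = np.median(d[d > 0]) if np.any(d > 0) else 1.0
        bandwidth = float(med)
    return np.exp(-sq / (2.0 * bandwidth**2))


def smoothness_penalty(Z_batch, K, lambda2: float) -> float:
    """lambda2 * mean_i sum_j K_ij ||z_i - z_j||^2; zero for equal rows."""
    if lambda2 == 0:
        return 0.0
    Z = np.atleast_2d(np.asarray(Z_batch, dtype=float))
    K = np.asarray(K, dtype=float)
    if np.any(K < 0):
        raise ValueError("kernel entries must be >= 0")
    sq = ((Z[:, None, :] - Z[None, :, :]) ** 2).sum(-1)
    return float(lambda2 * (K * sq).sum(axis=1).mean())


def _smoothness_grad(Z, K, lambda2):
    # d/dz_k of mean_i sum_j K_ij ||z_i - z_j||^2
    n = Z.shape[0]
    diffs = Z[:, None, :] - Z[None, :, :]          # (i, j, d) = z_i - z_j
    W = (K + K.T)[:, :, None]
    return lambda2 * 2.0 / n * (W * diffs).sum(axis=1)


# ------------------------------------------------------------- the estimator


class LSPINClassifier(BaseEstimator, ClassifierMixin):
    """Locally sparse neural classifier (scikit-learn estimator).

    ``fit`` trains the gating and prediction networks jointly by SGD on the
    gated cross-entropy plus the sparsity/smoothness regularizer.
    ``gate_values`` returns the inference-mode gate matrix; ``transform``
    returns the gated features x * z.
    """

    def __init__(
        self,
        gating_layers=(50, 50, 50),
        prediction_layers=(40, 20),
        activation="tanh",
        sigma=0.5,
        lambda1=0.01047,
        lambda2=0.0,
        kernel="rbf",
        learning_rate=0.0599,
        epochs=1000,
        batch_size=64,
        optimizer="sgd",
        random_state=0,
    ):
        self.gating_layers = gating_layers
        self.prediction_layers = prediction_layers
        self.activation = activation
        self.sigma = sigma
        self.lambda1 = lambda1
        self.lambda2 = lambda2
        self.kernel = kernel
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.optimizer = optimizer
        self.random_state = random_state

    def _init_nets(self, n_features, n_classes, rng):
        act = self.activation
        # gating output is tanh-bounded so mu lies in [-1, 1]: far enough to
        # saturate a gate fully open (z=1) or fully closed (z=0) at inference
        self.gating_net_ = MLP(
            [n_features, *self.gating_layers, n_features],
            [act] * len(self.gating_layers) + ["tanh"],
            rng,
        )
        self.prediction_net_ = MLP(
            [n_features, *self.prediction_layers, n_classes],
            [act] * len(self.prediction_layers) + ["linear"],
            rng,
        )

    def _forward(self, X, mode="infer", rng=None):
        mu, cache_g = self.gating_net_.forward(X)
        if mode == "train":
            eps = sample_noise(self.sigma, mu.shape, rng)
        elif mode == "infer":
            eps = np.zeros_like(mu)
        else:
            raise ValueError("mode must be 'train' or 'infer'")
        Z = gate(mu, eps)
        scores, cache_p = self.prediction_net_.forward(X * Z)
        return scores, Z, mu, eps, cache_g, cache_p

    def fit(self, X, y):
        cfg = LSPINConfig(
            gating_layers=tuple(self.gating_layers),
            prediction_layers=tuple(self.prediction_layers),
            activation=self.activation,
            sigma=self.sigma,
            lambda1=self.lambda1,
            lambda2=self.lambda2,
            kernel=self.kernel,
            learning_rate=self.learning_rate,
            epochs=self.epochs,
            batch_size=self.batch_size,
            optimizer=self.optimizer,
            seed=self.random_state,
        )
        if self.sigma == 0:
            raise ValueError(
                "sigma must be > 0 during training: the stochastic relaxation "
                "of the gates needs noise (sigma = 0 is the inference setting)"
            )
        X, y = check_X_y(X, y, dtype=float)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValueError("training requires at least two classes")
        self.n_features_in_ = X.shape[1]
        rng = np.random.default_rng(self.random_state)
        self._init_nets(X.shape[1], len(self.classes_), rng)
        opt_g = make_optimizer(self.optimizer, self.gating_net_.parameters(),
                               self.learning_rate)
        opt_p = make_optimizer(self.optimizer, self.prediction_net_.parameters(),
                               self.learning_rate)
        n = len(y_idx)
        history = []
        for epoch in range(cfg.epochs):
            order = rng.permutation(n)
            ep_loss, ep_sparsity, ep_open, n_batches = 0.0, 0.0, 0.0, 0
            for start in range(0, n, cfg.batch_size):
                sel = order[start:start + cfg.batch_size]
                losses = self._one_update(X[sel], y_idx[sel], opt_g, opt_p, rng)
                ep_loss += losses[0]
                ep_sparsity += losses[1]
                ep_open += losses[2]
                n_batches += 1
            history.append({
                "epoch": epoch,
                "loss": ep_loss / n_batches,
                "sparsity_penalty": ep_sparsity / n_batches,
                "mean_gate": ep_open / n_batches,
            })
            logger.debug("epoch %d: loss=%.4f mean_gate=%.3f", epoch,
                         history[-1]["loss"], history[-1]["mean_gate"])
        self.history_ = pd.DataFrame(history)
        return self

    def _one_update(self, Xb, yb, opt_g, opt_p, rng):
        scores, Z, mu, eps, cache_g, cache_p = self._forward(Xb, "train", rng)
        ce = cross_entropy(scores, yb)
        sp = sparsity_penalty(mu, self.sigma, self.lambda1)

        g_scores = cross_entropy_grad(scores, yb)
        grads_p, dXz = self.prediction_net_.backward(cache_p, g_scores)
        dZ = dXz * Xb
        sm = 0.0
        if self.lambda2 > 0:
            K = rbf_kernel(Xb) if self.kernel == "rbf" else np.ones((len(Xb),) * 2)
            sm = smoothness_penalty(Z, K, self.lambda2)
            dZ = dZ + _smoothness_grad(Z, K, self.lambda2)
        open_mask = (Z > 0.0) & (Z < 1.0)  # clip passes gradient only inside
        d_mu = dZ * open_mask
        d_mu = d_mu + _sparsity_grad(mu, self.sigma, self.lambda1)
        grads_g, _ = self.gating_net_.backward(cache_g, d_mu)
        opt_p.step(grads_p)
        opt_g.step(grads_g)
        return ce + sp + sm, sp, float(Z.mean())

    def predict_proba(self, X):
        check_is_fitted(self, "prediction_net_")
        X = check_array(X, dtype=float)
        scores, *_ = self._forward(X, "infer")
        return softmax(scores)

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]

    def gate_values(self, X) -> np.ndarray:
        """Inference-mode gate matrix Z in [0, 1], deterministic."""
        check_is_fitted(self, "gating_net_")
        X = check_array(X, dtype=float)
        _, Z, *_ = self._forward(X, "infer")
        return Z

    def transform(self, X):
        """Gated features x * z (inference gates)."""
        X = check_array(X, dtype=float)
        return X * self.gate_values(X)


# --------------------------------------------------------------- module ops


def lspin_forward(model: LSPINClassifier, X, mode: str = "infer", rng=None):
    """Forward pass returning (class scores, gate matrix Z)."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != model.n_features_in_:
        raise ValueError(
            f"feature-count mismatch: model expects {model.n_features_in_}, "
            f"got {X.shape[1]}"
        )
    if mode == "train" and rng is None:
        rng = getattr(model, "_rng", np.random.default_rng(model.random_state))
    scores, Z, *_ = model._forward(X, mode, rng)
    return scores, Z


def lspin_loss(model: LSPINClassifier, X, y, rng=None) -> float:
    """Gated cross-entropy + sparsity + smoothness, batch-averaged (train mode)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    y_idx = np.searchsorted(model.classes_, y)
    if np.any(model.classes_[np.clip(y_idx, 0, len(model.classes_) - 1)] != y):
        raise ValueError("batch contains labels unknown to the model")
    if rng is None:
        rng = np.random.default_rng(model.random_state)
    scores, Z, mu, eps, _, _ = model._forward(X, "train", rng)
    ce = cross_entropy(scores, y_idx)
    sp = sparsity_penalty(mu, model.sigma, model.lambda1)
    sm = 0.0
    if model.lambda2 > 0:
        K = rbf_kernel(X) if model.kernel == "rbf" else np.ones((len(X),) * 2)
        sm = smoothness_penalty(Z, K, model.lambda2)
    return ce + sp + sm


def make_lspin(cfg, n_features: int, n_classes: int = 5) -> LSPINClassifier:
    """Initialized (untrained) model with seeded weights, for the loss ops."""
    est = LSPINClassifier(**_config_to_estimator_params(cfg))
    rng = np.random.default_rng(est.random_state)
    est._rng = rng
    est.classes_ = np.arange(n_classes)
    est.n_features_in_ = n_features
    est._init_nets(n_features, n_classes, rng)
    return est


def _config_to_estimator_params(cfg) -> dict:
    if isinstance(cfg, LSPINConfig):
        d = asdict(cfg)
    elif isinstance(cfg, dict):
        d = dict(LSPINConfig(**cfg).__dict__)
    else:
        raise TypeError("cfg must be an LSPINConfig or a dict of its fields")
    d["random_state"] = d.pop("seed")
    return d


def train_lspin(
    cfg, data: DataSplit, label_column: str = "subclass_label"
) -> tuple[LSPINClassifier, pd.DataFrame]:
    """Fit the gated classifier on a normalized split's training partition."""
    if not data.is_normalized:
        raise ValueError("split must be normalized before training")
    feats = feature_columns(data.train)
    est = LSPINClassifier(**_config_to_estimator_params(cfg))
    est.fit(
        data.train[feats].to_numpy(dtype=float),
        data.train[label_column].to_numpy(),
    )
    return est, est.history_


def gate_matrix(model: LSPINClassifier, table: pd.DataFrame) -> pd.DataFrame:
    """Inference-time gate matrix for every row of a feature table."""
    feats = feature_columns(table)
    Z = model.gate_values(table[feats].to_numpy(dtype=float))
    index = table["sample_id"] if "sample_id" in table else table.index
    return pd.DataFrame(Z, columns=feats, index=index)


def cluster_gate_matrix(Z) -> tuple[np.ndarray, np.ndarray, dict]:
    """Agglomerative ordering of gate-matrix rows and columns for a heatmap.

    Euclidean distance, average linkage.  Returns (row order, column order,
    {'rows': row linkage, 'cols': column linkage}); degenerate axes get an
    identity order and no linkage.
    """
    Z = np.asarray(Z, dtype=float) if not isinstance(Z, pd.DataFrame) else Z.to_numpy()
    if Z.size == 0:
        raise ValueError("empty gate matrix")

    def _order(M):
        if M.shape[0] < 2:
            return np.arange(M.shape[0]), None
        link = linkage(M, method="average", metric="euclidean")
        return leaves_list(link), link

    row_order, row_link = _order(Z)
    col_order, col_link = _order(Z.T)
    return row_order, col_order, {"rows": row_link, "cols": col_link}


def plot_gate_heatmap(Z, path, row_order=None, col_order=None):
    """Clustered heatmap of the gate matrix (black = muted, white = open)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if row_order is None or col_order is None:
        row_order, col_order, _ = cluster_gate_matrix(Z)
    M = np.asarray(Z, dtype=float) if not isinstance(Z, pd.DataFrame) else Z.to_numpy()
    M = M[np.ix_(row_order, col_order)]
    fig, ax = plt.subplots(figsize=(8, 6))
    im = ax.imshow(M, aspect="auto", cmap="gray", vmin=0, vmax=1)
    ax.set_xlabel("electrophysiological features")
    ax.set_ylabel("test samples")
    fig.colorbar(im, ax=ax, label="gate value")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
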