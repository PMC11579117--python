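"""Frozen simulation protocols for the package's headline properties.

Each study here is a complete, seeded experiment on synthetic cohorts:

* :func:`transfer_gap_study` — the cross-species ablation: a classifier fit
  on one organism alone loses accuracy on the other when a strong shift is
  present, and does not when the domains are identically distributed.
* :func:`adversarial_benefit_study` — adversarial training with lambda tuned
  on validation matches or beats the pooled non-adversarial classifier on
  the target domain, and its representations are domain-invariant under a
  balanced linear probe.
* :func:`gate_recovery_study` — the locally sparse classifier, at its
  default hyperparameters, reopens exactly the features that carry each
  subclass's signal.

The same functions back both the test suite and the results-reproduction
script, so the numbers reported anywhere are produced by this one code path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression

from .dann import DANNConfig, domain_codes, train_dann
from .evaluation import cross_domain_ablation, evaluate_per_domain, fcnn_baseline
from .lspin import LSPINConfig, gate_matrix, train_lspin
from .preprocessing import feature_columns, run_preprocessing
from .synthetic import (
    MOUSE,
    SUBCLASSES,
    SyntheticConfig,
    block_informative_sets,
    confounding_shift,
    generate_cohort,
    paper_binary_composition,
)

logger = logging.getLogger(__name__)

BINARY_CLASSES = ("excitatory", "inhibitory")
#: informative blocks of 5 features per class for the two-class cohorts
BINARY_INFORMATIVE = block_informative_sets(BINARY_CLASSES, 41, 5)
#: strong structured shift used by the shifted-cohort studies
STRONG_SHIFT_MAGNITUDE = 2.0


def binary_cohort_split(seed: int, shifted: bool = True):
    """Two-species broad-type cohort at the study composition, preprocessed.

    ``shifted`` applies the structured confounding shift to the human domain;
    otherwise the two domains are identically distributed.
    """
    shift = (
        confounding_shift(BINARY_INFORMATIVE, 41, magnitude=STRONG_SHIFT_MAGNITUDE)
        if shifted
        else None
    )
    cfg = SyntheticConfig(
        paper_binary_composition(),
        informative_sets=BINARY_INFORMATIVE,
        class_effect_size=3.0,
        domain_shift=shift,
        seed=seed,
    )
    table, truth = generate_cohort(cfg)
    data, _ = run_preprocessing(table, seed=seed)
    return data, truth


def balanced_subclass_split(seed: int, n_per_class: int = 276):
    """Balanced five-subclass mouse cohort (default 1105 train rows)."""
    info = block_informative_sets(SUBCLASSES, 41, 5)
    cfg = SyntheticConfig(
        {(MOUSE, c): n_per_class for c in SUBCLASSES},
        informative_sets=info,
        class_effect_size=3.0,
        seed=seed,
    )
    table, truth = generate_cohort(cfg)
    data, _ = run_preprocessing(
        table, fractions=(0.7996, 0.0, 0.2004), stratify_on=("subclass_label",),
        seed=seed,
    )
    return data, truth


def domain_probe(H_train, d_train, H_eval, d_eval, seed: int = 0) -> float:
    """Accuracy of a fresh balanced logistic probe predicting the domain.

    Both the fit and the evaluation use equal-sized domain subsamples, so
    chance level is 0.5 regardless of the cohort's mouse/human imbalance.
    """
    rng = np.random.default_rng(seed)

    def _balanced(d):
        i0, i1 = np.flatnonzero(d == 0), np.flatnonzero(d == 1)
        n = min(len(i0), len(i1))
        return np.concatenate(
            [rng.choice(i0, n, replace=False), rng.choice(i1, n, replace=False)]
        )
    tr, te = _balanced(np.asarray(d_train)), _balanced(np.asarray(d_eval))
    clf = LogisticRegression(max_iter=1000)
    clf.fit(np.asarray(H_train)[tr], np.asarray(d_train)[tr])
    return float(clf.score(np.asarray(H_eval)[te], np.asarray(d_eval)[te]))


def _ablation_config(seed: int, epochs: int) -> DANNConfig:
    return DANNConfig(
        hidden_layers=(32, 16), epochs=epochs, lambda_=0.0,
        learning_rate=0.05, seed=seed,
    )


def transfer_gap_study(seeds=range(10), epochs: int = 150, shifted: bool = True):
    """Per-seed within-vs-cross-domain accuracy gaps of source-only training.

    Returns a list (one entry per seed) of the mean gap across the two
    transfer directions, in accuracy points (fractions).
    """
    gaps = []
    for seed in seeds:
        data, _ = binary_cohort_split(seed, shifted=shifted)
        abl = cross_domain_ablation(_ablation_config(seed, epochs), data)
        gap = float(np.mean([v["gap"] for v in abl.values()]))
        gaps.append(gap)
        logger.info("transfer gap (shifted=%s) seed %d: %.3f", shifted, seed, gap)
    return gaps


@dataclass
class AdversarialBenefitResult:
    seeds: list = field(default_factory=list)
    fcnn_target_acc: list = field(default_factory=list)
    dann_target_acc: list = field(default_factory=list)
    selected_lambda: list = field(default_factory=list)
    raw_probe: list = field(default_factory=list)
    embedding_probe: list = field(default_factory=list)

    @property
    def wins(self) -> int:
        """Seeds where the tuned adversarial model matches or beats the
        pooled baseline on the target domain."""
        return int(sum(
            d >= f for d, f in zip(self.dann_target_acc, self.fcnn_target_acc)
        ))


def adversarial_benefit_study(
    seeds=range(10),
    lambda_grid=(0.0, 1.0, 2.0, 3.0),
    epochs: int = 400,
) -> AdversarialBenefitResult:
    """Paired-seed comparison of tuned adversarial training vs. the pooled
    non-adversarial classifier on the shifted cohort.

    Per seed: train the lambda = 0 baseline and one model per candidate
    lambda; select the candidate with the best validation target-domain
    accuracy, breaking near-ties (within one validation cell) toward the
    most domain-invariant representation as measured by a balanced
    validation probe.  Record target-domain test accuracies and the
    balanced domain-probe accuracy on raw features vs. embeddings.
    """
    res = AdversarialBenefitResult()
    for seed in seeds:
        data, _ = binary_cohort_split(seed, shifted=True)
        feats = feature_columns(data.train)
        Xtr = data.train[feats].to_numpy(dtype=float)
        dtr = domain_codes(data.train["organism"])
        Xva = data.validation[feats].to_numpy(dtype=float)
        dva = domain_codes(data.validation["organism"])
        Xte = data.test[feats].to_numpy(dtype=float)
        dte = domain_codes(data.test["organism"])

        base_cfg = DANNConfig(
            hidden_layers=(64, 32, 8), epochs=epochs, lambda_=0.0,
            learning_rate=0.05, seed=seed,
        )
        _, freports = fcnn_baseline(base_cfg, data)

        candidates = []
        for lam in lambda_grid:
            cfg = DANNConfig(
                hidden_layers=(64, 32, 8), epochs=epochs, lambda_=lam,
                learning_rate=0.05, seed=seed,
            )
            model, history = train_dann(cfg, data)
            val_target = float(history["val_accuracy_target"].iloc[-1])
            val_probe = domain_probe(
                model.transform(Xtr), dtr, model.transform(Xva), dva, seed
            )
            candidates.append((val_target, val_probe, lam, model))
        best_val = max(c[0] for c in candidates)
        # one validation cell on 60 human validation rows is ~1/60 ≈ 0.017
        near = [c for c in candidates if c[0] >= best_val - 0.011]
        _, val_probe, lam, model = min(near, key=lambda c: c[1])

        dreports = evaluate_per_domain(model, data)
        res.seeds.append(int(seed))
        res.fcnn_target_acc.append(float(freports["human"].accuracy))
        res.dann_target_acc.append(float(dreports["human"].accuracy))
        res.selected_lambda.append(float(lam))
        res.raw_probe.append(domain_probe(Xtr, dtr, Xte, dte, seed))
        res.embedding_probe.append(
            domain_probe(model.transform(Xtr), dtr, model.transform(Xte), dte, seed)
        )
        logger.info(
            "adversarial benefit seed %d: lambda*=%.1f fcnn=%.3f dann=%.3f "
            "raw_probe=%.3f emb_probe=%.3f", seed, lam,
            res.fcnn_target_acc[-1], res.dann_target_acc[-1],
            res.raw_probe[-1], res.embedding_probe[-1],
        )
    return res


def gate_recovery_study(seeds=range(10)) -> dict:
    """Gate recovery of the locally sparse classifier at its defaults.

    On balanced five-subclass cohorts, trains with the default
    configuration and measures, per class, the mean inference gate on that
    class's informative features minus the mean gate on its uninformative
    features (rows of that class only), plus held-out accuracy.

    Returns ``{"accuracy": [per seed], "margins": {class: [per seed]}}``.
    """
    out = {"accuracy": [], "margins": {c: [] for c in SUBCLASSES}}
    for seed in seeds:
        data, truth = balanced_subclass_split(seed)
        model, _ = train_lspin(LSPINConfig(seed=seed), data)
        feats = feature_columns(data.test)
        y_true = data.test["subclass_label"].to_numpy()
        y_pred = model.predict(data.test[feats].to_numpy(dtype=float))
        out["accuracy"].append(float((y_pred == y_true).mean()))
        Z = gate_matrix(model, data.test).to_numpy()
        for cls in SUBCLASSES:
            mask = truth.mask_for(cls)
            rows = y_true == cls
            margin = float(Z[rows][:, mask].mean() - Z[rows][:, ~mask].mean())
            out["margins"][cls].append(margin)
        logger.info(
            "gate recovery seed %d: acc=%.3f margins=%s", seed,
            out["accuracy"][-1],
            {c: round(v[-1], 2) for c, v in out["margins"].items()},
        )
    return out
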