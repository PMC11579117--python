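"""Config-driven pipeline: simulate -> preprocess -> train -> evaluate -> interpret.

A single YAML/dict config describes a run.  Every stage config is validated
up front (fail fast: no partial training on a bad config), each stage
writes its artifacts into the run directory, and a manifest records every
output file with a content hash so identical configs can be checked for
byte-identical results.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import synthetic
from .dann import DANNConfig, train_dann, random_search
from .evaluation import evaluate_per_domain, score_labels
from .lspin import (
    LSPINConfig,
    cluster_gate_matrix,
    gate_matrix,
    plot_gate_heatmap,
    train_lspin,
)
from .preprocessing import feature_columns, load_feature_table, run_preprocessing
from .synthetic import (
    DomainShiftSpec,
    SyntheticConfig,
    block_informative_sets,
    generate_cohort,
    paper_binary_composition,
    paper_subclass_composition,
    write_cohort,
)

logger = logging.getLogger(__name__)

STAGE_ORDER = (
    "simulate", "preprocess", "search_dann", "train_dann",
    "train_lspin", "evaluate", "interpret",
)


class RunConfigError(ValueError):
    pass


def build_synthetic_config(section: dict, seed: int) -> SyntheticConfig:
    """Translate the ``simulate`` config section into a SyntheticConfig.

    ``composition`` is either the preset name ``binary`` / ``subclass`` or an
    explicit ``{domain: {class: count}}`` mapping.
    """
    comp = section.get("composition", "binary")
    if comp == "binary":
        counts = paper_binary_composition()
    elif comp == "subclass":
        counts = paper_subclass_composition()
    elif isinstance(comp, dict):
        counts = {
            (dom, cls): int(n)
            for dom, per in comp.items()
            for cls, n in per.items()
        }
    else:
        raise RunConfigError(f"simulate.composition: unknown value {comp!r}")
    classes = sorted({cls for _, cls in counts})
    d = int(section.get("d_features", 41))
    informative = section.get("informative_sets")
    if informative is None:
        informative = block_informative_sets(
            classes, d, per_class=int(section.get("informative_per_class", 5))
        )
    else:
        informative = {cls: set(v) for cls, v in informative.items()}
    shift = None
    shift_sec = section.get("shift")
    if shift_sec:
        if "offset" in shift_sec:
            shift = DomainShiftSpec(
                np.asarray(shift_sec["offset"], dtype=float),
                np.asarray(shift_sec.get("scale", np.ones(d)), dtype=float),
                domain=shift_sec.get("domain", synthetic.HUMAN),
            )
        else:
            shift = DomainShiftSpec.random(
                d,
                offset_sd=float(shift_sec.get("offset_sd", 1.5)),
                log_scale_sd=float(shift_sec.get("log_scale_sd", 0.0)),
                domain=shift_sec.get("domain", synthetic.HUMAN),
                seed=int(shift_sec.get("seed", seed)),
            )
    return SyntheticConfig(
        n_per_class_per_domain=counts,
        d_features=d,
        informative_sets=informative,
        class_effect_size=float(section.get("effect_size", 3.0)),
        domain_shift=shift,
        noise_sd=float(section.get("noise_sd", 1.0)),
        missing_rate=float(section.get("missing_rate", 0.0)),
        seed=int(section.get("seed", seed)),
    )


def validate_config(config: dict) -> dict:
    """Validate stage list and every stage section; returns parsed sub-configs."""
    stages = config.get("stages")
    if not stages:
        raise RunConfigError("config must list at least one stage under 'stages'")
    unknown = [s for s in stages if s not in STAGE_ORDER]
    if unknown:
        raise RunConfigError(f"unknown stages: {unknown}")
    order = [STAGE_ORDER.index(s) for s in stages]
    if order != sorted(order):
        raise RunConfigError(
            f"stages must follow the pipeline order {STAGE_ORDER}, got {stages}"
        )
    seed = int(config.get("seed", 0))
    parsed = {"seed": seed, "stages": list(stages)}
    if "simulate" in stages:
        parsed["simulate"] = build_synthetic_config(config.get("simulate", {}), seed)
    elif any(s in stages for s in STAGE_ORDER[1:]):
        if "data" not in config:
            raise RunConfigError(
                "a 'data' path is required when the run does not simulate"
            )
        if not Path(config["data"]).exists():
            raise RunConfigError(f"data file not found: {config['data']}")
    if "preprocess" not in stages and any(
        s in stages for s in ("train_dann", "train_lspin", "search_dann")
    ):
        raise RunConfigError("training stages require the preprocess stage")
    pre = config.get("preprocess", {})
    parsed["preprocess"] = {
        "fractions": tuple(pre.get("fractions", (0.6797, 0.1201, 0.2002))),
        "stratify_on": tuple(pre.get("stratify_on", ("organism", "broad_label"))),
        "merge_map": pre.get("merge_map"),
        "seed": int(pre.get("seed", seed)),
        "per_domain_normalize": bool(pre.get("per_domain_normalize", False)),
    }
    if "train_dann" in stages:
        sec = dict(config.get("train_dann", {}))
        sec.setdefault("seed", seed)
        if "hidden_layers" in sec:
            sec["hidden_layers"] = tuple(sec["hidden_layers"])
        if "head_hidden" in sec:
            sec["head_hidden"] = tuple(sec["head_hidden"])
        parsed["train_dann"] = DANNConfig(**sec)
    if "search_dann" in stages:
        sec = dict(config.get("search_dann", {}))
        parsed["search_dann"] = {
            "budget": int(sec.get("budget", 5)),
            "seed": int(sec.get("seed", seed)),
            "space": sec.get("space"),
        }
    if "train_lspin" in stages:
        sec = dict(config.get("train_lspin", {}))
        sec.setdefault("seed", seed)
        for key in ("gating_layers", "prediction_layers"):
            if key in sec:
                sec[key] = tuple(sec[key])
        parsed["train_lspin"] = LSPINConfig(**sec)
    return parsed


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_json(obj, path: Path):
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)


def run_pipeline(config: dict, out_dir) -> Path:
    """Execute the configured stages; returns the run directory.

    Writes every intermediate artifact plus ``manifest.json`` with a content
    hash per output.  Identical configs reproduce identical metrics.
    """
    parsed = validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = parsed["seed"]
    outputs = []

    table = None
    if "simulate" in parsed["stages"]:
        cohort_cfg = parsed["simulate"]
        table, truth = generate_cohort(cohort_cfg)
        write_cohort(table, truth, out / "cohort.csv", out / "ground_truth.json")
        outputs += [out / "cohort.csv", out / "ground_truth.json"]
    elif "data" in config:
        table = load_feature_table(config["data"])

    data = None
    if "preprocess" in parsed["stages"]:
        pre = parsed["preprocess"]
        data, accounting = run_preprocessing(
            table,
            line_map=pre["merge_map"],
            fractions=pre["fractions"],
            stratify_on=pre["stratify_on"],
            seed=pre["seed"],
            per_domain_normalize=pre["per_domain_normalize"],
        )
        for name, part in zip(("train", "validation", "test"), data.partitions()):
            part.to_csv(out / f"{name}.csv", index=False)
            outputs.append(out / f"{name}.csv")
        _write_json(accounting, out / "preprocess_accounting.json")
        outputs.append(out / "preprocess_accounting.json")

    dann_cfg = parsed.get("train_dann")
    if "search_dann" in parsed["stages"]:
        sec = parsed["search_dann"]
        best_cfg, trials = random_search(sec["space"], sec["budget"], sec["seed"], data)
        trials.to_csv(out / "search_trials.csv", index=False)
        outputs.append(out / "search_trials.csv")
        dann_cfg = best_cfg

    metrics_out = {}
    model = None
    if dann_cfg is not None and (
        "train_dann" in parsed["stages"] or "search_dann" in parsed["stages"]
    ):
        model, history = train_dann(dann_cfg, data)
        history.to_csv(out / "dann_history.csv", index=False)
        np.savez(out / "dann_weights.npz", *[
            p for net in model._nets() for p in net.parameters()
        ])
        outputs += [out / "dann_history.csv", out / "dann_weights.npz"]
        if "evaluate" in parsed["stages"]:
            reports = evaluate_per_domain(model, data)
            metrics_out["dann"] = {k: v.to_dict() for k, v in reports.items()}

    lspin_model = None
    if "train_lspin" in parsed["stages"]:
        lspin_cfg = parsed["train_lspin"]
        lspin_model, history = train_lspin(lspin_cfg, data)
        history.to_csv(out / "lspin_history.csv", index=False)
        np.savez(out / "lspin_weights.npz", *(
            lspin_model.gating_net_.parameters()
            + lspin_model.prediction_net_.parameters()
        ))
        outputs += [out / "lspin_history.csv", out / "lspin_weights.npz"]
        if "evaluate" in parsed["stages"]:
            feats = feature_columns(data.test)
            y_true = data.test["subclass_label"].to_numpy()
            y_pred = lspin_model.predict(data.test[feats].to_numpy(dtype=float))
            classes = list(lspin_model.classes_)
            rep = score_labels(
                [classes.index(v) for v in y_true],
                [classes.index(v) for v in y_pred],
                n_classes=len(classes),
            )
            metrics_out["lspin"] = {"classes": classes, **rep.to_dict()}

    if metrics_out:
        _write_json(metrics_out, out / "metrics.json")
        outputs.append(out / "metrics.json")

    if "interpret" in parsed["stages"]:
        if lspin_model is None:
            raise RunConfigError("interpret requires the train_lspin stage")
        Z = gate_matrix(lspin_model, data.test)
        Z.to_csv(out / "gate_matrix.csv")
        row_order, col_order, _ = cluster_gate_matrix(Z)
        plot_gate_heatmap(Z, out / "gate_heatmap.png", row_order, col_order)
        outputs += [out / "gate_matrix.csv", out / "gate_heatmap.png"]

    manifest = {
        "seed": seed,
        "stages": parsed["stages"],
        "config_hash": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "outputs": {p.name: _sha256(p) for p in outputs},
    }
    _write_json(manifest, out / "manifest.json")
    logger.info("run complete: %d artifacts in %s", len(outputs), out)
    return out


def load_run_config(path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)
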