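# neurotype

Cross-species neuronal cell-type classification from tabular
electrophysiological features.

Whole-cell current-clamp recordings summarize each neuron as 41 numeric
features (action-potential width, height, threshold, firing-rate
statistics, ...). Two classification problems on such tables are addressed
here, for computational neuroscientists working with mouse and human
patch-clamp data:

1. **Broad type across species.** Human recordings are scarce; mouse
   recordings are plentiful but systematically shifted (human pyramidal
   neurons have higher AP thresholds, lower input resistance, ...). A
   single pooled classifier is biased toward the abundant species. The
   package trains a **domain-adversarial neural network (DANN)**: a feature
   extractor `G_f` feeds an excitatory-vs-inhibitory label head `G_y` and a
   mouse-vs-human domain head `G_d`, optimizing the saddle-point criterion

   ```
   E(θ_f, θ_y, θ_d) = (1/N) Σᵢ L_y^i − (λ/N) Σᵢ L_d^i
   ```

   minimized over `θ_f, θ_y` and maximized over `θ_d` via gradient
   reversal: `θ_f ← θ_f − μ(∂L_y/∂θ_f − λ∂L_d/∂θ_f)`. The extractor is
   driven toward representations the domain head cannot separate, so the
   label head must use species-invariant structure.

2. **Interpretable subclass prediction.** Five transcriptomic subclasses
   (Glutamatergic, Pvalb, Htr3a+|Vip−, Sst, Vip) are predicted by a
   **locally sparse interpretable network (LSPIN)**: a gating network
   `ψ(x|Ω)` emits per-sample gate parameters `μ⁽ⁱ⁾`, each stochastic gate is
   `z_d = max(0, min(1, 0.5 + μ_d + ε_d))` with `ε_d ~ N(0, σ²)` during
   training (σ = 0 at inference), and a prediction network classifies the
   gated features `x ⊙ z` under the regularizer
   `λ₁‖z‖₀ + λ₂ Σⱼ K_ij‖z⁽ⁱ⁾ − z⁽ʲ⁾‖²`. The inference-time gate matrix
   (samples × features) shows exactly which features each prediction used.

A seeded synthetic-cohort generator reproduces the statistical structure of
the real two-species data (1424 mouse / 299 human cells; known informative
features per class; a controllable species shift), so every claim is
testable without any download. Real tables exported in the same CSV layout
are consumed by the same pipeline.

## Worked example

```python
import numpy as np
from neurotype import (
    DANNConfig, SyntheticConfig, generate_cohort, paper_binary_composition,
    run_preprocessing, train_dann, evaluate_per_domain,
)
from neurotype.synthetic import block_informative_sets, confounding_shift

info = block_informative_sets(["excitatory", "inhibitory"], 41, 5)
cfg = SyntheticConfig(
    paper_binary_composition(),          # 700/724 mouse, 231/68 human
    informative_sets=info,
    domain_shift=confounding_shift(info, 41, magnitude=2.0),
    seed=0,
)
table, truth = generate_cohort(cfg)      # 1723 cells x 41 features
data, _ = run_preprocessing(table, seed=0)   # 1171 / 207 / 345 split
model, history = train_dann(
    DANNConfig(hidden_layers=(64, 32, 8), epochs=400, lambda_=1.0,
               learning_rate=0.05, seed=0),
    data,
)
for organism, report in evaluate_per_domain(model, data).items():
    print(organism, round(report.accuracy, 3), round(report.macro_f1, 3))
```

prints

```
mouse 0.993 0.993
human 1.0 1.0
```

i.e. the jointly trained adversarial model classifies the held-out test
cells of both species (285 mouse, 60 human) at ≈ 1.0 accuracy on this
separable synthetic cohort, despite the strong mouse/human shift. The
same `DataSplit` feeds `train_lspin` for the five-subclass task; the
fitted model's `gate_values(X)` returns the per-cell gate matrix and
`cluster_gate_matrix` orders it for the heatmap.

A command-line interface wraps the same functions:

```bash
neurotype simulate --seed 0 --out runs/sim
neurotype train-dann --data runs/sim/cohort.csv --out runs/dann
neurotype run --config examples/full_run.yaml --out runs/full
```

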