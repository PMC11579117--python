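# Methods

## The two models

### Domain-adversarial broad-type classifier

Let `X ∈ R^D` (D = 41 electrophysiological features) and `Y ∈ {0, 1}` with
0 = excitatory, 1 = inhibitory. Mouse cells are the source domain `S ~ D_S`
(n samples), human cells the target `T ~ D_T` (N − n samples). The goal is
a classifier `η` with low target risk `R_{D_T} = Pr_{(x,y)~D_T}(η(x) ≠ y)`
while keeping the source risk low; a pooled model without correction is
biased toward the abundant source when the marginals differ (the domain
shift). Reported as `risk = 1 − accuracy` on the target test partition.

Three parameter blocks — extractor `θ_f`, label head `θ_y`, domain head
`θ_d` — are trained on the criterion

    E(θ_f, θ_y, θ_d) = mean_i L_y^i − λ · mean_i L_d^i

at its saddle point: `(θ_f, θ_y)` minimize `E`, `θ_d` maximizes it. Both
losses are softmax cross-entropies, averaged over the minibatch. One
training step applies

    θ_f ← θ_f − μ (∂L_y/∂θ_f − λ ∂L_d/∂θ_f)
    θ_y ← θ_y − μ ∂L_y/∂θ_y
    θ_d ← θ_d − μ λ ∂L_d/∂θ_d

implemented as an identity forward / negate-and-scale backward on the
extractor→domain-head edge (gradient reversal). With RMSProp or Adam the
same gradients are fed through the optimizer's state; with SGD the update
equals the rules verbatim, which is what the finite-difference tests check.

Design choices where the design was open:

* **Both species' labels enter `L_y`** (default). The joint model is
  supervised on both domains and reports per-domain metrics from one set of
  weights; `include_target_labels=False` gives the strictly unsupervised
  variant where only source labels carry label loss.
* **λ is constant** during training (the update rules use a constant λ);
  an optional ramp `λ(p) = λ·(2/(1+e^{−10p}) − 1)` over training progress
  `p` is available but off by default.
* **No class or domain reweighting** by default; inverse-frequency label
  weights are available via `class_weight="balanced"`.
* **Checkpointing**: final-epoch weights by default; best-validation
  selection is optional.
* **Weight decay** (L2 added to the gradient) applies to the extractor and
  label head weights; the domain head is a discriminator and follows the
  update rule exactly.
* **Argmax ties** resolve to the lowest class index.

### Locally sparse subclass classifier

A gating network ψ (default 3 × 50, tanh; tanh-bounded output so
`μ ∈ [−1, 1]`, which can saturate any gate fully open or fully closed) maps
each sample to gate parameters `μ⁽ⁱ⁾ = ψ(x⁽ⁱ⁾|Ω)`. Each gate is

    z_d = max(0, min(1, 0.5 + μ_d + ε_d)),  ε_d ~ N(0, σ²),

with σ fixed during training (default 0.5) and 0 at inference, making
inference deterministic. A prediction network `f_θ` (default 41→40→20→5,
tanh) classifies `x ⊙ z`. The loss is cross-entropy plus

    R(z) = λ₁‖z‖₀ + λ₂ Σ_j K_ij ‖z⁽ⁱ⁾ − z⁽ʲ⁾‖²₂.

`‖z‖₀` is not differentiable; it is replaced by its exact expectation under
the gate noise, `Σ_d Φ((μ_d + 0.5)/σ)` with Φ the standard normal CDF (the
probability each gate is open), the standard relaxation in the
stochastic-gates literature. ε is resampled per sample, per feature, per
training forward pass. The kernel for λ₂ > 0 is an RBF on the normalized
input features with median-heuristic bandwidth; the default configuration
uses λ₂ = 0, where the term vanishes.

Defaults are the study configuration: λ₁ = 0.01047, λ₂ = 0, σ = 0.5,
learning rate 0.0599, 1000 epochs, SGD. Batch size is not part of that
configuration and defaults to 64. Training with σ = 0 is rejected: without
noise the gate relaxation degenerates.

The inference gate matrix `Z` (samples × features, entries in [0, 1]) is
the interpretability surface; rows and columns are ordered by agglomerative
clustering (Euclidean distance, average linkage) for heatmap display, where
0 = muted (black) and 1 = passed through (white).

## Preprocessing

Fixed order: load → merge transgenic lines into subclasses → drop rows with
any missing feature → stratified split → z-score. Normalization statistics
are fit on the training partition only and reused for validation and test;
zero-variance features pass through unscaled with a warning. The split uses
largest-remainder rounding within each stratum (organism × broad label by
default), which reproduces the study's 1171/207/345 partition of 1723 cells
exactly, with 285 mouse + 60 human test cells. Normalization is pooled
across organisms because the joint classifier consumes both domains through
one input layer; per-organism statistics are available behind a flag. The
Cre-line → subclass merge map is user-supplied configuration, not
hard-coded.

## The synthetic cohort generator

Each feature is Gaussian: background `N(0, noise_sd²)` plus a mean offset
of `class_effect_size` (default 3) on that class's informative features —
disjoint 5-feature blocks per class by default. The offset is expressed
against the unit-variance baseline, so at the default `noise_sd = 1` it is
the separation in within-class standard deviations. The species shift is a
per-feature affine map `x → scale·x + offset` applied to one domain, with
an optional label-conditional component. Missing values are inserted
completely at random. Identical configurations are bit-identical (one
seeded generator drives everything).

The **strong shift** used by the transfer studies (`confounding_shift`) is
deliberately structured rather than random: offsets of ±2 move the shifted
domain's informative coordinates against the source class geometry (so a
source-only model misreads them), and +2 offsets on five otherwise
uninformative "species marker" features make the two domains trivially
separable in raw feature space. A random isotropic shift often misses the
label-discriminative directions entirely and produces erratic transfer
gaps; the structured shift produces the qualitative phenomenon the studies
probe — large cross-species transfer loss, high raw-feature domain
separability — while remaining a fixed affine map a learned representation
can remove.

What the generator emulates: the cohort sizes and class compositions of the
real data, a sparse informative-feature structure, a species shift, and
missing values. What it does not emulate: feature correlations and
heavy-tailed measurement noise of real electrophysiology, label noise in
dendrite-type annotation, and any relation between feature identity and
physiology. Passing tests therefore demonstrate that the algorithms behave
as designed under known ground truth — not that the real-data accuracy
figures transfer.

## Study protocols (frozen in `neurotype.protocols`)

* **Transfer-gap study.** Per seed: generate the study-composition cohort
  (with or without the strong shift), train a plain classifier on one
  organism only (150 epochs, 32/16 extractor), evaluate on both, average
  the within-minus-cross accuracy gap over the two directions. Median over
  10 seeds.
* **Adversarial-benefit study.** Per seed, on the shifted cohort: train the
  pooled λ = 0 baseline and one model per λ ∈ {0, 1, 2, 3} (400 epochs,
  64/32/8 extractor). Select the candidate with the highest validation
  target-domain accuracy, breaking near-ties (within one validation cell,
  0.011) toward the most domain-invariant representation, measured by a
  balanced logistic probe on validation embeddings — invariance being the
  method's own secondary objective. Report paired target-domain test
  accuracies and balanced domain probes on raw features vs. embeddings.
  The probe is balanced (equal-size domain subsamples for fit and
  evaluation) because the cohort is 83 % mouse: an unbalanced probe scores
  0.83 by majority vote, so only a balanced probe has a 0.5 chance level
  against which invariance is meaningful.
* **Gate-recovery study.** Per seed: a balanced five-subclass cohort (276
  cells per class; 1105 training rows — the same training size as the
  study's subclass task) is trained with the default locally sparse
  configuration. Per class, the margin is the mean inference gate on that
  class's informative features minus the mean gate on its uninformative
  features, over that class's test rows.

## Numerical choices

* Weight initialization: uniform `±1/√fan_in`, seeded; biases zero.
* Dropout is inverted (scaled at train time), applied to hidden extractor
  activations only, never at inference.
* Cross-entropy uses a max-shifted softmax and clips probabilities at
  1e-12.
* Clip-boundary gates (`z` exactly 0 or 1) pass zero gradient; the
  boundary has measure zero under the training noise.
* Largest-remainder rounding breaks allocation ties toward the partition
  with the largest fractional remainder, deterministically.
* Degenerate inputs: empty batches, single-domain training with λ > 0,
  all-rows-missing tables, zero-total confusion matrices and σ = 0
  training all raise informative errors rather than proceeding.

## Known limitations

* **Silent-majority-class degeneracy.** On a cohort where one class holds a
  large majority (e.g. the real mouse subclass composition, 700/1424
  Glutamatergic), the locally sparse model can converge to a solution that
  closes *every* gate for the majority class and predicts it as the
  zero-input default: that costs no cross-entropy (the all-muted pattern is
  unique to one class) and saves the full sparsity penalty. Accuracy is
  unaffected — on such cohorts the model still classifies ≈ 0.99 — but the
  gate matrix for that class is uninformative. This is a genuine property
  of per-sample gating under class imbalance, which is why the
  gate-recovery study uses a balanced cohort; interpretability claims on
  heavily imbalanced data should be checked per class.
* The adversarial saddle-point dynamics oscillate under plain SGD; the
  final-epoch representation's invariance varies across seeds, which the
  validation-probe tie-break in the λ-tuning protocol accounts for.
* Optimizer-state interaction: with RMSProp/Adam the three update rules
  hold for the gradients, not for the realized parameter increments.
* The random-search stage samples the published hyperparameter grid
  uniformly (seeded); it does not emulate adaptive tree-structured search.
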