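# viscocann

Viscoelastic constitutive neural networks for soft biological tissue,
linking local tissue *composition* to nonlinear, time-dependent
*mechanics* — with a relevance-propagation analysis that ranks which
compositional features matter for which part of the mechanical response.

## Who this is for

Researchers in soft-tissue biomechanics who have (a) uniaxial
compression–tension and stress-relaxation measurements on cylindrical
specimens and (b) per-specimen protein concentrations (e.g. 11 ELISA
markers: GFAP, Iba1, MBP, hyaluronic acid, chondroitin sulfate, lumican,
collagens I/IV/VI, fibronectin, laminin), and who want a single material
model that learns the full loading history rather than fitting isolated
stiffness parameters. Brain tissue is the motivating case: ultrasoft,
strongly compression–tension asymmetric, markedly viscoelastic, and
regionally heterogeneous.

## The model

The material is treated as quasi-linear viscoelastic, incompressible and
isotropic. Two small networks form the constitutive law:

**Energy block.** An invariant-based network maps
`(I1 − 3, I2 − 3, c1 … c11)` → `Ψ` (strain energy, kPa), where
`I1 = λ² + 2/λ` and `I2 = 2λ + 1/λ²` are the principal invariants of the
right Cauchy–Green tensor for uniaxial stretch λ, and `c` is the scaled
composition vector. The axial nominal (first Piola–Kirchhoff) stress
follows by exact differentiation,

    P₀ = 2 (λ − λ⁻²) (∂Ψ/∂I1 + λ⁻¹ ∂Ψ/∂I2),

so the undeformed state is stress-free by construction. Hidden layers
(32, 32, 48) use tanh, the output elu; dropout (rate 0.5) follows the
first hidden layer during training.

**Prony block.** A parallel network (11 → 12 → 4, sigmoid) maps the
composition to the parameters of a two-term Prony relaxation kernel

    g(t) = g₀ + g₁ exp(−t/τ₁) + g₂ exp(−t/τ₂),   g₀ + g₁ + g₂ = 1,

through a constraint mapping that makes every output a valid kernel
(weights partition unity, g₀ > 0, τ₁ ∈ [0.01, 10] s < τ₂ ∈ [10, 1000] s).

The time-dependent stress is the Fung convolution
`P(t) = ∫ g(t−s) ∂P₀/∂s ds`, evaluated by the standard recursive
update that is exact for piecewise-linear `P₀`. Training minimizes the
squared stress residual over cyclic loading curves with Adam
(learning rate 0.001, one specimen's 250-point curve per batch,
Glorot initialization); relaxation protocols are held out as pure
predictions. Leave-one-out cross-validation with per-fold best-epoch
selection quantifies generalization, and the αβ layer-wise relevance
propagation rule (α = 2, β = −1) attributes each block's output to the
11 composition inputs.

Because the real tissue datasets of this kind are not publicly
deposited, the package ships a first-class synthetic-data generator with
a known composition→mechanics ground truth (one-term Ogden energy with
fibronectin-driven modulus, cellular-marker-driven Prony weights, the
exact cyclic/relaxation loading protocols, 2 % measurement noise), so
every stage — training, cross-validation, relevance — can be scored as a
recovery experiment.

## Worked example

```sh
viscocann simulate --out data/ --n 10 --seed 7
viscocann train --data data/ --out run/ --epochs 500 --seed 0
viscocann relevance --run run/ --data data/
viscocann report --run run/
```

The `train` step prints one line per fold and a summary such as

```
fold 0 (C-00): best epoch 478, val R^2 0.9726
...
median R^2: train 0.9480, validation 0.9586
```

meaning the trained networks reproduce their training cyclic
stress–stretch curves with a median coefficient of determination of
0.948 and predict the held-out specimen's curve with a median of 0.959.
`report` then lists the top-ranked composition features per block
(here, with ten specimens, GFAP, collagen I and fibronectin head the
energy block and the cellular markers GFAP and Iba1 the Prony block).
A ten-specimen regionally-structured population is too small for clean
causal attribution — features are few-sample-correlated and the region
structure couples them deliberately; the relevance-recovery experiments
in the test suite use larger populations with independently drawn
features, where fibronectin (the generator's sole stiffness driver)
usually tops the energy block; `docs/methods.md` discusses the
remaining attribution limits at desk scale.

The same pipeline is available as a library (`viscocann.synthetic`,
`viscocann.training`, `viscocann.lrp`) for scripted studies.

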