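# Methods

## Constitutive framework

The material model assumes quasi-linear viscoelasticity for an
incompressible, isotropic solid: the stress response separates
multiplicatively into a nonlinear elastic part and a linear relaxation
kernel. For uniaxial loading of a cylindrical specimen (stretch
`λ = (H + Δz)/H`, free lateral faces) the deformation gradient is
`diag(λ, λ^-1/2, λ^-1/2)`, `det F = 1` exactly, and all constitutive
information enters through the invariants `I1 = λ² + 2/λ`,
`I2 = 2λ + 1/λ²` of `C = FᵀF`.

The quasi-elastic axial nominal stress is obtained from the strain
energy `Ψ(I1, I2)` by the chain rule with the hydrostatic pressure
eliminated through the traction-free lateral boundary,

    P0 = 2 (λ − λ⁻²) (Ψ,₁ + Ψ,₂ / λ),

which vanishes identically at λ = 1 through the kinematic factor — no
calibration offset exists anywhere in the model. The history-dependent
stress is the convolution `P(t) = ∫₀ᵗ g(t−s) ∂P0/∂s ds` with the
two-term Prony kernel `g(t) = g0 + Σ gᵢ exp(−t/τᵢ)`, `g0 + Σ gᵢ = 1`.
On a (possibly non-uniform) time grid it is evaluated by the recursive
update

    P(t_{n+1})  = g0 P0(t_{n+1}) + Σ hᵢ(t_{n+1}),
    hᵢ(t_{n+1}) = e_i hᵢ(t_n) + gᵢ κ_i [P0(t_{n+1}) − P0(t_n)],

with per-step `e_i = exp(−Δt/τᵢ)` and `κ_i = (1 − e_i)/(Δt/τᵢ)`; the
`Δt/τ → 0` limit of κ is taken by series expansion below `Δt/τ = 1e−8`
(through `expm1`, so no 0/0 arises). The update is exact for
piecewise-linear `P0`. Each recorded protocol restarts its history
(`hᵢ = 0` at its first sample); protocols begin unloaded, so the choice
of `P(0) = g0·P0(0)` versus `P0(0)` is immaterial. An independent
trapezoidal Stieltjes quadrature of the convolution integral serves as
the oracle in the test suite; the two agree to better than 1e−3
(peak-normalized) at steps of τ₁/20 and converge at second order under
grid refinement.

## Network parameterization

* **Energy block** 13 → 32 → 32 → 48 → 1, tanh hidden activations, elu
  output, dropout rate 0.5 after the first hidden layer (training
  only). Inputs are the shifted invariants `(I1 − 3, I2 − 3)` — zero at
  the undeformed state — multiplied by a fixed scale of 45
  (≈ the reciprocal standard deviation of the shifted invariants over
  stretches 0.85–1.15), plus the 11 standardized composition features.
  The network output parameterizes the correspondingly rescaled energy
  (physical `Ψ` = output / 45), so the network's forward-mode tangent
  with respect to its own scaled input *is* `∂Ψ/∂I` exactly, and the
  untrained stress magnitude starts at the sub-kPa scale of the data
  rather than 45× above it.
* **Prony block** 11 → 12 → 4, sigmoid throughout. The four raw
  outputs `s ∈ (0,1)` map to a valid kernel via `g1 = 0.95 s1`,
  `g2 = (1 − g1) 0.95 s2`, `g0 = 1 − g1 − g2 > 0`,
  `τ1 = 10^(−2+3 s3) s`, `τ2 = 10^(1+2 s4) s`. The disjoint decade
  ranges bracket the loading-ramp (7.5–18.75 s) and hold (300 s) time
  scales and enforce `τ1 < τ2` identifiability.

Composition features are transformed `u = log10(1 + x/x̄)` (the species
span ~6 orders of magnitude) and standardized, with `x̄` and the
moments computed from the **training fold only** — the left-out
specimen never touches any statistic.

All derivatives are exact: forward-mode tangents give `∂Ψ/∂I1, ∂Ψ/∂I2`;
the weight gradient of the loss (which depends on those tangents)
is computed by the adjoint of the joint activation/tangent pass
(second-order backpropagation); the recursion contributes forward
parameter sensitivities and an adjoint map back to `P0`. Everything is
verified against central finite differences in the test suite.

## Training protocol

Adam, learning rate 0.001, Glorot-uniform initialization, up to a
configurable number of epochs (desk-scale default 500 for synthetic
populations; published-scale tissue fits would use 4000). One batch is
one specimen's complete 250-point cyclic curve — the recursion needs
the temporal ordering, so time points are never shuffled; the specimen
order is permuted each epoch. Dropout masks are drawn once per
optimization step and shared along the time series (recurrent-dropout
semantics); per-sample masks would inject artificial high-frequency
noise into the stress increments that drive the history integrals.
Relaxation protocols are excluded from the loss and evaluated as pure
predictions.

Two small penalties complete the loss:

* **Energy normalization** (weight 0.01): `Ψ(identity) = 0`. The stress
  constrains only the energy's derivatives, so a composition-dependent
  offset in Ψ is a flat direction of the data loss; pinning the
  undeformed energy at zero is the canonical normalization of a strain
  energy and makes the energy *value* meaningful for relevance
  analysis.
* **L2 weight decay** (5e−4 on connection weights, never biases).
  Besides the usual generalization role, it shrinks weight directions
  the stress data leave unidentified, which keeps the relevance
  analysis from crediting causally inert inputs. (The original
  tuning of this family of models included an L2 term whose magnitude
  is not published; 5e−4 is this package's fixed default, and the
  relevance-recovery study uses 1e−3, preferring sparser attribution
  over the last fraction of fit.)

Leave-one-out cross-validation trains one model per specimen; per
epoch, the validation R² on the left-out cyclic curve is recorded and
the best epoch's parameters are checkpointed. Reported metrics: median
and standard deviation of training-curve R² (pooled over folds) and of
validation R². A non-finite loss marks a fold failed without aborting
the run. All randomness (initialization, dropout, shuffling) derives
from one run seed plus the fold index; reruns are bit-identical.

## Relevance propagation

The αβ rule (α = 2, β = −1) redistributes each neuron's relevance over
its inputs in proportion to the positive and negative parts of
`z_ij = w_ij x_i` (bias sign-parts enter the denominators). Documented
choices where the rule leaves gaps:

* **Zero-denominator guard** — a neuron with single-signed inputs uses
  the available part with coefficient 1 (the raw rule would inflate by
  α); conservation then holds exactly for every neuron with any
  nonzero input.
* **Bias absorption** — bias relevance is absorbed, not redistributed;
  this is the (small) conservation leak across deep stacks.
* **Seeding** — the energy block is seeded with its energy output at a
  fixed probe set of deformation states (λ ∈ {0.85, 0.9, 1.1, 1.15})
  and the share landing on the invariant inputs is discarded; the Prony
  block is seeded with its four raw outputs jointly by default, or with
  the two kernel-weight heads only (`outputs="weights"`) when the
  question concerns the Prony weights specifically — the relaxation-time
  heads are weakly constrained by cyclic data and mostly contribute
  attribution noise.
* **Aggregation** — per sample, the 11 relevance *magnitudes* are
  normalized to mean 1, then averaged (pooled, and within anatomical
  regions). Signed αβ relevances can nearly cancel in the mean, which
  makes sign-preserving mean-1 normalization numerically explosive;
  magnitudes preserve ranking and the O(1) reporting scale. Only folds
  whose validation R² reaches 0.7 contribute (model-reliability
  filter).

A structural caveat documented here because it shapes every relevance
result: cyclic data constrain mainly the product of the quasi-elastic
stress scale and the long-term kernel fraction, so stiffness drivers
can partially leak into the Prony block's attribution and kernel
drivers into the energy block's. The recovery experiments therefore
compare the cellular trio against extracellular features *excluding*
fibronectin in the Prony block.

## Synthetic-data generator

The generator emulates the full experimental design:

* **Protocols.** Cylindrical specimens (8 mm diameter, default height
  5 mm). Cyclic: three cycles 1 → 0.85 → 1.15 → 1 at 40 µm/s
  (quarter-stroke 18.75 s), 250 samples with turning points on the
  grid (intervals distributed 20/21 per segment — exact extrema were
  preferred over exact uniformity). Relaxation: 100 µm/s ramps to
  λ = 0.85 or 1.15 sampled at 10 Hz, then 50 log-spaced samples over a
  300 s hold.
* **Composition priors.** Per-feature ranges follow the reported
  concentration windows (e.g. GFAP 0.1–1.1, fibronectin 1–58, collagen
  IV 0–62, chondroitin sulfate ~1e−5 ng/mg total protein); fibronectin
  is drawn log-uniformly. Documented per-region sub-ranges reproduce
  the reported regional trends (cellular markers higher in white
  matter, hyaluronic acid higher in cerebral gray matter). These
  sub-ranges deliberately correlate features across regions; recovery
  experiments switch them off (`region_effects=False`) so causes are
  independent.
* **Ground truth.** One-term Ogden energy with exponent −20 (strong
  compression–tension asymmetry of brain-like tissue; the exponent is
  *not* told to the model, which must discover the shape from the
  invariants), modulus `μ = 0.6 kPa · exp(0.4 z_FN)` — fibronectin
  alone drives stiffness. Prony weights come from the cellular markers
  through the same sigmoid constraint mapping
  (`s1 = σ(0.8 z_GFAP + 0.5 z_Iba1 + 0.4 z_MBP)`,
  `s2 = σ(−0.3 + 0.6 z_MBP + 0.5 z_Iba1)`); relaxation times are fixed
  at τ₁ ≈ 3 s, τ₂ ≈ 63 s, both visible on the protocol time scales.
  Gaussian noise with σ = 2 % of each specimen's noise-free peak
  |stress| is added independently per sample. The manifest records
  every coefficient, so noise-free curves are bit-reproducible.
* **What it does not emulate.** Adhesion/tilt artifacts, conditioning
  damage between cycles, temperature drift, inter-donor variability
  beyond the composition draws, and measurement noise correlation.
  Passing recovery tests therefore demonstrate that the pipeline
  identifies a known causal map under clean conditions, not that it
  would do so on real tissue.

## Problem sizes and defaults

The cross-validation analog uses 10 specimens (population seed 7),
500 epochs per fold; it reproduces training cyclic curves with median
R² ≈ 0.95 and predicts held-out curves with median R² ≈ 0.96, with the
occasional poorly-predicted extrapolation fold (consistent with the
large validation spread such small-sample studies report). The
relevance-recovery study uses 20 replicates of 36-specimen
independent-feature populations, two 300-epoch models pooled per
replicate, with weight-head Prony seeding. At this scale the recovery is
partial: fibronectin usually tops the energy-block ranking and the
cellular trio clusters at the top of the Prony-block ranking, but the
strict conjunction (exact top rank plus all three cellular markers above
all seven non-fibronectin extracellular features) fails in a sizable
minority of replicates, through marginal rank inversions rooted in the
block credit-leak above and in finite-sample feature confounding.
Reliable strict recovery would need population sizes and epoch counts
near the original tissue study's scale. Relaxation prediction is reliable in compression (R²
0.8–0.96); in tension the stresses under the asymmetric ground truth
are an order of magnitude smaller and R² of the prediction is poor —
a known limitation shared by the identifiability of slow relaxation
times from cyclic data alone.

## Degenerate inputs and numerical edges

Non-positive stretches, non-increasing time stamps, negative
concentrations, missing features and unknown protocol or region labels
are rejected with messages naming the offending sample/row. R² of a
constant observed series is undefined and reported as NaN with a
warning. The Ogden invariant derivatives on the uniaxial branch come
from the 2×2 chain-rule system, with the analytic λ → 1 limit
substituted inside |λ − 1| < 1e−7. Relevance of an all-zero input
vector is identically zero.
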