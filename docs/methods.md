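# Methods

## The measurement system

Mixed rumen microbes suspended in dilute electrolyte carry a net negative
surface charge; their drift velocity per unit field (electrophoretic mobility
μₑ) is converted to zeta potential ξ through the Henry relation

    ξ = 3 μₑ η / (2 ε_r ε₀ f(κa)),

with η the dynamic viscosity, ε_r the relative permittivity of the medium, ε₀
the vacuum permittivity and f(κa) the Henry factor interpolating between the
Hückel (f = 1) and Smoluchowski (f = 3/2) limits.  Defaults are water at the
incubation temperature of 39 °C (η = 6.66 × 10⁻⁴ Pa·s, ε_r = 73.0) and
f = 3/2, the large-κa regime appropriate for bacteria-sized particles in
aqueous buffer and the convention of PALS-type instruments.  With these
constants one mobility unit (10⁻⁸ m² V⁻¹ s⁻¹) corresponds to ≈ 10.3 mV; the
paired columns of the bundled published table exhibit a median ratio of
10.26 mV per unit with every row within 3.5 % of the median, which is what
`estimate_conversion_constant` checks.  The instrument's exact settings are
not published; these are literature values for the medium, selectable per
call, not asserted instrument constants.  The bare printed form of the
conversion (numerator 3/2 with no Henry factor) is recovered with f = 1.

## Featurization

For each variable V under combinatorial condition c, the expectation ⟨V⟩ is
the arithmetic mean over all replicates and time points of that condition,
and the moving-average (Box–Jenkins) perturbation is ΔV = V − ⟨V⟩.  Two
deliberate choices:

* **Centring split.**  Condition-constant treatment factors (SSA, ST) have
  identically zero within-condition deltas, which would erase them from the
  model; they are centred on the grand mean over all cases instead.  All
  time-varying variables use within-condition centring, so their deltas sum
  to zero within each condition by construction.
* **Standardization.**  ξ is z-scored with the mean and *sample* (n − 1)
  standard deviation over the whole t₁ block.  The expected-measurement input
  ξₑ is the z-score of the condition-mean ξ under the same constants; the
  target is the z-score of the observed ξ.

A modelling case is an ordered pair of one t₁-block case and one t₂-block
case — the unrestricted Cartesian product (t₁-major), which is the only
pairing that reproduces the 216 × 144 = 31,104 case arithmetic of the full
design.  Pairs from different conditions are therefore included by design; a
condition-matched pairing is available as an off-by-default option.  Time
enters as raw hours on both scales.  The 15-input manifest order is
ξₑ, t₁, ΔSSA, ΔST, ΔD, ΔNH₃-N, ΔpH, Δγ, t₂ and the six VFA deltas; when the
optional covariates (D, NH₃-N, pH) are absent — as in the published
condition-mean tables — the manifest shrinks to 12 and is recorded on the
dataset and on every fitted model, keeping fits and sensitivity reports
aligned.

The train/validation split is uniformly random with |train| = round(0.75 n),
driven entirely by an explicit seed.

## Model families

* **Linear (LNN).**  Minimum-norm least squares via `numpy.linalg.lstsq`
  (pseudo-inverse).  Rank-deficient designs are solved, not rejected, with a
  logged warning — the bundled VFA table prints two identical columns, so
  this path is exercised by real data.  Inputs enter raw by default.
* **MLP.**  One hidden layer of logistic units, linear output, mean-squared
  loss.  Phase 1: full-batch gradient descent (backpropagation) with learning
  rate 0.01 and momentum 0.9 — period defaults of the software era the method
  comes from — for 100 epochs.  Phase 2: Polak–Ribière conjugate gradient
  (scipy's CG with the analytic gradient) for up to 500 iterations; the
  refined weights are kept only if they do not increase the loss.  Inputs are
  z-scaled; weights are initialized N(0, 1/√fan-in) from the seed.
* **RBF.**  Centers from Lloyd's k-means (seeded k-means++ initialization,
  ≤ 100 iterations or center shift < 10⁻⁶; empty clusters reseeded to the
  farthest point).  The width of a center is the mean distance to its
  knn_k = 2 nearest other centers, floored at 10⁻⁶ against duplicate
  centers.  Hidden activations are exp(−‖x−c‖²/2w²); the output layer (plus
  bias) is solved by pseudo-inverse, so the training residual is orthogonal
  to the activation design.  Inputs are z-scaled.

Fit reports give, per subset, the Pearson correlation between predicted and
observed values, the sd of the observed values, and the mean and sd of
error = observed − predicted; constant predictions are flagged degenerate
with correlation reported as 0.  Across families, "best" means highest
validation correlation.

## Sensitivity (Var Ratio)

The Var Ratio of input j is RMSE(input j replaced by its evaluation-subset
mean in every case) / RMSE(baseline), evaluated on the training subset by
default.  For a linear model, a zero-weight input gives exactly 1; ratios are
invariant to affine rescaling of the target; ranks are assigned by descending
ratio with ties broken by manifest order.  Mean-substitution is one of
several conventions for this statistic (case-deletion is another); the choice
is documented here rather than asserted as the original analysis software's.

## Synthetic data

The generator reproduces the study layout (12 conditions × 3 replicates,
t₁ grid of six and t₂ grid of four hours) with phenomenological trends:

* ξ(t) = baseline + amp · (1 − (ln(t/24 h)/w)²) + condition effects + noise —
  a quadratic-in-log-time kernel peaking at 24 h (defaults −34.5 mV, 6 mV,
  w = 1.6, SSA effect 1.2 mV per m²/g, ST effect 0.05 mV per mN/m, replicate
  noise sd 0.8 mV), keeping all values inside the observed −40…−20 mV window;
* μₑ = ξ / 10.2308, the conversion constant implied by the published paired
  columns;
* γ relaxes from the condition's initial ST toward a common asymptote
  (46 mN/m, time constant 10 h, 80 % mixing);
* VFAs follow base + amp · exp(−(ln(t/26 h))²) per acid — rising to a ~24 h
  maximum then declining slightly — with small ST effects on propionate and
  isovalerate and 5 % proportional noise, clipped at zero;
* pH drifts down ~0.002 h⁻¹, digestibility saturates (max 0.65, half-time
  6 h), ammonia-N accumulates (12 + 8·t/(t+8) mg/dL).

One design point deserves emphasis: the covariate time profiles saturate
early and carry realistic measurement noise.  With slow, clean profiles, the
five time-varying regressors would span essentially any function on a
six-point time grid, and an affine model could reproduce the rise-then-fall ξ
kernel through cancellation between covariates — erasing the structural
point of the comparison (an additive perturbation model cannot represent the
nonlinear time trend, a kernel-based one can).  Early saturation keeps t₁
itself as the only strong un-saturated time variable, which is also the
physically sensible reading: digestion and ammonia release are fastest in
the first hours of fermentation.

What the generator does **not** emulate: mechanistic fermentation kinetics
(no growth or substrate ODEs), heteroscedastic or correlated replicate
errors, condition × time interactions in ξ beyond the additive effects, and
the real study's replicate-level variance (only condition means are
published; the noise sds here are plausible placeholders).  Tests that pass
on synthetic data therefore validate the pipeline's arithmetic and the
qualitative model-family ordering, not quantitative claims about real rumen
data.

`generate_linear_ptml` overwrites the target with an exact additive function
of the assembled features (plus optional Gaussian noise and an optional
product interaction term), with the generating coefficients stored alongside
the dataset, so least-squares recovery can be checked against ground truth.
With zero noise the fit recovers every coefficient to ~10⁻¹² relative.  Note
that the t₁ × ΔD interaction is only mildly nonlinear in practice: ΔD's
within-condition variation is dominated by its deterministic time component,
which the linear feature set partially spans, so the RBF-over-linear margin
from that term alone is a few hundredths of correlation.  The kernel-driven
block data provide the stronger nonlinearity (RBF exceeds the linear model
by ≥ 0.1 validation correlation at the 12-condition scale).

## Numerical choices and degenerate inputs

* Level snapping on read: SSA/ST values within 0.05 (absolute, configurable)
  of a canonical design level are snapped to it; times must lie exactly on
  the block's grid.  Canonical levels are the measured ones
  (3.37/3.73/4.44 m²/g; 53.95/46.09/42.78/36.07 mN/m).
* CSV round-trips write the shortest exact float representation.
* Constant ξ blocks, all-zero mobilities, perfect models in sensitivity, and
  splits with n < 4 raise typed degenerate-input errors rather than returning
  NaNs.
* Every stochastic operation (generation, splitting, k-means, MLP
  initialization) takes an explicit integer seed and is bit-reproducible.

## Problem sizes used in checks

The automated checks run the full 31,104-case design for counting, linear
fitting and coefficient recovery; model-family comparisons in the test suite
use a 2-replicate design (13,824 cases, 250 RBF centers) and the bundled
condition-mean tables (3,456 cases, 120 centers), while the acceptance script
fits the full-size RBF (794 centers) on the complete design.

## Known limitations

* The published condition-mean table's printed standardized column cannot be
  reproduced row-by-row from the printed means: no affine standardization
  brings all 72 rows within ±0.15 of it (best achievable max deviation
  ≈ 0.32), and one condition's implied means are offset by ~1.5 mV.  The
  column evidently derives from unpublished replicate-level data; the
  package reports the deviation rather than hiding it.
* The RBF-at-least-linear training-correlation property is checked on the
  datasets this package targets; it is not a theorem for arbitrary data and
  center counts (the two models span different function spaces).
* The Henry factor is a user scalar; no κa-dependent interpolation is
  provided.
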