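# Methods

This note documents the models, estimators and numerical choices implemented
in `poprf`, the assumptions behind them, and what the synthetic studies in the
test suite do and do not demonstrate.

## The hierarchical structural model

The HSM encodes the joint stimulus-response function of a local population of
`s3` V1 neurons as a three-layer feed-forward network built from the classical
picture of the early visual pathway: LGN relay cells with center-surround
(difference-of-Gaussians) receptive fields, simple cells formed by feedforward
summation of LGN inputs, and complex-like cells formed by pooling simple
cells.  Its central structural assumption is that the *whole population*
shares one small pool of `s1` LGN-like inputs, which couples the neurons'
likelihoods and regularizes the fit far beyond what per-neuron estimation can
achieve from the same data.

Layer by layer:

* **LGN** (`s1` units, 6 parameters each).  The kernel at pixel `(k, l)` of a
  `p × p` grid is `(α/σc²)·exp(−d²/2σc²) − (β/σs²)·exp(−d²/2σs²)` with
  `d² = (k − μx)² + (l − μy)²`.  Coordinates are 0-based pixel indices;
  centers are continuous in the same frame ("inside the image" means
  `[0, p−1]`); no sub-pixel resampling is performed.  The kernel is evaluated
  literally on the discrete grid — the Gaussians are *not* re-normalized by
  their discrete sums, so with the `1/σ²` scaling a kernel's total mass is
  approximately `2π(α − β)` independent of its widths.  `α` and `β` are not
  sign-constrained: both ON- and OFF-center units are representable, at the
  cost of a sign redundancy against the downstream weights.
* **Hidden layer** (`s2` units) and **output layer** (`s3` units): linear
  integrators with the softplus (logistic-loss) transfer
  `f(x) = log(1 + exp(x − t))`, thresholds `t` per unit, applied inside each
  unit.  Softplus approaches the identity (slope 1) for `x − t ≫ 0` and
  a decaying exponential for `x − t ≪ 0`; its strictly positive output is the
  Poisson rate of the neuron.
* `s2` defaults to `max(1, floor(γ·s3))` with `γ = 0.2`; `s1` defaults to 9.
  Both are meta-parameters outside the likelihood; performance saturates near
  these values and the `sweep` command reproduces that scan.

Parameter count: `6·s1 + s2 + s3 + s1·s2 + s2·s3` (2417 for `s1 = 9`,
`s2 = 20`, `s3 = 103`).  The flat packing order is: per-LGN-unit blocks
`(μx, μy, σc, σs, α, β)`, hidden weights (row-major), hidden thresholds,
output weights, output thresholds.

## Fitting

The objective is the Poisson log-likelihood `Σ_{i,j} y_ij·log M_ij − M_ij`
summed over stimuli and neurons.  The `log y!` term is constant in the
parameters and omitted, which also makes the objective well-defined for the
non-integer responses produced by calcium-signal spike inference.  Responses
enter as-is; no early stopping is used (holding out part of an already small
training set costs more than it saves).

* **Optimizer**: scipy's bound-constrained truncated-Newton (`TNC`) on the
  negative log-likelihood with an analytic gradient; up to 2000 function
  evaluations per restart, `ftol = 1e-8`.  Bounds constrain DoG centers to
  `[0, p−1]` and widths to `[0.01, p]` pixels (the optimizer needs a closed
  interval, so "positive width" is realized as `≥ 0.01 px`); weights and
  thresholds are unbounded.
* **Gradient**: hand-derived reverse-mode differentiation.  The softplus
  derivative is the logistic sigmoid; DoG parameters receive the inner
  product of a per-unit image-weighted sensitivity map with analytic kernel
  partials.  The gradient is validated against central finite differences
  (relative tolerance 1e-4) in the test suite.
* **Numerical stability**: softplus is computed as
  `max(0, u) + log1p(exp(−|u|))` so it never overflows and never underflows
  to exactly zero within float range; `log M` is computed as `u` itself for
  `u < −30` (where `softplus(u) = exp(u)` to machine precision), and the
  ratio `sigmoid(u)/softplus(u)` appearing in the gradient uses its
  asymptotic value 1 on the same branch.  This keeps the objective and
  gradient finite for arbitrarily poor intermediate parameter values.
* **Restarts**: the likelihood is non-convex, so fitting restarts from
  initial values drawn uniformly from configured ranges — centers over the
  full image extent, `σc ~ U(0.5, p/8)`, `σs ~ U(0.5, p/2)`,
  `α, β ~ U(0, 1)`, weights `U(−0.1, 0.1)`, thresholds `U(0, 1)` (a
  small-signal start inside the bounds; the ranges live in the config so
  sweeps can vary them).  Defaults: 50 restarts for production fits, 20 for
  meta-parameter sweeps.  The selected restart is the one with the highest
  *training-set performance*, defined as the mean per-neuron Pearson
  correlation between predictions and the single-trial training responses;
  the log-likelihood of every restart is recorded alongside (the two
  selectors rarely disagree, and correlation is the quantity reported
  everywhere else).  Restart seeds spawn deterministically from the master
  seed, so a fit is bitwise reproducible.
* **Per-neuron condition**: each neuron is refit as an `s3 = 1` model with
  the same `s1` and with `s2` held at the *population* value, so the only
  removed ingredient is the sharing of inputs across neurons.  (Scaling `s2`
  to the single neuron would conflate the ablation with a capacity change.)
* Different restarts routinely reach different parameters with nearly
  identical input-output behavior (permutation and sign redundancies, plus
  genuine non-identifiability at realistic data sizes).  Recovery is
  therefore always assessed on predicted *responses*, never on parameters.

## The regularized LN baseline

For each neuron the linear kernel is `k̂ = pinv(SᵀS + αL)Sᵀr`, where `S` is
the `(n, p²)` matrix of flattened training images and `r` the neuron's
responses.  `L` is realized as `DᵀD` with `D` the 5-point discrete Laplacian
with reduced stencils at borders (no wraparound — RFs near borders must not
couple across edges): penalizing the squared Laplacian is what makes the
quadratic form positive semidefinite and biases kernels to be locally smooth
rather than small, with constants in the null space.

`α` is selected per neuron by maximizing the Pearson correlation of the
*linear-stage* prediction on a 10% holdout of the training stimuli; the split
is one seeded shuffle shared by all neurons, and the kernel is refit on the
full training set at the selected value.  The default grid is 10
logarithmically spaced values spanning `1e-2` to `1e5` times
`trace(SᵀS)/p²` (the mean per-pixel stimulus energy), making the grid
meaningful across image contrasts and training-set sizes; ties take the first
(smallest) maximizer.

The point nonlinearity is a histogram fit: the range of training filter
outputs is split into 20 equal bins, each bin's value is the mean response of
the points in it, empty bins are filled by linear interpolation between their
non-empty neighbors, and prediction interpolates linearly between the two
nearest bin centers (clamping outside the training range).  Constant filter
outputs or a constant holdout response are rejected as degenerate.

No intercept or mean-subtraction is applied anywhere — images are used as
stored.  One documented consequence: when the response has a large constant
offset relative to its stimulus-driven variance, the offset leaks into the
kernel estimate through the finite design (there is no bias column to absorb
it), inflating kernel noise.  With per-image-standardized stimuli a kernel is
likewise only identified up to an additive constant.  Both effects are mild
at realistic response statistics and are exercised explicitly in the tests.

## Evaluation

All performance statistics use the validation set: `v` held-out stimuli with
`r ≥ 2` trials per neuron.

* **Correlation**: Pearson r between the prediction and the trial-averaged
  response, per neuron; zero-variance predictions or means yield NaN.
  Significance uses a percentile bootstrap over validation stimuli (default
  1000 resamples): a neuron is significant iff its 95% CI excludes zero.
* **Power decomposition** (per neuron, across-stimulus variances with
  `ddof = 1`): `total = mean over trials of Var_s(single trial)`;
  `signal = (r·Var_s(trial mean) − total)/(r − 1)` (the unbiased estimator
  that removes the trial-mean's noise inflation); `noise = total − signal`.
  `signal + noise = total` holds exactly.  Normalized noise power is
  `noise/total`, clipped to `[0, 1]` with a flag when clipping occurred.
* **FEV**: `(signal − (MSE(pred, trial mean) − noise/r)) / signal` — the
  fraction of *signal* power captured, after subtracting from the MSE the
  part attributable to noise in the trial mean itself.  An oracle predictor
  (the true rate) scores 1 in expectation and a constant predictor 0.
  Neurons with normalized noise power above 0.70 are flagged out of FEV
  summaries (their correction term is unreliable); neurons with non-positive
  signal estimates (possible at small `r`) are reported as undefined rather
  than clipped.
* **Linearization and NLI**: the fitted HSM is linearized by running the full
  rLN pipeline with the HSM's responses to the training images in place of
  recorded responses.  The non-linearity index is
  `(LC − max(LLC, 0))/LC`, set to 0 when `LC < LLC` and when `LC ≤ 0` (the
  ratio is meaningless there); NLI always lies in `[0, 1]`, and is ≈ 0 for a
  generator operating in the softplus linear regime.
* Population summaries pool the mean over all neurons (per-region tables are
  emitted alongside by the CLI, so either convention can be read off).

## Synthetic data

The generator emulates the experimental data layout exactly: an `(n, p, p)`
training stimulus stack, an `(n, m)` single-trial response matrix, and a
`(v, m, r)` validation tensor (defaults: 1800 training images, 50 validation
images × 10 trials, `p = 31`).

* **Stimuli** are spectral noise with radially averaged power `∝ 1/f^e`
  (default `e = 1`), standardized to zero mean and unit variance per image —
  a copyright-free stand-in for natural scenes that reproduces their
  second-order statistics.  Higher-order natural-image structure (edges,
  objects, sparseness) is *not* emulated, so passing tests demonstrate
  correctness of the estimators, not performance figures transferable to
  real recordings.
* **Ground-truth populations** draw DoG centers in the central half of the
  grid with surrounds 1.5-3× the center width; each hidden unit is a sparse
  signed mixture of up to 3 LGN units (push-pull, oriented subunits), and
  output units pool hidden units with non-negative weights — a genuinely
  nonlinear population that shares its inputs.  A scalar gain on the output
  weights is calibrated by bisection (monotone by construction) until the
  mean rate over a ≥200-image calibration batch is within 2% of the target
  mean rate (default 2.0 inferred spikes per presentation, a typical evoked
  count for a 500 ms natural-image flash in mouse V1 L2/3).
* **Emission** is Poisson per stimulus × neuron (× trial), matching the
  fitting likelihood.  A Gaussian mode (additive, clipped at zero) exists to
  probe likelihood misspecification, and a noiseless mode returns the rates
  themselves; both are off by default.  Calcium dynamics, imaging noise and
  spike-inference artifacts are out of scope.

## Problem sizes used in the shipped studies

The test suite and `scripts/acceptance.py` run the full pipeline at reduced
scale, chosen as the smallest sizes at which every qualitative effect is
stable across seeds: response recovery uses `s1 = 2, s2 = 2, s3 = 3` with 500
noiseless training images and 10 restarts (held-out correlation with the true
rates > 0.9, in practice > 0.99); the model comparison uses 6-8 neurons
sharing 3 DoG inputs, 300-400 Poisson training trials, 50 validation images ×
8-10 trials, 6-8 restarts for the population fit and a matched total restart
budget (1 per neuron) for the per-neuron condition.  At these sizes the
population HSM consistently outperforms both the rLN baseline and the
per-neuron HSM in validation correlation and FEV — the same ordering as at
full scale — while the entire suite runs in well under a minute of fitting
time.  Full-scale numbers (hundreds of neurons, thousands of images, 50
restarts) require hours of CPU per fit and the original recordings.

## Known limitations

* No temporal RF structure: the model maps one static image to one rate per
  presentation; spike-history and coupling filters are out of scope.
* HSM parameters are functional descriptions, not circuit estimates: many
  parameterizations realize the same response function, and the fitted `s1`
  and `s2` undercount the true afferent populations.
* The Poisson likelihood is an approximation for deconvolved, sliding-
  averaged calcium responses; the Gaussian simulation mode exists to measure
  the cost of that approximation.
* The rLN baseline has no intercept; its kernel estimates degrade for
  responses whose mean greatly exceeds their stimulus-driven variability
  (see above), and with zero-mean stimuli kernels are identified only up to
  an additive constant.
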