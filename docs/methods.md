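# Methods

## Signal model and feature extraction

One sample from a voltammetric e-tongue is a matrix `X ∈ R^{m×d}`: `m`
working electrodes recorded at `d` time points while the cell is driven by a
shared multi-frequency pulse excitation. Because the excitation is common to
all electrodes, each response is dominated by a highly correlated
excitation-locked component; the class information lives in the small
differences between electrodes. For any pair `(i, j)`,

    x_i = x_c^{ij} + x_s^{ij},   x_j = x_c^{ij} − x_s^{ij},

with `x_c = (x_i + x_j)/2` the common mode and `x_s = (x_i − x_j)/2` the
specificity component. Feature specificity enhancement (FSE) evaluates a
kernel of each pair,

    Z_ij = exp(−‖x_i − x_j‖² / (2σ²)),  i ≠ j,

which depends only on `2 x_s` — the common mode cancels identically, not
approximately. The feature count is `m(m−1)` (30 for six electrodes)
independent of `d`, and extraction is unsupervised.

All `m(m−1)` ordered pairs are emitted by default even though the RBF makes
`Z_ij = Z_ji`; the flattening order is row-major `(i, j)` for
`i = 1..m, j ≠ i`. The duplication is deliberate fidelity to the method as
used in practice; `FSEConfig(unique_pairs=True)` emits only the
`m(m−1)/2` unordered pairs. No input normalization is applied by default —
σ is a width in raw response units and per-electrode z-scoring (available
behind `FSEConfig(zscore=True)`) would break the exact common-mode
cancellation whenever channel scales differ. The kernel-width default is
σ = 10, the center of the width range over which recognition accuracy is
flat on simulated data (see the sweep discussion below). `d = 1` inputs are
legal (kernels of scalars); only the RBF kernel is implemented —
"polynomial" and "sigmoid" are reserved names that raise.

The contrast method KBM applies the same kernel to each electrode's raw
norm, `Z_i = exp(−‖x_i‖²/(2σ²))`. It exists to quantify what common-mode
removal buys: any shared component inflates every `‖x_i‖` and saturates
these features.

## Classifiers

**KELM.** With one-hot targets `T ∈ R^{N×C}` (classes ordered
lexicographically; each row has exactly one 1) and kernel matrix
`K_ij = k(x_i, x_j)`, the dual coefficients solve `(K + I_N/μ) A = T` and a
query scores `f(x) = k(x, ·) A`. `K + I/μ` is symmetric positive definite
for the RBF kernel, so the solve is a Cholesky factorization, never an
explicit inverse. Predicted class = argmax score, ties broken toward the
lowest class index. The KELM kernel reuses the RBF form with its own width,
`exp(−‖u−v‖²/(2θ²))`; whether the denominator is `2θ²` or `θ` is a
convention that only relabels the sweep axis. Defaults are μ = 1000 and
θ = 10, the empirically favorable settings for features bounded in (0, 1];
μ is the same quantity that sensitivity sweeps usually call γ. A linear
(inner-product) kernel is provided because it makes KELM exactly equivalent
to ridge regression with penalty 1/μ — the package's correctness oracle.

**ELM.** The random-hidden-layer variant draws `W, b` uniform on [−1, 1]
from a seed, applies a numerically stable sigmoid, and computes the output
weights by whichever of the two equivalent closed forms is cheaper:

    β = (HᵀH + I_L/μ)⁻¹ HᵀT        (N ≥ L)
    β = Hᵀ (HHᵀ + I_N/μ)⁻¹ T       (N < L)

The second branch is written here in the standard dual form with an `N×N`
identity; printed treatments of the under-determined branch sometimes carry
a dimensionally inconsistent `HᵀH`, which cannot be combined with an `N×N`
identity — the two forms above are the ones that are algebraically
identical (tested to 1e−6 on square-ish problems).

## The MLAPV simulator

The generator emulates the acquisition design of a six-electrode MLAPV
e-tongue: a 60 s excitation cycle of three frequency segments (0.2, 1,
2 Hz), each stepping through five pulse amplitudes (1.0 → 0.2 V, 50% duty),
sampled at 150 Hz → 9000 points per electrode; 7 beverage classes × 3
concentrations (14%, 25%, 100%) × 3 replicates = 63 samples. A benchmark
mimic produces 114 samples of 6 × 2050 in 13 classes (ten classes of 9 and
three of 8 — the most even partition of 114 over 13).

Pulse timing is resolved in samples: each segment occupies five pulse
periods (32.5 s total for the default programme) and the remaining time is
split as evenly as possible into zero-valued blanks between segments —
blank lengths are not part of the published design, so an even split is
used and is configurable. The benchmark's 2050-point records reuse the same
60 s programme at the correspondingly lower effective sampling rate.

Each electrode's response is

    r_e(t) = A_cm · h_cm(t)  +  conc^κ · s_e · Σ_a g[c, e, a] · h_e^{(a)}(t)  +  ε(t),

where `h(t)` are first-order RC charge/discharge transients of the pulse
edges (`lfilter` with per-electrode time constants 0.10–0.35 s; 1.0 s for
the common template), `A_cm` the common-mode gain, `s_e` the electrode's
specificity sensitivity, and `g[c, e, a]` a per-class gain for each pulse
amplitude. Design choices, with reasons:

* **Common mode 10× the strongest specificity signal**
  (`common_mode_gain = 1000` vs max sensitivity 100): raw traces are
  dominated by the shared excitation response, the regime the method is
  designed for.
* **Log-normal class gains** (`exp(3.0·N(0,1))`): electrochemical couplings
  between an analyte and dissimilar electrode metals vary over orders of
  magnitude, and multiplicative spread is what makes the kernel features
  flip fully between classes rather than shift marginally.
* **Sensitivities spanning ~4 decades** `(100, 3, 0.08, 0.012, 0.009,
  0.006)`: a strongly catalytic noble electrode down to a trio of
  passivated low-current metals. The values are chosen so that pairwise
  squared distances populate the decades that kernel widths of interest
  probe; with near-equal sensitivities the feature set is informative only
  in a narrow width band.
* **Concentration as deformation, not just scale**: amplitude scales as
  `conc^0.1` (strongly sublinear, adsorption-saturated), and dilution also
  *deforms* the gain pattern along a class-specific direction
  (`gains · exp(0.4·(1−conc)·M)`). Dilution series of real beverages change
  the response shape, not merely its size; without this, the three
  concentration clusters of a class collapse onto a one-parameter curve
  that a kernel classifier cannot use.
* **Absolute noise floor** (`noise_sd = 3e−5` instrument units, identical
  on all channels): an input-referred amplifier/ADC floor, about 1% of the
  weakest electrode's signal. Channel-proportional noise would bury the
  small-electrode pairs on which small kernel widths rely.
* **Randomness**: one top-level seed; stream 0 draws class gains and
  modulation directions, stream 1 draws measurement noise in sample order.
  With `noise_sd = 0` the generator is a deterministic function of the
  spec.

What the simulator does *not* emulate: electrode kinetics
(Butler–Volmer currents, double-layer charging), drift and hysteresis
between replicates, cross-contamination, or the real datasets' accuracy
values. Passing tests on simulated data demonstrate the pipeline's
correctness and the common-mode mechanism, not field performance.

## Evaluation protocols

* `loo_replicate`: for a balanced design with R samples per class, round r
  holds out the r-th sample of every class — 9 rounds of 56 train / 7 test
  on the 63-sample design. (The field often calls this "leave-one-out"
  although one sample per *class* is left out per round.)
* `fourfold`: seeded stratified grouping; every class reaches every group
  and group sizes are maximally even (28/29/28/29 for 114 samples).
  Within-class assignment is the seeded part; the design does not dictate
  it.

Accuracy is aggregated as mean and sample standard deviation (ddof = 1) of
per-split accuracies, reported in percent to two decimals. Feature
extractors are fitted on training indices only (trivially so for the
stateless FSE/KBM; materially for the PCA baseline). Baseline adapters
(PCA, DWT features; SVM with C = 1000 and kernel coefficient 0.001, random
forest with 50 trees, LDA, Gaussian NB) delegate to scikit-learn and
PyWavelets and are conveniences for comparison grids, not part of the core
method. Sweep points that fail (e.g. classifiers that cannot handle
features that have underflowed to exactly zero at extreme widths) are
recorded with a diagnostic rather than aborting the sweep.

## Numerical notes

* RBF features underflow to exactly 0 once `‖Δ‖²/(2σ²) > ~745`; this is
  expected at extreme widths and is the documented failure mode of some
  baseline classifiers there.
* The KELM solve raises a diagnostic `NumericalError` if the regularized
  kernel matrix loses positive definiteness (possible only through
  non-finite inputs; the RBF kernel plus `I/μ` is SPD for finite data).
* Text serialization uses `%.17e`, which round-trips float64 exactly
  (tables are re-read with pandas' `round_trip` parser); `.npz` bundles are
  the binary fidelity format.

## Kernel-width sensitivity: what the simulator reproduces and what not

Sweeping σ over {1e−3 … 1e3} on a default-seed dataset, accuracy rises
steeply through σ ≈ 0.1–1 and is flat within a few points over roughly
σ ∈ [3, 100], with the default σ = 10 at the plateau center — recognition
is insensitive to the width over about two decades. The simulator does
**not** reproduce width-insensitivity over the full four decades
[0.1, 1000] that rich laboratory data can show, and the acceptance check of
that four-decade band fails honestly. The limitation is structural, not a
tuning artifact: six electrodes yield only 15 informative pair distances,
and a single RBF scalar is class-discriminative over at most ~2–3 decades
of squared distance around `2σ²` (below that it saturates to 1 and the
μ = 1000 ridge absorbs the contrast; above it underflows to 0). Covering
eight decades of distance with enough redundancy (~5 informative pairs per
width) would require roughly twice as many electrode pairs as exist.
Real recordings escape the budget because each electrode pair's distance is
not a single parametric scale but spreads quasi-continuously across decades
with large between-class dispersion at every scale.
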