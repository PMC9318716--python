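# Methods

## Ordinal encoding and the PE estimator

Each window of `m` consecutive samples is encoded as its *rank vector*:
entry `j` holds the rank of sample `j` within the window, 1 being the
smallest. Ties are resolved by temporal index — the earlier sample gets the
smaller rank — using exact floating-point comparison, with no tolerance:
any epsilon would itself need justification, and for continuous-valued data
exact ties are measure-zero (for heavily quantized data the tie rule
injects spurious ascending structure regardless of how equality is
tested). Note that this is the rank convention, not the argsort (inverse
permutation) convention used by some other ordinal-analysis packages; the
two give identical entropies but permuted pattern labels, a common source
of off-by-inverse confusion when comparing pattern tables across tools.

The estimator is the plug-in Shannon entropy over *visited* patterns plus
the Miller–Madow correction `(M̂ − 1) / (2 (N − m + 1))`, where `M̂` is the
number of distinct patterns observed and `N − m + 1` the number of
windows. Patterns with zero count contribute to neither term. All
entropies are in nats; the normalized value divides by `log(m!)`. The
correction compensates the negative bias of the plug-in estimator; for a
monotone series (single pattern) both terms are exactly zero, and for
white noise the corrected normalized PE fluctuates around 1 and may
slightly exceed it.

Two analytic variability estimates are provided for comparison with the
surrogate-based one. For a memoryless multinomial symbol source the PE
standard deviation is, to leading order, `sqrt(Λ̂₀ / (N − m + 1))` with
`Λ̂₀ = Σ p̂ log²p̂ − (Σ p̂ log p̂)²` — the population variance of `−log p̂`.
This leading term vanishes when the pattern distribution is uniform; the
floor it then falls to is the uniform-multinomial limit
`sqrt((m! − 1) / 2) / N`, which dominates in the high-noise regime where
all patterns are equiprobable. The overlap of consecutive windows makes
the symbol stream non-memoryless in general, which is precisely why these
closed forms are comparison baselines rather than the method itself.

## IAAFT surrogates

Spectral surrogate methods implicitly assume periodicity, so a mismatch
between the first and last sample produces artifacts. Instead of trimming
(which discards data, unacceptable for experimental series), the series is
detrended by subtracting the straight line through its endpoints; the
perturbation to any one window is of order `m·σ/N` and is negligible for
`m ≪ N`. The detrended original is the series the PE value, and therefore
its uncertainty, refer to.

Each IAAFT cycle (i) takes the Fourier amplitudes of the original with the
phases of the current iterate, (ii) inverse-transforms, and (iii)
rank-remaps the result onto the original's sorted values. The real-input
FFT (`numpy.fft.rfft`) enforces Hermitian symmetry; the DC and Nyquist
bins of the iterate are real, so their phases are automatically restricted
to {0, π} and the inverse transform is real without any imaginary residue
to discard. Every iterate therefore carries the original's amplitude
multiset *exactly*, while the spectrum is conserved approximately — the
relative spectral discrepancy decays like `N^(-3/2)` and is below `1e-2`
for the series lengths of interest here.

Iteration stops when the squared Euclidean distance between consecutive
iterates drops below `1e-6` of the iterate's squared norm. The iterate
compared is the rank-remapped output of step (iii), the natural end of a
cycle. Two guards supplement the threshold: the map can lock into a cycle
of rank orderings (most often period 2), detected by comparing the current
ordering with the previous two and treated as terminal (no further change
is possible, so the iterate is accepted); and an all-zero input returns
immediately, since `0 < 0` would never satisfy the threshold. The
iteration cap defaults to 1000 cycles; a capped, non-converged surrogate
is kept — with a logged warning — rather than regenerated, so ensemble
size and seeding stay deterministic. In practice convergence takes tens of
cycles at `N ≈ 10⁴`.

Ensembles are seeded through `numpy.random.SeedSequence(seed).spawn(L)`,
one child stream per surrogate: reproducible given `(x, L, seed)`,
mutually independent across surrogates. Each surrogate is endpoint-
detrended after generation, as the uncertainty pipeline requires;
this second detrending slightly perturbs the amplitude multiset, which is
exact for the raw IAAFT output.

## The uncertainty assignment

`estimate_pe_with_uncertainty` runs detrend → ensemble → per-surrogate PE
→ `Σ = α·s`, with `s` the (L−1)-denominator sample standard deviation of
PE over the ensemble. Defaults: `L = 100`, a trade-off between the
sampling error of a standard deviation (relative error ≈ `(2L)^(-1/2)`,
about 7% at L = 100) and cost; `α = 2`, the reciprocal of the lower edge
of the surrogate-to-reference ratio band observed on the synthetic benches
(below). `α` is an educated guess by construction: it approaches 1 when
the series is noiseless-deterministic or noise-dominated and 2 when signal
and noise are comparable, so the default is the conservative choice.

## Synthetic benches and the validation benchmark

The generators' defaults are the study conditions of the validation:
series length `N = 10006` (so that `N − m + 1 = 10⁴` windows at `m = 7`),
burn-in of 1000 samples, `L = 100`.

**Lorenz.** `dx/dt = a(y−x)`, `dy/dt = x(c−z)−y`, `dz/dt = xy−bz` at
`(a, b, c) = (10, 8/3, 28)`, sampled every `dt = 0.3` — a sampling
interval; internally the 8th-order adaptive Dormand–Prince integrator
(`scipy` DOP853) subdivides each interval to tolerance `1e-10` (a config
field, like the initial condition drawn uniformly from `[−10, 10]³`).
Observational noise adds `σ_Lorenz · η · ε_n` with `ε_n` standard normal;
`σ_Lorenz = 7.9252822` is pinned as a constant — the long-run standard
deviation of the noiseless x coordinate at these parameters, reproduced by
the calibration run in `scripts/acceptance.py` — so that `η` always means
the same thing (power signal-to-noise ratio `η⁻²`) regardless of the
realization. Negative `η` is rejected.

**ARFIMA.** `x_n = Σ_{k=1}^{kmax} c_k x_{n−k} + ε_n` with
`c_k = ρ Γ(k−ρ) / (Γ(1−ρ) Γ(k+1))` evaluated through log-Γ, truncation
`kmax = 100`, zero-initialized history absorbed by the burn-in, and
standard-normal innovations. `ρ ∈ [0, 1)`: 0 is white noise, values near
1 give long memory; negative `ρ` (anti-correlated) is rejected. The
recursion is an all-pole filter and is evaluated by `scipy.signal.lfilter`.

**Benchmark.** The *reference* PE spread is the sample std over `L`
independent detrended realizations (realization 0 is the configured one;
the other seeds are derived deterministically from it, so they cannot
collide). The *surrogate* spread is the sample std over `L` IAAFT
surrogates of realization 0. Their ratio `s_Y / s_X` is the figure of
merit: on these benches it stays within `[0.5, 1]` unless the
autocorrelation time gets very long, which is what licenses `Σ = α·s`
with `α ≤ 2`. The observed ratio at the canonical setting (ARFIMA
`1 − ρ = 0.5`, `m = 4`) is reproduced by `scripts/acceptance.py`; the
test suite additionally checks a widened band `[0.45, 1.1]` across three
seeds to absorb seed-to-seed scatter.

Because the surrogate ensemble is anchored to realization 0, its PE mean
tracks that realization's PE, which itself scatters across realizations
with std `s_X`. The two ensemble means therefore coincide at the scale of
the realization spread — not at the (≈10× smaller) standard error of the
mean — and that is the scale at which the test suite asserts their
agreement. For a noiseless chaotic source the surrogate mean sits
systematically *above* the reference mean: linear surrogates cannot
replicate deterministic structure, and that excess is itself a useful
nonlinearity signature.

## Validation statistics

Two PE values with uncertainties are compared by a two-sided z test,
`z = (h₂ − h₁)/sqrt(σ₁² + σ₂²)`. A sequence of segment-wise PE values is
tested against a drift law `a + bk + ck²` (or `a + bk`) by weighted least
squares; the model is linear in the coefficients, so the minimum of the
normalized residual sum `S = Σ [(h_k − model(k))/Σ_k]²` is found in closed
form via the weighted normal equations (`numpy.linalg.lstsq` on the
scaled design). With six points the quadratic fit leaves ν = 3 degrees of
freedom (ν = 4 linear), and under the null hypothesis — error bars correct,
drift law adequate — `S_min` is χ²_ν distributed; the upper-tail
probability flags segments where the drift model fails (p < 0.01). The
χ²₃ density `sqrt(x/2π) e^(−x/2)` is provided explicitly as the reference
curve for histogramming `S_min` values. The module is scale-agnostic:
values and uncertainties may be in nats or normalized by `log(m!)` as long
as they share a scale (normalized, in the EEG-style use case).

## What the synthetic benches do and do not show

The two benches emulate observational noise on deterministic chaos and
intrinsic stochasticity with tunable memory. They do not emulate
nonstationarity within a segment, quantization/heavy ties, missing
samples, or point-process data (for which spectral surrogates are
unsuitable). A passing benchmark therefore supports the method for
approximately stationary, continuously distributed series at moderate
`m ≪ log N / log m`-ish pattern budgets; it says nothing about drifting
sources — which is exactly what the drift-fit machinery is for
downstream.

## Problem sizes and numerical choices

- The Lorenz calibration uses 3×10⁵ post-transient samples, where the
  sample std of the x coordinate is stable to well under 1%.
- The benchmark ratio uses the full study conditions
  (`N = 10006`, `L = 100`, `m = 4`), a few seconds of work; spot checks at
  several seeds stand in for a full parameter-grid sweep, which
  `run_sweep` / `pevar ratio --config` expose as an explicit long-running
  option.
- Integrator tolerance tightening is verified over a short horizon
  (30 samples, 9 time units): for a chaotic flow with Lyapunov exponent
  ≈ 0.9 nat per time unit, a `1e-10` local perturbation saturates the
  attractor diameter within ~25 time units, so trajectory-wise
  convergence can only be asserted before that horizon; afterwards only
  distributional statistics (like `σ_Lorenz`) are meaningful.
- The drift-fit null calibration (2000 replicates) checks both the χ²₃
  shape (Kolmogorov–Smirnov) and the false-positive rate of the p < 0.01
  outlier rule.

## Known limitations

- Non-converged IAAFT surrogates are kept (flagged, warned) to preserve
  determinism; at pathological inputs this can bias `s` slightly.
- The `α = 2` default is calibrated on these two benches; for sources far
  from both (e.g. strongly multimodal amplitude distributions), the
  ratio band `[0.5, 1]` has not been verified here.
- Delay-embedded ordinal patterns (lag τ > 1) and entropy-rate
  extrapolation over `m` are out of scope.
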