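# pevar — permutation entropy with surrogate-based uncertainty

Permutation entropy (PE) is widely used to track changes in the randomness
of a signal — EEG segments, optical intensity records, geophysical series —
but a PE value without an error bar cannot support a claim that two
segments actually differ. When the source cannot be re-run (one recording,
one event), the usual route of repeating the measurement is closed.

`pevar` implements a practical answer for users of PE who have exactly one
time series: estimate the variability of the PE statistic from an ensemble
of IAAFT surrogates of that same series. IAAFT (iterative amplitude-adjusted
Fourier transform) replicas keep the amplitude distribution of the original
exactly and its power spectrum — hence autocorrelation, hence the local
window structure PE is built on — approximately, so the spread of PE across
the ensemble tracks the spread that independent realizations of the source
would show.

## The method

For a series *X* of length *N* and pattern dimension *m*, each window of
*m* consecutive samples is encoded as its rank vector (ties broken by
temporal index), and

H&#770;<sub>m</sub>(X) = −Σ<sub>S</sub> p&#770;<sub>S</sub> log p&#770;<sub>S</sub> + (M&#770;−1)/(2(N−m+1)),

the plug-in Shannon entropy of the observed pattern frequencies plus the
Miller–Madow bias correction (M&#770; = number of visited patterns; natural
logarithms throughout). The uncertainty of this single number is assigned
as:

1. detrend *X* so its endpoints coincide (subtract the line through the
   first and last sample);
2. generate L IAAFT surrogates of the detrended series, detrending each;
3. compute PE on every surrogate and take the sample standard deviation
   s<sub>H&#770;m</sub>(Y) over the ensemble;
4. report Σ<sub>H&#770;m</sub> = α · s<sub>H&#770;m</sub>(Y).

Defaults are L = 100 (relative sampling error of s ≈ (2L)<sup>−1/2</sup> ≈ 7%)
and α = 2, which covers the systematic underestimation of the surrogate
spread relative to truly independent realizations; α ≈ 1 is appropriate in
the noiseless-deterministic and noise-dominated limits, α ≈ 2 when signal
and noise are comparable.

The package also ships the two synthetic benches used to validate the
method — the Lorenz attractor with observational noise and an ARFIMA
long-memory process — together with the benchmark comparing the surrogate
spread against the reference spread over independent realizations, and the
statistics used to exploit the error bars downstream (two-sided z test for
a pair of PE values, weighted quadratic/linear drift fits with χ²-
distributed residual sums).

## Worked example

```python
import numpy as np
import pevar

# an ARFIMA(rho = 0.5) series: stochastic, moderately autocorrelated
x = pevar.simulate_arfima(pevar.ARFIMAConfig(rho=0.5, seed=1))
res = pevar.estimate_pe_with_uncertainty(x, m=4, l=100, alpha=2.0, seed=1)
print(f"H_4 = {res.estimate.h:.4f} +/- {res.sigma:.4f} nats")
print(f"normalized: {res.estimate.h_normalized:.4f}")
print(f"surrogate std s = {res.s_surrogate:.2e}, alpha = {res.alpha:g}")
```

prints

```
H_4 = 3.1493 +/- 0.0043 nats
normalized: 0.9910
surrogate std s = 2.16e-03, alpha = 2
```

The PE of this realization is 3.1493 nats, 99.1% of the maximum log(4!)
— the series is close to, but measurably below, white noise. The
surrogate ensemble spread is 0.0022 nats; scaled by α = 2 it gives the
error bar ±0.0043. For comparison, the reference spread across 100
independent ARFIMA realizations at these settings is 0.0028 nats, so the
unscaled surrogate estimate recovers the true variability to within the
expected factor of 0.5–1:

```python
r = pevar.ratio_experiment(pevar.ARFIMAConfig(rho=0.5, seed=1), m=4, l=100)
print(f"s_Y / s_X = {r.ratio:.3f}")   # -> s_Y / s_X = 0.801
```

Two PE values with error bars can then be compared:

```python
z, p = pevar.z_test_pe(0.487, 0.006, 0.507, 0.007)
print(f"z = {z:.2f}, p = {p:.3f}")    # -> z = 2.17, p = 0.030
```

The same pipeline is available from the shell:

```sh
pevar simulate arfima --rho 0.5 --seed 1 -o series.txt
pevar uncertainty series.txt -m 4 -L 100 --alpha 2 --seed 1 -o report.json
pevar ratio --system arfima --rho 0.5 -m 4 -L 100 --seed 1
```

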