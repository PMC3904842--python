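# pulsedecon

Sparse blind deconvolution of pulsatile hormone time series.

Serum cortisol is released in 15–22 discrete secretory events per day.
Given only a coarsely sampled concentration series (one sample every
10 minutes for 24 h), `pulsedecon` recovers

* the number, timing (to the minute) and amplitude of the secretory events, and
* the two first-order kinetic rates — adrenal→blood infusion θ₁ and
  hepatic clearance θ₂ —

by treating the problem as compressed sensing: the secretory input
u ∈ ℝ¹⁴⁴⁰ is sparse and nonnegative, the observations are
y = A(θ)u + b(θ)y₀ + ν with a bi-exponential impulse response

    h(t) = θ₁/(θ₁−θ₂) · (e^{−θ₂t} − e^{−θ₁t}),

and the estimate solves the non-convex program

    min_{θ,u}  ‖y − A(θ)u − b(θ)y₀‖² + λ‖u‖_p^p ,   p = 0.5,
    s.t.       u ≥ 0,  ‖u‖₀ ≤ 22,  θ₁ ≥ 4θ₂ ≥ 0,

by coordinate descent: FOCUSS+ (reweighted-ℓ₂ sparse recovery with a
nonnegativity clip and a sparsity cap) for u, constrained nonlinear least
squares on the cone for θ, with the regularizer λ re-selected at every
iteration by generalized cross-validation (golden-section search on
λ ∈ [0, 10]), multi-start over random initial kinetics.

Intended users: endocrine physiologists and biomedical engineers analysing
serial hormone assays, and anyone benchmarking sparse deconvolution of
renewal-process impulse trains through slow linear kinetics.

## Worked example

```python
import numpy as np
from pulsedecon import (CortisolDeconvolver, KineticParams, PulseTrain,
                        generate_dataset)

theta = KineticParams(0.0739, 0.0067)          # published subject-1 kinetics
truth = PulseTrain(np.arange(18) * 78 + 20,    # 18 events, 78 min apart
                   np.random.default_rng(0).uniform(2, 10, 18))
series = generate_dataset(theta, truth, y0=5.0, sigma_nu=0.0, seed=1)

est = CortisolDeconvolver(n_starts=3, random_state=7).fit(series)
print(est.theta_,)
print(est.n_pulses_, est.r_squared_)
print(est.pulses_.times)
```

prints

```
KineticParams(theta1=0.07389999999128209, theta2=0.0067000000006508485)
18 1.0
[  20   98  176  254  332  410  488  566  644  722  800  878  956 1034
 1112 1190 1268 1346]
```

i.e. on noiseless data the blind estimate recovers both kinetic rates to
nine significant digits, the exact event minutes, and a perfect fit
(R² = 1.0).  With realistic assay noise (σ between 0.29 and 1.44
concentration units) fits stay above R² ≈ 0.94 and matched event timings
are recovered to within ~20 minutes; small trough events near the noise
floor can be missed or duplicated (see `docs/methods.md`).

The same pipeline is available from the shell:

```bash
pulsedecon simulate --seed 11 --out-dir sims/
pulsedecon deconvolve --input sims/subject01_series.csv --seed 7 \
    --n-starts 3 --out result.json --pulses-out pulses.csv
pulsedecon evaluate --truth sims/subject01_truth.json --result result.json \
    --out metrics.json
```

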