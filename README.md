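# lntransit

How long does a recirculating T lymphocyte spend inside a single lymph
node? `lntransit` infers the distribution of lymph-node transit times from
long-term cannulation time courses — the percentage of labelled cells in
blood (input) and in efferent lymph (output) — and compares the inferred
distribution against mechanistic first-passage models.

The package is aimed at quantitative immunologists and modellers working
with labelled-cell recirculation kinetics (the motivating experiments are
sheep single-node cannulations, where both blood and the efferent lymphatic
of one node can be sampled for 100+ hours).

## The model

Efflux is a scaled, lagged convolution of the blood input with the
transit-time distribution `p` over 50 two-hour bins:

    L = c · B p,    sum(p) = 1,  p ≥ 0,

where `B` is the 50×50 lower-triangular matrix of lagged blood percentages
and `c` a proportionality constant (estimated as the L1 norm of the
unconstrained nonnegative least-squares solution). `p` is inferred by
simplex-constrained least squares, optionally with a curvature penalty
`λ‖Dp‖²` (S-LASSO), with `λ` chosen by resampled concatenation of animals
and held-out efflux error. Mechanistic comparators produce `p` from first
principles:

- a discrete Markov-chain random walk (forward/backward/stay probabilities
  per step, first-passage law from entry to exit vertex),
- the inverse Gaussian IG(μ, λ) — the first-passage law of Brownian motion
  with drift, and
- a Gaussian of transit times (directed migration; deliberately naive).

A synthetic-data module generates open-loop experiments with known truth
(exponential blood decay, convolved efflux, realistic sampling schedules,
multiplicative noise) and closed-loop agent simulations in which cells
actually recirculate, for validating steady-state occupancy and the
throughput identity t̄ = N/F. See `docs/methods.md` for details.

## Worked example

```python
import numpy as np
import lntransit as ln
from lntransit.synthetic import TruthSpec, simulate_open_loop

# a synthetic cannulation: inverse-Gaussian truth (mean transit 30 h),
# blood lifetime 7 h, sampled every 2 h, noise-free
spec = TruthSpec(transit_family="inverse_gaussian",
                 family_params={"mu": 30.0, "lam": 60.0},
                 blood_tau=7.0, noise_model="none",
                 schedule="uniform_2h", seed=1)
res = simulate_open_loop(spec)

sys_ = ln.build_convolution_system(
    ln.interpolate_to_grid(res.timecourse, "linear"))
c = ln.estimate_c(sys_)
dist = ln.solve_lasso(sys_)
median_h, mean_h = ln.transit_summary(dist)
print(f"c = {c:.4f}")
print(f"median transit = {median_h:.1f} h, mean transit = {mean_h:.2f} h")
print(f"L2 error vs truth = "
      f"{np.linalg.norm(dist.p - res.truth.normalized().p):.2e}")
```

prints

```
c = 0.9862
median transit = 24.0 h, mean transit = 29.69 h
L2 error vs truth = 4.03e-12
```

The estimated `c` is below 1 because ~1.4% of the IG(30, 60) transit mass
lies beyond the 100-hour window; the deconvolution exactly identifies the
truth renormalised onto the window, and its mean transit (29.69 h) sits
within half an hour of the generating 30 h.

There is also a thin CLI (`lntransit simulate | deconvolve | fit-mc |
compare`) over the same functions, e.g.

```
lntransit simulate --family ig --mu 30 --lam 60 --noise-cv 0.05 --out cohort/
lntransit deconvolve --manifest cohort/manifest.csv --n-train 3 --seed 1
```

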