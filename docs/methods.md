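# Methods

## The problem

Naive T lymphocytes recirculate continuously between blood and lymph nodes.
In a cannulated sheep lymph node one can measure, after reinfusing
CFSE-labelled lymphocytes, the percentage of labelled cells in blood (the
input to the node, via high endothelial venules) and in efferent lymph (the
output) over 100+ hours. The quantity of interest is the distribution of
*transit times*: how long an individual cell spends inside the node between
entry and exit.

## Model

All analysis works on a fixed discretisation: 50 two-hour bins covering
(0, 100] h. Writing `B(t)` for the blood percentage and `L(t)` for the lymph
percentage, the core assumption is that cells enter the node at a rate
proportional to their frequency in blood and exit after a random transit
time `theta` drawn independently per cell:

    L(t) = c * sum_j B(t - theta_j) * p_j ,   theta_j = 2j hours, j = 1..50,

or in matrix form `L = c * B p`, with `B` the 50x50 lower-triangular
lagged-input matrix, `p` the transit-time probability vector and `c` a
proportionality constant absorbing the relative volumes and flows of the two
compartments. There is deliberately no zero-lag bin: a cell needs nonzero
time to cross the node, and a zero-lag column would duplicate the input and
degrade the rank of `B`. The lag exactly equal to the observation time
refers to blood at t = 0, which is off the grid; the value at the smallest
grid time (2 h) stands in for it.

### Gridding

Observations are irregular (minutes-scale blood draws early, daily draws
late; lymph collected every few hours). Both channels are interpolated onto
the 2-hour grid by linear or natural cubic-spline interpolation —
interpolation, not smoothing, so gridded values reproduce observations.
Outside the observed span values are held flat; negative spline excursions
are clipped to zero. Late profiles are smooth enough that the two methods
give similar distributions; linear is the default.

### Blood lifetime

The early blood channel follows `B(t) = B0 * exp(-t/tau)`; `tau` is the mean
lifetime in blood before trans-endothelial migration. Only the first 8 h are
fitted, before transited cells start returning to blood. The default fit is
nonlinear least squares on the raw percent scale, initialised from the
log-linear regression (which makes it deterministic); a pure log-scale fit
is available. Raw-scale avoids the log-transform's downweighting of the
early, most informative samples.

### Deconvolution (LASSO / S-LASSO)

`c` is estimated first: solve the unconstrained nonnegative least-squares
problem `min ||L - B q||^2, q >= 0` and take `c = sum(q)` (the L1 norm of
the solution). Then `p` solves

    min ||L - c B p||^2 + lambda ||D p||^2    s.t.  sum(p) = 1, p >= 0.

An L1 bound of 1 on a nonnegative vector that must spend its whole budget is
exactly the probability simplex, so no separate L1 machinery is needed. `D`
is the second-difference operator (48x50): the penalty targets curvature,
i.e. non-smoothness, and keeps the problem a convex QP; a first-difference
variant is available. `lambda = 0` is the plain LASSO.

Numerically the QP is solved by augmented nonnegative least squares: stack
`c B` with a heavily weighted all-ones row (weight 1e5 x the data scale)
enforcing the equality constraint and with `sqrt(lambda) D`, solve by
Lawson–Hanson NNLS, clip negatives (NNLS returns exact zeros) and
renormalise. The residual sum deviation from 1 is O(1/weight^2), far below
the 1e-6 invariant; the unit tests verify the solution against a brute-force
simplex-grid enumeration on small problems.

Smoothing selection mirrors the resampling design: draw `n_train` systems
(3 or 9) with replacement, stack their regressions (duplicates stacked
twice, each system entering with its own pre-estimated `c`), solve for every
lambda on the grid (default {0, 1, 2, 5, 10, 20, 50, 100, 200}), and score
by the average efflux SSE over the systems never drawn in that repetition;
repeat 50 times and keep the overall best. Per-bin 95% confidence bands use
mean +/- 1.96 * s/sqrt(n) with the (n-1)-denominator standard deviation.

The tail-constraint experiment refits with the last `n` bins forced to zero
(columns removed before solving) versus `n` random bins, and reports total
held-out SSE for both — probing whether the long tail of slow cells is
load-bearing for prediction.

### Discrete random walk

Cells hop between `n` vertices on the HEV-to-medulla axis with per-step
probabilities `q_fwd`, `q_bwd`, `q_stay` (summing to 1) and step duration
`dt_min` minutes. Vertex 1 reflects (a backward move at the entry folds into
staying — the schematic leaves the boundary open, and reflection conserves
probability without new parameters); vertex `n` absorbs for first-passage
computation, making the `[1, n]` entry of the k-step matrix power the
cumulative arrival probability. The law is computed by iterated
vector-matrix products; step-indexed arrivals aggregate onto the 2-hour bins
(step k lands in bin (t-2, t] when `k*dt` is in ((t-2)*60, t*60] minutes).
Mass beyond 100 h is kept as an explicit tail, never renormalised away.

Fitting is a two-stage exhaustive search scored by efflux SSE: stage 1 over
`q_stay` in 0.1 steps, a drift-ratio grid around 1, `n` in {5,...,50} and
`dt` in {1, 2, 5, 10} min; stage 2 fixes `q_stay`, `n`, `dt` and refines
`(q_fwd, q_bwd)` on a 0.01 grid. The SSE surface over the
`(q_stay, q_fwd/q_bwd)` plane at the optimal `(n, dt)` is exported for the
drift heat map.

For steady state the exit flux is reinjected at vertex 1 (entry and exit
balance in an unchallenged node); the stationary vector of that chain is a
single linear solve. Near zero drift it declines from the entry vertex
toward the exit — cells accumulate near the HEVs.

### Continuous comparators

The inverse Gaussian IG(mu, lam) — density
`sqrt(lam/(2 pi t^3)) exp(-lam (t-mu)^2 / (2 mu^2 t))` — is the exact first
passage law of Brownian motion with drift: barrier distance `d = sqrt(lam)`,
drift `v = d/mu`, unit variance. It is the continuous analogue of the walk;
low drift gives the same heavy right skew. The Gaussian comparator models
perfectly directed migration and is intentionally naive; its negative-time
mass goes to the tail rather than being truncated-renormalised. Densities
discretise onto the bins by exact CDF differences (quadrature route kept and
cross-checked). Fits minimise training efflux SSE by multi-start
Nelder–Mead on log-parameters (30/24 grid starts; deterministic).

## Synthetic data

No raw time courses were deposited, so the generator is the test bed and
defines the study conditions. The open-loop generator mirrors the model's
own assumptions: exponential blood decay (default `tau = 7.3` h, the median
reported blood lifetime; `B0 = 2%`, a typical labelled fraction), efflux
equal to `c * B p_truth` (default `c = 1`) with truth drawn from an IG
(default mu = 30, lam = 60 — mean transit ~30 h as reported), a zero-drift
walk, a two-component IG mixture (bimodal), or a point mass; sampling either
on the exact 2-hour grid or on a realistic schedule (blood at minutes 2-30,
then hourly to daily; lymph every 4 h to 48 h then every 8 h); optional
multiplicative Gaussian noise, default CV 5% (measurement noise was not
quantified experimentally; 5% is a realistic flow-cytometry repeatability
figure, and tests sweep it).

What open-loop data do *not* contain: recirculation of labelled cells back
into blood (the measured blood curve is taken as-is, exactly as the
deconvolution assumes), transit mass beyond 100 h only enters through the
truth's tail, and no drift in `c` over time. Passing recovery tests
therefore shows correctness of the inference machinery under the model's
assumptions, not robustness to their violation in real sheep.

The closed-loop generator is an agent simulation in which every cell
actually recirculates: exponential blood residence, the per-step walk inside
the node, exit back to blood from the last vertex on a forward move (the
reinjection chain). After a 200-hour burn-in, a cohort in blood is labelled
and followed. It checks the throughput identity (mean transit time =
node occupancy / entry rate, verified via batch-means Monte-Carlo errors),
reproduces the stationary occupancy profile, and conserves label by
construction. Its measured transit time exceeds the absorbing-chain mean by
the sojourn at the terminal vertex — a deliberate, visible difference
between "arriving at the medulla" and "leaving through it".

## Recovery behaviour worth knowing

With a noise-free truth whose tail extends beyond 100 h (IG(30, 60) carries
~1.4% of its mass there), the pipeline identifies the truth *renormalised
onto the window*: the L1-based `c` estimate absorbs the tail factor
(`c_hat = c_true * sum(p_truth)`) and the simplex solution equals
`p_truth / sum(p_truth)` to solver precision (~1e-12 L2). This is an
identifiability limit of a 100-hour design, not an estimation error; tests
and the acceptance script compare against the windowed truth and report the
recovered mean transit (29.69 h for the IG(30, 60) condition, against a
windowed-truth mean of the same value).

## Numerical choices

- Equality-constraint weight 1e5 x data scale in the augmented NNLS; final
  renormalisation; entries in (-1e-9, 0) clipped.
- Median of a binned distribution: smallest bin edge where the cumulative
  reaches 0.5, ties to the lower bin.
- First-passage horizon: enough steps to cover 100 h (`ceil(6000/dt_min)`),
  cap 1e6; tail mass recorded, never renormalised.
- Euler–Maruyama first-passage oracle uses the Broadie–Glasserman
  continuity correction (barrier lowered by `0.5826 sqrt(dt)`); without it
  the O(sqrt(dt)) discrete-crossing bias would dominate the
  Kolmogorov–Smirnov comparison at dt = 1e-3.
- Problem sizes in tests and the acceptance script: 10^5 walkers / Brownian
  paths, 20-seed model-ordering suite on 6-animal cohorts, 20 000-cell
  closed-loop cohorts — sizes at which Monte-Carlo error is comfortably
  below the assertions' tolerances.

## Known limitations

- One-dimensional walk: perpendicular motion is only folded into `q_stay`;
  no explicit node geometry.
- The open-loop generator cannot probe bias from labelled-cell
  recirculation into the blood input; the closed-loop simulator exists for
  that but is not itself run through the deconvolution by default.
- `c` is estimated per animal before stacking concatenated regressions;
  a joint estimate across animals would assume homogeneous scaling.
- Reported per-animal values for real sheep are shipped only as summary
  inputs; per-animal raw time courses are not recoverable, so the real-data
  figures (individual distributions, heat maps) can only be reproduced
  qualitatively on synthetic cohorts.
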