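# Methods

## The model

Cyton2 describes the burst of proliferation that stimulated B and T
lymphocytes undergo in vitro: an exponential expansion, a halt of division
("division destiny"), and eventual death. Its defining feature relative to
earlier competing-timer models (e.g. the original Cyton model) is that the
controlling timers are *familial*: they are drawn once per founder cell and
inherited unchanged by all descendants.

Each clonal family is governed by independent non-negative random times

- `T_div0` — time from stimulation to the founder's first mitosis,
- `M_g` (or a constant `m`) — the time between subsequent mitoses, shared
  by all cells of a generation within the family,
- `T_dd` — the division-destiny time: when it passes, every cell of the
  family loses its licence to divide and waits, quiescent,
- `T_die` — the global death time at which every family member dies.

The update rules are strict-inequality: a division scheduled at exactly
`min(T_dd, T_die)` does not happen, and survival always means `P(T > t)`.
A family at time `t < min(T_dd, T_die)` is in generation
`G(t) = max{g : sum_{k<=g} division times < t}` and holds `2^G(t)` cells.

### Expected counts

For data where individual families are not resolved (division-tracking
dyes read by flow cytometry), the package evaluates the expected number of
live cells per generation. Writing `S` for survival functions and `f_dd`
for the destiny density:

    y_0(t) = n0 * S_die(t) * [ S_div0(t) S_dd(t)
                               + int_0^t f_dd(tau) S_div0(tau) dtau ]
    y_g(t) = n0 * 2^g * S_die(t) * [ S_dd(t) P(t - g m < T_div0 <= t-(g-1)m)
             + int_0^t f_dd(tau) P(tau - g m < T_div0 <= tau-(g-1)m) dtau ]

The two bracket terms split families into those still licensed to divide
and those frozen at destiny at some `tau < t`. The *reduced* model
(constant `m`) is what gets fitted to data; the *full* model takes
per-generation `M_g` distributions, with the window probability replaced
by a numerical convolution of `T_div0` with the `M_g` (uniform grid,
default 0.1 h spacing over [0, 400] h). When every `M_g` is a point mass
the convolution is bypassed and the reduced-style closed form is used, so
the two routes agree exactly in that case.

### Numerical choices

- The destiny integral uses Gauss–Legendre quadrature on `[0, t]`. By
  default the node count doubles from 64 until two successive evaluations
  agree to 1e-6 relative; during optimisation a fixed 64-node rule is used
  (the adaptive and fixed answers agree to <1e-6 on the fitting problems
  the package targets, which the test suite checks).
- Point-mass destiny/death distributions are handled analytically (no
  quadrature), which is what makes the hand-derivable trajectories exact.
- Normal timers may place mass at negative times; that mass is treated as
  mass at zero (the cdf is evaluated as given, and window probabilities
  clip negative arguments). Gaussian timers are only recommended where the
  additive-prediction analysis needs them.
- Expected timecourses warn when the lineage-occupancy mass beyond the
  truncation generation exceeds 1e-4 (default maximum generation 10,
  matching what division-tracking dyes can resolve, ~8 generations).

## Agent-based simulator

`simulate_family` realises one family tree cell-by-cell; every cell of a
generation divides simultaneously, all cells die at the familial death
time, and cells that reach destiny are retained (they die later). A
vectorised cohort variant (`simulate_generation_counts`) computes
per-generation live counts for 1e5+ families in milliseconds and serves as
the Monte-Carlo oracle for the analytic equations: the package's
primary internal consistency check requires agreement within 3 Monte-Carlo
standard errors at every (generation, time) cell, where the SE floor comes
from the analytic occupancy probability so that empty simulation cells are
scored fairly.

## Observation rules and censoring-induced correlation

In imaging data a timer is observed only if its event happens: the first
division is unobserved when `T_div0 >= min(T_dd, T_die)`, a subsequent
division time requires the second division to complete, destiny is
unobserved when death pre-empts it (`T_dd > T_die`), and the time of last
division `T_ld` — the observable proxy for destiny, identified with it
under the study's working assumption — shares destiny's observability.
`censorship_study` samples the four timers independently (the
no-correlation construction), applies these rules, and reports sample
correlations and Bayes factors for all six variable pairs on the true and
the observable values. Because the truth is independent by construction,
any H1-favouring Bayes factor on the observable side is induced purely by
right censoring. Pair Bayes factors are computed on a configurable
subsample (default in the acceptance pipeline: 1e4) because the BF
integral's evidence scales with n and would otherwise flag correlations of
~0.01 as real at 1e5+ families.

## Lineage-tree analysis

Clones are retained when the founder divided at least once and the latest
recorded event in the tree is a death (lost cells are tolerated anywhere
else; an exact tie between a loss and the last death retains the clone).
Retained trees are collapsed to per-generation mean division times, the
mean death time, and the mean time of last division, defined per died cell
as its birth time — i.e. its parent's division time — so that the statistic
is itself a division time. The average subsequent division time of a clone
is the mean of consecutive per-generation mean differences and requires at
least two divisions. Within-clone coefficients of variation use raw
per-cell times (not per-generation means) and the n−1 sample standard
deviation; clones with fewer than two observations of a variable are
skipped and flagged.

## Fitting

The reduced model has 7 free parameters per condition (two per timer
distribution plus `m`); the founder count `n0` is fixed from the mean
total cell number at the earliest harvest. The cost is the unweighted
residual sum of squares over all (time, generation, replicate) records.
Optimisation is bounded trust-region least squares in log-parameter space,
restarted from (by default) 100 random initial vectors drawn uniformly in
the bounds; joint fits over several conditions share named parameters,
default to 200 starts, and additionally seed one start from cheap
independent per-condition fits. Default bounds: medians/means 0.1–200 h,
lognormal shapes 0.05–1.5, Gaussian SDs 0.5–40 h, `m` 5–50 h — wide enough
to cover lymphocyte cultures by a large margin, and configurable.

Uncertainty comes from a replicate bootstrap (default B = 1000): within
each time point, replicate generation-profiles are resampled with
replacement as units, the model refit from the best estimate, and 95%
percentile intervals and extrapolation bands read off the refits. The
bands are confidence bands for the mean curve, not prediction bands for
individual replicates.

The combined-stimulus prediction assumes Gaussian timers and timer-space
additivity: combined mean `mu_base + sum(mu_x - mu_base)` and variance
`sigma_base^2 + sum(sigma_x^2 - sigma_base^2)` for each of the three
timers. The variance difference can go non-positive; that raises a named
error by default, with an opt-in floor.

The data-requirement study enumerates all admissible time-point-removal
sets (at least three points retained; the first or second point — the
`n0` anchor — must survive; 366 cases for a nine-point design), refits on
replicate-bootstrapped subsets, and scores each case by the RMSE of the
refitted model against the full original table. Fit failures are counted
and excluded rather than raised.

## Bayesian components

The correlation of two fate times across clones is modelled as a bivariate
normal with uniform priors (`mu, sigma ~ U(0, 1000)`, `rho ~ U(-1, 1)`).
The default Bayes factor for H1: `rho ~ U(-1, 1)` against H0: `rho = 0` is

    BF10 = 1/2 * int_{-1}^1 (1 - rho^2)^{(n-1)/2} (1 - rho r)^{-(n-3/2)} drho

evaluated by adaptive quadrature in log space (stable for n in the
hundreds of thousands). Evidence categories: Anecdotal (1, 3], Moderate
(3, 10], Strong (10, 30], Very strong (30, 100], Extreme (> 100), applied
to whichever of BF10/BF01 exceeds one.

Candidate timer families (gamma, lognormal with median/shape
parameterization, normal, Weibull, delayed exponential, delayed lognormal)
are fitted by MCMC under fixed priors: U(0, 200) for gamma/lognormal/
normal parameters, HalfNormal(500) for Weibull, U(0, 2) for the delayed-
exponential rate (1/h), and U(0, sample minimum) for shift parameters —
exactly equivalent to the improper U(0, inf) prior because the likelihood
vanishes beyond the smallest observation. Sampling uses the
affine-invariant ensemble sampler (emcee) behind a fixed convergence
contract (R-hat < 1.01, bulk ESS > 400, computed by arviz after pooling
the interacting walkers into four long pseudo-chains); non-convergence is
flagged on the result, never hidden. Posterior summaries are medians with
equal-tailed 95% intervals.

Model comparison uses deviance-scale WAIC,
`WAIC = -2 (lppd - penalty)` with pointwise
`lppd_i = log mean_s P(z_i | theta_s)` and penalty
`p_i = Var_s log P(z_i | theta_s)` (1/(S−1) sample variance), the
in-sample deviance `-2 lppd` reported alongside, standard errors
`sqrt(n Var_i(WAIC_i))`, and paired pointwise differences between
candidates.

## Synthetic data: what it emulates, and what it does not

`synthesize_counts` produces generation-structured counts from the
analytic mean perturbed by multiplicative lognormal noise,
`count = y_g(t) exp(eps)`, `eps ~ N(0, 0.05^2)` per record — emulating the
roughly proportional scatter of replicate cell counts. The default design
is nine harvests over 120 h with three replicates. `synthesize_trees`
writes agent-based family trees in the microscopy table dialect. The
default parameter sets are: "B-cell-like" (first division median 40 h,
shape 0.2; subsequent divisions 10 h; destiny median 60 h; death median
100 h, well separated from the first division) and "T-cell-like" (40 h /
0.3; 18 h; destiny 50 h and death 60 h with strong overlap, hence heavy
censoring). Medians follow the ~40 h first-division and ~10 h / ~18 h
subsequent-division times seen in stimulated murine B and CD8+ T cell
imaging; destiny/death placement reproduces the qualitative separation
(B) versus overlap (T) regimes.

What the generator does *not* emulate: counting error that scales other
than multiplicatively, spectral spillover/gating artefacts, loss of dye
resolution beyond ~8 generations, partial activation of the starting
population, asymmetric division, differentiation, and any feedback (e.g.
autocrine IL-2). Passing recovery tests on these fixtures therefore
demonstrates the estimator's correctness under the model's own
assumptions, not robustness to such real-data effects.

## Problem sizes used in validation

The validation pipeline (tests and `scripts/acceptance.py`) uses 1e5
simulated families for simulator-vs-analytic and censoring studies, 20
synthetic fitting datasets with 30 optimisation starts and 200 bootstrap
resamples each, 10 seeded replicates of the WAIC recovery experiment at
n = 200, and 20-start joint fits for the additivity check. These sizes
give Monte-Carlo error comfortably below the tolerances being asserted
while keeping a full run in the minutes range; production analyses should
use the library defaults (100/200 starts, B = 1000).

## Known limitations

- Means only: the analytic module gives expected counts, not variances of
  counts; family-level variability must come from the simulator.
- The reduced model assumes a constant subsequent division time; the full
  model's convolution route supports per-generation distributions but is
  grid-based and slower.
- Bayes factors are specific to the uniform-prior default test; no
  alternative priors are implemented.
- The bootstrap quantifies sampling noise given the model; it does not
  detect model misspecification.
- In-vivo dynamics (memory transition, two-phase decay) are out of scope.
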