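# Methods

`spikegc` analyzes how directed functional connectivity among simultaneously
recorded neurons evolves within behavioural trials. It implements a five-stage
pipeline — continuous rate reconstruction, non-negative embedding,
sliding-window conditional Granger causality, network metrics, and group
statistics — together with a synthetic spike-data generator that plants a
known coupling structure so every stage can be validated end to end.

## Continuous rates from spike trains

A spike train is a sequence of action-potential times; connectivity models
need a continuous signal. The reconstruction proceeds in three steps:

1. **Interval rate.** On each interspike interval the rate is `1/ISI`
   (a step function `r(t)`).
2. **Local integration.** The integrated rate over a window of length
   `δT = δ × (mean ISI of the train)` is converted to a local average rate
   `f(t) = (1/δT) ∫ r ds` over a centered, full-width window. `δ = 0.25`
   keeps the window well below the train's own timescale. Dividing by `δT`
   makes `f` a rate (spikes/s), so the trial integral of the output tracks
   the spike count — the conservation property the tests enforce.
3. **Smoothing.** `f` is piecewise linear with corners half a window on
   either side of each spike; a shape-preserving piecewise cubic (PCHIP)
   through knots at exactly those corners is evaluated on a uniform grid
   (default `dt = 0.01 s`) and clamped at zero. A shape-preserving
   interpolant is used because an unconstrained cubic spline overshoots
   badly between bursty knots and can inflate the trial integral by large
   factors; PCHIP preserves the knot mass to within a few percent.

Edge policy: before the first and after the last spike the rate is held at
the nearest knot value, capped at `0.5/gap` so each empty edge interval
carries at most half a spike of mass (the interspike intervals themselves
integrate to `K−1` spikes; the two boundary spikes own the remainder).
Trains with fewer than three spikes fall back to a constant rate
`count/duration` with a logged warning — they stay in the matrix rather
than crashing the trial.

Numerical consequences: for a perfectly regular train the output is exactly
`1/ISI` everywhere; for Poisson trains with ≥ 10 spikes the trial integral
matches the spike count within 10% (checked against trapezoid quadrature),
with the residual dominated by ±1-spike granularity at low counts.

## Non-negative embedding and rank selection

Each trial's rate matrix `X` (m neurons × n samples) is factorized as
`X ≈ W H`, `W, H ≥ 0`, by multiplicative updates minimizing the Frobenius
residual. Implementation choices:

- initialization `uniform(0,1) × sqrt(mean(X)/r)`, 10 seeded restarts,
  best final residual wins (the objective is non-convex);
- update denominators floored at `1e−12` (silent neurons/components);
- stop at relative objective change `< 1e−6` or 500 iterations — the VAF is
  insensitive beyond this.

The rank is the smallest `r` whose variance accounted for,
`VAF = 1 − ‖X−WH‖²_F / ‖X‖²_F`, exceeds 0.9, subject to the admissibility
bound `r < mn/(m+n)` (the bound wins on conflict). Within an animal, the
per-trial ranks are harmonized to their maximum and every trial is refit at
that common rank; the refit VAF is recomputed and verified ≥ 0.9 rather than
assumed. Component time courses `H` live on the same grid as `X`, so the
windowing downstream is identical in neuron space and component space.

## Sliding-window conditional Granger causality

A 0.5-s window advancing in 0.125-s steps is applied to each trial (13
windows on a 2-s trial). Within a window, rows are mean-centered and a
VAR(p) is fit by per-equation OLS; `p` is chosen by BIC
(`ln det Σ̂ + N²p·ln(T_eff)/T_eff`, `T_eff = T − p`) over `1..p_max`
(default cap 3 — a 0.5-s window at 100 Hz has only 50 samples). The
conditional Granger causality from node `j` to node `i` is

    F[i, j] = ln( ρ_ii / Σ_ii ),

with `Σ_ii` the residual variance of `x_i` in the full model and `ρ_ii` its
residual variance in the restricted model that omits `x_j` from both the
predictor and predicted sets. Negative estimates (finite-sample artifacts)
are floored at zero and counted.

Each ordered pair is tested with the nested-regression F-statistic
`((RSS_r − RSS_u)/p) / (RSS_u/(T_eff − N·p − 1))` with df
`(p, T_eff − N·p − 1)`; p-values are Benjamini–Hochberg corrected across all
`N(N−1)` pairs **within** the window, and non-significant connections are
set to zero. Safeguards: when `N·p + 1 > T/2` the fits switch to light ridge
regularization (`λ = 1e−8·trace`) and the network is flagged; windows with a
zero-variance row or non-positive df are skipped, never interpolated; a
trial with more than half its windows skipped is reported unanalyzable.

On a bivariate system this construction reduces exactly to pairwise Granger
causality; the closed form `F = ln(1+c²)` for `y(t) = c·x(t−1) + e` is the
main numerical anchor of the test suite.

## Network metrics and group statistics

- **Causal density** `Cd = Num_GC / (N(N−1))`: the fraction of ordered pairs
  with a surviving edge; bounded in [0, 1].
- **Global efficiency** `E = (1/(N(N−1))) Σ_{i≠j} 1/L_ij` on the directed
  pruned graph with edge length `1/F`; `L` is the directed shortest-path
  length (Dijkstra) and unreachable pairs contribute 0. The directed graph
  is the faithful reading (the networks are directed by construction); an
  unpruned-weights variant is exposed for sensitivity analysis.

Per-trial metric time courses are aligned to the trial's reference time
(RT). The group-comparison scalar for a trial is the metric's mean over the
windows within ±0.25 s of its own peak (ties break to the earliest window).
Groups (correct / error / baseline trials) are compared with a two-sample
Welch t-test, two-sided, α = 0.05. The Welch form was chosen because the
variance of peak-window statistics differs between states.

The pipeline also reports two weight summaries in each space: the pooled
mean over surviving edges, and the mean of the pruned connectivity matrices
(zeros included) over the peak ± 0.25 s windows of correct trials. The
latter is the quantity used for the component-space versus neuron-space
contrast: it reflects both how dense and how strong the significant
structure is, and is insensitive to the significance floor that makes
surviving-edge means scale with network size.

## Synthetic data: what it emulates and what it does not

The generator emulates multi-neuron recordings during a decision task in
which only assemblies of neurons carry the task signal:

- **Latents.** `n_components = 8` rectified AR(1) components at
  `dt = 10 ms`: `z_t = max(0, μ + A(z_{t−1} − μ) + σ ε_t)` with target mean
  `μ = 5` (rate units), innovation `σ = 2`, self-persistence 0.9 (≈ 100 ms
  correlation time — slow enough to survive rate reconstruction, fast
  enough to fluctuate within a 0.5-s window). Coupling acts on deviations
  from the mean, so the gain modulates fluctuation propagation without
  shifting the operating point.
- **Coupling topology.** A hub component drives all others (coefficient
  0.2) plus a few feed-forward links between targets (0.15). The
  off-diagonal part is strictly triangular, hence nilpotent: the spectral
  radius stays at the self-persistence 0.9 for *any* gain, so the planted
  ramp can never destabilize the dynamics. A chain topology was rejected
  because variance (and rectification bias) compounds multiplicatively down
  a chain under gain.
- **The task signal.** In correct trials the off-diagonal coupling is
  multiplied by a piecewise-linear ramp rising from 1 over
  `[RT−0.75, RT−0.25]` to `coupling_peak_gain = 4`, then decaying back to 1
  by `RT+0.25`. Error and baseline trials keep gain 1 throughout, so error
  trials are statistically identical to baseline — the pipeline must find
  nothing there.
- **Spiking.** Each neuron is an inhomogeneous Poisson process with
  intensity `baseline + loading · z(t)` (baseline 3 spikes/s; each neuron
  loads on one or two components with weights 0.8–2), realized by thinning
  at the trial's peak intensity. Typical rates are 15–40 spikes/s with
  strong assembly-driven modulation.
- **Reproducibility.** One global seed expands into per-trial, per-purpose,
  per-neuron `SeedSequence` substreams (spawn key
  `(trial_index, purpose, neuron)`), so any single trial can be regenerated
  independently and datasets are byte-identical across runs.

Deliberately not modelled: refractory periods, bursting statistics,
electrode noise, non-Poisson count dispersion, and behavioural variability
in RT. Trial-to-trial changes in which neurons are active are available as
an option (`silence_prob`: each neuron silent for a whole trial with that
probability) but default to off, since no realistic silencing rate is
established. Passing tests therefore show the pipeline
recovers assembly-level directed coupling from Poisson spikes at realistic
rates and trial counts — not that it is robust to every physiological
nuisance in real recordings.

## Study-scale choices and what the end-to-end test shows

The default experiment is 40 correct, 40 error and 40 baseline trials of
2.0 s with RT at 1.5 s, from 20 neurons — sizes in the range of a typical
single-animal session. At this scale the pipeline recovers the planted
structure: group-mean causal density and global efficiency in component
space peak at a window centered 0.25 s before RT, the correct-trial
peak-window means exceed baseline at p < 0.01 (Welch), error trials show no
significant excess, and the mean connection weight of the pruned peak
matrices is higher in component space than in neuron space. Per-window
conditional GC at 50 samples is individually noisy — the recovery is a
group-level property, which mirrors how such experiments are actually
analyzed.

## Numerical details and degenerate inputs

- Rate grid `dt = 0.01 s` by default (50 samples per window); it is a
  configuration field, not a constant, as is the interpolation choice's
  averaging fraction `δ`.
- NMF on an all-zero matrix, VAF of a zero matrix, metrics on N < 2 nodes,
  and empty trial lists are rejected with explicit errors.
- Zero-variance rows inside a window skip the window with a warning.
- VAR order candidates are restricted to those with a feasible regression;
  if none fits, the error reports the minimum sample count.
- All stochastic stages draw from explicit seeds; reruns of the file
  pipeline produce identical artifact hashes (verified in tests).

## Known limitations

- The conditional GC bookkeeping fits `N+1` VAR models per window; at
  `N ≳ 30` neurons in 50-sample windows the fits are ridge-regularized and
  the F-tests lose power — metrics in neuron space degrade accordingly
  (this matches the method's behaviour, not a bug, but limits how large a
  population the neuron-space analysis can handle per window).
- The VAF rank rule on reconstruction-noisy rates selects ranks above the
  true latent dimensionality (12–13 for 8 planted components in the default
  conditions); harmonized-rank VAF stays above 0.9 by construction.
- Peak-window statistics of a flat (null) time course are inflated by
  max-selection bias; comparisons are therefore between identically
  constructed statistics (correct vs baseline), never against zero.
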