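# spikegc

Directed functional-connectivity analysis of multi-neuron spike recordings,
for systems neuroscientists studying how coordination among simultaneously
recorded neurons changes within behavioural trials (e.g. working-memory
tasks where network coupling ramps up before a choice point).

The pipeline:

1. **Rate reconstruction** — each spike train becomes a continuous
   instantaneous firing rate: `r(t) = 1/ISI` per interval, locally averaged
   over `δT = 0.25 × mean ISI`, smoothed by shape-preserving cubic
   interpolation onto a uniform grid.
2. **Non-negative embedding** — each trial's rate matrix `X` (m neurons ×
   n samples) is factorized `X ≈ WH` (`W, H ≥ 0`, multiplicative updates);
   the rank is the smallest `r` with
   `VAF = 1 − ‖X−WH‖²_F/‖X‖²_F > 0.9` subject to `r < mn/(m+n)`, harmonized
   to the per-animal maximum across trials.
3. **Connectivity** — a 0.5-s window moving in 0.125-s steps; per window a
   BIC-ordered VAR(p) and conditional Granger causality
   `F_{j→i} = ln(ρ_ii/Σ_ii)` for every ordered pair, F-tested and
   Benjamini–Hochberg pruned; run both on neurons ("original space") and on
   the NMF component time courses `H` ("NMF space").
4. **Network metrics** — causal density `Cd = Num_GC/(N(N−1))` and global
   efficiency `E = (1/(N(N−1))) Σ 1/L_ij` (directed shortest paths, edge
   length = 1/strength), per window, aligned to the trial's reference time
   (RT).
5. **Group statistics** — per-trial peak-window means (peak ± 0.25 s),
   Welch t-tests between correct / error / baseline trial groups.

A synthetic-data module generates spike datasets from rectified latent
assembly dynamics with a known directed coupling that ramps up 0.25 s
before RT in correct trials only — so the whole pipeline is testable
without any recordings.

## Worked example

```python
import numpy as np
from spikegc import (default_config, build_dataset, analyze_trials,
                     PipelineConfig, conditional_gc, significance_filter,
                     simulate_var_series)

# closed-form anchor: y(t) = 0.5 x(t-1) + e  =>  F_{x->y} = ln(1.25) = 0.223
A = np.array([[0.0, 0.0], [0.5, 0.0]])
x = simulate_var_series(A[None], np.eye(2), 20000, seed=42)
net = significance_filter(conditional_gc(x))
print(f"F x->y = {net.F[1,0]:.4f}, significant: {net.sig_mask[1,0]}")
# F x->y = 0.2253, significant: True

# full synthetic experiment: 40 correct / 40 error / 40 baseline trials
ds = build_dataset(default_config(seed=1))
summary = analyze_trials(ds.trials, PipelineConfig(seed=1)).summary
print(summary["cd_peak_time_nmf"])                         # -0.25
print(summary["cd_correct_vs_baseline_nmf"]["pvalue"])     # 6.4e-05
print(summary["cd_error_vs_baseline_nmf"]["pvalue"])       # 0.19
```

The numbers say: group-mean causal density in NMF space peaks at the window
centered 0.25 s **before** the reference time; correct-trial peak-window
causal density significantly exceeds the baseline state (p ≈ 6e-5), while
error trials — generated without the coupling ramp — show no significant
excess (p ≈ 0.19). That is exactly the planted ground truth.

A thin CLI mirrors the stages:

```bash
spikegc simulate --out data/ --seed 1
spikegc run --spikes data/spikes.tsv --events data/events.tsv --out run/ --seed 1
```

Short narrative scripts, one per capability, live in `examples/`.

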