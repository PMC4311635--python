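"""Convert a spike train to a continuous rate and slice it into windows.

The trial integral of the reconstructed rate should match the spike count
(a rate estimator that loses or invents spikes would bias every later stage).
"""

import numpy as np

from spikegc import SpikeTrain, WindowSpec, build_rate_matrix, instantaneous_rate, sliding_windows

rng = np.random.default_rng(0)
times = np.unique(np.sort(rng.uniform(0, 2.0, rng.poisson(16))))  # ~8 spikes/s
train = SpikeTrain(0, times, 0.0, 2.0)

rs = instantaneous_rate(train, delta=0.25, dt=0.01)
integral = np.trapezoid(rs.values, rs.times)
print(f"spikes: {train.n_spikes}, integral of rate: {integral:.2f} "
      f"(relative error {abs(integral-train.n_spikes)/train.n_spikes:.1%})")

rm = build_rate_matrix([train], dt=0.01)
wins = sliding_windows(rm, WindowSpec(width=0.5, step=0.125), rt=1.5)
print(f"{len(wins)} windows of 50 samples; centers relative to RT run "
      f"from {wins[0][0]:+.3f} s to {wins[-1][0]:+.3f} s")
print("A 2-s trial yields 13 half-open 0.5-s windows stepped by 0.125 s.")
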