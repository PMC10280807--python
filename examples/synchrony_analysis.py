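"""Spike synchrony and co-depolarization in a coupled population.

Simulates a target cell sharing excitatory drive with 16 reference cells
at pair-specific weights, then measures for each pair: the spike CCG, the
fraction of spikes within 5 ms (against a shuffle control), the synchrony
strength (coincidence rate in |Δt| ≤ 1.5 ms over the 15–25 ms control
band), and the subthreshold co-depolarization of the target around each
reference's spikes.  Finally correlates synchrony with co-depolarization
across references, with a distance-matched different-reference control.
"""

import numpy as np

from voltimage import (
    PopulationConfig, VmConfig, ccg, fraction_synchronous, simulate_cells,
    synchrony_codep_correlation, synchrony_strength,
)

n_refs = 16
rng = np.random.default_rng(0)
weights = np.zeros((n_refs + 1, n_refs + 1))
w_vals = np.linspace(0.15, 0.6, n_refs)
rng.shuffle(w_vals)
weights[0, 1:] = w_vals
weights[1:, 0] = w_vals

cfg = PopulationConfig(
    n_cells=n_refs + 1,
    cell_positions=rng.uniform(0, 300.0, (n_refs + 1, 2)),
    shared_input_weights=weights,
    vm=VmConfig(duration=300.0, spike_rate=2.0),
    noise_sd=0.0003,
    shared_event_rate=1.0,
    codep_bump_mv=15.0,
    seed=0,
)
rec, truth = simulate_cells(cfg)

strongest = 1 + int(np.argmax(w_vals))
weakest = 1 + int(np.argmin(w_vals))
for j, label in ((strongest, "strongest"), (weakest, "weakest")):
    frac, shuf = fraction_synchronous(rec.spikes[0], rec.spikes[j],
                                      rec.duration, seed=1)
    s = synchrony_strength(rec.spikes[j], rec.spikes[0])
    g = ccg(rec.spikes[j], rec.spikes[0])
    print(f"{label} pair (weight {weights[0, j]:.2f}): "
          f"{frac:.1f}% of spikes within 5 ms "
          f"(shuffle {shuf:.1f}%), synchrony strength {s:.1f}, "
          f"CCG FWHM {g.fwhm_ms:.2f} ms")

res = synchrony_codep_correlation(
    rec, min_refs=10, exclusion_ms=30.0, win_ms=(-30.0, 30.0),
    baseline_ms=(-30.0, -20.0))
r0 = {r.target: r for r in res}[0]
print(f"\ntarget cell 0 ({r0.n_references} references): "
      f"r(synchrony, co-depolarization) same pairs = {r0.r_same:.2f}, "
      f"different (distance-matched) pairs = {r0.r_different:.2f}")
# a high same-pair correlation with a near-zero different-pair control is
# the signature of pair-specific shared excitatory input
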