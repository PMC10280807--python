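"""Characterize a sensor: F–V slope, step kinetics, synPSP detectability.

Runs the automated-electrophysiology analyses on synthetic step records:
a voltage-step protocol (+50 to −110 mV in −20 mV steps from −70 mV) for
the fluorescence–voltage curve and its subthreshold slope; a step response
for the double-exponential kinetics fit; and 10-trial synPSP sets
(−15…+15 mV in 5 mV steps) for the d′ detectability slope.
"""

import numpy as np

from voltimage import (
    SensorParams, Trace, fit_double_exponential, fv_curve, synpsp_dprime,
    vm_to_fluorescence,
)
from voltimage.synth import psp_waveform

fs = 500.0
sensor = SensorParams(sensitivity_slope=-0.54, bleach_tau=np.inf)

# --- F-V curve: 0.5 s baseline at -70 mV, 1 s step ---
records = {}
for v in np.arange(50.0, -111.0, -20.0):
    vm = np.full(int(1.5 * fs), -70.0)
    vm[int(0.5 * fs):] = v
    f = vm_to_fluorescence(Trace(values=vm, fs=fs, units="mV"), sensor,
                           noise_sd=0.01, seed=int(v) + 200, v_rest=-70.0)
    base = np.mean(f.values[: int(0.5 * fs)])
    records[v] = (f.values - base) / base
curve = fv_curve(records, fs=fs, step_onset_s=0.5)
print("F-V responses (steady state, % ΔF/F):")
for v, r in zip(curve.step_voltages_mv, curve.dff_per_step_pct):
    print(f"  {v:+6.0f} mV -> {r:+7.2f}%")
print(f"subthreshold slope (-90..-50 mV): "
      f"{curve.subthreshold_slope_pct_per_mv:.3f} %/mV")

# --- kinetics: double-exponential fit of a relaxation at 3.2 kHz ---
fs_k = 3200.0
t = np.arange(int(0.08 * fs_k)) / fs_k
rng = np.random.default_rng(0)
sweeps = (0.7 * np.exp(-t / 0.67e-3) + 0.3 * np.exp(-t / 3.26e-3)
          + rng.normal(0, 0.01, (10, t.size)))
fit = fit_double_exponential(sweeps.mean(axis=0), fs_k)
print(f"\nkinetics: τ_fast = {fit.tau_fast_ms:.2f} ms, "
      f"τ_slow = {fit.tau_slow_ms:.2f} ms, "
      f"%fast = {fit.percent_fast:.0f}%")

# --- synPSP d' detectability ---
amps = np.arange(-15.0, 16.0, 5.0)
n_trial, sigma = 10, 1.5e-2
trials = {}
t_tr = np.arange(int(0.25 * fs)) / fs
onset = 0.1
trng = np.random.default_rng(42)
for a in amps:
    resp = (-0.54 / 100.0) * psp_waveform(t_tr - onset, a, 2.0, 10.0)
    trials[a] = resp[None, :] + trng.normal(0, sigma, (n_trial, t_tr.size))
res = synpsp_dprime(trials, fs, onset, raw_fluorescence=False)
print("\nsynPSP d' per amplitude:")
for a, d in zip(res.amplitudes_mv, res.dprimes):
    print(f"  {a:+5.0f} mV -> d' = {d:+6.2f}")
print(f"d'/mV = {res.dprime_per_mv:.3f} "
      "(steeper magnitude = finer subthreshold discrimination)")
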