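"""Synthetic voltage-imaging data with ground truth.

This module generates membrane-potential traces, converts them into
fluorescence through a linear sensor model with double-exponential on/off
kinetics, single-exponential photobleaching and additive noise, couples
cells through pairwise shared excitatory drive, and renders small
field-stimulation plate movies — everything the analysis stages consume,
with a ground-truth sidecar so each stage can be verified quantitatively.

Model summary
-------------
* Membrane potential: resting level plus action potentials (triangular
  rise, exponential decay, parameterized by amplitude and half-width),
  optional PSP events (difference of exponentials), optional 3–5 Hz
  sinusoidal oscillation episodes, and subthreshold bumps injected by
  shared-input events.
* Fluorescence: F(t) = f0·(1 + k(t)) · exp(−t/τ_bleach) + background +
  noise, where k(t) is (slope/100)·(V − v_rest) passed through a
  double-exponential kinetic filter (exact first-order recursions, so a
  voltage step reproduces a(1−e^{−t/τf}) + b(1−e^{−t/τs}) to machine
  precision).  Negative-going sensors carry a negative slope.
* Populations: each cell pair with weight w shares a common Poisson event
  stream; every event triggers a spike in each of the two cells with
  probability w and otherwise injects a depolarizing bump whose amplitude
  scales with w.  Independent Poisson spikes top each cell up to its
  nominal rate.  Near-coincident spiking and co-depolarization therefore
  both increase with w.
* Plate movies: 96-well-style field-stimulation recordings (8 pulses at
  8.3 Hz, ~1.5 kHz frames) with disk-shaped cells, per-pixel bleaching,
  dim background pixels, and shot-like Gaussian noise.

All randomness flows from explicit integer seeds through
``numpy.random.SeedSequence``; identical configuration and seed give
bitwise-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .population import PopulationRecording
from .preprocess import dff_detrend
from .spikes import SpikeTrain
from .traces import Trace

__all__ = [
    "SensorParams",
    "VmConfig",
    "PopulationConfig",
    "GroundTruth",
    "WellSpec",
    "PlateConfig",
    "ap_waveform",
    "psp_waveform",
    "simulate_vm",
    "vm_to_fluorescence",
    "simulate_cells",
    "render_plate_movie",
]


@dataclass
class SensorParams:
    """Linear voltage sensor with double-exponential kinetics.

    ``sensitivity_slope`` is the signed percent ΔF/F per mV on the raw
    fluorescence (negative for negative-going sensors).  Time constants are
    in ms; ``frac_fast_on``/``frac_fast_off`` weight the fast component of
    the onset and decay.  ``bleach_tau`` (s) may be ``inf`` for no
    bleaching.
    """

    sensitivity_slope: float = -0.2  # % ΔF/F per mV
    tau_fast_on: float = 0.67  # ms
    tau_slow_on: float = 3.26  # ms
    tau_fast_off: float = 0.89  # ms
    tau_slow_off: float = 6.27  # ms
    frac_fast_on: float = 0.75
    frac_fast_off: float = 0.6
    f0: float = 1000.0  # a.u.
    bleach_tau: float = 1700.0  # s
    background: float = 0.0  # a.u.

    def __post_init__(self) -> None:
        for tau in (self.tau_fast_on, self.tau_slow_on,
                    self.tau_fast_off, self.tau_slow_off):
            if not tau > 0:
                raise ValueError("sensor time constants must be positive")
        for frac in (self.frac_fast_on, self.frac_fast_off):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fast fractions must lie in [0, 1]")
        if not self.bleach_tau > 0:
            raise ValueError("bleach_tau must be positive (inf allowed)")
        if not self.f0 > self.background >= 0:
            raise ValueError("require f0 > background >= 0")

    @classmethod
    def linear(cls, sensitivity_slope: float, f0: float = 1000.0,
               background: float = 0.0) -> "SensorParams":
        """Sensor with effectively instantaneous kinetics and no bleaching."""
        return cls(
            sensitivity_slope=sensitivity_slope,
            tau_fast_on=1e-6, tau_slow_on=1e-6,
            tau_fast_off=1e-6, tau_slow_off=1e-6,
            frac_fast_on=1.0, frac_fast_off=1.0,
            f0=f0, bleach_tau=np.inf, background=background,
        )


@dataclass
class VmConfig:
    """Single-cell membrane-potential model parameters."""

    v_rest: float = -70.0  # mV
    spike_rate: float = 2.0  # Hz
    ap_amplitude: float = 80.0  # mV
    ap_halfwidth: float = 0.7  # ms
    psp_schedule: list[tuple[float, float, float, float]] = field(
        default_factory=list
    )  # (onset s, amplitude mV, rise ms, decay ms)
    oscillation_episodes: list[tuple[float, float, float, float]] = field(
        default_factory=list
    )  # (start s, duration s, freq Hz, peak-to-peak mV)
    duration: float = 180.0  # s
    fs: float = 1000.0  # Hz
    refractory_ms: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.duration > 0:
            raise ValueError("duration must be positive")
        if self.spike_rate < 0:
            raise ValueError("spike_rate must be non-negative")
        for _, _, freq, _ in self.oscillation_episodes:
            if not self.fs > 2 * freq:
                raise ValueError("fs must exceed twice the oscillation frequency")


@dataclass
class PopulationConfig:
    """Coupled multi-cell recording configuration.

    ``shared_input_weights`` is a symmetric matrix with zero diagonal and
    entries in [0, 1]: the probability that a common excitatory event in a
    pair's shared stream triggers a spike in each member.  Non-triggering
    events inject a subthreshold bump of ``codep_bump_mv * weight`` mV.
    ``shared_event_rate`` (Hz) is the rate of each pair's common stream;
    by default the minimum per-cell spike rate.
    """

    n_cells: int
    cell_positions: np.ndarray  # (n, 2) μm
    shared_input_weights: np.ndarray  # (n, n) in [0, 1]
    vm: VmConfig | list[VmConfig]
    sensor: SensorParams = field(default_factory=SensorParams)
    noise_sd: float = 0.01  # ΔF/F fraction per frame
    shared_event_rate: float | None = None
    codep_bump_mv: float = 3.0
    bump_rise_ms: float = 2.0
    bump_decay_ms: float = 20.0
    spike_jitter_ms: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.cell_positions = np.asarray(self.cell_positions, dtype=float)
        w = np.asarray(self.shared_input_weights, dtype=float)
        if w.shape != (self.n_cells, self.n_cells):
            raise ValueError("weight matrix shape must be (n_cells, n_cells)")
        if not np.allclose(w, w.T):
            raise ValueError("weight matrix must be symmetric")
        if np.any(np.diag(w) != 0):
            raise ValueError("weight matrix diagonal must be zero")
        if np.any(w < 0) or np.any(w > 1):
            raise ValueError("weights must lie in [0, 1]")
        self.shared_input_weights = w
        if self.cell_positions.shape != (self.n_cells, 2):
            raise ValueError("cell_positions must be (n_cells, 2)")

    def vm_for(self, i: int) -> VmConfig:
        return self.vm[i] if isinstance(self.vm, list) else self.vm


@dataclass
class GroundTruth:
    """Everything the generator knows that the analyses must recover."""

    spike_times: list[np.ndarray]  # s, per cell
    common_events: list[tuple[float, float, tuple[int, ...]]]
    vm: list[Trace]
    responsive_pixels: dict[str, list[tuple[int, int]]] | None = None


def ap_waveform(t_rel_s: np.ndarray, amplitude_mv: float,
                halfwidth_ms: float) -> np.ndarray:
    """Triangular-exponential action potential, peak at t_rel = 0.

    Linear rise over 2h/3 before the peak and exponential decay with
    τ = (2h/3)/ln 2 after it, which makes the full width at half maximum
    equal to the half-width parameter h.
    """
    h = halfwidth_ms * 1e-3
    rise = 2.0 * h / 3.0
    tau = rise / math.log(2.0)
    t = np.asarray(t_rel_s, dtype=float)
    y = np.zeros_like(t)
    up = (t >= -rise) & (t <= 0)
    y[up] = 1.0 + t[up] / rise
    down = t > 0
    y[down] = np.exp(-t[down] / tau)
    return amplitude_mv * y


def psp_waveform(t_rel_s: np.ndarray, amplitude_mv: float,
                 rise_ms: float, decay_ms: float) -> np.ndarray:
    """Difference-of-exponentials PSP, onset at t_rel = 0, peak = amplitude."""
    tr, td = rise_ms * 1e-3, decay_ms * 1e-3
    if not td > tr > 0:
        raise ValueError("require decay > rise > 0")
    t = np.asarray(t_rel_s, dtype=float)
    y = np.zeros_like(t)
    pos = t >= 0
    raw = np.exp(-t[pos] / td) - np.exp(-t[pos] / tr)
    tpk = (tr * td / (td - tr)) * math.log(td / tr)
    peak = math.exp(-tpk / td) - math.exp(-tpk / tr)
    y[pos] = raw / peak
    return amplitude_mv * y


def _add_events(vm: np.ndarray, fs: float, times_s: np.ndarray,
                waveform, support_s: tuple[float, float]) -> None:
    """Add a waveform (callable on relative times) at each event time."""
    n = vm.size
    pre = int(math.ceil(-support_s[0] * fs))
    post = int(math.ceil(support_s[1] * fs))
    rel = np.arange(-pre, post + 1) / fs
    for t in times_s:
        i = int(round(t * fs))
        lo, hi = i - pre, i + post + 1
        s_lo = max(0, lo)
        s_hi = min(n, hi)
        if s_lo >= s_hi:
            continue
        vm[s_lo:s_hi] += waveform(rel[s_lo - lo: s_hi - lo] + (i / fs - t))


def _apply_refractory(times: np.ndarray, refractory_s: float) -> np.ndarray:
    if times.size == 0:
        return times
    times = np.sort(times)
    kept = [times[0]]
    for t in times[1:]:
        if t - kept[-1] >= refractory_s:
            kept.append(t)
    return np.asarray(kept)


def simulate_vm(
    cfg: VmConfig,
    rng: np.random.Generator | None = None,
    extra_spike_times: np.ndarray | None = None,
    extra_bumps: list[tuple[float, float, float, float]] | None = None,
) -> tuple[Trace, np.ndarray]:
    """Simulate a membrane-potential trace.

    ``extra_spike_times`` (s) are merged with the cell's own Poisson
    spikes; ``extra_bumps`` are (onset s, amplitude mV, rise ms, decay ms)
    subthreshold events.  Returns the Vm trace (mV) and the realized spike
    times after refractory enforcement.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    n = int(round(cfg.duration * cfg.fs))
    vm = np.full(n, cfg.v_rest, dtype=float)

    n_own = rng.poisson(cfg.spike_rate * cfg.duration)
    own = np.sort(rng.uniform(0.0, cfg.duration, size=n_own))
    all_spikes = own
    if extra_spike_times is not None and len(extra_spike_times):
        all_spikes = np.concatenate([own, np.asarray(extra_spike_times, float)])
    spikes = _apply_refractory(all_spikes, cfg.refractory_ms * 1e-3)
    spikes = spikes[(spikes >= 0) & (spikes < cfg.duration)]
    # spike times follow the peak-sample convention: quantize to the frame
    # grid so each AP peaks exactly on a sample
    spikes = np.unique(np.round(spikes * cfg.fs)) / cfg.fs
    spikes = spikes[spikes < cfg.duration]

    h = cfg.ap_halfwidth * 1e-3
    _add_events(
        vm, cfg.fs, spikes,
        lambda t: ap_waveform(t, cfg.ap_amplitude, cfg.ap_halfwidth),
        (-(2 * h / 3), 10 * h),
    )
    for onset, amp, rise, decay in list(cfg.psp_schedule) + list(extra_bumps or []):
        _add_events(
            vm, cfg.fs, np.array([onset]),
            lambda t, a=amp, r=rise, d=decay: psp_waveform(t, a, r, d),
            (0.0, 8 * decay * 1e-3),
        )
    t_axis = np.arange(n) / cfg.fs
    for start, dur, freq, pp in cfg.oscillation_episodes:
        win = (t_axis >= start) & (t_axis < start + dur)
        vm[win] += 0.5 * pp * np.sin(2 * math.pi * freq * (t_axis[win] - start))
    return Trace(values=vm, fs=cfg.fs, units="mV"), spikes


def _kinetic_filter_py(x: np.ndarray, a_on: float, a_off: float) -> np.ndarray:
    y = np.empty_like(x)
    prev = 0.0
    for i in range(x.size):
        xi = x[i]
        a = a_on if abs(xi) >= abs(prev) else a_off
        prev = xi + (prev - xi) * a
        y[i] = prev
    return y


try:  # numba shaves ~100x off the sequential recursion on long records
    from numba import njit

    _kinetic_filter_fast = njit(cache=False)(_kinetic_filter_py)
except ImportError:  # pragma: no cover
    _kinetic_filter_fast = _kinetic_filter_py


def _kinetic_filter(x: np.ndarray, fs: float, tau_on_ms: float,
                    tau_off_ms: float) -> np.ndarray:
    """Exact first-order relaxation toward x with direction-dependent τ.

    For zero-order-hold input the recursion y[n] = x[n] + (y[n−1] −
    x[n])·exp(−dt/τ) reproduces the continuous solution exactly, so step
    responses match their closed forms to machine precision.  τ_on applies
    when the drive moves away from baseline (|x| ≥ |y|), τ_off on the way
    back.
    """
    dt_ms = 1e3 / fs
    a_on = math.exp(-dt_ms / tau_on_ms)
    a_off = math.exp(-dt_ms / tau_off_ms)
    return _kinetic_filter_fast(np.ascontiguousarray(x, dtype=float),
                                a_on, a_off)


def vm_to_fluorescence(
    vm: Trace,
    sensor: SensorParams,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
    v_rest: float | None = None,
) -> Trace:
    """Convert a membrane-potential trace into raw fluorescence.

    F(t) = f0·(1 + k(t))·exp(−t/τ_bleach) + background + ε, where k(t) is
    the kinetically filtered (slope/100)·(V − v_rest) and ε is i.i.d.
    Gaussian with SD ``noise_sd·f0`` (``noise_sd`` is a ΔF/F fraction).
    """
    if not np.all(np.isfinite(vm.values)):
        raise ValueError("Vm contains non-finite samples")
    vr = vm.values[0] if v_rest is None else v_rest
    x = (sensor.sensitivity_slope / 100.0) * (vm.values - vr)
    y_fast = _kinetic_filter(x, vm.fs, sensor.tau_fast_on, sensor.tau_fast_off)
    y_slow = _kinetic_filter(x, vm.fs, sensor.tau_slow_on, sensor.tau_slow_off)
    k = sensor.frac_fast_on * y_fast + (1.0 - sensor.frac_fast_on) * y_slow
    t = np.arange(vm.values.size) / vm.fs
    bleach = np.exp(-t / sensor.bleach_tau) if np.isfinite(sensor.bleach_tau) else 1.0
    f = sensor.f0 * (1.0 + k) * bleach + sensor.background
    if noise_sd > 0:
        rng = (seed if isinstance(seed, np.random.Generator)
               else np.random.default_rng(seed))
        f = f + rng.normal(0.0, noise_sd * sensor.f0, size=f.size)
    return Trace(values=f, fs=vm.fs, t0=vm.t0, units="au")


def simulate_cells(pop: PopulationConfig) -> tuple[PopulationRecording, GroundTruth]:
    """Simulate a coupled population: Vm, fluorescence, ΔF/F, ground truth.

    Pairwise shared Poisson streams realize common excitatory drive: each
    event makes each member of the pair spike with probability equal to the
    pair weight, and injects a subthreshold bump (amplitude ∝ weight) into
    members that do not spike.  Per-cell independent Poisson spikes top the
    rate up to the configured value.  The returned ΔF/F traces use the
    inverted moving-average convention (positive spikes).
    """
    n = pop.n_cells
    ss = np.random.SeedSequence(pop.seed)
    child = ss.spawn(n * n + n + 1)
    vm0 = pop.vm_for(0)
    duration, fs = vm0.duration, vm0.fs

    rates = np.array([pop.vm_for(i).spike_rate for i in range(n)])
    rho = pop.shared_event_rate
    if rho is None:
        rho = float(rates.min()) if n else 0.0

    shared_spikes: list[list[np.ndarray]] = [[] for _ in range(n)]
    bumps: list[list[tuple[float, float, float, float]]] = [[] for _ in range(n)]
    common_events: list[tuple[float, float, tuple[int, ...]]] = []
    k = 0
    for i in range(n):
        for j in range(i + 1, n):
            w = pop.shared_input_weights[i, j]
            rng_pair = np.random.default_rng(child[k])
            k += 1
            if w == 0 or rho == 0:
                continue
            n_ev = rng_pair.poisson(rho * duration)
            ev = np.sort(rng_pair.uniform(0.0, duration, size=n_ev))
            hit_i = rng_pair.random(n_ev) < w
            hit_j = rng_pair.random(n_ev) < w
            if pop.spike_jitter_ms > 0:
                jit_i = rng_pair.normal(0, pop.spike_jitter_ms * 1e-3, n_ev)
                jit_j = rng_pair.normal(0, pop.spike_jitter_ms * 1e-3, n_ev)
            else:
                jit_i = jit_j = np.zeros(n_ev)
            shared_spikes[i].append(ev[hit_i] + jit_i[hit_i])
            shared_spikes[j].append(ev[hit_j] + jit_j[hit_j])
            bump_amp = pop.codep_bump_mv * w
            for t_ev, hi, hj in zip(ev, hit_i, hit_j):
                recipients = []
                if not hi:
                    bumps[i].append(
                        (t_ev, bump_amp, pop.bump_rise_ms, pop.bump_decay_ms))
                    recipients.append(i)
                if not hj:
                    bumps[j].append(
                        (t_ev, bump_amp, pop.bump_rise_ms, pop.bump_decay_ms))
                    recipients.append(j)
                common_events.append((float(t_ev), float(bump_amp),
                                      tuple(recipients)))
    k = n * n  # cell seeds start after the pair block

    dffs, trains, vms, gt_spikes = [], [], [], []
    for i in range(n):
        cfg = pop.vm_for(i)
        shared_rate_i = float(np.sum(pop.shared_input_weights[i]) * rho)
        r_ind = max(0.0, cfg.spike_rate - shared_rate_i)
        cfg_i = VmConfig(
            v_rest=cfg.v_rest, spike_rate=r_ind,
            ap_amplitude=cfg.ap_amplitude, ap_halfwidth=cfg.ap_halfwidth,
            psp_schedule=cfg.psp_schedule,
            oscillation_episodes=cfg.oscillation_episodes,
            duration=cfg.duration, fs=cfg.fs,
            refractory_ms=cfg.refractory_ms, seed=cfg.seed,
        )
        rng_cell = np.random.default_rng(child[k + i])
        extra = (np.concatenate(shared_spikes[i])
                 if shared_spikes[i] else np.array([]))
        vm, spikes = simulate_vm(cfg_i, rng_cell, extra_spike_times=extra,
                                 extra_bumps=bumps[i])
        f = vm_to_fluorescence(vm, pop.sensor, pop.noise_sd, rng_cell,
                               v_rest=cfg.v_rest)
        dff = dff_detrend(f, method="moving_avg_1s_inverted")
        dffs.append(dff)
        trains.append(SpikeTrain(times=spikes,
                                 amplitudes=np.full(spikes.size, np.nan),
                                 detector="ground_truth"))
        vms.append(vm)
        gt_spikes.append(spikes)

    rec = PopulationRecording(dff=dffs, spikes=trains,
                              positions=pop.cell_positions)
    truth = GroundTruth(spike_times=gt_spikes, common_events=common_events,
                        vm=vms)
    return rec, truth


@dataclass
class WellSpec:
    """One well of a screening plate."""

    name: str
    construct: str
    is_control: bool = False
    sensitivity_multiplier: float = 1.0


@dataclass
class PlateConfig:
    """Field-stimulation plate rendering parameters.

    Defaults emulate the screening assay: 8 field pulses at 8.3 Hz imaged
    at 1497 Hz, disk-shaped cells over a dim background, per-pixel
    single-exponential bleaching and shot-like Gaussian noise.  The
    control construct responds with per-pulse amplitude ``base_dffmax``
    (signed ΔF/F fraction; negative for negative-going sensors); variants
    scale it by their ``sensitivity_multiplier``.
    """

    wells: list[WellSpec]
    frame_shape: tuple[int, int] = (24, 24)
    n_cells_per_well: int = 3
    cell_radius_px: int = 3
    frame_rate: float = 1497.0
    n_pulses: int = 8
    pulse_rate: float = 8.3
    pre_s: float = 0.15
    tail_s: float = 0.10
    base_dffmax: float = -0.04
    tau_on_ms: float = 1.0
    tau_off_ms: float = 10.0
    f0_cell: float = 2000.0
    background_frac: float = 0.1
    bleach_tau_s: float = 60.0
    noise_sd_frac: float = 0.005

    def __post_init__(self) -> None:
        if not self.frame_rate > 2 * self.pulse_rate:
            raise ValueError("frame rate must exceed twice the pulse rate")

    @property
    def pulse_times(self) -> np.ndarray:
        return self.pre_s + np.arange(self.n_pulses) / self.pulse_rate

    @property
    def duration(self) -> float:
        return self.pre_s + self.n_pulses / self.pulse_rate + self.tail_s


def _response_kernel(t_s: np.ndarray, tau_on_ms: float,
                     tau_off_ms: float) -> np.ndarray:
    """Rising×decaying exponential product, normalized to unit peak."""
    ton, toff = tau_on_ms * 1e-3, tau_off_ms * 1e-3
    t = np.asarray(t_s, dtype=float)
    y = np.zeros_like(t)
    pos = t >= 0
    y[pos] = (1.0 - np.exp(-t[pos] / ton)) * np.exp(-t[pos] / toff)
    tpk = ton * math.log(1.0 + toff / ton)
    peak = (1.0 - math.exp(-tpk / ton)) * math.exp(-tpk / toff)
    return y / peak


def render_plate_movie(
    plate: PlateConfig, seed: int = 0
) -> tuple[dict[str, np.ndarray], GroundTruth]:
    """Render per-well field-stimulation movies with a ground-truth sidecar.

    Returns a mapping well name → movie array (frames, H, W, float32) and a
    :class:`GroundTruth` whose ``responsive_pixels`` lists the truly
    voltage-sensitive (row, col) pixels of each well (empty for wells whose
    sensitivity multiplier is zero).
    """
    ss = np.random.SeedSequence(seed)
    child = ss.spawn(len(plate.wells))
    h, wdt = plate.frame_shape
    n_frames = int(round(plate.duration * plate.frame_rate))
    t = np.arange(n_frames) / plate.frame_rate
    dff_t = np.zeros(n_frames)
    for tp in plate.pulse_times:
        dff_t += _response_kernel(t - tp, plate.tau_on_ms, plate.tau_off_ms)
    bleach = np.exp(-t / plate.bleach_tau_s)

    movies: dict[str, np.ndarray] = {}
    responsive: dict[str, list[tuple[int, int]]] = {}
    for wspec, cseed in zip(plate.wells, child):
        rng = np.random.default_rng(cseed)
        cell_mask = np.zeros((h, wdt), dtype=bool)
        rr, cc = np.mgrid[0:h, 0:wdt]
        for _ in range(plate.n_cells_per_well):
            cy = rng.integers(plate.cell_radius_px, h - plate.cell_radius_px)
            cx = rng.integers(plate.cell_radius_px, wdt - plate.cell_radius_px)
            cell_mask |= (rr - cy) ** 2 + (cc - cx) ** 2 <= plate.cell_radius_px ** 2
        gain = 1.0 + 0.1 * rng.standard_normal((h, wdt))
        f0_map = np.where(cell_mask, plate.f0_cell,
                          plate.background_frac * plate.f0_cell) * np.abs(gain)
        amp = plate.base_dffmax * wspec.sensitivity_multiplier
        dff_map = np.where(cell_mask, amp, 0.0)
        movie = (
            f0_map[None, :, :]
            * (1.0 + dff_map[None, :, :] * dff_t[:, None, None])
            * bleach[:, None, None]
        )
        movie = movie + rng.normal(
            0.0, plate.noise_sd_frac * plate.f0_cell, size=movie.shape
        )
        movies[wspec.name] = movie.astype(np.float32)
        if wspec.sensitivity_multiplier != 0:
            pix = np.argwhere(cell_mask)
        else:
            pix = np.empty((0, 2), dtype=int)
        responsive[wspec.name] = [tuple(p) for p in pix]
    truth = GroundTruth(spike_times=[], common_events=[], vm=[],
                        responsive_pixels=responsive)
    return movies, truth
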