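"""Subthreshold and sensor-characterization analytics.

Covers: detection of 3–5 Hz subthreshold oscillation episodes by band-pass
filtering and MAD-thresholded outlier statistics; d′ detectability of
millivolt-scale synthetic PSPs; fluorescence–voltage curves with the
subthreshold slope (%/mV); double-exponential kinetics fits of step
responses; and a simple photobleaching metric.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, signal

from .traces import DffTrace, Trace

__all__ = [
    "OscillationResult",
    "SynPspResult",
    "FVCurve",
    "KineticsFit",
    "detect_oscillations",
    "dprime",
    "synpsp_dprime",
    "fv_curve",
    "fit_double_exponential",
    "photobleach_metric",
]

MAD_SCALE = 1.4826  # normal-consistent MAD scaling


@dataclass
class OscillationResult:
    """Outliers of a band-passed ΔF/F trace above a MAD threshold."""

    outlier_indices: np.ndarray
    mean_abs_outlier_amplitude_pct: float
    band_hz: tuple[float, float]
    has_outliers: bool
    bandpassed: np.ndarray = field(repr=False, default=None)


def detect_oscillations(
    dff: DffTrace,
    band_hz: tuple[float, float] = (3.0, 5.0),
    mad_k: float = 3.0,
    order: int = 4,
) -> OscillationResult:
    """Detect oscillation episodes as MAD outliers of a band-passed trace.

    The ΔF/F trace is zero-phase band-pass filtered (Butterworth, 4th
    order, forward-backward); samples whose deviation from the median of
    the filtered trace exceeds ``mad_k`` × scaled MAD (×1.4826) are
    outliers, and the oscillation amplitude is the mean |value| of those
    outliers in ΔF/F percent.  A stationary sinusoid produces *no*
    outliers (its MAD is amplitude/√2, so 3×scaled MAD exceeds the
    amplitude); episodic bursts on a quiet background do.
    """
    lo, hi = band_hz
    if not dff.fs > 2 * hi:
        raise ValueError("sampling rate must exceed twice the band top")
    if dff.duration < 5.0 / lo:
        raise ValueError("trace shorter than 5 cycles of the band bottom")
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=dff.fs,
                        output="sos")
    bp = signal.sosfiltfilt(sos, dff.values)
    med = np.median(bp)
    mad = np.median(np.abs(bp - med))
    thr = mad_k * MAD_SCALE * mad
    out = np.nonzero(np.abs(bp - med) > thr)[0]
    if out.size:
        amp = float(np.mean(np.abs(bp[out]))) * 100.0
    else:
        amp = 0.0
    return OscillationResult(
        outlier_indices=out,
        mean_abs_outlier_amplitude_pct=amp,
        band_hz=band_hz,
        has_outliers=bool(out.size),
        bandpassed=bp,
    )


def dprime(signal_vals: np.ndarray, noise_vals: np.ndarray) -> float:
    """Sensitivity index d′ = (μS − μN) / sqrt(½(σS² + σN²)).

    The denominator is the root of the pooled (equal-weight) variance of
    the signal and noise windows; population (ddof=0) SDs are used.
    """
    s = np.asarray(signal_vals, dtype=float)
    n = np.asarray(noise_vals, dtype=float)
    if s.size < 2 or n.size < 2:
        raise ValueError("need at least two values per window")
    denom = np.sqrt(0.5 * (s.std() ** 2 + n.std() ** 2))
    if denom == 0:
        return float("nan")
    return float((s.mean() - n.mean()) / denom)


@dataclass
class SynPspResult:
    amplitudes_mv: np.ndarray
    dprimes: np.ndarray
    dprime_per_mv: float
    n_trials: int


def _detrend_trial(trace: np.ndarray, fs: float, onset_s: float,
                   baseline_fit_ms: float = 40.0) -> np.ndarray:
    """ΔF/F relative to a regression-line baseline fit pre-onset.

    A least-squares line is fit to the ``baseline_fit_ms`` window before
    the PSP onset and extrapolated over the whole trial; the trial is
    returned as (F − baseline)/baseline.
    """
    n = trace.size
    i_on = int(round(onset_s * fs))
    i0 = max(0, i_on - int(round(baseline_fit_ms * 1e-3 * fs)))
    if i_on - i0 < 2:
        raise ValueError("baseline window too short")
    t = np.arange(n) / fs
    coef = np.polyfit(t[i0:i_on], trace[i0:i_on], 1)
    base = np.polyval(coef, t)
    return (trace - base) / base


def synpsp_dprime(
    trials_by_amplitude: dict[float, np.ndarray],
    fs: float,
    onset_s: float,
    noise_win_ms: float = 10.0,
    signal_win_ms: tuple[float, float] = (4.0, 14.0),
    baseline_fit_ms: float = 40.0,
    raw_fluorescence: bool = True,
) -> SynPspResult:
    """Detectability of synthetic PSPs across injected amplitudes.

    ``trials_by_amplitude`` maps PSP amplitude (mV, e.g. −15…+15 in 5 mV
    steps) to a (n_trials, n_samples) array of fluorescence trials.  Each
    trial is converted to ΔF/F against a regression-line baseline fit to
    40 ms before onset (skipped when ``raw_fluorescence`` is False).  For
    each amplitude, the per-trial mean of a noise window (``noise_win_ms``
    before onset) and of a signal window (4–14 ms after onset) give the
    (μ, σ) pairs entering d′; the summary slope d′/mV is the OLS slope of
    d′ against amplitude.
    """
    amps = np.array(sorted(trials_by_amplitude), dtype=float)
    i_on = int(round(onset_s * fs))
    n_noise = int(round(noise_win_ms * 1e-3 * fs))
    i_s0 = i_on + int(round(signal_win_ms[0] * 1e-3 * fs))
    i_s1 = i_on + int(round(signal_win_ms[1] * 1e-3 * fs))
    dps, n_trials = [], 0
    for a in amps:
        trials = np.asarray(trials_by_amplitude[a], dtype=float)
        n_trials = trials.shape[0]
        sig_means, noise_means = [], []
        for tr in trials:
            x = (_detrend_trial(tr, fs, onset_s, baseline_fit_ms)
                 if raw_fluorescence else tr)
            noise_means.append(np.mean(x[i_on - n_noise: i_on]))
            sig_means.append(np.mean(x[i_s0:i_s1]))
        dps.append(dprime(np.array(sig_means), np.array(noise_means)))
    dps = np.array(dps)
    slope = (float(np.polyfit(amps, dps, 1)[0]) if amps.size >= 2
             else float("nan"))
    return SynPspResult(amplitudes_mv=amps, dprimes=dps,
                        dprime_per_mv=slope, n_trials=n_trials)


@dataclass
class FVCurve:
    step_voltages_mv: np.ndarray
    dff_per_step_pct: np.ndarray
    subthreshold_slope_pct_per_mv: float  # |slope|
    signed_slope_pct_per_mv: float
    slope_range_mv: tuple[float, float]
    holding_mv: float


def fv_curve(
    step_records: dict[float, np.ndarray],
    fs: float,
    step_onset_s: float,
    step_duration_s: float = 1.0,
    holding_mv: float = -70.0,
    slope_range_mv: tuple[float, float] = (-90.0, -50.0),
    mode: str = "steady_state",
    steady_window_s: float = 0.2,
) -> FVCurve:
    """Fluorescence–voltage curve and subthreshold slope.

    ``step_records`` maps command voltage (mV) to a ΔF/F trace (fraction)
    aligned to the step protocol (e.g. 0.5 s baseline then a 1 s step from
    a −70 mV holding level).  The per-step response is the mean ΔF/F over
    the final ``steady_window_s`` of the step (``mode="steady_state"``) or
    the signed extremum during the step (``mode="peak"``, for sensors with
    a transient peak).  The subthreshold slope is the OLS slope (%/mV)
    over the steps inside ``slope_range_mv``, including the zero-response
    point at the holding potential; the magnitude is reported alongside
    the signed value.
    """
    volts = np.array(sorted(step_records), dtype=float)
    resp = []
    i_on = int(round(step_onset_s * fs))
    i_off = i_on + int(round(step_duration_s * fs))
    for v in volts:
        x = np.asarray(step_records[v], dtype=float)
        if mode == "steady_state":
            i0 = i_off - int(round(steady_window_s * fs))
            r = float(np.mean(x[i0:i_off]))
        elif mode == "peak":
            seg = x[i_on:i_off]
            r = float(seg[np.argmax(np.abs(seg))])
        else:
            raise ValueError("mode must be 'steady_state' or 'peak'")
        resp.append(r * 100.0)
    resp = np.array(resp)

    lo, hi = slope_range_mv
    sel = (volts >= lo) & (volts <= hi)
    vv = np.concatenate([volts[sel], [holding_mv]])
    rr = np.concatenate([resp[sel], [0.0]])
    slope = float(np.polyfit(vv, rr, 1)[0])
    return FVCurve(
        step_voltages_mv=volts,
        dff_per_step_pct=resp,
        subthreshold_slope_pct_per_mv=abs(slope),
        signed_slope_pct_per_mv=slope,
        slope_range_mv=slope_range_mv,
        holding_mv=holding_mv,
    )


@dataclass
class KineticsFit:
    a: float
    b: float
    tau_fast_ms: float
    tau_slow_ms: float
    c: float
    percent_fast: float
    rmse: float
    identifiable: bool = True


def fit_double_exponential(
    step_response: np.ndarray,
    fs: float,
    t0_s: float = 0.0,
) -> KineticsFit:
    """Fit y(t) = a·e^(−t/τfast) + b·e^(−t/τslow) + c to a relaxation.

    Onset kinetics are fit by passing the distance from steady state (a
    decaying quantity).  Constrained nonlinear least squares with a, b ≥ 0
    and τfast < τslow (enforced by sorting); the fit is flagged
    non-identifiable when the two time constants are within 5% of each
    other.  ``percent_fast`` = 100·a/(a+b).
    """
    y = np.asarray(step_response, dtype=float)
    i0 = int(round(t0_s * fs))
    y = y[i0:]
    t = np.arange(y.size) / fs

    span = y[0] - y[-1]
    p0 = (0.6 * span, 0.4 * span, 1e-3, 5e-3, y[-1])

    def model(tt, a, b, tf, ts, c):
        return a * np.exp(-tt / tf) + b * np.exp(-tt / ts) + c

    try:
        popt, _ = optimize.curve_fit(
            model, t, y, p0=p0,
            bounds=([0, 0, 1e-6, 1e-6, -np.inf],
                    [np.inf, np.inf, 1.0, 10.0, np.inf]),
            maxfev=20000,
        )
    except RuntimeError:
        popt = p0
    a, b, tf, ts, c = popt
    if tf > ts:
        a, b, tf, ts = b, a, ts, tf
    rmse = float(np.sqrt(np.mean((model(t, a, b, tf, ts, c) - y) ** 2)))

    # a single exponential that fits no worse wins: the double-exponential
    # split is then non-identifiable and the data are mono-exponential
    def single(tt, a1, tau1, c1):
        return a1 * np.exp(-tt / tau1) + c1

    try:
        popt1, _ = optimize.curve_fit(
            single, t, y, p0=(span, 1e-3, y[-1]),
            bounds=([0, 1e-6, -np.inf], [np.inf, 10.0, np.inf]),
            maxfev=20000,
        )
        rmse1 = float(np.sqrt(np.mean((single(t, *popt1) - y) ** 2)))
    except RuntimeError:
        rmse1 = np.inf
    scale = max(abs(span), 1e-12)
    if rmse1 <= rmse + 1e-9 * scale:
        a, tf, c = popt1
        b, ts = 0.0, float("nan")
        rmse = rmse1
    identifiable = not (b > 0 and a > 0 and np.isfinite(ts)
                        and abs(ts - tf) < 0.05 * ts)
    denom = a + b
    pf = float(100.0 * a / denom) if denom > 0 else float("nan")
    return KineticsFit(
        a=float(a), b=float(b), tau_fast_ms=float(tf * 1e3),
        tau_slow_ms=float(ts * 1e3), c=float(c), percent_fast=pf,
        rmse=rmse, identifiable=identifiable,
    )


def photobleach_metric(
    trace: Trace, horizon_s: float, window_s: float = 1.0
) -> float:
    """Percent fluorescence reduction over a horizon.

    100·(F_start − F_end)/F_start, where F_start and F_end are means over
    ``window_s``-long windows at the start of the record and at the
    horizon.  Negative values (brightening) are allowed.
    """
    if trace.duration < horizon_s:
        raise ValueError("trace shorter than the requested horizon")
    n_win = max(1, int(round(window_s * trace.fs)))
    i_end = int(round(horizon_s * trace.fs))
    f_start = float(np.mean(trace.values[:n_win]))
    f_end = float(np.mean(trace.values[max(0, i_end - n_win): i_end]))
    return 100.0 * (f_start - f_end) / f_start
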