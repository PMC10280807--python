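"""Spike detection from ΔF/F traces, spike amplitudes, SNR, and cell QC.

Two detectors are implemented.

The KDE detector works on a high-pass ΔF/F trace with *positive* spikes.
Candidate peaks are local maxima; a kernel density estimate of their
amplitudes, P(x), is compared with the density of peaks of the inverted
trace, Pnoise(x); the spike-amplitude density is S(x) = P(x) − Pnoise(x)
and the threshold th1 sits where S crosses Pnoise (the boundary between the
noise-dominated and spike-dominated amplitude ranges, which balances type I
and type II errors).  If the expected number of false positives at th1 —
counted as supra-threshold peaks in the inverted trace — exceeds a rate
cap, a higher fallback threshold th2 is used that keeps the count at the
cap (18 for a 180-s record at 0.1 Hz).  Detected spikes define an AP
template; candidate amplitudes shadowed by a larger neighbor within ±2 ms
are corrected by subtracting the neighbor's template contribution, and the
corrected amplitudes are re-thresholded.

The fixed-threshold detector works on a ΔF/F trace with *negative* spikes
and a noise SD estimated by sign symmetrization: samples below −k·SD (k=4
by default) are grouped into consecutive runs, and each run yields one
spike at its extremum (the doublet rule).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .preprocess import dff_detrend, estimate_noise_spike_excluded
from .traces import DffTrace, Trace

__all__ = [
    "SpikeTrain",
    "APTemplate",
    "SpikeDetectionModel",
    "CellQCReport",
    "detect_spikes_kde",
    "amplitude_correct",
    "detect_spikes_fixed_threshold",
    "spike_waveform_and_halfwidth",
    "snr_cell",
    "cell_qc",
    "spike_amplitude_trough_to_peak",
    "snr_high_frequency",
]


@dataclass
class SpikeTrain:
    """Detected (or ground-truth) spike times with per-spike amplitudes."""

    times: np.ndarray  # s, sorted
    amplitudes: np.ndarray  # ΔF/F fraction, positive convention
    detector: str = "unknown"
    threshold: float = float("nan")

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.amplitudes.shape:
            raise ValueError("times and amplitudes must be matching 1-D arrays")
        if self.times.size > 1 and np.any(np.diff(self.times) < 0):
            raise ValueError("spike times must be sorted")

    @property
    def n_spikes(self) -> int:
        return self.times.size

    def rate(self, duration: float) -> float:
        return self.n_spikes / duration if duration > 0 else float("nan")


@dataclass
class APTemplate:
    """Mean action-potential waveform AP(t) on a lag grid around the peak."""

    lags_s: np.ndarray
    values: np.ndarray

    def __call__(self, lag_s: float | np.ndarray) -> np.ndarray | float:
        """Template value at a lag; zero outside the covered window."""
        return np.interp(lag_s, self.lags_s, self.values, left=0.0, right=0.0)


@dataclass
class SpikeDetectionModel:
    """All intermediates of the KDE detector, exposed for inspection."""

    candidate_times: np.ndarray
    candidate_amps: np.ndarray
    corrected_amps: np.ndarray
    noise_peak_amps: np.ndarray
    grid: np.ndarray
    p_density: np.ndarray
    pnoise_density: np.ndarray
    s_density: np.ndarray
    th1: float | None
    th2: float | None
    threshold: float
    n_fp: int
    ap_template: APTemplate | None
    amplitude_mean: float = float("nan")  # A
    noise_sd: float = float("nan")  # σ
    snr: float = float("nan")
    fp_cap: int = 0


def _local_maxima(x: np.ndarray) -> np.ndarray:
    """Indices of local maxima; a plateau contributes its first sample."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 3:
        return np.array([], dtype=int)
    s = np.sign(np.diff(x)).astype(int)  # length n-1
    pos = np.arange(n - 1)
    valid = np.where(s != 0, pos, n - 1)  # n-1 = "no change" sentinel
    nxt = np.minimum.accumulate(valid[::-1])[::-1]
    has_next = nxt <= n - 2
    s_next = np.zeros(n - 1, dtype=int)
    s_next[has_next] = s[nxt[has_next]]
    i = np.arange(1, n - 1)
    mask = (s[i - 1] > 0) & (s_next[i] < 0)
    return i[mask]


def _positive_peaks(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    idx = _local_maxima(x)
    idx = idx[x[idx] > 0]
    return idx, x[idx]


def highpass_dff(dff: DffTrace, median_window_ms: float = 5.0) -> DffTrace:
    """High-pass a ΔF/F trace by subtracting a short running median."""
    from scipy import ndimage

    n = int(round(median_window_ms * 1e-3 * dff.fs))
    n = max(n, 1)
    if n % 2 == 0:
        n += 1
    hp = dff.values - ndimage.median_filter(dff.values, size=n, mode="reflect")
    return DffTrace(
        values=hp,
        fs=dff.fs,
        t0=dff.t0,
        polarity=dff.polarity,
        baseline_method=dff.baseline_method,
    )


def amplitude_correct(
    candidate_times: np.ndarray,
    candidate_amps: np.ndarray,
    ap_template: APTemplate | None,
    window_ms: float = 2.0,
) -> np.ndarray:
    """Correct candidate amplitudes shadowed by a larger nearby peak.

    Each candidate i with a strictly larger neighbor j within ±window has
    the neighbor's template contribution subtracted from its amplitude:
    ``p_i − AP(t_i − t_j)``.  When several larger neighbors qualify, the
    largest one is subtracted.  Isolated peaks and peaks whose neighbors
    are all smaller pass through unchanged.  The larger/smaller comparison
    uses the *raw* amplitudes (single pass).
    """
    t = np.asarray(candidate_times, dtype=float)
    p = np.asarray(candidate_amps, dtype=float)
    if ap_template is None or t.size < 2:
        return p.copy()
    w = window_ms * 1e-3
    corrected = p.copy()
    for i in range(t.size):
        near = np.nonzero((np.abs(t - t[i]) <= w) & (p > p[i]))[0]
        near = near[near != i]
        if near.size:
            j = near[np.argmax(p[near])]
            corrected[i] = p[i] - float(ap_template(t[i] - t[j]))
    return corrected


def spike_waveform_and_halfwidth(
    hp: DffTrace,
    spike_times_s: np.ndarray,
    win_ms: tuple[float, float] = (-2.0, 4.0),
) -> tuple[APTemplate | None, float]:
    """Mean spike waveform and its FWHM.

    Segments of the high-pass trace around each spike (peak-aligned,
    ``win_ms`` relative to the peak) are averaged; spikes whose window runs
    off either end of the trace are dropped.  The half-width is the full
    width at half of the template maximum, with the crossings located by
    linear interpolation.  Returns ``(None, nan)`` when no usable segment
    remains.
    """
    times = np.atleast_1d(np.asarray(spike_times_s, dtype=float))
    pre = int(round(-win_ms[0] * 1e-3 * hp.fs))
    post = int(round(win_ms[1] * 1e-3 * hp.fs))
    segs = []
    for t in times:
        i = int(round((t - hp.t0) * hp.fs))
        if i - pre < 0 or i + post >= hp.n_samples:
            continue
        segs.append(hp.values[i - pre: i + post + 1])
    if not segs:
        return None, float("nan")
    template = np.mean(segs, axis=0)
    lags = (np.arange(-pre, post + 1)) / hp.fs
    tpl = APTemplate(lags_s=lags, values=template)
    return tpl, _fwhm_ms(lags, template)


def _fwhm_ms(lags_s: np.ndarray, y: np.ndarray) -> float:
    """FWHM of the central peak of y, in ms, by linear interpolation."""
    k = int(np.argmax(y))
    peak = y[k]
    if peak <= 0:
        return float("nan")
    half = peak / 2.0
    left = right = None
    for i in range(k, 0, -1):
        if y[i - 1] <= half <= y[i]:
            frac = (half - y[i - 1]) / (y[i] - y[i - 1])
            left = lags_s[i - 1] + frac * (lags_s[i] - lags_s[i - 1])
            break
    for i in range(k, y.size - 1):
        if y[i + 1] <= half <= y[i]:
            frac = (y[i] - half) / (y[i] - y[i + 1])
            right = lags_s[i] + frac * (lags_s[i + 1] - lags_s[i])
            break
    if left is None or right is None:
        return float("nan")
    return float((right - left) * 1e3)


def detect_spikes_kde(
    dff: DffTrace,
    fp_rate_cap: float = 0.1,
    median_window_ms: float = 5.0,
    template_win_ms: tuple[float, float] = (-2.0, 4.0),
    grid_points: int = 512,
) -> tuple[SpikeTrain, SpikeDetectionModel]:
    """KDE-threshold spike detection on a positive-spike ΔF/F trace.

    See the module docstring for the full pipeline.  ``fp_rate_cap`` (Hz)
    bounds the tolerated false-positive rate; the absolute cap is
    ``floor(fp_rate_cap * duration)`` (18 for 0.1 Hz × 180 s).
    """
    if dff.polarity != "positive_spikes":
        raise ValueError("KDE detector expects positive_spikes polarity")
    hp = highpass_dff(dff, median_window_ms)
    duration = hp.duration
    cap = int(np.floor(fp_rate_cap * duration))

    cand_idx, cand_amps = _positive_peaks(hp.values)
    noise_idx, noise_amps = _positive_peaks(-hp.values)
    cand_times = hp.t0 + cand_idx / hp.fs

    empty = SpikeTrain(
        times=np.array([]), amplitudes=np.array([]), detector="kde"
    )
    if cand_amps.size < 5 or np.ptp(cand_amps) == 0 or noise_amps.size < 5:
        model = SpikeDetectionModel(
            candidate_times=cand_times,
            candidate_amps=cand_amps,
            corrected_amps=cand_amps.copy(),
            noise_peak_amps=noise_amps,
            grid=np.array([]),
            p_density=np.array([]),
            pnoise_density=np.array([]),
            s_density=np.array([]),
            th1=None,
            th2=None,
            threshold=float("inf"),
            n_fp=0,
            ap_template=None,
            fp_cap=cap,
        )
        return empty, model

    grid = np.linspace(0.0, cand_amps.max(), grid_points)
    p_density = stats.gaussian_kde(cand_amps, bw_method="silverman")(grid)
    pnoise_density = stats.gaussian_kde(noise_amps, bw_method="silverman")(grid)
    s_density = p_density - pnoise_density

    # th1: largest upward crossing of S(x) over Pnoise(x)
    diff = s_density - pnoise_density
    crossings = np.nonzero((diff[:-1] < 0) & (diff[1:] >= 0))[0] + 1
    th1 = float(grid[crossings[-1]]) if crossings.size else None

    def n_fp(th: float) -> int:
        return int(np.sum(noise_amps >= th))

    noise_desc = np.sort(noise_amps)[::-1]
    if noise_desc.size <= cap:
        th2 = 0.0
    else:
        th2 = float(np.nextafter(noise_desc[cap], np.inf))

    if th1 is not None and n_fp(th1) <= cap:
        threshold = th1
    else:
        threshold = max(th2, th1 if th1 is not None else 0.0)

    # initial spikes -> AP template
    init_mask = cand_amps >= threshold
    template, _ = spike_waveform_and_halfwidth(
        hp, cand_times[init_mask], template_win_ms
    )

    corrected = amplitude_correct(cand_times, cand_amps, template)
    final_mask = corrected >= threshold
    spike_times = cand_times[final_mask]
    spike_amps = corrected[final_mask]

    amplitude_mean = float(np.mean(spike_amps)) if spike_amps.size else float("nan")
    try:
        sigma = estimate_noise_spike_excluded(hp, spike_times)
    except ValueError:
        sigma = float("nan")
    snr = amplitude_mean / sigma if sigma and np.isfinite(sigma) else float("nan")

    train = SpikeTrain(
        times=spike_times,
        amplitudes=spike_amps,
        detector="kde",
        threshold=threshold,
    )
    model = SpikeDetectionModel(
        candidate_times=cand_times,
        candidate_amps=cand_amps,
        corrected_amps=corrected,
        noise_peak_amps=noise_amps,
        grid=grid,
        p_density=p_density,
        pnoise_density=pnoise_density,
        s_density=s_density,
        th1=th1,
        th2=th2,
        threshold=threshold,
        n_fp=n_fp(threshold),
        ap_template=template,
        amplitude_mean=amplitude_mean,
        noise_sd=sigma,
        snr=snr,
        fp_cap=cap,
    )
    return train, model


def detect_spikes_fixed_threshold(
    dff_aps: DffTrace, sd_noise: float, k: float = 4.0
) -> SpikeTrain:
    """Fixed-threshold detector: THR = −k·SDnoise on a negative-spike trace.

    Samples strictly below the threshold are grouped into consecutive runs;
    each run produces one spike at its most negative sample (doublet rule:
    adjacent crossings merge, the larger-amplitude time point wins).
    """
    if dff_aps.polarity != "negative_spikes":
        raise ValueError("fixed-threshold detector expects negative_spikes polarity")
    if not sd_noise > 0:
        raise ValueError("sd_noise must be positive")
    thr = -k * sd_noise
    below = dff_aps.values < thr
    if not below.any():
        return SpikeTrain(
            times=np.array([]), amplitudes=np.array([]),
            detector="fixed_threshold", threshold=thr,
        )
    edges = np.diff(below.astype(int))
    starts = np.nonzero(edges == 1)[0] + 1
    ends = np.nonzero(edges == -1)[0] + 1
    if below[0]:
        starts = np.concatenate(([0], starts))
    if below[-1]:
        ends = np.concatenate((ends, [below.size]))
    idx = np.array(
        [s + int(np.argmin(dff_aps.values[s:e])) for s, e in zip(starts, ends)]
    )
    return SpikeTrain(
        times=dff_aps.t0 + idx / dff_aps.fs,
        amplitudes=-dff_aps.values[idx],
        detector="fixed_threshold",
        threshold=thr,
    )


def snr_cell(amplitude_mean: float, noise_sd: float) -> float:
    """Cell SNR = mean spike amplitude A over noise SD σ."""
    if not noise_sd > 0:
        raise ValueError("noise SD must be positive")
    return amplitude_mean / noise_sd


# QC threshold profiles.  The hippocampal profile applies all four gates
# with strict comparisons; the ALM profile keeps only an SNR >= 3 gate.
QC_PROFILES = {
    "hippocampus": dict(
        snr_min_exclusive=5.0,
        n_spikes_min_exclusive=90,
        max_frac_isi_below_2ms=0.01,
        halfwidth_max_ms=0.85,
    ),
    "alm": dict(snr_min_inclusive=3.0),
}


@dataclass
class CellQCReport:
    snr: float
    n_spikes: int
    frac_isi_below_2ms: float
    halfwidth_ms: float
    criteria: dict = field(default_factory=dict)
    passed: bool = False
    profile: str = "hippocampus"


def cell_qc(
    snr: float,
    spike_train: SpikeTrain,
    halfwidth_ms: float,
    duration_s: float,
    profile: str = "hippocampus",
) -> CellQCReport:
    """Per-cell inclusion gates on SNR, spike count, ISI violations, width.

    Hippocampal profile: SNR must *exceed* 5; the number of detected spikes
    must *exceed* 90 (a 0.5 Hz rate over 180 s); fewer than 1% of ISIs may
    fall below 2 ms; the spike half-width must be shorter than 0.85 ms.
    ALM profile: SNR ≥ 3 is the only numeric gate.
    """
    if profile not in QC_PROFILES:
        raise ValueError(f"unknown QC profile {profile!r}")
    n = spike_train.n_spikes
    if n >= 2:
        isi = np.diff(spike_train.times)
        frac_short = float(np.mean(isi < 2e-3))
    else:
        frac_short = 0.0
    rules = QC_PROFILES[profile]
    criteria: dict[str, bool] = {}
    if "snr_min_exclusive" in rules:
        criteria["snr"] = snr > rules["snr_min_exclusive"]
    if "snr_min_inclusive" in rules:
        criteria["snr"] = snr >= rules["snr_min_inclusive"]
    if "n_spikes_min_exclusive" in rules:
        criteria["n_spikes"] = n > rules["n_spikes_min_exclusive"]
    if "max_frac_isi_below_2ms" in rules:
        criteria["isi"] = frac_short < rules["max_frac_isi_below_2ms"]
    if "halfwidth_max_ms" in rules:
        criteria["halfwidth"] = halfwidth_ms < rules["halfwidth_max_ms"]
    return CellQCReport(
        snr=snr,
        n_spikes=n,
        frac_isi_below_2ms=frac_short,
        halfwidth_ms=halfwidth_ms,
        criteria=criteria,
        passed=all(criteria.values()),
        profile=profile,
    )


def spike_amplitude_trough_to_peak(
    dff: DffTrace,
    spike_train: SpikeTrain,
    max_prev_isi_ms: float = 20.0,
) -> np.ndarray:
    """Trough-to-peak amplitudes of closely preceded spikes.

    Only spikes that occur less than ``max_prev_isi_ms`` after the previous
    spike qualify; each amplitude is the ΔF/F at the spike peak minus the
    trough between the spike and its predecessor.  The trace is oriented so
    that spikes are positive regardless of the declared polarity.
    """
    x = dff.values if dff.polarity == "positive_spikes" else -dff.values
    t = spike_train.times
    if t.size < 2:
        return np.array([])
    amps = []
    for k in range(1, t.size):
        if (t[k] - t[k - 1]) * 1e3 >= max_prev_isi_ms:
            continue
        i_prev = int(round((t[k - 1] - dff.t0) * dff.fs))
        i_cur = int(round((t[k] - dff.t0) * dff.fs))
        i_prev = np.clip(i_prev, 0, dff.n_samples - 1)
        i_cur = np.clip(i_cur, 0, dff.n_samples - 1)
        if i_cur <= i_prev:
            continue
        trough = float(np.min(x[i_prev: i_cur + 1]))
        amps.append(float(x[i_cur]) - trough)
    return np.asarray(amps)


def snr_high_frequency(trace: DffTrace, spike_train: SpikeTrain) -> float:
    """Mean spike value over the RMS deviation of the trace from its median.

    The denominator is the root-mean-square of (x − median(x)), a robust
    stand-in for the high-frequency noise scale; the trace is oriented so
    spikes are positive.  Infinity is returned (and should be flagged by
    callers) when the trace is flat outside the spikes.
    """
    if spike_train.n_spikes == 0:
        raise ValueError("at least one spike required")
    x = trace.values if trace.polarity == "positive_spikes" else -trace.values
    idx = np.round((spike_train.times - trace.t0) * trace.fs).astype(int)
    idx = np.clip(idx, 0, trace.n_samples - 1)
    num = float(np.mean(x[idx]))
    denom = float(np.sqrt(np.mean((x - np.median(x)) ** 2)))
    if denom == 0:
        return float("inf")
    return num / denom
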