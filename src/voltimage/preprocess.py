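"""Baseline correction, ΔF/F detrending, and noise estimation.

Raw traces from pixel time series or ROI means are converted into ΔF/F under
one of three detrending conventions used for different preparations:

``moving_avg_1s_inverted``
    baseline F0 is a 1-s moving average and ΔF/F = −(F − F0)/F0, so the
    negative-going sensor transients come out *positive* (used upstream of
    the KDE spike detector);
``median_5s`` / ``median_20ms`` / ``median_50ms``
    baseline B is a running median and ΔF/F = (F − B)/B, preserving the
    native negative spike polarity.

Two noise estimators are provided: a sign-symmetrization scheme that assumes
all spikes are negative, and a spike-excluded standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage, optimize

from .traces import DffTrace, Trace

__all__ = [
    "BleachFit",
    "fit_bleach_exponential",
    "subtract_bleach",
    "background_estimate",
    "roi_trace",
    "dff_detrend",
    "estimate_noise_sign_symmetrized",
    "estimate_noise_spike_excluded",
]


@dataclass
class BleachFit:
    """Single-exponential photobleach model ``p1 * exp(-t * p2)``.

    ``p2`` is a per-second decay rate (time measured in seconds from the
    first frame).  ``baseline_at_t0`` is the fitted value at the first
    frame, used as the baseline fluorescence of the pixel or ROI.
    """

    p1: float
    p2: float
    baseline_at_t0: float
    fs: float
    n_samples: int

    def evaluate(self, n_samples: int | None = None) -> np.ndarray:
        """Evaluate the fitted curve on the original sample grid."""
        n = self.n_samples if n_samples is None else n_samples
        t = np.arange(n) / self.fs
        return self.p1 * np.exp(-t * self.p2)


def _exclusion_mask(n: int, exclude_windows: Sequence[tuple[int, int]]) -> np.ndarray:
    """Boolean mask of retained samples; windows are half-open [start, end)."""
    keep = np.ones(n, dtype=bool)
    for start, end in exclude_windows:
        keep[max(0, int(start)): max(0, int(end))] = False
    return keep


def fit_bleach_exponential(
    trace: Trace,
    exclude_windows: Sequence[tuple[int, int]] = (),
) -> BleachFit:
    """Fit a decaying exponential ``p1*exp(-t*p2)`` to a fluorescence trace.

    Samples inside ``exclude_windows`` (half-open sample intervals, e.g.
    frames following each stimulus pulse) do not contribute to the fit.
    The fit is nonlinear least squares with a log-linear initialization;
    the value of the fitted curve at frame 0 is the baseline fluorescence.

    Raises
    ------
    ValueError
        If fewer than 10 samples remain outside the exclusion windows.
    """
    keep = _exclusion_mask(trace.n_samples, exclude_windows)
    if keep.sum() < 10:
        raise ValueError("fewer than 10 samples outside exclusion windows")
    t = np.arange(trace.n_samples)[keep] / trace.fs
    y = trace.values[keep]

    # log-linear init; robust to non-positive samples via a floor
    ypos = np.maximum(y, max(1e-12, 1e-6 * max(abs(y).max(), 1.0)))
    slope, intercept = np.polyfit(t, np.log(ypos), 1)
    p0 = (float(np.exp(intercept)), float(max(-slope, 0.0)))

    def model(tt, p1, p2):
        return p1 * np.exp(-tt * p2)

    try:
        popt, _ = optimize.curve_fit(model, t, y, p0=p0, maxfev=10000)
        p1, p2 = float(popt[0]), float(popt[1])
    except RuntimeError:
        p1, p2 = p0
    return BleachFit(
        p1=p1, p2=p2, baseline_at_t0=p1, fs=trace.fs, n_samples=trace.n_samples
    )


def subtract_bleach(trace: Trace, fit: BleachFit) -> Trace:
    """Subtract a fitted bleach curve from a trace (not idempotent).

    The returned residual still carries the trace's original units; applying
    the subtraction twice removes the curve twice.
    """
    if fit.n_samples != trace.n_samples:
        raise ValueError("bleach fit computed on a different trace length")
    return Trace(
        values=trace.values - fit.evaluate(),
        fs=trace.fs,
        t0=trace.t0,
        units=trace.units,
    )


def background_estimate(pixel_baselines: np.ndarray) -> float:
    """Background fluorescence: 1st percentile of per-pixel baselines.

    ``pixel_baselines`` holds one ``baseline_at_t0`` value per pixel (any
    shape).  The percentile uses linear interpolation.
    """
    vals = np.asarray(pixel_baselines, dtype=float).ravel()
    if vals.size == 0:
        raise ValueError("no pixel baselines supplied")
    return float(np.percentile(vals, 1.0))


def roi_trace(
    movie: np.ndarray,
    roi: np.ndarray,
    neuropil_roi: np.ndarray | None = None,
    fs: float = 1.0,
) -> Trace:
    """Per-frame mean over an ROI, optionally neuropil-subtracted.

    ``movie`` is (frames, H, W); ``roi`` and ``neuropil_roi`` are boolean
    masks of shape (H, W).  When a neuropil mask is given, its per-frame
    mean is subtracted from the cell ROI mean.
    """
    movie = np.asarray(movie, dtype=float)
    if movie.ndim != 3:
        raise ValueError("movie must be (frames, H, W)")
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != movie.shape[1:]:
        raise ValueError("roi shape does not match frame shape")
    if not roi.any():
        raise ValueError("empty ROI")
    vals = movie[:, roi].mean(axis=1)
    if neuropil_roi is not None:
        neuropil_roi = np.asarray(neuropil_roi, dtype=bool)
        if neuropil_roi.shape != movie.shape[1:]:
            raise ValueError("neuropil ROI shape does not match frame shape")
        if (roi & neuropil_roi).any():
            raise ValueError("cell and neuropil ROIs overlap")
        vals = vals - movie[:, neuropil_roi].mean(axis=1)
    return Trace(values=vals, fs=fs)


def _odd_window_samples(window_s: float, fs: float) -> int:
    """Convert a window length in seconds to an odd sample count (≥1)."""
    n = int(round(window_s * fs))
    n = max(n, 1)
    if n % 2 == 0:
        n += 1
    return n


_METHOD_WINDOWS_S = {
    "moving_avg_1s_inverted": 1.0,
    "median_5s": 5.0,
    "median_20ms": 0.020,
    "median_50ms": 0.050,
}


def dff_detrend(
    trace: Trace,
    method: str = "median_5s",
    window_s: float | None = None,
) -> DffTrace:
    """Detrend a raw trace to ΔF/F under a named baseline convention.

    ``moving_avg_1s_inverted`` computes F0 as a moving average and returns
    ΔF/F = −(F − F0)/F0 (positive spikes); the ``median_*`` methods use a
    running median B and return (F − B)/B (negative spikes).  Window lengths
    are converted to odd sample counts; edges use reflect padding.
    ``window_s`` overrides the method's default window.
    """
    if method not in _METHOD_WINDOWS_S:
        raise ValueError(f"unknown detrend method {method!r}")
    w = _METHOD_WINDOWS_S[method] if window_s is None else float(window_s)
    if w <= 0:
        raise ValueError("window must be positive")
    if w >= trace.duration:
        raise ValueError("window must be shorter than the trace")
    n = _odd_window_samples(w, trace.fs)

    if method == "moving_avg_1s_inverted":
        baseline = ndimage.uniform_filter1d(trace.values, size=n, mode="reflect")
        dff = -(trace.values - baseline) / baseline
        polarity = "positive_spikes"
    else:
        baseline = ndimage.median_filter(trace.values, size=n, mode="reflect")
        dff = (trace.values - baseline) / baseline
        polarity = "negative_spikes"
    return DffTrace(
        values=dff,
        fs=trace.fs,
        t0=trace.t0,
        polarity=polarity,
        baseline_method=method,
    )


def estimate_noise_sign_symmetrized(
    dff_aps: DffTrace, seed: int | np.random.Generator = 0
) -> float:
    """Noise SD by sign symmetrization of the non-negative samples.

    Assumes all spikes are negative-going (``negative_spikes`` polarity):
    negative samples are discarded, random ± signs are assigned to the rest
    (zeros included), and the SD of the resulting sample is returned.
    Deterministic for a fixed seed.
    """
    if dff_aps.polarity != "negative_spikes":
        raise ValueError(
            "sign-symmetrized noise estimation requires negative_spikes polarity"
        )
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    pos = dff_aps.values[dff_aps.values >= 0.0]
    if pos.size == 0:
        return float("nan")
    if np.ptp(pos) == 0.0:
        # degenerate: a constant retained sample carries no noise information
        return 0.0
    signs = rng.choice([-1.0, 1.0], size=pos.size)
    return float(np.std(signs * pos))


def estimate_noise_spike_excluded(
    hp: DffTrace,
    spike_times_s: np.ndarray,
    pre_ms: float = 2.0,
    post_ms: float = 4.0,
) -> float:
    """SD of a trace excluding a window around each detected spike.

    A window from ``pre_ms`` before to ``post_ms`` after each spike is
    removed (overlapping windows merge naturally through the boolean mask);
    the SD of the retained samples is returned.
    """
    keep = np.ones(hp.n_samples, dtype=bool)
    pre = int(round(pre_ms * 1e-3 * hp.fs))
    post = int(round(post_ms * 1e-3 * hp.fs))
    for t in np.atleast_1d(np.asarray(spike_times_s, dtype=float)):
        i = int(round((t - hp.t0) * hp.fs))
        keep[max(0, i - pre): min(hp.n_samples, i + post + 1)] = False
    if not keep.any():
        raise ValueError("no samples retained after spike exclusion")
    return float(np.std(hp.values[keep]))
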