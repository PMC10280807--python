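"""Field-stimulation plate-screen analytics.

The screen evokes action potentials by field stimulation (8 pulses at
8.3 Hz, imaged at ~1.5 kHz) while recording small movies per well.  The
pipeline per movie: per-pixel photobleach correction; pulse-aligned
averaging; per-pixel Mann–Whitney responsiveness tests; pooling of
responsive-pixel ΔF/F0 across wells; a rising×decaying exponential fit to
the averaged response; control normalization by ratio of pool medians; and
plate-level quality control built on a bootstrap statistic (PDI — percent
detectable improvement) that quantifies the smallest sensitivity
improvement distinguishable from the variability of the in-plate controls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .preprocess import fit_bleach_exponential
from .traces import Trace

__all__ = [
    "StimProtocol",
    "ResponseFit",
    "QCReport",
    "PlateScreenResult",
    "movie_dff",
    "detect_responsive_pixels",
    "average_stim_response",
    "fit_response_kernel",
    "pdi",
    "plate_qc",
    "normalize_to_control",
]


@dataclass
class StimProtocol:
    """Field-stimulation timing: pulse times and camera frame rate."""

    pulse_times: np.ndarray  # s
    frame_rate: float = 1497.0  # Hz
    pulse_rate: float = 8.3  # Hz

    def __post_init__(self) -> None:
        self.pulse_times = np.asarray(self.pulse_times, dtype=float)
        if np.any(np.diff(self.pulse_times) < 0):
            raise ValueError("pulse times must be sorted")
        if not self.frame_rate > 2 * self.pulse_rate:
            raise ValueError("frame rate must exceed twice the pulse rate")

    @classmethod
    def default(cls, n_pulses: int = 8, pulse_rate: float = 8.3,
                frame_rate: float = 1497.0, first_pulse_s: float = 0.15
                ) -> "StimProtocol":
        return cls(
            pulse_times=first_pulse_s + np.arange(n_pulses) / pulse_rate,
            frame_rate=frame_rate, pulse_rate=pulse_rate,
        )

    def pulse_frames(self) -> np.ndarray:
        return np.round(self.pulse_times * self.frame_rate).astype(int)


@dataclass
class ResponseFit:
    """Rising×decaying exponential fit of the averaged pulse response."""

    amplitude: float
    tau_on_ms: float
    tau_off_ms: float
    dffmax: float  # signed extremum of the fitted curve, percent
    fit_rmse: float
    converged: bool = True


@dataclass
class QCReport:
    control_mean_abs_dff_pct: float
    pdi_pct: float
    n_responsive_pixels: int
    criteria: dict = field(default_factory=dict)
    passed: bool = False


@dataclass
class PlateScreenResult:
    """Pooled per-construct screen statistics for one plate."""

    responsive_pixel_counts: dict[str, int]  # per well
    construct_pixel_pools: dict[str, np.ndarray]  # |ΔF/F0| fractions
    control_construct: str = "control"
    pdi_pct: float = float("nan")
    normalized_ratio: dict[str, float] = field(default_factory=dict)
    mannwhitney_p: dict[str, float] = field(default_factory=dict)
    qc: QCReport | None = None


def movie_dff(
    movie: np.ndarray,
    protocol: StimProtocol,
    exclude_post_ms: float = 50.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Bleach-correct a movie pixelwise and convert it to ΔF/F0.

    A single decaying exponential is fit to each pixel's time series,
    excluding the frames following each stimulus pulse (``exclude_post_ms``
    after each pulse, when the response nominally occurs), and subtracted.
    The fitted value at the first frame is the pixel's baseline F0, and
    ΔF/F0 = residual / F0.  Returns (dff movie, per-pixel baseline map).
    """
    n_frames, h, w = movie.shape
    fs = protocol.frame_rate
    post = int(round(exclude_post_ms * 1e-3 * fs))
    windows = [(f, f + post) for f in protocol.pulse_frames()]
    dff = np.empty_like(movie, dtype=float)
    baseline = np.empty((h, w))
    for r in range(h):
        for c in range(w):
            tr = Trace(values=movie[:, r, c].astype(float), fs=fs)
            fit = fit_bleach_exponential(tr, windows)
            f0 = fit.baseline_at_t0
            dff[:, r, c] = (tr.values - fit.evaluate()) / f0
            baseline[r, c] = f0
    return dff, baseline


def average_stim_response(
    dff: np.ndarray,
    protocol: StimProtocol,
    pre_ms: float = 20.0,
    post_ms: float = 60.0,
) -> tuple[np.ndarray, int]:
    """Pulse-aligned mean response.

    ``dff`` is (frames, ...) — a trace or a movie.  Segments from
    ``pre_ms`` before to ``post_ms`` after each pulse frame are averaged
    across pulses.  Returns (avg segment, index of the pulse frame within
    the segment).  Pulses whose window leaves the record raise an error.
    """
    fs = protocol.frame_rate
    pre = int(round(pre_ms * 1e-3 * fs))
    post = int(round(post_ms * 1e-3 * fs))
    frames = protocol.pulse_frames()
    if frames.size == 0:
        raise ValueError("protocol has no pulses")
    segs = []
    for f in frames:
        if f - pre < 0 or f + post >= dff.shape[0]:
            raise ValueError("pulse window outside the recording")
        segs.append(dff[f - pre: f + post + 1])
    return np.mean(segs, axis=0), pre


def detect_responsive_pixels(
    movie_dff_arr: np.ndarray,
    protocol: StimProtocol,
    pre_ms: float = 20.0,
    post_ms: tuple[float, ...] = (10.0, 20.0, 40.0),
    alpha: float = 1e-3,
) -> tuple[np.ndarray, np.ndarray]:
    """Mann–Whitney responsiveness test per pixel on the averaged response.

    For each pixel, the ``pre_ms`` frames preceding the pulse in the
    pulse-averaged response are compared with the first 10, 20 and 40 ms of
    frames following it (two-sided rank-sum).  A pixel is responsive iff
    any of the three tests gives p < ``alpha``.  Returns (boolean mask,
    per-pixel minimum p).
    """
    fs = protocol.frame_rate
    avg, onset = average_stim_response(
        movie_dff_arr, protocol, pre_ms=pre_ms, post_ms=max(post_ms) + 5.0
    )
    h, w = avg.shape[1:]
    min_p = np.ones((h, w))
    pre_block = avg[:onset]
    for pm in post_ms:
        n_post = int(round(pm * 1e-3 * fs))
        post_block = avg[onset + 1: onset + 1 + n_post]
        for r in range(h):
            for c in range(w):
                pre_v = pre_block[:, r, c]
                post_v = post_block[:, r, c]
                if np.ptp(pre_v) == 0 and np.ptp(post_v) == 0 \
                        and pre_v[0] == post_v[0]:
                    continue  # identical constant samples: no evidence
                _, p = stats.mannwhitneyu(pre_v, post_v,
                                          alternative="two-sided")
                if p < min_p[r, c]:
                    min_p[r, c] = p
    return min_p < alpha, min_p


def fit_response_kernel(
    avg: np.ndarray,
    fs: float,
    onset_frame: int,
) -> ResponseFit:
    """Fit y(t) = A·(1−e^(−t/τon))·e^(−t/τoff) to an averaged response.

    ``onset_frame`` (from the stimulus record, not detected from data)
    marks t = 0.  A may be negative for negative-going responses.
    ``dffmax`` is the signed extremum of the fitted curve in percent,
    reached at t* = τon·ln(1 + τoff/τon).
    """
    y = np.asarray(avg, dtype=float)[onset_frame:]
    t = np.arange(y.size) / fs

    def model(tt, a, ton, toff):
        return a * (1.0 - np.exp(-tt / ton)) * np.exp(-tt / toff)

    peak = y[np.argmax(np.abs(y))]
    p0 = (peak * 1.5, 1e-3, 10e-3)
    try:
        popt, _ = optimize.curve_fit(
            model, t, y, p0=p0,
            bounds=([-np.inf, 1e-6, 1e-6], [np.inf, 1.0, 10.0]),
            maxfev=20000,
        )
        a, ton, toff = popt
        converged = True
    except RuntimeError:
        a, ton, toff = p0
        converged = False
    t_star = ton * np.log1p(toff / ton)
    dffmax = model(np.array([t_star]), a, ton, toff)[0]
    rmse = float(np.sqrt(np.mean((model(t, a, ton, toff) - y) ** 2)))
    return ResponseFit(
        amplitude=float(a), tau_on_ms=float(ton * 1e3),
        tau_off_ms=float(toff * 1e3), dffmax=float(dffmax * 100.0),
        fit_rmse=rmse, converged=converged,
    )


def pdi(
    control_pixel_dffs: np.ndarray,
    n_boot: int = 10000,
    seed: int | np.random.Generator = 0,
    quantile_of: str = "means",
) -> float:
    """Percent detectable improvement of a plate's control pixel pool.

    PDI = 100·(mean(x) − q01)/mean(x) on the |ΔF/F0| values x of control
    pixels, where q01 is the 1st percentile of the bootstrap distribution:
    of resample *means* by default (``quantile_of="means"``), or of the
    pooled resampled *values* (``quantile_of="values"``).  Deterministic
    for a fixed seed; scale-invariant.
    """
    x = np.abs(np.asarray(control_pixel_dffs, dtype=float).ravel())
    if x.size < 2:
        raise ValueError("need at least two control pixel values")
    m = x.mean()
    if m == 0:
        raise ValueError("PDI undefined for zero-mean control pool")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    idx = rng.integers(0, x.size, size=(n_boot, x.size))
    if quantile_of == "means":
        sample = x[idx].mean(axis=1)
    elif quantile_of == "values":
        sample = x[idx].ravel()
    else:
        raise ValueError("quantile_of must be 'means' or 'values'")
    q01 = np.quantile(sample, 0.01)
    return float(100.0 * (m - q01) / m)


def plate_qc(
    result: PlateScreenResult,
    construct: str,
    min_responsive_per_well: int = 4,
    control_min_abs_dff_pct: float = 3.6,
    pdi_max_pct: float = 30.0,
    min_responsive_pixels: int = 100,
) -> QCReport:
    """Plate- and construct-level QC gates (strict comparisons as printed).

    Fails if the mean |ΔF/F0| of the in-plate controls is < 3.6%, if the
    plate PDI is > 30%, or if the construct has < 100 responsive pixels.
    Wells with fewer than ``min_responsive_per_well`` responsive pixels are
    assumed to have been discarded before pooling (see
    ``responsive_pixel_counts``).
    """
    control_pool = result.construct_pixel_pools[result.control_construct]
    control_mean_pct = 100.0 * float(np.mean(np.abs(control_pool)))
    n_resp = int(result.construct_pixel_pools[construct].size)
    criteria = {
        "control_mean": not (control_mean_pct < control_min_abs_dff_pct),
        "pdi": not (result.pdi_pct > pdi_max_pct),
        "responsive_pixels": not (n_resp < min_responsive_pixels),
    }
    return QCReport(
        control_mean_abs_dff_pct=control_mean_pct,
        pdi_pct=result.pdi_pct,
        n_responsive_pixels=n_resp,
        criteria=criteria,
        passed=all(criteria.values()),
    )


def discard_unresponsive_wells(
    well_counts: dict[str, int], min_pixels: int = 4
) -> list[str]:
    """Wells with fewer than ``min_pixels`` responsive pixels are dropped."""
    return [w for w, n in well_counts.items() if n >= min_pixels]


def normalize_to_control(
    variant_pixels: np.ndarray,
    control_pixels: np.ndarray,
) -> tuple[float, float]:
    """Control normalization: ratio of pool medians plus rank-sum p value.

    Both pools are |ΔF/F0| values of responsive pixels pooled across
    wells.  The ratio is median(variant)/median(control); significance is
    a two-sided Mann–Whitney U test (exact for pools of ≤20 without ties,
    normal approximation with tie correction otherwise).
    """
    v = np.abs(np.asarray(variant_pixels, dtype=float).ravel())
    c = np.abs(np.asarray(control_pixels, dtype=float).ravel())
    if v.size == 0 or c.size == 0:
        raise ValueError("both pixel pools must be non-empty")
    ratio = float(np.median(v) / np.median(c))
    method = "exact" if (v.size <= 20 and c.size <= 20
                         and np.unique(np.concatenate([v, c])).size
                         == v.size + c.size) else "asymptotic"
    _, p = stats.mannwhitneyu(v, c, alternative="two-sided", method=method)
    return ratio, float(p)
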