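"""Spike-synchrony and subthreshold co-depolarization statistics.

For pairs of simultaneously imaged cells: spike cross-correlograms (CCG)
with FWHM of the central peak; the fraction of spikes falling within ±5 ms
of a partner spike (against a random-shuffle control); a synchrony-strength
ratio comparing coincidence rates in a synchronous window (|Δt| ≤ 1.5 ms)
to a nearby control window (15–25 ms); spike-triggered average subthreshold
depolarization of a target cell around reference spikes (excluding epochs
where the target itself spikes); and the per-target correlation between
synchrony and co-depolarization across reference cells, with a
distance-matched different-reference control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .population import PopulationRecording
from .spikes import SpikeTrain
from .traces import DffTrace

__all__ = [
    "CCGResult",
    "PairStats",
    "ccg",
    "fraction_synchronous",
    "synchrony_strength",
    "co_depolarization",
    "synchrony_codep_correlation",
]


@dataclass
class CCGResult:
    lags_ms: np.ndarray  # bin centers
    counts: np.ndarray
    rate: np.ndarray  # counts / (n_ref · bin width s)
    fwhm_ms: float  # nan when no central peak stands above baseline
    baseline: float


def _pair_lags(a: np.ndarray, b: np.ndarray, maxlag_s: float) -> np.ndarray:
    """All lags t_b − t_a within ±maxlag (sorted inputs, two pointers)."""
    lags = []
    j0 = 0
    for ta in a:
        while j0 < b.size and b[j0] < ta - maxlag_s:
            j0 += 1
        j = j0
        while j < b.size and b[j] <= ta + maxlag_s:
            lags.append(b[j] - ta)
            j += 1
    return np.asarray(lags)


def ccg(
    spikes_a: SpikeTrain,
    spikes_b: SpikeTrain,
    bin_ms: float = 0.5,
    maxlag_ms: float = 50.0,
    baseline_window_ms: tuple[float, float] = (15.0, 25.0),
) -> CCGResult:
    """Spike cross-correlogram of two trains.

    Histogram of all pairwise lags t_b − t_a within ±maxlag on a symmetric
    bin grid.  The FWHM of the central peak is computed after subtracting
    a baseline (mean count in the |lag| ∈ [15, 25] ms band) and located by
    linear interpolation; it is NaN when the central bin does not rise
    above baseline (flat CCG).
    """
    if spikes_a.n_spikes == 0 or spikes_b.n_spikes == 0:
        raise ValueError("both spike trains must be non-empty")
    maxlag = maxlag_ms * 1e-3
    nbins = int(round(2 * maxlag_ms / bin_ms))
    if nbins % 2 == 0:
        nbins += 1  # symmetric grid with a bin centered on zero lag
    edges = np.linspace(-maxlag, maxlag, nbins + 1)
    lags = _pair_lags(spikes_a.times, spikes_b.times, maxlag)
    counts, _ = np.histogram(lags, bins=edges)
    centers = 1e3 * 0.5 * (edges[:-1] + edges[1:])
    rate = counts / (spikes_a.n_spikes * (edges[1] - edges[0]))

    lo, hi = baseline_window_ms
    base_mask = (np.abs(centers) >= lo) & (np.abs(centers) <= hi)
    baseline = float(counts[base_mask].mean()) if base_mask.any() else 0.0
    y = counts.astype(float) - baseline
    k = int(np.argmin(np.abs(centers)))
    # climb to the top of the central peak
    while 0 < k < y.size - 1 and (y[k + 1] > y[k] or y[k - 1] > y[k]):
        k = k + 1 if y[k + 1] >= y[k - 1] else k - 1
    fwhm = float("nan")
    # the central peak must stand above Poisson counting noise of the
    # baseline, otherwise the CCG is flat and the width is undefined
    significant = y[k] > 3.0 * np.sqrt(max(baseline, 1.0))
    if y[k] > 0 and significant:
        half = y[k] / 2.0
        left = right = None
        for i in range(k, 0, -1):
            if y[i - 1] <= half <= y[i]:
                frac = (half - y[i - 1]) / (y[i] - y[i - 1])
                left = centers[i - 1] + frac * (centers[i] - centers[i - 1])
                break
        for i in range(k, y.size - 1):
            if y[i + 1] <= half <= y[i]:
                frac = (y[i] - half) / (y[i] - y[i + 1])
                right = centers[i] + frac * (centers[i + 1] - centers[i])
                break
        if left is not None and right is not None:
            fwhm = float(right - left)
        else:
            fwhm = float("nan")
    return CCGResult(lags_ms=centers, counts=counts, rate=rate,
                     fwhm_ms=fwhm, baseline=baseline)


def _frac_with_partner(a: np.ndarray, b: np.ndarray, w: float) -> float:
    """Fraction of pooled spikes with a partner in the other train within ±w."""
    def has_partner(x, y):
        idx = np.searchsorted(y, x)
        ok = np.zeros(x.size, dtype=bool)
        left = idx > 0
        ok[left] = (x[left] - y[idx[left] - 1]) <= w
        right = idx < y.size
        ok[right] |= (y[idx[right]] - x[right]) <= w
        return ok
    n_hit = has_partner(a, b).sum() + has_partner(b, a).sum()
    return float(n_hit / (a.size + b.size))


def fraction_synchronous(
    spikes_a: SpikeTrain,
    spikes_b: SpikeTrain,
    duration_s: float,
    window_ms: float = 5.0,
    n_shuffles: int = 20,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Fraction of spikes (pooled) within ±window of a partner spike.

    The shuffle control redraws each train's spike times uniformly over
    [0, duration] (preserving counts) and averages the same statistic over
    ``n_shuffles`` draws.  Returns (observed %, shuffled %).  Symmetric in
    its two arguments.
    """
    if spikes_a.n_spikes == 0 or spikes_b.n_spikes == 0:
        raise ValueError("both spike trains must be non-empty")
    w = window_ms * 1e-3
    obs = 100.0 * _frac_with_partner(spikes_a.times, spikes_b.times, w)
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    shuf = []
    for _ in range(n_shuffles):
        sa = np.sort(rng.uniform(0, duration_s, spikes_a.n_spikes))
        sb = np.sort(rng.uniform(0, duration_s, spikes_b.n_spikes))
        shuf.append(_frac_with_partner(sa, sb, w))
    return obs, 100.0 * float(np.mean(shuf))


def synchrony_strength(
    spikes_ref: SpikeTrain,
    spikes_target: SpikeTrain,
    sync_window_ms: float = 1.5,
    control_window_ms: tuple[float, float] = (15.0, 25.0),
    mode: str = "ratio",
) -> float:
    """Coincidence-rate ratio between a synchronous and a control period.

    Numerator: mean per-ms pairwise-lag count with |Δt| ≤ ``sync_window``.
    Denominator: mean per-ms count with |Δt| in the control band (both
    sides pooled).  ``mode="difference"`` returns the difference of the
    two per-ms rates instead of their ratio.  NaN when the control band is
    empty.
    """
    if spikes_ref.n_spikes == 0 or spikes_target.n_spikes == 0:
        raise ValueError("both spike trains must be non-empty")
    lo, hi = control_window_ms
    lags_ms = 1e3 * _pair_lags(spikes_ref.times, spikes_target.times,
                               hi * 1e-3)
    if lags_ms.size == 0:
        return float("nan")
    n_sync = np.sum(np.abs(lags_ms) <= sync_window_ms)
    n_ctrl = np.sum((np.abs(lags_ms) >= lo) & (np.abs(lags_ms) <= hi))
    rate_sync = n_sync / (2.0 * sync_window_ms)
    rate_ctrl = n_ctrl / (2.0 * (hi - lo))
    if mode == "ratio":
        return float(rate_sync / rate_ctrl) if rate_ctrl > 0 else float("nan")
    if mode == "difference":
        return float(rate_sync - rate_ctrl)
    raise ValueError("mode must be 'ratio' or 'difference'")


@dataclass
class CoDepResult:
    lags_s: np.ndarray
    avg_trace: np.ndarray
    codep_size_pct: float
    n_segments: int
    low_confidence: bool


def co_depolarization(
    target_dff: DffTrace,
    target_spikes: SpikeTrain,
    ref_spikes: SpikeTrain,
    exclusion_ms: float = 10.0,
    win_ms: tuple[float, float] = (-50.0, 50.0),
    baseline_ms: tuple[float, float] = (-50.0, -30.0),
    min_segments: int = 10,
) -> CoDepResult:
    """Spike-triggered average subthreshold depolarization of a target cell.

    Segments of the target ΔF/F around each reference spike are averaged,
    keeping only reference spikes with no target spike within
    ±``exclusion_ms`` (to stay clear of membrane nonlinearity near the
    target's own APs) and whose window fits inside the record.  The mean
    over ``baseline_ms`` is subtracted; the co-depolarization size is the
    peak of the averaged trace within ±10 ms of lag 0, in ΔF/F percent
    (depolarization-positive, following the trace's polarity).  Results
    from fewer than ``min_segments`` usable segments are flagged.
    """
    fs = target_dff.fs
    pre = int(round(-win_ms[0] * 1e-3 * fs))
    post = int(round(win_ms[1] * 1e-3 * fs))
    excl = exclusion_ms * 1e-3
    x = (target_dff.values if target_dff.polarity == "positive_spikes"
         else -target_dff.values)
    segs = []
    tt = target_spikes.times
    for tr in ref_spikes.times:
        if tt.size:
            j = np.searchsorted(tt, tr)
            near = False
            if j > 0 and tr - tt[j - 1] <= excl:
                near = True
            if j < tt.size and tt[j] - tr <= excl:
                near = True
            if near:
                continue
        i = int(round((tr - target_dff.t0) * fs))
        if i - pre < 0 or i + post >= target_dff.n_samples:
            continue
        segs.append(x[i - pre: i + post + 1])
    lags = np.arange(-pre, post + 1) / fs
    if not segs:
        return CoDepResult(lags_s=lags, avg_trace=np.zeros(lags.size),
                           codep_size_pct=float("nan"), n_segments=0,
                           low_confidence=True)
    avg = np.mean(segs, axis=0)
    b0 = int(round((baseline_ms[0] - win_ms[0]) * 1e-3 * fs))
    b1 = int(round((baseline_ms[1] - win_ms[0]) * 1e-3 * fs))
    avg = avg - np.mean(avg[b0:b1])
    central = (lags >= -10e-3) & (lags <= 10e-3)
    size = float(np.max(avg[central])) * 100.0
    return CoDepResult(lags_s=lags, avg_trace=avg, codep_size_pct=size,
                       n_segments=len(segs),
                       low_confidence=len(segs) < min_segments)


@dataclass
class TargetCorrelation:
    target: int
    r_same: float
    r_different: float
    n_references: int


def _greedy_distance_match(distances: np.ndarray,
                           rng: np.random.Generator | None = None
                           ) -> np.ndarray:
    """Match each reference to a *different* reference at similar distance.

    Greedy without replacement over reference pairs ordered by |Δdistance|;
    returns for each reference index the index of its matched partner.
    Requires an even number of references drops nothing: with an odd
    count the leftover reference is matched to its nearest unused-distance
    partner (reuse allowed only for that one).
    """
    n = distances.size
    pairs = sorted(
        ((abs(distances[i] - distances[j]), i, j)
         for i in range(n) for j in range(i + 1, n)),
    )
    partner = np.full(n, -1, dtype=int)
    used = np.zeros(n, dtype=bool)
    for _, i, j in pairs:
        if not used[i] and not used[j]:
            partner[i], partner[j] = j, i
            used[i] = used[j] = True
    for i in range(n):
        if partner[i] == -1:  # odd leftover
            others = np.array([j for j in range(n) if j != i])
            partner[i] = others[np.argmin(np.abs(distances[others]
                                                 - distances[i]))]
    return partner


def synchrony_codep_correlation(
    recording: PopulationRecording,
    min_refs: int = 10,
    **codep_kwargs,
) -> list[TargetCorrelation]:
    """Per-target correlation between synchrony and co-depolarization.

    For each target cell with more than ``min_refs`` simultaneously imaged
    reference cells, computes the Pearson correlation across references
    between synchrony strength and co-depolarization size (``r_same``),
    and a control correlation in which each reference's synchrony is paired
    with the co-depolarization of a *different* reference at a similar
    distance from the target (``r_different``; greedy |Δdistance|
    matching without replacement).  Targets whose statistics are degenerate
    (all sizes equal, too few valid references) get NaN correlations.
    """
    results = []
    n = recording.n_cells
    for t_idx in range(n):
        refs = [i for i in range(n) if i != t_idx]
        if len(refs) <= min_refs:
            continue
        sync, codep, dist, valid = [], [], [], []
        for r_idx in refs:
            try:
                s = synchrony_strength(recording.spikes[r_idx],
                                       recording.spikes[t_idx])
            except ValueError:
                s = float("nan")
            cd = co_depolarization(recording.dff[t_idx],
                                   recording.spikes[t_idx],
                                   recording.spikes[r_idx],
                                   **codep_kwargs)
            d = float(np.linalg.norm(recording.positions[r_idx]
                                     - recording.positions[t_idx]))
            if np.isfinite(s) and np.isfinite(cd.codep_size_pct):
                sync.append(s)
                codep.append(cd.codep_size_pct)
                dist.append(d)
        sync = np.array(sync)
        codep = np.array(codep)
        dist = np.array(dist)
        if sync.size <= min_refs or np.ptp(codep) == 0 or np.ptp(sync) == 0:
            results.append(TargetCorrelation(t_idx, float("nan"),
                                             float("nan"), sync.size))
            continue
        r_same = float(stats.pearsonr(sync, codep)[0])
        partner = _greedy_distance_match(dist)
        r_diff = float(stats.pearsonr(sync, codep[partner])[0])
        results.append(TargetCorrelation(t_idx, r_same, r_diff, sync.size))
    return results
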