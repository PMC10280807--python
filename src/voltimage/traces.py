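"""Core time-series containers for voltage-imaging analysis.

Fluorescence is carried either as raw camera intensity (:class:`Trace`) or as
a baseline-normalized fractional change (:class:`DffTrace`).  A ``DffTrace``
always declares the sign convention of its action-potential transients:
rhodopsin-based chemigenetic sensors of this class are negative-going on raw fluorescence, so ΔF/F spikes
are negative unless the detrending step inverted the sign.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Trace", "DffTrace", "POLARITIES", "BASELINE_METHODS"]

POLARITIES = ("positive_spikes", "negative_spikes")
BASELINE_METHODS = (
    "moving_avg_1s_inverted",
    "median_5s",
    "median_20ms",
    "median_50ms",
)


@dataclass
class Trace:
    """A single fluorescence time series sampled at a fixed rate.

    Parameters
    ----------
    values : array of float
        Fluorescence samples, arbitrary camera units.
    fs : float
        Sampling rate in Hz, > 0.
    t0 : float
        Time of the first sample in seconds.
    units : str
        Free-form units tag (``"au"`` for raw intensity).
    """

    values: np.ndarray
    fs: float
    t0: float = 0.0
    units: str = "au"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("trace values must be 1-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace contains non-finite samples")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.values.size / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds (frame 0 is at ``t0``)."""
        return self.t0 + np.arange(self.values.size) / self.fs


@dataclass
class DffTrace(Trace):
    """Baseline-normalized fluorescence (ΔF/F as a fraction).

    ``polarity`` states whether action-potential transients are positive or
    negative excursions; detectors check it and refuse mismatched input.
    ``baseline_method`` records which detrending convention produced the
    trace.
    """

    polarity: str = "negative_spikes"
    baseline_method: str = "median_5s"
    units: str = field(default="dff_fraction")

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.polarity not in POLARITIES:
            raise ValueError(f"polarity must be one of {POLARITIES}")
        if self.baseline_method not in BASELINE_METHODS:
            raise ValueError(
                f"baseline_method must be one of {BASELINE_METHODS}"
            )
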