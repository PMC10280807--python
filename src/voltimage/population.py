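"""Simultaneously recorded cell populations."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spikes import SpikeTrain
from .traces import DffTrace

__all__ = ["PopulationRecording"]


@dataclass
class PopulationRecording:
    """A set of simultaneously imaged cells.

    Holds one ΔF/F trace and one spike train per cell together with cell
    positions (μm).  This is the substrate for the synchrony and
    co-depolarization analyses.
    """

    dff: list[DffTrace]
    spikes: list[SpikeTrain]
    positions: np.ndarray  # (n_cells, 2) μm

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        n = len(self.dff)
        if len(self.spikes) != n or self.positions.shape != (n, 2):
            raise ValueError("dff, spikes and positions must agree in length")
        durations = {t.n_samples for t in self.dff}
        if len(durations) > 1:
            raise ValueError("all cells must share one record length")
        if len({tuple(p) for p in self.positions}) != n:
            raise ValueError("cell positions must be unique")

    @property
    def n_cells(self) -> int:
        return len(self.dff)

    @property
    def fs(self) -> float:
        return self.dff[0].fs

    @property
    def duration(self) -> float:
        return self.dff[0].duration
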