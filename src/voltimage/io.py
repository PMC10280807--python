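"""File formats: TIFF movies, CSV traces, JSON spike trains and sidecars.

Conventions: pixel coordinates are 0-based (row, col); all times are in
seconds; frame 0 corresponds to t0.  Trace CSVs have a ``time_s`` first
column and one column per cell; ΔF/F CSVs carry the polarity and baseline
method in a ``#`` header comment line.  Movies round-trip losslessly as
multi-page TIFF for 16-bit integer data.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .spikes import SpikeTrain
from .traces import DffTrace, Trace

__all__ = [
    "write_movie", "read_movie",
    "write_traces", "read_traces",
    "write_dff_trace", "read_dff_trace",
    "write_spikes", "read_spikes",
]


def write_movie(path: str | Path, movie: np.ndarray) -> None:
    """Write a (frames, H, W) stack as multi-page TIFF."""
    movie = np.asarray(movie)
    if movie.ndim != 3:
        raise ValueError("movie must be (frames, H, W)")
    tifffile.imwrite(str(path), movie)


def read_movie(path: str | Path) -> np.ndarray:
    try:
        movie = tifffile.imread(str(path))
    except Exception as exc:  # noqa: BLE001 - re-raise with file context
        raise ValueError(f"cannot read TIFF movie {path}: {exc}") from exc
    if movie.ndim == 2:
        movie = movie[None]
    return movie


def write_traces(path: str | Path, traces: list[Trace],
                 names: list[str] | None = None) -> None:
    """Write traces as CSV: time_s column plus one column per cell."""
    if not traces:
        raise ValueError("no traces to write")
    fs = traces[0].fs
    n = traces[0].n_samples
    for t in traces:
        if t.fs != fs or t.n_samples != n:
            raise ValueError("traces must share fs and length")
    names = names or [f"cell{i}" for i in range(len(traces))]
    df = pd.DataFrame({"time_s": traces[0].times})
    for name, t in zip(names, traces):
        df[name] = t.values
    df.to_csv(path, index=False, float_format="%.10e")


def read_traces(path: str | Path) -> tuple[list[Trace], list[str]]:
    df = pd.read_csv(path, comment="#")
    if "time_s" not in df.columns:
        raise ValueError(f"{path}: missing required column 'time_s'")
    t = df["time_s"].to_numpy()
    if t.size < 2:
        raise ValueError(f"{path}: need at least two samples")
    fs = 1.0 / float(np.mean(np.diff(t)))
    names = [c for c in df.columns if c != "time_s"]
    traces = [Trace(values=df[c].to_numpy(), fs=fs, t0=float(t[0]))
              for c in names]
    return traces, names


def write_dff_trace(path: str | Path, dff: DffTrace, name: str = "cell0") -> None:
    """Write a ΔF/F trace with polarity/baseline metadata in a comment line."""
    header = (f"# polarity={dff.polarity} baseline_method={dff.baseline_method}"
              f" fs={dff.fs!r}\n")
    df = pd.DataFrame({"time_s": dff.times, name: dff.values})
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False, float_format="%.10e")


def read_dff_trace(path: str | Path) -> DffTrace:
    with open(path) as fh:
        first = fh.readline()
    if not first.startswith("#"):
        raise ValueError(f"{path}: missing '#' metadata header line")
    meta = dict(tok.split("=", 1) for tok in first[1:].split())
    df = pd.read_csv(path, comment="#")
    if "time_s" not in df.columns:
        raise ValueError(f"{path}: missing required column 'time_s'")
    cols = [c for c in df.columns if c != "time_s"]
    t = df["time_s"].to_numpy()
    return DffTrace(
        values=df[cols[0]].to_numpy(),
        fs=float(meta.get("fs", 1.0 / float(np.mean(np.diff(t))))),
        t0=float(t[0]),
        polarity=meta["polarity"],
        baseline_method=meta["baseline_method"],
    )


def write_spikes(path: str | Path, train: SpikeTrain) -> None:
    payload = {
        "times_s": train.times.tolist(),
        "amplitudes": train.amplitudes.tolist(),
        "detector": train.detector,
        "threshold": None if np.isnan(train.threshold) else train.threshold,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_spikes(path: str | Path) -> SpikeTrain:
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"{path}: malformed spike JSON at line "
                         f"{exc.lineno}: {exc.msg}") from exc
    for key in ("times_s", "amplitudes"):
        if key not in payload:
            raise ValueError(f"{path}: missing key {key!r}")
    thr = payload.get("threshold")
    return SpikeTrain(
        times=np.asarray(payload["times_s"], dtype=float),
        amplitudes=np.asarray(payload["amplitudes"], dtype=float),
        detector=payload.get("detector", "unknown"),
        threshold=float("nan") if thr is None else float(thr),
    )
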