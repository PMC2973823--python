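"""Delimited-text formats for spike trains and stimulus logs.

Spike tables are CSV with header ``cell_id,spike_time_ms``; stimulus logs
CSV with header ``onset_ms,colour,intensity``.  Times are milliseconds
from recording start, serialised with 3 decimal places; colour labels are
lowercase strings.  Reading validates ordering and ranges and reports the
offending line number on failure.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from rgcdecode.synthdata import (
    FlashEvent,
    PopulationRecording,
    SpikeTrain,
    StimulusSequence,
)

__all__ = [
    "write_spike_table", "read_spike_table",
    "write_stimulus_log", "read_stimulus_log",
]


def write_spike_table(
    trains: list[SpikeTrain] | PopulationRecording, path: str | Path
) -> None:
    if isinstance(trains, PopulationRecording):
        trains = list(trains.trains)
    rows = [
        (t.cell_id, f"{st:.3f}") for t in trains for st in t.spike_times
    ]
    df = pd.DataFrame(rows, columns=["cell_id", "spike_time_ms"])
    df.to_csv(path, index=False)


def read_spike_table(path: str | Path) -> list[SpikeTrain]:
    """Parse a spike table into per-cell sorted trains.

    Duplicate timestamps within a cell are collapsed with a warning;
    negative or (per cell) unsorted times raise with the line number.
    """
    df = pd.read_csv(path, dtype={"cell_id": str, "spike_time_ms": float})
    if list(df.columns) != ["cell_id", "spike_time_ms"]:
        raise ValueError(
            f"{path}: expected header cell_id,spike_time_ms, got {list(df.columns)}"
        )
    neg = df.index[df["spike_time_ms"] < 0]
    if len(neg):
        raise ValueError(
            f"{path}, line {neg[0] + 2}: negative spike time "
            f"{df['spike_time_ms'].iloc[neg[0]]}"
        )
    trains = []
    for cell_id, grp in df.groupby("cell_id", sort=True):
        t = grp["spike_time_ms"].to_numpy()
        if np.any(np.diff(t) < 0):
            bad = int(grp.index[np.argmax(np.diff(t) < 0) + 1])
            raise ValueError(
                f"{path}, line {bad + 2}: spike times of cell {cell_id} not sorted"
            )
        uniq = np.unique(t)
        if uniq.size != t.size:
            warnings.warn(
                f"{path}: collapsed {t.size - uniq.size} duplicate "
                f"timestamps for cell {cell_id}"
            )
        trains.append(SpikeTrain(str(cell_id), uniq))
    return trains


def write_stimulus_log(stimulus: StimulusSequence, path: str | Path) -> None:
    df = pd.DataFrame(
        [
            (f"{f.onset:.3f}", f.colour, f"{f.intensity:.6g}")
            for f in stimulus.flashes
        ],
        columns=["onset_ms", "colour", "intensity"],
    )
    with open(path, "w") as fh:
        fh.write(
            f"# flash_duration_ms={stimulus.flash_duration:.3f} "
            f"total_duration_ms={stimulus.total_duration:.3f}\n"
        )
        df.to_csv(fh, index=False)


def read_stimulus_log(
    path: str | Path,
    flash_duration: float | None = None,
    total_duration: float | None = None,
) -> StimulusSequence:
    """Parse a stimulus log; the header comment carries the durations."""
    with open(path) as fh:
        first = fh.readline()
    meta = {}
    if first.startswith("#"):
        for tok in first[1:].split():
            if "=" in tok:
                k, v = tok.split("=", 1)
                meta[k] = float(v)
        skip = 1
    else:
        skip = 0
    if flash_duration is None:
        flash_duration = meta.get("flash_duration_ms", 66.0)
    df = pd.read_csv(path, skiprows=skip)
    if list(df.columns) != ["onset_ms", "colour", "intensity"]:
        raise ValueError(
            f"{path}: expected header onset_ms,colour,intensity, got {list(df.columns)}"
        )
    flashes = []
    prev_off = -np.inf
    for i, row in df.iterrows():
        line = i + skip + 2
        colour = str(row["colour"])
        if colour not in ("red", "green"):
            raise ValueError(f"{path}, line {line}: unknown colour {colour!r}")
        onset = float(row["onset_ms"])
        if onset < prev_off:
            raise ValueError(
                f"{path}, line {line}: flash at {onset} ms overlaps the previous one"
            )
        prev_off = onset + flash_duration
        flashes.append(FlashEvent(onset, colour, float(row["intensity"])))
    if total_duration is None:
        total_duration = meta.get(
            "total_duration_ms",
            (flashes[-1].onset + flash_duration) if flashes else 0.0,
        )
    return StimulusSequence(tuple(flashes), flash_duration, total_duration)
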