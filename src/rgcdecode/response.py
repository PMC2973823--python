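"""Overlapping-window spike-count representation.

All linear decoders consume spike counts in 25 ms boxcar windows with 50%
overlap (12.5 ms stride).  Windows are half-open ``[a, a + w)``: a spike
exactly on a window's right edge belongs to the next window, and a spike in
the interior of the grid is counted by exactly two windows at 50% overlap.
The fractional stride is kept exact (no rounding).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from rgcdecode.synthdata import PopulationRecording, SpikeTrain, StimulusSequence

__all__ = [
    "RED", "GREEN", "COLOUR_CODE", "BinnedResponse", "StimulusIndicator",
    "bin_response", "indicator_from_stimulus",
]

#: numeric stimulus coding used throughout the decoders
RED, GREEN = 1, 2
COLOUR_CODE = {"red": RED, "green": GREEN}


@dataclass(frozen=True)
class BinnedResponse:
    """Cells × windows spike-count matrix on a regular overlapping grid.

    Window ``t`` covers ``[start_time + t*stride, start_time + t*stride +
    window_length)``.
    """

    counts: np.ndarray  # (n_cells, n_windows) int
    window_length: float = 25.0
    stride: float = 12.5
    start_time: float = 0.0
    cell_ids: tuple[str, ...] = ()

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_windows(self) -> int:
        return self.counts.shape[1]

    @property
    def window_starts(self) -> np.ndarray:
        return self.start_time + self.stride * np.arange(self.n_windows)


@dataclass(frozen=True)
class StimulusIndicator:
    """Stimulus represented on the decoding grid.

    ``binary`` coding: one value per window, 1 iff the window overlaps a
    flash interval.  ``colour`` coding: one value per flash, 1 for red and
    2 for green.
    """

    values: np.ndarray
    coding: str  # "binary" | "colour"


def _count_windows(spikes: np.ndarray, starts: np.ndarray, w: float) -> np.ndarray:
    # half-open [s, s+w): left edge included, right excluded
    return (
        np.searchsorted(spikes, starts + w, side="left")
        - np.searchsorted(spikes, starts, side="left")
    )


def bin_response(
    source: SpikeTrain | PopulationRecording,
    window_length: float = 25.0,
    overlap: float = 0.5,
    epoch: tuple[float, float] | None = None,
) -> BinnedResponse:
    """Bin spikes into overlapping windows over ``epoch``.

    ``overlap`` is the fraction of each window shared with the next; the
    default 0.5 gives a 12.5 ms stride.  The grid origin is the epoch
    start; only windows fully inside the epoch are produced.
    """
    if window_length <= 0:
        raise ValueError("window_length must be > 0")
    if not 0.0 <= overlap < 1.0:
        raise ValueError("overlap must lie in [0, 1)")
    stride = window_length * (1.0 - overlap)

    if isinstance(source, PopulationRecording):
        trains = source.trains
        cell_ids = tuple(source.cell_ids)
        rec_end = source.stimulus.total_duration
    else:
        trains = (source,)
        cell_ids = (source.cell_id,)
        rec_end = float(source.spike_times[-1]) if source.n_spikes else 0.0

    if epoch is None:
        epoch = (0.0, rec_end)
    t0, t1 = epoch
    if t0 < 0 or t1 < t0:
        raise ValueError(f"invalid epoch {epoch}")
    if isinstance(source, PopulationRecording) and t1 > rec_end + 1e-9:
        raise ValueError(
            f"epoch end {t1} ms is outside the recording ({rec_end} ms)"
        )

    n_windows = max(0, int(np.floor((t1 - t0 - window_length) / stride)) + 1)
    starts = t0 + stride * np.arange(n_windows)
    counts = np.zeros((len(trains), n_windows), dtype=np.int64)
    for i, tr in enumerate(trains):
        if tr.n_spikes:
            counts[i] = _count_windows(tr.spike_times, starts, window_length)
    return BinnedResponse(counts, window_length, stride, t0, cell_ids)


def indicator_from_stimulus(
    stimulus: StimulusSequence,
    grid: BinnedResponse,
    coding: str = "binary",
) -> StimulusIndicator:
    """Stimulus on the decoding grid.

    ``binary``: window marked 1 iff its half-open interval overlaps a flash
    interval ``[onset, onset + flash_duration)`` (partial overlap counts).
    ``colour``: per-flash values, 1 = red, 2 = green.
    """
    if coding == "colour":
        vals = np.array([COLOUR_CODE[f.colour] for f in stimulus.flashes], dtype=int)
        return StimulusIndicator(vals, "colour")
    if coding != "binary":
        raise ValueError(f"unknown coding {coding!r}; expected 'binary' or 'colour'")
    starts = grid.window_starts
    vals = np.zeros(grid.n_windows, dtype=int)
    for f in stimulus.flashes:
        off = f.onset + stimulus.flash_duration
        vals[(starts < off) & (starts + grid.window_length > f.onset)] = 1
    return StimulusIndicator(vals, "binary")
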