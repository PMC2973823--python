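"""Interspike-interval (ISI) Bayesian stimulus classification.

Without an external time reference, a readout can only use relative spike
times — the ISIs of a single cell.  Each ISI is keyed by its second spike:
if that spike falls within ``assign_window`` ms after a flash onset
(default 216 = a 150 ms response window + the 66 ms flash), the ISI is
assigned to the flash's colour, otherwise to "black" (no stimulus).  The
empirical joint distribution over (ISI bin × {red, green, black}) supports
two classifiers:

* **maximum likelihood** — argmax over P(ISI bin | stimulus), which
  ignores how rare flashes are and therefore fires false alarms at a rate
  of ``baseline_rate × confusable_fraction`` on a black screen;
* **maximum a posteriori** — argmax over P(stimulus | ISI bin); under a
  realistic rare-flash prior it almost always answers "black".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from rgcdecode.synthdata import SpikeTrain, StimulusSequence

__all__ = [
    "STIMULI", "ISIJointDistribution", "build_isi_joint", "ml_classify",
    "map_classify", "false_alarm_interval",
]

STIMULI = ("red", "green", "black")
#: deterministic tie-break order: black beats green beats red
_TIE_ORDER = {"black": 0, "green": 1, "red": 2}


@dataclass(frozen=True)
class ISIJointDistribution:
    """Empirical joint P(ISI bin, stimulus) with its stimulus prior."""

    isi_edges: np.ndarray  # bin edges, ms
    joint: np.ndarray  # (n_bins, 3) columns in STIMULI order; sums to 1
    prior: np.ndarray  # (3,) stimulus prior, sums to 1
    assign_window: float = 216.0

    @property
    def n_bins(self) -> int:
        return self.joint.shape[0]

    @property
    def conditionals(self) -> np.ndarray:
        """P(ISI bin | stimulus), each column summing to 1."""
        sums = self.joint.sum(axis=0, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(sums > 0, self.joint / sums, 0.0)

    @property
    def posterior(self) -> np.ndarray:
        """P(stimulus | ISI bin), each non-empty row summing to 1."""
        rows = self.joint.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(rows > 0, self.joint / rows, 0.0)

    def bin_of(self, isi: float) -> int:
        if isi < self.isi_edges[0] or isi > self.isi_edges[-1]:
            warnings.warn(
                f"ISI {isi} ms outside binned range "
                f"[{self.isi_edges[0]}, {self.isi_edges[-1]}]; clamped to edge bin"
            )
        b = int(np.searchsorted(self.isi_edges, isi, side="right")) - 1
        return int(np.clip(b, 0, self.n_bins - 1))


def build_isi_joint(
    train: SpikeTrain,
    stimulus: StimulusSequence,
    assign_window: float = 216.0,
    isi_bin: float = 25.0,
    isi_range: tuple[float, float] = (0.0, 1000.0),
) -> ISIJointDistribution:
    """Tabulate the empirical joint distribution of ISIs and stimuli."""
    spikes = train.spike_times
    if spikes.size < 2:
        raise ValueError(f"need at least 2 spikes, got {spikes.size}")
    isis = np.diff(spikes)
    second = spikes[1:]

    onsets = stimulus.onsets
    labels = np.full(second.size, "black", dtype=object)
    if onsets.size:
        idx = np.searchsorted(onsets, second, side="right") - 1
        valid = idx >= 0
        within = np.zeros(second.size, dtype=bool)
        within[valid] = second[valid] < onsets[idx[valid]] + assign_window
        for i in np.nonzero(within)[0]:
            labels[i] = stimulus.flashes[idx[i]].colour

    edges = np.arange(isi_range[0], isi_range[1] + isi_bin, isi_bin)
    n_bins = edges.size - 1
    joint = np.zeros((n_bins, 3))
    bins = np.clip(np.searchsorted(edges, isis, side="right") - 1, 0, n_bins - 1)
    for b, lab in zip(bins, labels):
        joint[b, STIMULI.index(lab)] += 1
    prior = joint.sum(axis=0)
    joint /= joint.sum()
    prior /= prior.sum()
    return ISIJointDistribution(edges, joint, prior, assign_window)


def _argmax_label(scores: np.ndarray) -> str:
    best = scores.max()
    tied = [s for s, v in zip(STIMULI, scores) if v == best]
    return min(tied, key=lambda s: _TIE_ORDER[s])


def ml_classify(dist: ISIJointDistribution, isi: float) -> str:
    """Maximum-likelihood label: argmax over P(ISI bin | stimulus)."""
    return _argmax_label(dist.conditionals[dist.bin_of(isi)])


def map_classify(
    dist: ISIJointDistribution, isi: float, prior: np.ndarray | None = None
) -> str:
    """MAP label: argmax over P(stimulus | ISI bin) ∝ likelihood × prior.

    ``prior`` overrides the empirical stimulus prior (e.g. a uniform prior
    makes MAP coincide with ML)."""
    b = dist.bin_of(isi)
    p = dist.prior if prior is None else np.asarray(prior, dtype=float)
    return _argmax_label(dist.conditionals[b] * p)


def false_alarm_interval(
    baseline_rate: float, confusable_fraction: float
) -> float:
    """Expected ms between ML false alarms on a black screen.

    A cell firing at ``baseline_rate`` Hz produces one ISI per spike; a
    fraction of those ISIs falls in the stimulus-classified range, so false
    alarms occur every ``1000 / (rate × fraction)`` ms on average (a 6 Hz
    cell with half its ISIs confusable gives one every ~333 ms).  A zero
    fraction yields an unbounded interval (``inf``).
    """
    if baseline_rate <= 0:
        raise ValueError(f"baseline_rate must be > 0, got {baseline_rate}")
    if not 0.0 <= confusable_fraction <= 1.0:
        raise ValueError("confusable_fraction must lie in [0, 1]")
    if confusable_fraction == 0.0:
        return float("inf")
    return 1000.0 / (baseline_rate * confusable_fraction)
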