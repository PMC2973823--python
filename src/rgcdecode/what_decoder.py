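"""Single-cell colour ("what") readouts.

Two readouts estimate flash colour from one cell's response given an onset
time (true, or estimated by the population detector):

* **Linear-nonlinear**: the stimulus code s ∈ {1 = red, 2 = green} is
  estimated as ŝ = Σ_τ h(τ)·x(τ) + C, where x(τ) are overlapping-window
  spike counts over a 375 ms filter span after onset.  h and C minimise
  the squared error Σ_n (s_n − ŝ_n)²; a threshold θ (chosen to minimise
  training misclassifications; its optimum sits very close to 1.5 for
  balanced trials) converts ŝ into a colour label.
* **First-spike latency**: the joint histogram of (first-spike latency
  bin, colour) is estimated on training trials; test trials are classified
  by maximum likelihood over the per-colour conditionals.

Decoders are always fitted on one half of the data and evaluated on the
other (chronological split).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from rgcdecode._linalg import RIDGE, best_threshold, ridge_lstsq
from rgcdecode.response import COLOUR_CODE, GREEN, RED
from rgcdecode.synthdata import SpikeTrain, StimulusSequence

__all__ = [
    "ColourTrial", "ColourLNDecoder", "FirstSpikeDecoder",
    "make_colour_trials", "fit_colour_ln", "linear_estimate",
    "predict_colour", "first_spike_latencies", "fit_first_spike",
    "predict_colour_first_spike", "error_by_intensity", "split_half",
]


@dataclass(frozen=True)
class ColourTrial:
    """One flash, seen by one cell: windowed counts aligned to the onset."""

    response: np.ndarray  # counts over the filter lags
    colour: int  # 1 = red, 2 = green
    intensity: float
    onset_used: float  # ms; true or estimated onset (+ causal offset)


@dataclass(frozen=True)
class ColourLNDecoder:
    """Fitted LN colour readout: filter h(τ), constant C, threshold θ."""

    filter: np.ndarray
    constant: float
    threshold: float
    filter_length: float = 375.0
    stride: float = 12.5

    @property
    def n_lags(self) -> int:
        return int(self.filter.size)


@dataclass(frozen=True)
class FirstSpikeDecoder:
    """Joint (latency bin × colour) histogram plus the ML decision rule."""

    joint: np.ndarray  # (n_bins, 2): columns red, green; sums to 1
    latency_bin: float
    window: float
    no_spike_rule: int = RED  # fallback label when no spike is observed

    @property
    def conditionals(self) -> np.ndarray:
        """P(latency bin | colour), one column per colour, each summing to 1."""
        col_sums = self.joint.sum(axis=0, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            cond = np.where(col_sums > 0, self.joint / col_sums, 0.0)
        return cond


def _n_lags(filter_length: float, stride: float) -> int:
    return int(round(filter_length / stride))


def make_colour_trials(
    train: SpikeTrain,
    stimulus: StimulusSequence,
    onsets: np.ndarray | None = None,
    time_zero_offset: float = 0.0,
    filter_length: float = 375.0,
    window_length: float = 25.0,
    stride: float = 12.5,
) -> list[ColourTrial]:
    """Extract per-flash windowed responses aligned to (true or given) onsets.

    ``onsets`` defaults to the true flash onsets; in the two-stage readout
    it carries the estimated onsets and ``time_zero_offset`` the causal
    shift (the onset-filter length).  Lag τ covers
    ``[onset + offset + τ·stride, … + window_length)``.
    """
    if onsets is None:
        onsets = stimulus.onsets
    onsets = np.asarray(onsets, dtype=float)
    if onsets.size != stimulus.n_flashes:
        raise ValueError("one onset per flash required")
    L = _n_lags(filter_length, stride)
    lag_starts = stride * np.arange(L)
    spikes = train.spike_times
    trials = []
    for f, onset in zip(stimulus.flashes, onsets):
        starts = onset + time_zero_offset + lag_starts
        resp = (
            np.searchsorted(spikes, starts + window_length, side="left")
            - np.searchsorted(spikes, starts, side="left")
        )
        trials.append(
            ColourTrial(resp.astype(float), COLOUR_CODE[f.colour], f.intensity,
                        float(onset + time_zero_offset))
        )
    return trials


def split_half(trials: list) -> tuple[list, list]:
    """Chronological two-way split: first half for training, second for test."""
    h = len(trials) // 2
    return trials[:h], trials[h:]


def fit_colour_ln(
    trials: list[ColourTrial],
    filter_length: float = 375.0,
    stride: float = 12.5,
    ridge: float = RIDGE,
) -> ColourLNDecoder:
    """Least-squares fit of the LN colour readout on training trials."""
    labels = np.array([t.colour for t in trials])
    if np.sum(labels == RED) < 2 or np.sum(labels == GREEN) < 2:
        raise ValueError("need at least 2 trials of each colour to fit")
    X = np.stack([t.response for t in trials])
    sol = ridge_lstsq(X, labels.astype(float), ridge=ridge)
    h, C = sol[:-1], float(sol[-1])
    shat = X @ h + C
    theta = best_threshold(shat, labels, hi_label=GREEN, lo_label=RED)
    return ColourLNDecoder(h, C, theta, filter_length, stride)


def linear_estimate(decoder: ColourLNDecoder, trial: ColourTrial) -> float:
    """The linear stage ŝ = h·x + C for one trial."""
    if trial.response.size != decoder.n_lags:
        raise ValueError(
            f"trial has {trial.response.size} lags, filter expects {decoder.n_lags}"
        )
    return float(decoder.filter @ trial.response + decoder.constant)


def predict_colour(decoder: ColourLNDecoder, trial: ColourTrial) -> int:
    """Threshold nonlinearity: green (2) iff ŝ ≥ θ, else red (1)."""
    return GREEN if linear_estimate(decoder, trial) >= decoder.threshold else RED


def first_spike_latencies(
    train: SpikeTrain,
    stimulus: StimulusSequence,
    onsets: np.ndarray | None = None,
    time_zero_offset: float = 0.0,
    window: float = 375.0,
) -> list[tuple[float | None, int, float]]:
    """(latency | None, colour, intensity) per flash; latency from time zero.

    Latency is the time of the first spike within ``window`` ms after
    ``onset + time_zero_offset``; None when the cell stayed silent there.
    """
    if onsets is None:
        onsets = stimulus.onsets
    onsets = np.asarray(onsets, dtype=float)
    spikes = train.spike_times
    out = []
    for f, onset in zip(stimulus.flashes, onsets):
        t0 = onset + time_zero_offset
        i = np.searchsorted(spikes, t0, side="left")
        lat = None
        if i < spikes.size and spikes[i] < t0 + window:
            lat = float(spikes[i] - t0)
        out.append((lat, COLOUR_CODE[f.colour], f.intensity))
    return out


def fit_first_spike(
    latency_colour_pairs: list[tuple[float | None, int]],
    latency_bin: float = 10.0,
    window: float = 375.0,
    no_spike_rule: int = RED,
) -> FirstSpikeDecoder:
    """Empirical joint histogram of first-spike latency and colour."""
    n_bins = int(np.ceil(window / latency_bin))
    joint = np.zeros((n_bins, 2))
    seen = {RED: 0, GREEN: 0}
    for lat, colour in latency_colour_pairs:
        seen[colour] += 1
        if lat is None:
            continue
        b = min(int(lat // latency_bin), n_bins - 1)
        joint[b, colour - 1] += 1
    if not (seen[RED] and seen[GREEN]):
        raise ValueError("need at least one trial per colour")
    total = joint.sum()
    if total > 0:
        joint /= total
    return FirstSpikeDecoder(joint, latency_bin, window, no_spike_rule)


def predict_colour_first_spike(
    decoder: FirstSpikeDecoder, latency: float | None
) -> int:
    """ML over the per-colour conditionals; no spike → the fallback label."""
    if latency is None:
        return decoder.no_spike_rule
    b = min(int(latency // decoder.latency_bin), decoder.joint.shape[0] - 1)
    cond = decoder.conditionals[b]
    # tie (including both zero) goes to the fallback label
    if cond[GREEN - 1] > cond[RED - 1]:
        return GREEN
    if cond[RED - 1] > cond[GREEN - 1]:
        return RED
    return decoder.no_spike_rule


def error_by_intensity(
    correct: np.ndarray,
    intensities: np.ndarray,
    colours: np.ndarray,
    n_windows: int = 5,
    intensity_range: tuple[float, float] | None = None,
) -> dict[int, np.ndarray]:
    """Relative contribution of each intensity window to false detections.

    For each colour, the misclassified trials are histogrammed over
    ``n_windows`` equal intensity bins and normalised to sum to 1 (all-zero
    when that colour produced no errors).
    """
    correct = np.asarray(correct, dtype=bool)
    intensities = np.asarray(intensities, dtype=float)
    colours = np.asarray(colours)
    if not correct.size == intensities.size == colours.size:
        raise ValueError("correct, intensities and colours must be aligned")
    if intensity_range is None:
        intensity_range = (float(intensities.min()), float(intensities.max()))
    edges = np.linspace(intensity_range[0], intensity_range[1], n_windows + 1)
    out: dict[int, np.ndarray] = {}
    for colour in (RED, GREEN):
        sel = (~correct) & (colours == colour)
        hist, _ = np.histogram(intensities[sel], bins=edges)
        total = hist.sum()
        out[colour] = hist / total if total > 0 else np.zeros(n_windows)
    return out
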