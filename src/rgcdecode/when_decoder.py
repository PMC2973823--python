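"""Population onset ("when") detection.

The linear-nonlinear onset detector estimates the binary stimulus
indicator s_t (1 while a flash is on the screen) from the population
response:

    ŝ_t = Σ_i Σ_τ h_i(τ) · x_i(t + τ) + C ,

an *anticausal* estimator — the decision at window t uses spike counts
from t up to t + T, where T is the filter length (250 ms by default,
125 ms in the two-stage readout).  Filters and C jointly minimise the
squared error Σ_t (s_t − ŝ_t)² over all cells; the threshold θ is then
chosen to minimise the summed count of false positives and false
negatives on the training half (both error types weighted equally).

Detected onsets are the rising-edge threshold crossings of the linear
output (one event per supra-threshold excursion); the reported onset time
is the window-start time t.  Detections are matched to true flashes by
greedy nearest-neighbour assignment within ±125 ms; unmatched flashes are
false negatives (normalised by the number of true events) and unmatched
detections false positives (normalised by the number of detections).
Timing error over matched pairs is split into an RMS component and a
red-minus-green bias.

Two naive rate-code detectors are provided for comparison: a thresholded
total population count in a 250 ms window, and the same with per-cell
weights fitted by least squares (no temporal structure within the window).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from rgcdecode._linalg import RIDGE
from rgcdecode.response import bin_response, indicator_from_stimulus
from rgcdecode.synthdata import PopulationRecording, StimulusSequence

__all__ = [
    "OnsetLNDecoder", "NaiveRateDetector", "OnsetEstimate",
    "DetectionReport", "TimingReport", "half_epochs", "fit_onset_ln",
    "fit_naive_rate", "linear_output", "detect_onsets", "score_detection",
    "matched_triples", "timing_errors", "evaluate_detector",
    "population_size_sweep",
]

DETECTION_TOLERANCE = 125.0  # ms; the ± matching criterion


@dataclass(frozen=True)
class OnsetLNDecoder:
    """Per-cell filters h_i(τ), constant C and threshold θ."""

    filters: np.ndarray  # (n_cells, n_lags)
    constant: float
    threshold: float
    filter_length: float
    cell_ids: tuple[str, ...]
    window_length: float = 25.0
    stride: float = 12.5

    @property
    def n_lags(self) -> int:
        return self.filters.shape[1]


@dataclass(frozen=True)
class NaiveRateDetector:
    """Rate-code detector: (weighted) population count in one long window."""

    weights: np.ndarray  # (n_cells,)
    constant: float
    threshold: float
    window: float
    cell_ids: tuple[str, ...]
    stride: float = 12.5


@dataclass(frozen=True)
class OnsetEstimate:
    """One detected onset; matching info is filled in by scoring."""

    time: float
    matched_flash: int | None = None
    colour_of_match: str | None = None


@dataclass(frozen=True)
class DetectionReport:
    """FP/FN rates under the ±tolerance criterion."""

    false_negative_rate: float
    false_positive_rate: float
    n_true: int
    n_detected: int
    n_matched: int
    tolerance: float = DETECTION_TOLERANCE


@dataclass(frozen=True)
class TimingReport:
    """RMS timing error and red−green bias over matched detections."""

    rms_error: float
    bias: float
    n_matched: int
    empty: bool = False


def half_epochs(
    stimulus: StimulusSequence,
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Chronological train/test halves of the recording epoch."""
    mid = stimulus.total_duration / 2.0
    return (0.0, mid), (mid, stimulus.total_duration)


def _lagged_gram(
    counts: np.ndarray, y: np.ndarray, n_lags: int, ridge: float
) -> np.ndarray:
    """Solve the joint multi-cell lagged least squares via chunked normal
    equations (the full design matrix is never materialised)."""
    n_cells = counts.shape[0]
    p = n_cells * n_lags + 1
    G = np.zeros((p, p))
    b = np.zeros(p)
    sw = sliding_window_view(counts, n_lags, axis=1)  # (cells, valid, lags) view
    n_valid = sw.shape[1]
    chunk = max(256, int(8e6 / p))
    for a in range(0, n_valid, chunk):
        z = min(a + chunk, n_valid)
        X = sw[:, a:z, :].transpose(1, 0, 2).reshape(z - a, -1).astype(float)
        A = np.column_stack([X, np.ones(z - a)])
        G += A.T @ A
        b += A.T @ y[a:z]
    G[np.diag_indices_from(G)] += ridge
    try:
        sol = np.linalg.solve(G, b)
    except np.linalg.LinAlgError:
        sol = np.linalg.pinv(G) @ b
    return sol


def _linear_series(
    counts: np.ndarray, filters: np.ndarray, constant: float
) -> np.ndarray:
    """ŝ_t = Σ_i correlate(x_i, h_i) + C over all valid windows."""
    n_lags = filters.shape[1]
    if counts.shape[1] < n_lags:
        return np.empty(0)
    shat = np.full(counts.shape[1] - n_lags + 1, constant)
    for xi, hi in zip(counts, filters):
        shat += np.correlate(xi.astype(float), hi, mode="valid")
    return shat


def _rising_edges(times: np.ndarray, shat: np.ndarray, theta: float) -> np.ndarray:
    above = shat >= theta
    if above.size == 0:
        return np.empty(0)
    rising = above.copy()
    rising[1:] &= ~above[:-1]
    return times[rising]


def _greedy_match(
    est: np.ndarray, true: np.ndarray, tol: float
) -> list[tuple[int, int]]:
    """Nearest-first greedy assignment of detections to true flashes,
    each used at most once; only pairs within ±tol are eligible."""
    pairs = []
    for j, t in enumerate(true):
        lo = np.searchsorted(est, t - tol, side="left")
        hi = np.searchsorted(est, t + tol, side="right")
        for i in range(lo, hi):
            pairs.append((abs(est[i] - t), i, j))
    pairs.sort()
    used_e: set[int] = set()
    used_t: set[int] = set()
    matches = []
    for _, i, j in pairs:
        if i in used_e or j in used_t:
            continue
        used_e.add(i)
        used_t.add(j)
        matches.append((i, j))
    return matches


def _flashes_in(stimulus: StimulusSequence, epoch: tuple[float, float]):
    return [
        (k, f) for k, f in enumerate(stimulus.flashes)
        if epoch[0] <= f.onset < epoch[1]
    ]


def _event_cost(
    times: np.ndarray, shat: np.ndarray, theta: float,
    true_onsets: np.ndarray, tol: float,
) -> int:
    est = _rising_edges(times, shat, theta)
    n_matched = len(_greedy_match(est, true_onsets, tol))
    return len(true_onsets) + len(est) - 2 * n_matched


def _optimise_threshold(
    times: np.ndarray, shat: np.ndarray, true_onsets: np.ndarray,
    tol: float, n_candidates: int = 201,
) -> float:
    qs = np.unique(np.quantile(shat, np.linspace(0.0, 1.0, n_candidates)))
    cands = np.concatenate([(qs[:-1] + qs[1:]) / 2.0, [qs[-1] + 1.0]])
    costs = [_event_cost(times, shat, th, true_onsets, tol) for th in cands]
    best = np.min(costs)
    # ties broken toward the largest threshold (fewest detections)
    return float(cands[np.nonzero(np.asarray(costs) == best)[0][-1]])


def fit_onset_ln(
    recording: PopulationRecording,
    cell_subset: list[str] | None = None,
    filter_length: float = 250.0,
    epoch: tuple[float, float] | None = None,
    ridge: float = RIDGE,
    window_length: float = 25.0,
    overlap: float = 0.5,
    tolerance: float = DETECTION_TOLERANCE,
) -> OnsetLNDecoder:
    """Fit the multi-cell LN onset detector on ``epoch`` (training half)."""
    rec = recording if cell_subset is None else recording.subset(cell_subset)
    if rec.n_cells == 0:
        raise ValueError("empty cell subset")
    if epoch is None:
        epoch = half_epochs(recording.stimulus)[0]
    true_onsets = np.array([f.onset for _, f in _flashes_in(recording.stimulus, epoch)])
    if true_onsets.size == 0:
        raise ValueError("no events: the training epoch contains no flashes")

    binned = bin_response(rec, window_length, overlap, epoch)
    stride = binned.stride
    n_lags = int(round(filter_length / stride))
    if binned.n_windows < n_lags:
        raise ValueError("training epoch shorter than the filter")
    s = indicator_from_stimulus(recording.stimulus, binned, "binary").values.astype(float)
    sol = _lagged_gram(binned.counts, s[: binned.n_windows - n_lags + 1], n_lags, ridge)
    filters = sol[:-1].reshape(rec.n_cells, n_lags)
    C = float(sol[-1])

    shat = _linear_series(binned.counts, filters, C)
    times = binned.window_starts[: shat.size]
    theta = _optimise_threshold(times, shat, true_onsets, tolerance)
    return OnsetLNDecoder(
        filters, C, theta, filter_length, tuple(rec.cell_ids), window_length, stride
    )


def _naive_counts(
    rec: PopulationRecording, epoch: tuple[float, float],
    window: float, stride: float,
) -> tuple[np.ndarray, np.ndarray]:
    t0, t1 = epoch
    n_grid = max(0, int(np.floor((t1 - t0 - window) / stride)) + 1)
    starts = t0 + stride * np.arange(n_grid)
    counts = np.zeros((rec.n_cells, n_grid))
    for i, tr in enumerate(rec.trains):
        sp = tr.spike_times
        counts[i] = np.searchsorted(sp, starts + window) - np.searchsorted(sp, starts)
    return starts, counts


def fit_naive_rate(
    recording: PopulationRecording,
    cell_subset: list[str] | None = None,
    window: float = 250.0,
    weighted: bool = False,
    weights: np.ndarray | None = None,
    epoch: tuple[float, float] | None = None,
    stride: float = 12.5,
    ridge: float = RIDGE,
    tolerance: float = DETECTION_TOLERANCE,
) -> NaiveRateDetector:
    """Fit a naive rate-code detector (total or weighted population count).

    ``weights`` overrides the fit (e.g. all-equal weights reduce the
    weighted detector to the unweighted one exactly).
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    rec = recording if cell_subset is None else recording.subset(cell_subset)
    if rec.n_cells == 0:
        raise ValueError("empty cell subset")
    if epoch is None:
        epoch = half_epochs(recording.stimulus)[0]
    true_onsets = np.array([f.onset for _, f in _flashes_in(recording.stimulus, epoch)])
    if true_onsets.size == 0:
        raise ValueError("no events: the training epoch contains no flashes")

    starts, counts = _naive_counts(rec, epoch, window, stride)
    grid = bin_response(rec, 25.0, 0.5, epoch)  # indicator grid
    s = indicator_from_stimulus(recording.stimulus, grid, "binary").values
    s = s[: starts.size].astype(float)

    if weights is not None:
        w = np.asarray(weights, dtype=float)
        C = 0.0
    elif weighted:
        A = np.column_stack([counts.T, np.ones(starts.size)])
        G = A.T @ A
        G[np.diag_indices_from(G)] += ridge
        sol = np.linalg.solve(G, A.T @ s)
        w, C = sol[:-1], float(sol[-1])
    else:
        w = np.ones(rec.n_cells)
        C = 0.0

    shat = counts.T @ w + C
    theta = _optimise_threshold(starts, shat, true_onsets, tolerance)
    return NaiveRateDetector(w, C, theta, window, tuple(rec.cell_ids), stride)


def linear_output(
    decoder: OnsetLNDecoder | NaiveRateDetector,
    recording: PopulationRecording,
    epoch: tuple[float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """(window-start times, linear estimate ŝ) over ``epoch``."""
    rec = recording.subset(list(decoder.cell_ids))
    if epoch is None:
        epoch = half_epochs(recording.stimulus)[1]
    if isinstance(decoder, NaiveRateDetector):
        starts, counts = _naive_counts(rec, epoch, decoder.window, decoder.stride)
        return starts, counts.T @ decoder.weights + decoder.constant
    binned = bin_response(rec, decoder.window_length, 0.5, epoch)
    # order counts to match the decoder's cell order
    order = [binned.cell_ids.index(c) for c in decoder.cell_ids]
    shat = _linear_series(binned.counts[order], decoder.filters, decoder.constant)
    return binned.window_starts[: shat.size], shat


def detect_onsets(
    decoder: OnsetLNDecoder | NaiveRateDetector,
    recording: PopulationRecording,
    epoch: tuple[float, float] | None = None,
) -> list[OnsetEstimate]:
    """Rising-edge threshold crossings of the linear output.

    After a crossing no new event is reported until the output falls back
    below θ (one event per supra-threshold excursion)."""
    times, shat = linear_output(decoder, recording, epoch)
    return [OnsetEstimate(float(t)) for t in _rising_edges(times, shat, decoder.threshold)]


def score_detection(
    estimates: list[OnsetEstimate],
    stimulus: StimulusSequence,
    tolerance: float = DETECTION_TOLERANCE,
    epoch: tuple[float, float] | None = None,
) -> tuple[DetectionReport, list[OnsetEstimate]]:
    """Match detections to true flashes within ±tolerance and score.

    Returns the report and a copy of the estimates annotated with their
    matched flash index and colour.  ``epoch`` restricts the true flashes
    considered (e.g. the test half).
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    if epoch is None:
        epoch = (0.0, stimulus.total_duration)
    flashes = _flashes_in(stimulus, epoch)
    est_times = np.array([e.time for e in estimates], dtype=float)
    order = np.argsort(est_times, kind="stable")
    true_onsets = np.array([f.onset for _, f in flashes])
    matches = _greedy_match(est_times[order], true_onsets, tolerance)

    annotated = list(estimates)
    for i_sorted, j in matches:
        i = int(order[i_sorted])
        k, f = flashes[j]
        annotated[i] = replace(annotated[i], matched_flash=k, colour_of_match=f.colour)
    n_true, n_det, n_m = len(flashes), len(estimates), len(matches)
    fn = (n_true - n_m) / n_true if n_true else 0.0
    fp = (n_det - n_m) / n_det if n_det else 0.0
    report = DetectionReport(fn, fp, n_true, n_det, n_m, tolerance)
    return report, annotated


def matched_triples(
    annotated: list[OnsetEstimate], stimulus: StimulusSequence
) -> list[tuple[float, float, str]]:
    """(estimated time, true onset, colour) for every matched detection."""
    return [
        (e.time, stimulus.flashes[e.matched_flash].onset, e.colour_of_match)
        for e in annotated
        if e.matched_flash is not None
    ]


def timing_errors(triples: list[tuple[float, float, str]]) -> TimingReport:
    """RMS of (estimate − true) and the red−green mean-error bias."""
    if not triples:
        return TimingReport(0.0, 0.0, 0, empty=True)
    err = np.array([e - t for e, t, _ in triples])
    col = np.array([c for _, _, c in triples])
    rms = float(np.sqrt(np.mean(err**2)))
    red, green = err[col == "red"], err[col == "green"]
    bias = float(red.mean() - green.mean()) if red.size and green.size else 0.0
    return TimingReport(rms, bias, len(triples))


def evaluate_detector(
    decoder: OnsetLNDecoder | NaiveRateDetector,
    recording: PopulationRecording,
    epoch: tuple[float, float] | None = None,
    tolerance: float = DETECTION_TOLERANCE,
) -> tuple[DetectionReport, TimingReport]:
    """Detect on ``epoch`` (default: test half) and score against the truth."""
    if epoch is None:
        epoch = half_epochs(recording.stimulus)[1]
    est = detect_onsets(decoder, recording, epoch)
    report, annotated = score_detection(est, recording.stimulus, tolerance, epoch)
    return report, timing_errors(matched_triples(annotated, recording.stimulus))


def population_size_sweep(
    recording: PopulationRecording,
    sizes: list[int] = (1, 5, 10, 25, 50, 75, 100),
    n_subgroups: int = 50,
    seed: int = 0,
    detector: str = "ln",
    filter_length: float = 250.0,
    naive_window: float = 250.0,
    weighted: bool = False,
    tolerance: float = DETECTION_TOLERANCE,
) -> dict[int, dict[str, float]]:
    """Mean detection/timing error versus population size.

    For every size, ``n_subgroups`` random cell subsets are drawn (seeded;
    a size equal to the whole population degenerates to a single fit), the
    detector is fitted on the training half and scored on the test half,
    and the FP/FN/RMS/bias values are averaged.
    """
    rng = np.random.default_rng(seed)
    all_ids = recording.cell_ids
    train_ep, test_ep = half_epochs(recording.stimulus)
    out: dict[int, dict[str, float]] = {}
    for size in sizes:
        if size > len(all_ids):
            raise ValueError(f"subgroup size {size} exceeds population {len(all_ids)}")
        reps = 1 if size == len(all_ids) else n_subgroups
        fn, fp, rms, bias = [], [], [], []
        for _ in range(reps):
            ids = list(rng.choice(all_ids, size=size, replace=False))
            if detector == "ln":
                dec = fit_onset_ln(
                    recording, ids, filter_length, train_ep, tolerance=tolerance
                )
            elif detector == "naive":
                dec = fit_naive_rate(
                    recording, ids, naive_window, weighted,
                    epoch=train_ep, tolerance=tolerance,
                )
            else:
                raise ValueError(f"unknown detector {detector!r}")
            drep, trep = evaluate_detector(dec, recording, test_ep, tolerance)
            fn.append(drep.false_negative_rate)
            fp.append(drep.false_positive_rate)
            if not trep.empty:
                rms.append(trep.rms_error)
                bias.append(trep.bias)
        out[size] = {
            "false_negative_rate": float(np.mean(fn)),
            "false_positive_rate": float(np.mean(fp)),
            "rms_error": float(np.mean(rms)) if rms else float("nan"),
            "bias": float(np.mean(bias)) if bias else float("nan"),
        }
    return out
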