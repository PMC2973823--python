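"""Colour readouts: LN least-squares fit, threshold, first-spike ML."""

from __future__ import annotations

import numpy as np
import pytest

import rgcdecode as rd
from rgcdecode.response import GREEN, RED
from rgcdecode.what_decoder import (
    ColourTrial,
    error_by_intensity,
    first_spike_latencies,
    fit_colour_ln,
    fit_first_spike,
    linear_estimate,
    make_colour_trials,
    predict_colour,
    predict_colour_first_spike,
    split_half,
)


def _trials_from(X, labels):
    return [
        ColourTrial(np.asarray(x, dtype=float), int(l), 0.3, 0.0)
        for x, l in zip(X, labels)
    ]


class TestFitColourLN:
    def test_separable_templates_fit_perfectly(self):
        X = [[3, 0, 0]] * 3 + [[0, 0, 3]] * 3
        labels = [RED] * 3 + [GREEN] * 3
        dec = fit_colour_ln(_trials_from(X, labels), filter_length=37.5)
        preds = [predict_colour(dec, t) for t in _trials_from(X, labels)]
        assert preds == labels

    def test_fit_matches_closed_form_least_squares(self):
        # independent oracle: pseudo-inverse of the same ridge normal equations
        rng = np.random.default_rng(0)
        X = rng.poisson(2.0, size=(200, 30)).astype(float)
        labels = rng.choice([RED, GREEN], size=200)
        labels[:2] = RED
        labels[2:4] = GREEN
        dec = fit_colour_ln(_trials_from(X, labels))
        A = np.column_stack([X, np.ones(200)])
        sol = np.linalg.pinv(A.T @ A + 1e-6 * np.eye(31)) @ (A.T @ labels)
        assert np.allclose(dec.filter, sol[:-1], atol=1e-8)
        assert np.isclose(dec.constant, sol[-1], atol=1e-8)

    def test_needs_two_trials_per_colour(self):
        X = [[1, 0], [0, 1], [1, 1]]
        with pytest.raises(ValueError, match="2 trials"):
            fit_colour_ln(_trials_from(X, [RED, RED, GREEN]))

    def test_optimal_threshold_close_to_1_5(self, tuned_recording):
        # balanced red(1)/green(2) coding puts the decision boundary near 1.5
        stim, train = tuned_recording
        trials = make_colour_trials(train, stim)
        fit, _ = split_half(trials)
        dec = fit_colour_ln(fit)
        assert abs(dec.threshold - 1.5) <= 0.2


class TestPredictColour:
    @pytest.mark.parametrize("shat,expected", [(1.2, RED), (1.8, GREEN)])
    def test_threshold_rule(self, shat, expected):
        dec = rd.ColourLNDecoder(np.array([shat]), 0.0, 1.5, 12.5, 12.5)
        trial = ColourTrial(np.array([1.0]), RED, 0.3, 0.0)
        assert predict_colour(dec, trial) == expected

    def test_tie_at_threshold_goes_green(self):
        dec = rd.ColourLNDecoder(np.array([1.5]), 0.0, 1.5, 12.5, 12.5)
        trial = ColourTrial(np.array([1.0]), RED, 0.3, 0.0)
        assert linear_estimate(dec, trial) == dec.threshold
        assert predict_colour(dec, trial) == GREEN

    def test_length_mismatch_rejected(self):
        dec = rd.ColourLNDecoder(np.zeros(30), 0.0, 1.5)
        with pytest.raises(ValueError, match="lags"):
            predict_colour(dec, ColourTrial(np.zeros(10), RED, 0.3, 0.0))

    def test_tuned_cell_error_below_10_percent(self, tuned_recording):
        stim, train = tuned_recording
        fit, test = split_half(make_colour_trials(train, stim))
        dec = fit_colour_ln(fit)
        err = np.mean([predict_colour(dec, t) != t.colour for t in test])
        assert err < 0.10

    def test_untuned_cell_is_at_chance(self):
        from rgcdecode.synthdata import sample_cell_params

        stim = rd.generate_stimulus(500, seed=21)
        p = sample_cell_params("untuned", "u", np.random.default_rng(21))
        train = rd.simulate_cell(p, stim, seed=22)
        fit, test = split_half(make_colour_trials(train, stim))
        dec = fit_colour_ln(fit)
        acc = np.mean([predict_colour(dec, t) == t.colour for t in test])
        assert abs(acc - 0.5) < 4 * 0.5 / np.sqrt(len(test))


class TestFirstSpike:
    def test_perfect_separation_at_170ms(self):
        # green latencies below 170 ms, red above: training decisions perfect
        pairs = [(100.0 + i, GREEN) for i in range(20)] + [
            (200.0 + i, RED) for i in range(20)
        ]
        dec = fit_first_spike(pairs)
        assert all(predict_colour_first_spike(dec, l) == c for l, c in pairs)

    def test_single_trial_per_colour_still_normalised(self):
        dec = fit_first_spike([(50.0, RED), (150.0, GREEN)])
        assert np.allclose(dec.conditionals.sum(axis=0), 1.0)

    def test_ml_equals_bruteforce_argmax_per_bin(self, tuned_recording):
        stim, train = tuned_recording
        pairs = [
            (l, c) for l, c, _ in first_spike_latencies(train, stim) if l is not None
        ]
        dec = fit_first_spike(pairs)
        cond = dec.conditionals
        for b in range(dec.joint.shape[0]):
            lat = b * dec.latency_bin + 0.5 * dec.latency_bin
            got = predict_colour_first_spike(dec, lat)
            if cond[b, GREEN - 1] > cond[b, RED - 1]:
                assert got == GREEN
            elif cond[b, RED - 1] > cond[b, GREEN - 1]:
                assert got == RED
            else:
                assert got == dec.no_spike_rule

    def test_no_spike_falls_back_to_configured_label(self):
        dec = fit_first_spike([(50.0, RED), (150.0, GREEN)])
        assert predict_colour_first_spike(dec, None) == RED

    def test_accuracy_close_to_ln_on_tuned_cells(self):
        # both readouts extract similar colour information from tuned
        # cells; residual baseline spikes ahead of the response cost the
        # first-spike readout a few percentage points, so compare means
        # over several cells with that margin
        from rgcdecode.synthdata import sample_cell_params

        gaps = []
        for seed in (51, 52, 53):
            stim = rd.generate_stimulus(500, seed=seed)
            p = sample_cell_params("tuned", "t", np.random.default_rng(seed))
            train = rd.simulate_cell(p, stim, seed=seed + 500)
            fit, test = split_half(make_colour_trials(train, stim))
            ln = fit_colour_ln(fit)
            ln_acc = np.mean([predict_colour(ln, t) == t.colour for t in test])
            pairs = [(l, c) for l, c, _ in first_spike_latencies(train, stim)]
            fit_p, test_p = split_half(pairs)
            fs = fit_first_spike(fit_p)
            fs_acc = np.mean(
                [predict_colour_first_spike(fs, l) == c for l, c in test_p]
            )
            gaps.append(ln_acc - fs_acc)
        assert np.mean(gaps) < 0.08

    def test_monotone_in_latency_separation(self):
        from rgcdecode.synthdata import CellParams

        stim = rd.generate_stimulus(250, seed=31)
        accs = []
        for sep in (0.0, 30.0, 70.0):
            vals = []
            for seed in (1, 2):
                p = CellParams(
                    "c", 8.0, "OFF", gain={"red": 4.0, "green": 4.0},
                    latency={"red": 130.0 + sep, "green": 130.0},
                    gain_slope=0.0, suppression=0.9,
                )
                train = rd.simulate_cell(p, stim, seed=seed)
                fit, test = split_half(make_colour_trials(train, stim))
                dec = fit_colour_ln(fit)
                vals.append(
                    np.mean([predict_colour(dec, t) == t.colour for t in test])
                )
            accs.append(np.mean(vals))
        # allow small Monte-Carlo slack
        assert accs[1] >= accs[0] - 0.05 and accs[2] >= accs[1] - 0.05


class TestErrorByIntensity:
    def test_no_errors_gives_zero_contributions(self):
        out = error_by_intensity(
            np.ones(10, bool), np.linspace(0.1, 0.6, 10),
            np.array([RED, GREEN] * 5), n_windows=4,
        )
        assert np.all(out[RED] == 0) and np.all(out[GREEN] == 0)

    def test_all_errors_in_one_window(self):
        correct = np.array([False, False, True, True])
        inten = np.array([0.1, 0.12, 0.5, 0.6])
        colours = np.array([RED, RED, RED, RED])
        out = error_by_intensity(correct, inten, colours, n_windows=5,
                                 intensity_range=(0.07, 0.7))
        assert out[RED][0] == 1.0 and out[RED][1:].sum() == 0

    def test_intensity_independent_errors_spread_uniformly(self):
        rng = np.random.default_rng(4)
        n = 20000
        inten = rng.uniform(0.07, 0.7, n)
        colours = rng.choice([RED, GREEN], n)
        correct = rng.random(n) > 0.2  # errors independent of intensity
        out = error_by_intensity(correct, inten, colours, n_windows=5,
                                 intensity_range=(0.07, 0.7))
        for colour in (RED, GREEN):
            assert np.allclose(out[colour].sum(), 1.0)
            # multinomial 4-sigma band around uniform 0.2
            n_err = ((~correct) & (colours == colour)).sum()
            band = 4 * np.sqrt(0.2 * 0.8 / n_err)
            assert np.all(np.abs(out[colour] - 0.2) < band)
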