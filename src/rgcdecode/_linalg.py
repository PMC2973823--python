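"""Shared least-squares machinery for the linear-nonlinear readouts."""

from __future__ import annotations

import warnings

import numpy as np

RIDGE = 1e-6  # default Tikhonov shift on the Gram matrix, for conditioning


def ridge_lstsq(X: np.ndarray, y: np.ndarray, ridge: float = RIDGE) -> np.ndarray:
    """Solve min ||Xw + c − y||² via normal equations with a small ridge.

    Returns the stacked solution [w..., c] (the intercept is appended as a
    column of ones and is ridged together with the weights; the shift is
    small enough to be irrelevant for well-posed problems).  Singular
    designs fall back to the pseudo-inverse with a warning.
    """
    A = np.column_stack([X, np.ones(X.shape[0])])
    G = A.T @ A
    G[np.diag_indices_from(G)] += ridge
    b = A.T @ y
    try:
        return np.linalg.solve(G, b)
    except np.linalg.LinAlgError:
        warnings.warn("singular design; using pseudo-inverse solution")
        return np.linalg.pinv(G) @ b


def best_threshold(
    shat: np.ndarray, labels: np.ndarray, hi_label: int, lo_label: int
) -> float:
    """Threshold minimising misclassification count for 'hi iff shat >= θ'.

    Candidates are midpoints between consecutive sorted unique estimates,
    plus sentinels below/above all of them — an exact, deterministic search
    (no generic optimiser).  When several candidates tie, the midpoint of
    the lowest and highest optimal candidates is returned (the centre of
    the separating margin when the classes separate cleanly).
    """
    shat = np.asarray(shat, dtype=float)
    u = np.unique(shat)
    if u.size == 0:
        return 0.0
    cands = np.concatenate([[u[0] - 1.0], (u[:-1] + u[1:]) / 2.0, [u[-1] + 1.0]])
    errs = np.array([
        np.sum(np.where(shat >= th, hi_label, lo_label) != labels) for th in cands
    ])
    opt_c = cands[errs == errs.min()]
    centre = (opt_c[0] + opt_c[-1]) / 2.0
    return float(opt_c[np.argmin(np.abs(opt_c - centre))])
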