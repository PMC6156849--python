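"""Percent-spliced-in (Ψ) estimation via penalized non-negative least squares.

The measured signal of a path is modeled as S_i = a_i · t_i, the product of
an affinity (probe affinity on arrays, effective length for sequencing
coverage) and the concentration of the isoforms using the path. Because the
isoforms through the reference path are exactly those through Path 1 plus
those through Path 2,

    S_R = u·S1 + v·S2,   u = a_R/a_1,  v = a_R/a_2,

and Ψ per sample follows directly from signal values:

    Ψ = t1/(t1 + t2) = u·S1 / (u·S1 + v·S2).

u and v are estimated by NNLS on the stacked per-sample signal rows with
three penalty rows that pull u and v together and towards 1 (affinities of
the three paths are expected to be similar):

    A = [[S1, S2], [λ, −λ], [λ, 0], [0, λ]],  b = [S_R, 0, λ, λ].

The relative residual error ε = ‖u·S1 + v·S2 − S_R‖₂/‖S_R‖₂ measures how
well the additive model fits; events with large ε are measured incoherently
and their estimates are less reliable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import nnls

#: λ as a fraction of the root-mean-square reference signal. The estimates
#: are insensitive to λ whenever the event shows differential splicing; the
#: scale factor keeps the penalty rows commensurate with the signal rows.
DEFAULT_LAMBDA_SCALE = 0.1


@dataclass
class UVEstimate:
    u: float
    v: float
    lambda_: float
    epsilon: float
    degenerate: bool = False


@dataclass
class PsiProfile:
    psi: np.ndarray  # per-sample Ψ, NaN where u·S1 + v·S2 = 0
    delta_psi: Optional[float] = None


def _validate(S1, S2, SR=None):
    S1 = np.asarray(S1, dtype=float)
    S2 = np.asarray(S2, dtype=float)
    arrays = [S1, S2]
    if SR is not None:
        SR = np.asarray(SR, dtype=float)
        arrays.append(SR)
    n = {a.shape for a in arrays}
    if len(n) != 1 or arrays[0].ndim != 1:
        raise ValueError("S1, S2, SR must be 1-D vectors of equal length")
    for a in arrays:
        if np.any(a < 0) or not np.all(np.isfinite(a)):
            raise ValueError("signals must be finite and non-negative")
    return (S1, S2, SR) if SR is not None else (S1, S2)


def summarize_path_signal(edge_signals: np.ndarray) -> np.ndarray:
    """Summarize per-edge signals into one path signal per sample.

    ``edge_signals`` has shape (n_edges, n_samples); the summary is the
    arithmetic mean across edges.
    """
    arr = np.atleast_2d(np.asarray(edge_signals, dtype=float))
    if arr.size == 0:
        raise ValueError("path has no edges to summarize")
    return arr.mean(axis=0)


def default_lambda(SR: Sequence[float], scale: float = DEFAULT_LAMBDA_SCALE) -> float:
    """λ = scale × RMS(S_R); falls back to ``scale`` itself when S_R ≡ 0."""
    SR = np.asarray(SR, dtype=float)
    rms = float(np.sqrt(np.mean(SR**2)))
    return scale * rms if rms > 0 else scale


def relative_error(S1, S2, SR, uv: UVEstimate) -> float:
    """ε = ‖(u·S1 + v·S2) − S_R‖₂ / ‖S_R‖₂ (NaN when S_R ≡ 0)."""
    S1, S2, SR = _validate(S1, S2, SR)
    denom = np.linalg.norm(SR)
    if denom == 0:
        return float("nan")
    return float(np.linalg.norm(uv.u * S1 + uv.v * S2 - SR) / denom)


def estimate_uv(S1, S2, SR, lambda_: Optional[float] = None) -> UVEstimate:
    """Estimate the affinity fractions (u, v) for one event.

    Solves min ‖Ax − b‖₂ subject to x ≥ 0 with the penalty construction
    above; the per-sample signal rows of every sample are stacked into one
    problem. When all signals are zero the penalty rows dominate and the
    estimate degenerates to u = v = 1.
    """
    S1, S2, SR = _validate(S1, S2, SR)
    if lambda_ is None:
        lambda_ = default_lambda(SR)
    if lambda_ <= 0:
        raise ValueError("lambda_ must be positive")
    if not (np.any(S1) or np.any(S2) or np.any(SR)):
        return UVEstimate(u=1.0, v=1.0, lambda_=lambda_, epsilon=0.0, degenerate=True)
    lam = float(lambda_)
    A = np.vstack([
        np.column_stack([S1, S2]),
        [[lam, -lam], [lam, 0.0], [0.0, lam]],
    ])
    b = np.concatenate([SR, [0.0, lam, lam]])
    x, _ = nnls(A, b)
    uv = UVEstimate(u=float(x[0]), v=float(x[1]), lambda_=lam, epsilon=0.0)
    uv.epsilon = relative_error(S1, S2, SR, uv)
    if np.isnan(uv.epsilon):
        uv.degenerate = True
        uv.epsilon = 0.0
    return uv


def compute_psi(
    S1,
    S2,
    uv: UVEstimate,
    condition: Optional[Sequence] = None,
) -> PsiProfile:
    """Per-sample Ψ = u·S1/(u·S1 + v·S2); NaN where the denominator is zero.

    With two-level ``condition`` labels, ΔΨ is the difference of condition
    means (second level minus first, levels in order of first appearance),
    skipping undefined samples.
    """
    S1, S2 = _validate(S1, S2)
    num = uv.u * S1
    den = uv.u * S1 + uv.v * S2
    with np.errstate(invalid="ignore", divide="ignore"):
        psi = np.where(den > 0, num / np.maximum(den, 1e-300), np.nan)
    profile = PsiProfile(psi=psi)
    if condition is not None:
        condition = np.asarray(condition)
        levels = list(dict.fromkeys(condition.tolist()))
        if len(levels) == 2:
            m = [np.nanmean(psi[condition == lv]) if np.any(~np.isnan(psi[condition == lv]))
                 else np.nan for lv in levels]
            profile.delta_psi = float(m[1] - m[0])
    return profile
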