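"""Differential-splicing statistics.

Counts from sequencing are transformed to log2-CPM with observation-level
precision weights derived from a fitted mean–variance trend (the voom
scheme); array signals enter as log2 values with unit weights. Each path of
each event is then fit with a weighted linear model under a user design, the
contrast of interest is extracted, and residual variances are moderated by
empirical-Bayes shrinkage towards a common prior before computing moderated
t-statistics.

An event is called significant when the two alternative paths change in
opposite directions (opposite fold-change signs) and the summarized p-value
— the maximum of the two path p-values, an intersection-union test — is
below 0.001; it is non-significant when the summarized p-value exceeds 0.2
or the directions agree, and inconclusive otherwise.

The null proportion π0 is estimated from the p-value histogram above 0.5
(Storey's estimator at λ = 0.5) and converted to FDR/q-values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats as sps
from statsmodels.nonparametric.smoothers_lowess import lowess

logger = logging.getLogger(__name__)

SIG_THRESHOLD = 0.001
NONSIG_THRESHOLD = 0.2
MIN_ROWS_FOR_TREND = 50
P_SUMMARY_METHODS = ("max", "fisher", "irwin_hall")


@dataclass
class DesignSpec:
    """Design matrix (samples × covariates) and a contrast in its row space."""

    design: np.ndarray
    contrast: np.ndarray
    column_names: Optional[list] = None

    def __post_init__(self) -> None:
        self.design = np.atleast_2d(np.asarray(self.design, dtype=float))
        self.contrast = np.asarray(self.contrast, dtype=float).ravel()
        n, p = self.design.shape
        if self.contrast.shape[0] != p:
            raise ValueError("contrast length must equal number of design columns")
        if self.column_names is None:
            self.column_names = [f"x{j}" for j in range(p)]
        if np.linalg.matrix_rank(self.design) < p:
            raise ValueError(
                "design matrix is rank deficient; collinear columns among "
                + ", ".join(self.column_names)
            )

    @classmethod
    def from_factors(
        cls, block: Sequence, treatment: Sequence, test_level=None
    ) -> "DesignSpec":
        """Additive design: intercept + block (e.g. cell line) + treatment.

        No block×treatment interaction is included; the contrast tests the
        treatment effect (``test_level`` vs. the reference level).
        """
        block = np.asarray(block)
        treatment = np.asarray(treatment)
        b_levels = list(dict.fromkeys(block.tolist()))
        t_levels = list(dict.fromkeys(treatment.tolist()))
        if test_level is None:
            test_level = t_levels[-1]
        cols = [np.ones(len(block))]
        names = ["intercept"]
        for lv in b_levels[1:]:
            cols.append((block == lv).astype(float))
            names.append(f"block_{lv}")
        for lv in t_levels[1:]:
            cols.append((treatment == lv).astype(float))
            names.append(f"treatment_{lv}")
        design = np.column_stack(cols)
        contrast = np.zeros(design.shape[1])
        contrast[names.index(f"treatment_{test_level}")] = 1.0
        return cls(design, contrast, names)


@dataclass
class EventTestResult:
    event_id: str
    logfc1: float
    logfc2: float
    p1: float
    p2: float
    p_summary: float
    direction_ok: bool
    sig_class: str  # {"significant", "inconclusive", "non_significant"}


@dataclass
class FdrResult:
    pi0: float
    fdr_at_threshold: float
    q_values: np.ndarray
    threshold: float


@dataclass
class LinearFit:
    coefficients: np.ndarray  # per-row contrast estimates
    stdev_unscaled: float  # sqrt(cᵗ (XᵗWX)⁻¹ c), per row when weighted
    sigma2: np.ndarray  # residual variances
    df_residual: float
    stdev_unscaled_rows: Optional[np.ndarray] = None


def voom_transform(
    counts: np.ndarray,
    library_sizes: Sequence[float],
    design: Optional[np.ndarray] = None,
    span: float = 0.5,
):
    """Counts → (log2-CPM matrix, precision weights).

    y = log2((count + 0.5)/(library_size + 1) × 1e6). Row-wise residual
    standard deviations under the design are paired with mean log2 counts, a
    lowess trend of sqrt(sd) versus mean log-count is fitted, and each
    observation's weight is the predicted sqrt-sd at its fitted log-count
    raised to the −4th power. With fewer rows than the trend can support,
    unit weights are returned.
    """
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    lib = np.asarray(library_sizes, dtype=float)
    if np.any(lib <= 0):
        raise ValueError("library sizes must be positive")
    n_rows, n_samples = counts.shape
    y = np.log2((counts + 0.5) / (lib + 1.0)[None, :] * 1e6)
    if design is None:
        design = np.ones((n_samples, 1))
    design = np.atleast_2d(np.asarray(design, dtype=float))
    p = design.shape[1]
    df = n_samples - p
    if df <= 0:
        raise ValueError("design leaves no residual degrees of freedom")

    Q, _ = np.linalg.qr(design)
    fitted = y @ Q @ Q.T  # hat-matrix projection, shared across rows
    resid = y - fitted
    s = np.sqrt((resid**2).sum(axis=1) / df)

    if n_rows < MIN_ROWS_FOR_TREND:
        logger.warning(
            "voom: only %d rows (< %d); falling back to unit weights",
            n_rows, MIN_ROWS_FOR_TREND,
        )
        return y, np.ones_like(y)

    mean_log_count = y.mean(axis=1) + np.mean(np.log2(lib + 1.0)) - np.log2(1e6)
    sqrt_sd = np.sqrt(s)
    trend = lowess(sqrt_sd, mean_log_count, frac=span, return_sorted=True)
    tx, ty = trend[:, 0], trend[:, 1]

    fitted_log_count = fitted + (np.log2(lib + 1.0) - np.log2(1e6))[None, :]
    pred = np.interp(fitted_log_count, tx, ty)
    pred = np.clip(pred, max(1e-6, float(ty.min()) * 1e-3), None)
    weights = pred**-4
    return y, weights


def fit_contrasts(
    signal: np.ndarray,
    weights: Optional[np.ndarray],
    design: DesignSpec,
) -> LinearFit:
    """Row-wise weighted least squares; returns contrast estimates and SEs.

    Estimates are invariant to a common rescaling of the weights.
    """
    signal = np.atleast_2d(np.asarray(signal, dtype=float))
    n_rows, n_samples = signal.shape
    X = design.design
    c = design.contrast
    p = X.shape[1]
    df = n_samples - p
    if df <= 0:
        raise ValueError("design leaves no residual degrees of freedom")
    if weights is None:
        weights = np.ones_like(signal)
    weights = np.atleast_2d(np.asarray(weights, dtype=float))
    if weights.shape != signal.shape:
        weights = np.broadcast_to(weights, signal.shape).copy()

    coefs = np.empty(n_rows)
    sigma2 = np.empty(n_rows)
    unscaled = np.empty(n_rows)
    for i in range(n_rows):
        w = weights[i]
        sw = np.sqrt(w)
        Xw = X * sw[:, None]
        yw = signal[i] * sw
        XtX = Xw.T @ Xw
        XtX_inv = np.linalg.pinv(XtX)
        beta = XtX_inv @ (Xw.T @ yw)
        resid = yw - Xw @ beta
        coefs[i] = float(c @ beta)
        sigma2[i] = float(resid @ resid) / df
        unscaled[i] = float(np.sqrt(c @ XtX_inv @ c))
    return LinearFit(
        coefficients=coefs,
        stdev_unscaled=float(np.median(unscaled)),
        sigma2=sigma2,
        df_residual=float(df),
        stdev_unscaled_rows=unscaled,
    )


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton iterations)."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def fit_variance_prior(sigma2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of (d0, s0²) on log residual variances.

    Models s² ~ s0² · F(df, d0); matching the mean and variance of
    log(s²) gives the prior degrees of freedom d0 and prior variance s0².
    """
    s2 = np.asarray(sigma2, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0)
    if ok.sum() < 2:
        return np.inf, float(np.nanmean(s2[ok])) if ok.any() else 1.0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(e.mean())
    e_var = float(e.var(ddof=1)) - float(special.polygamma(1, df / 2.0))
    if e_var <= 0:
        d0 = np.inf
        s0_2 = float(np.exp(e_mean))
    else:
        d0 = 2.0 * _trigamma_inverse(e_var)
        s0_2 = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_2


def moderate(
    coefficients: np.ndarray,
    stdev_unscaled: np.ndarray,
    sigma2: np.ndarray,
    df: float,
    d0: Optional[float] = None,
    s0_2: Optional[float] = None,
):
    """Empirical-Bayes moderated t-test p-values.

    Posterior variance s̃² = (d0·s0² + df·s²)/(d0 + df); t = β/(s̃·SE_unscaled)
    with d0 + df degrees of freedom. With d0 = 0 this is the ordinary t-test;
    as d0 → ∞ all variances shrink to s0².
    """
    coefficients = np.asarray(coefficients, dtype=float)
    sigma2 = np.asarray(sigma2, dtype=float)
    stdev_unscaled = np.broadcast_to(
        np.asarray(stdev_unscaled, dtype=float), coefficients.shape
    )
    bad = ~np.isfinite(sigma2)
    if bad.any():
        logger.warning("moderate: dropping %d rows with non-finite variances", bad.sum())
    if d0 is None or s0_2 is None:
        if len(sigma2[~bad]) < 10:
            raise ValueError("need >= 10 rows to estimate the variance prior")
        d0, s0_2 = fit_variance_prior(sigma2[~bad], df)
    if np.isinf(d0):
        s2_post = np.full_like(sigma2, s0_2)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_2 + df * sigma2) / (d0 + df)
        df_total = d0 + df
    with np.errstate(divide="ignore", invalid="ignore"):
        t = coefficients / (np.sqrt(s2_post) * stdev_unscaled)
    if np.isinf(df_total):
        p = 2.0 * sps.norm.sf(np.abs(t))
    else:
        p = 2.0 * sps.t.sf(np.abs(t), df_total)
    p = np.where(bad, np.nan, p)
    return t, p, s2_post, df_total


def summarize_p(p1: float, p2: float, method: str = "max") -> float:
    """Combine the two path p-values into the summarized event p-value."""
    if method == "max":
        return max(p1, p2)
    if method == "fisher":
        stat = -2.0 * (np.log(max(p1, 1e-300)) + np.log(max(p2, 1e-300)))
        return float(sps.chi2.sf(stat, 4))
    if method == "irwin_hall":
        s = p1 + p2  # sum of two uniforms
        cdf = s**2 / 2.0 if s <= 1 else 1.0 - (2.0 - s) ** 2 / 2.0
        return float(cdf)
    raise ValueError(f"unknown p-summary method {method!r}")


def summarize_event(
    event_id: str,
    p1: float,
    p2: float,
    logfc1: float,
    logfc2: float,
    sig_threshold: float = SIG_THRESHOLD,
    nonsig_threshold: float = NONSIG_THRESHOLD,
    method: str = "max",
) -> EventTestResult:
    """Apply the opposite-sign + summarized-p decision rule to one event.

    significant: opposite fold-change signs and p_summary < sig_threshold;
    non-significant: same-sign (or zero) fold changes, or
    p_summary > nonsig_threshold; inconclusive otherwise.
    """
    p_summary = summarize_p(p1, p2, method)
    direction_ok = bool(np.sign(logfc1) == -np.sign(logfc2) and np.sign(logfc1) != 0)
    if direction_ok and p_summary < sig_threshold:
        sig_class = "significant"
    elif (not direction_ok) or p_summary > nonsig_threshold:
        sig_class = "non_significant"
    else:
        sig_class = "inconclusive"
    return EventTestResult(
        event_id=event_id,
        logfc1=float(logfc1),
        logfc2=float(logfc2),
        p1=float(p1),
        p2=float(p2),
        p_summary=float(p_summary),
        direction_ok=direction_ok,
        sig_class=sig_class,
    )


def estimate_pi0_fdr(p: np.ndarray, threshold: float = SIG_THRESHOLD) -> FdrResult:
    """Storey π0 at λ = 0.5, plug-in FDR at a p cutoff, and q-values.

    π̂0 = #{p > 0.5}/(0.5·m) clipped to [0, 1];
    FDR(t) = π̂0·m·t / #{p ≤ t}; q-values by step-up monotonization.
    """
    p = np.asarray(p, dtype=float)
    p = p[np.isfinite(p)]
    m = len(p)
    if m == 0:
        raise ValueError("no p-values")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    pi0 = float(np.clip(np.sum(p > 0.5) / (0.5 * m), 0.0, 1.0))
    n_sig = int(np.sum(p <= threshold))
    fdr_at = float(pi0 * m * threshold / n_sig) if n_sig > 0 else float("nan")

    order = np.argsort(p)
    ranked = p[order]
    raw = pi0 * m * ranked / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(raw[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return FdrResult(pi0=pi0, fdr_at_threshold=fdr_at, q_values=q, threshold=threshold)


def subsample_counts(
    counts: np.ndarray,
    fraction: float,
    seed: int,
    library_sizes: Optional[Mapping] = None,
):
    """Binomial thinning of a count matrix to a given depth fraction.

    Each count is replaced by Binomial(count, fraction); library sizes are
    rescaled by the same fraction. Deterministic under a fixed seed.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must be in (0, 1]")
    counts = np.asarray(counts)
    if fraction == 1.0:
        thinned = counts.copy()
    else:
        rng = np.random.default_rng(seed)
        thinned = rng.binomial(counts.astype(np.int64), fraction)
    if library_sizes is None:
        return thinned
    scaled = {k: v * fraction for k, v in library_sizes.items()}
    return thinned, scaled
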