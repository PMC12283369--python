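"""Expression-decile dose-response curves and Hill-equation fits.

The dosage question: does target-gene lethality track anchor expression
continuously, like a drug dose-response? Cell lines are split into ten
near-equal expression deciles; each bin contributes its median gene effect
(with interquartile range) at its mean expression, and a Hill curve

    y = bottom + (top - bottom) / (1 + (d50 / d)^h),   d = 2^x

is least-squares fitted through the bin summary points. Expression is on the
log2(TPM + pseudocount) scale with pseudocount 0.0625 by default; ``bottom``
is the maximal-lethality asymptote (gene effect near -1), ``top`` the
no-lethality asymptote (near 0), and ``ec50`` the expression at half response.
The fraction of samples below the half-max expression measures how much of
the panel shows at least half the maximal synthetic lethality.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .core_data import Scale

__all__ = [
    "DecileBin",
    "DecileCurve",
    "DoseResponseFit",
    "decile_curve",
    "fit_hill",
    "half_max_fraction",
    "hill_response",
    "to_log2_pseudocount",
]

DEFAULT_PSEUDOCOUNT = 0.0625
N_BINS = 10
MAX_NFEV = 20_000


def to_log2_pseudocount(
    values: np.ndarray, input_scale: Scale, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> np.ndarray:
    """Convert expression values to log2(TPM + pseudocount) via linear TPM."""
    values = np.asarray(values, dtype=float)
    if input_scale == Scale.linear_tpm:
        lin = values
    elif input_scale == Scale.log2_tpm_plus1:
        lin = np.exp2(values) - 1.0
    elif input_scale == Scale.log2_tpm_plus_1_16:
        lin = np.exp2(values) - 0.0625
    else:  # pragma: no cover
        raise ValueError(f"unknown scale {input_scale!r}")
    return np.log2(np.clip(lin, 0.0, None) + pseudocount)


@dataclass(frozen=True)
class DecileBin:
    center: float  # mean expression of members, log2(TPM + pseudocount)
    median: float  # central lethality (gene effect)
    q25: float
    q75: float
    count: int


@dataclass
class DecileCurve:
    bins: list[DecileBin]
    pseudocount: float
    n: int

    @property
    def centers(self) -> np.ndarray:
        return np.array([b.center for b in self.bins])

    @property
    def medians(self) -> np.ndarray:
        return np.array([b.median for b in self.bins])


@dataclass
class DoseResponseFit:
    bottom: float  # maximal-lethality asymptote (gene effect)
    top: float  # no-lethality asymptote
    ec50: float  # expression at half response, log2(TPM + pseudocount)
    hill_slope: float
    fit_r: float  # Pearson between fitted and observed bin values
    pseudocount: float

    @property
    def half_max_expression(self) -> float:
        return self.ec50


def hill_response(
    x: np.ndarray, bottom: float, top: float, ec50: float, hill_slope: float
) -> np.ndarray:
    """Hill curve evaluated at log2-scale expression x (dose d = 2^x)."""
    x = np.asarray(x, dtype=float)
    # (d50/d)^h = 2^((ec50 - x) * h); compute in log space for stability
    return bottom + (top - bottom) / (1.0 + np.exp2((ec50 - x) * hill_slope))


def decile_curve(
    expression: np.ndarray,
    lethality: np.ndarray,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    input_scale: Scale = Scale.log2_tpm_plus1,
) -> DecileCurve:
    """Split paired (expression, lethality) samples into 10 expression deciles.

    Rank-based split with a stable sort so ties stay together: when a tie
    block straddles a bin boundary the boundary moves to the end of the
    block, so counts can deviate from equality in heavily tied data. The
    remainder of n/10 is spread from the lowest bin upward.
    """
    expression = np.asarray(expression, dtype=float)
    lethality = np.asarray(lethality, dtype=float)
    if expression.shape != lethality.shape:
        raise ValueError("paired vectors required")
    mask = ~(np.isnan(expression) | np.isnan(lethality))
    x = to_log2_pseudocount(expression[mask], input_scale, pseudocount)
    y = lethality[mask]
    n = x.size
    if n < 20:
        raise ValueError(f"need >= 20 paired samples, got {n}")

    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]

    base, rem = divmod(n, N_BINS)
    sizes = [base + (1 if i < rem else 0) for i in range(N_BINS)]
    edges = np.cumsum(sizes)[:-1]
    # move each edge to the end of any tie block it splits
    adj = []
    for e in edges:
        while 0 < e < n and xs[e] == xs[e - 1]:
            e += 1
        adj.append(e)
    bounds = [0] + sorted(set(min(e, n) for e in adj)) + [n]
    bounds = sorted(set(bounds))

    bins = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        if hi <= lo:
            continue
        seg_x, seg_y = xs[lo:hi], ys[lo:hi]
        bins.append(
            DecileBin(
                center=float(np.mean(seg_x)),
                median=float(np.median(seg_y)),
                q25=float(np.percentile(seg_y, 25)),
                q75=float(np.percentile(seg_y, 75)),
                count=int(hi - lo),
            )
        )
    return DecileCurve(bins=bins, pseudocount=pseudocount, n=n)


def fit_hill(curve: DecileCurve) -> DoseResponseFit:
    """Least-squares Hill fit through the decile summary points.

    Deterministic initialization: bottom = min median, top = max median,
    ec50 = the center of the steepest adjacent-bin segment, slope = 1.
    Raises on constant response or non-convergence.
    """
    xc = curve.centers
    yc = curve.medians
    if len(xc) < 4 or len(np.unique(xc)) < 4:
        raise ValueError("need >= 4 bins with distinct centers")
    if np.ptp(yc) == 0:
        raise ValueError("constant response: no dose-response to fit")

    slopes = np.diff(yc) / np.maximum(np.diff(xc), 1e-12)
    k = int(np.argmax(np.abs(slopes)))
    ec50_0 = 0.5 * (xc[k] + xc[k + 1])
    p0 = [float(yc.min()), float(yc.max()), float(ec50_0), 1.0]

    try:
        with warnings.catch_warnings():
            # the parameter covariance is unused; a singular Jacobian on
            # perfectly-fit data is not an error here
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, _ = optimize.curve_fit(
                hill_response, xc, yc, p0=p0, maxfev=MAX_NFEV, method="lm"
            )
    except RuntimeError as exc:
        raise RuntimeError(
            f"Hill fit did not converge within {MAX_NFEV} evaluations: {exc}"
        ) from exc
    bottom, top, ec50, slope = (float(v) for v in popt)
    if slope < 0:
        # same curve with swapped asymptotes and flipped slope sign
        bottom, top, slope = top, bottom, -slope
    fitted = hill_response(xc, bottom, top, ec50, slope)
    if np.ptp(fitted) == 0:
        fit_r = float("nan")
    else:
        fit_r = float(stats.pearsonr(fitted, yc)[0])
    return DoseResponseFit(
        bottom=bottom,
        top=top,
        ec50=ec50,
        hill_slope=slope,
        fit_r=fit_r,
        pseudocount=curve.pseudocount,
    )


def half_max_fraction(
    expression: np.ndarray,
    fit: DoseResponseFit,
    input_scale: Scale = Scale.log2_tpm_plus1,
) -> tuple[int, int, float]:
    """Count samples whose expression sits strictly below the half-max level.

    These are the samples showing at least half of the maximal synthetic
    lethality. Returns (n_below, n_total, pct_below).
    """
    x = to_log2_pseudocount(
        np.asarray(expression, dtype=float), input_scale, fit.pseudocount
    )
    x = x[~np.isnan(x)]
    n_total = int(x.size)
    n_below = int(np.sum(x < fit.half_max_expression))
    pct = 100.0 * n_below / n_total if n_total else float("nan")
    return n_below, n_total, pct
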