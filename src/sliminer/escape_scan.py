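"""Partial-correlation scan for features that modulate target lethality.

If the anchor gene fully explains target-gene lethality, no other feature
should correlate with lethality once the anchor's (linear) effect is removed.
The scan therefore computes, for every gene-level feature (RNA expression,
damaging and hotspot mutations), the partial Pearson correlation with the
target's gene effect controlling for anchor expression:

    r_xy.z = (r_xy - r_xz * r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2))

with a two-sided p from the t-transform on n-3 degrees of freedom. Binary
mutation features enter the same product-moment formula (point-biserial).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .core_data import FeatureMatrix, GeneId, Modality
from .sli_scoring import CorrelationResult, DegenerateInputError, DEFAULT_MIN_OVERLAP

__all__ = ["EscapeRecord", "EscapeScanResult", "partial_pearson", "scan_features"]

MIN_MINOR_COUNT = 3  # binary features with fewer minor-category samples are skipped


@dataclass
class EscapeRecord:
    feature: GeneId
    modality: Modality
    partial_r: float
    p: float
    p_bonferroni: float
    n: int
    significant: bool


@dataclass
class EscapeScanResult:
    records: list[EscapeRecord]
    covariate_reference_r: float  # plain r(covariate, lethality): the "red line"
    n_tests: int
    n_skipped: int
    skip_reasons: dict[str, str]


def _plain_r(x: np.ndarray, y: np.ndarray) -> float:
    xm = x - x.mean()
    ym = y - y.mean()
    denom = np.sqrt((xm @ xm) * (ym @ ym))
    if denom == 0:
        raise DegenerateInputError("constant vector")
    return float(np.clip((xm @ ym) / denom, -1.0, 1.0))


def partial_pearson(
    x: Sequence[float], y: Sequence[float], z: Sequence[float]
) -> CorrelationResult:
    """Partial Pearson correlation of x and y controlling for z.

    Entries missing in any of the three vectors are removed listwise; needs
    n >= 4 complete triples, all vectors non-constant, and |r_xz|, |r_yz| < 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    if not (x.shape == y.shape == z.shape):
        raise ValueError("vectors must have equal length")
    mask = ~(np.isnan(x) | np.isnan(y) | np.isnan(z))
    x, y, z = x[mask], y[mask], z[mask]
    n = x.size
    if n < 4:
        raise DegenerateInputError(f"need >= 4 complete triples, got {n}")
    for v, name in ((x, "x"), (y, "y"), (z, "z")):
        if np.ptp(v) == 0:
            raise DegenerateInputError(f"constant vector {name}")
    r_xy = _plain_r(x, y)
    r_xz = _plain_r(x, z)
    r_yz = _plain_r(y, z)
    if abs(r_xz) >= 1.0 or abs(r_yz) >= 1.0:
        raise DegenerateInputError("covariate collinear with an input")
    pr = (r_xy - r_xz * r_yz) / np.sqrt((1.0 - r_xz**2) * (1.0 - r_yz**2))
    pr = float(np.clip(pr, -1.0, 1.0))
    df = n - 3
    if abs(pr) >= 1.0:
        p = np.nextafter(0.0, 1.0)
    else:
        t = pr * np.sqrt(df / (1.0 - pr * pr))
        p = 2.0 * stats.t.sf(abs(t), df)
    return CorrelationResult(r=pr, p=float(min(p, 1.0)), n=int(n))


def scan_features(
    features: FeatureMatrix,
    lethality: Sequence[float],
    covariate: Sequence[float],
    samples: Sequence[str] | None = None,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    alpha: float = 0.05,
    exclude_symbols: Sequence[str] = (),
) -> EscapeScanResult:
    """Partial-correlate every feature with lethality, controlling the anchor.

    ``lethality`` and ``covariate`` are vectors over ``samples`` (defaulting
    to the feature matrix's sample order). Features identical to the
    covariate, constant features, and binary features with a minor-category
    count below 3 are skipped with a recorded reason; Bonferroni is over the
    valid tests. ``exclude_symbols`` removes e.g. the target and anchor rows
    themselves.
    """
    if samples is None:
        samples = features.samples
    col_idx = [features.samples.index(s) for s in samples]
    data = features.data.to_numpy(dtype=float)[:, col_idx]
    leth = np.asarray(lethality, dtype=float)
    cov = np.asarray(covariate, dtype=float)
    if leth.size != len(samples) or cov.size != len(samples):
        raise ValueError("lethality/covariate length must match sample count")

    base_mask = ~(np.isnan(leth) | np.isnan(cov))
    ref_r = _plain_r(cov[base_mask], leth[base_mask])

    results: list[tuple[GeneId, Modality, CorrelationResult]] = []
    skip_reasons: dict[str, str] = {}
    excl = set(exclude_symbols)
    for gi, (gene, mod) in enumerate(zip(features.genes, features.modalities)):
        key = f"{gene.symbol}|{mod.value}"
        if gene.symbol in excl:
            skip_reasons[key] = "excluded"
            continue
        x = data[gi]
        mask = base_mask & ~np.isnan(x)
        if mask.sum() < max(min_overlap, 4):
            skip_reasons[key] = "insufficient_overlap"
            continue
        xv = x[mask]
        if mod in (Modality.damaging_mutation, Modality.hotspot_mutation):
            minor = min(np.sum(xv == 0), np.sum(xv == 1))
            if minor < MIN_MINOR_COUNT:
                skip_reasons[key] = "minor_category_too_small"
                continue
        try:
            res = partial_pearson(xv, leth[mask], cov[mask])
        except DegenerateInputError as exc:
            skip_reasons[key] = f"degenerate: {exc}"
            continue
        results.append((gene, mod, res))

    if not results:
        raise ValueError("no valid features in escape scan")
    n_tests = len(results)
    records = [
        EscapeRecord(
            feature=gene,
            modality=mod,
            partial_r=res.r,
            p=res.p,
            p_bonferroni=min(1.0, res.p * n_tests),
            n=res.n,
            significant=min(1.0, res.p * n_tests) < alpha,
        )
        for gene, mod, res in results
    ]
    return EscapeScanResult(
        records=records,
        covariate_reference_r=ref_r,
        n_tests=n_tests,
        n_skipped=len(skip_reasons),
        skip_reasons=skip_reasons,
    )
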