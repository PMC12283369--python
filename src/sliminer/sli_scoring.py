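"""Pairwise expression-dependency scoring, hit-list construction, classifiers.

The scoring engine computes, for every (anchor, target) pair, the Pearson
correlation between anchor-gene status (RNA, protein, mutation, methylation)
and target-gene dependency (CERES/Chronos gene effect) across cell lines.
Because a synthetic-lethal anchor is LOW where knocking out the target kills
the cell (a more negative gene effect), an RNA/protein-anchored SLI shows up
as a large POSITIVE correlation; for mutation and methylation anchors the
direction of "less gene activity" is reversed, so the ranking flips sign.

The scan is vectorized with pairwise-complete handling of missing values and
must agree with the per-pair product-moment formula to 1e-10 — tests enforce
that equivalence against an independent per-pair oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .core_data import (
    DependencyMatrix,
    ExpressionMatrix,
    FeatureMatrix,
    GeneId,
    GeneMatrix,
    Modality,
    align_matrices,
)

__all__ = [
    "CorrelationResult",
    "PairScore",
    "CutoffConfig",
    "ScanResult",
    "DegenerateInputError",
    "pearson_r_p",
    "score_pairs",
    "directional_rank_key",
    "known_partner_rank",
    "build_hit_list",
    "classify_dependency",
    "classify_expression",
]

DEFAULT_MIN_OVERLAP = 30


class DegenerateInputError(ValueError):
    """Raised when a correlation is undefined (constant input, n too small)."""


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int


@dataclass
class PairScore:
    """One anchor-target candidate pair."""

    anchor: GeneId
    target: GeneId
    modality: Modality
    r: float
    r_directional: float
    p: float
    p_bonferroni: float
    n: int
    rank_within_anchor: int = 0
    hit_rank: int = 0


@dataclass
class CutoffConfig:
    """Thresholds used by the dependency/expression classifiers.

    ``lethal_ceres_below``: a cell line counts as lethal for a target when its
    gene effect is strictly below this (default -0.5, halfway between the
    non-essential 0 and core-essential -1 conventions).
    ``high_expression_cutoffs`` sit just before the high-expression peak of
    each marker gene's bimodal log2(TPM+1) histogram.
    """

    lethal_ceres_below: float = -0.5
    low_expression_below: dict[str, float] = field(
        default_factory=lambda: {"CDS1": 1.5}
    )
    high_expression_cutoffs: dict[str, float] = field(
        default_factory=lambda: {"CDS1": 2.5, "CDH1": 4.5, "ZEB1": 2.0, "VIM": 6.0}
    )
    top_fraction: float = 0.05
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.top_fraction < 1:
            raise ValueError("top_fraction must lie in (0,1)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0,1)")


# ---------------------------------------------------------------------------
# Correlation primitives
# ---------------------------------------------------------------------------


def pearson_r_p(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson r with two-sided p from the t-transform (n-2 df).

    Entries missing in either vector are removed pairwise first. Raises
    :class:`DegenerateInputError` for n < 3 or a constant vector.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    mask = ~(np.isnan(x) | np.isnan(y))
    x, y = x[mask], y[mask]
    n = x.size
    if n < 3:
        raise DegenerateInputError(f"need >= 3 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("constant vector: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(r=float(r), p=float(p), n=int(n))


def _p_from_r(r: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Two-sided p-value for Pearson r via the t-transform with n-2 df."""
    r = np.clip(r, -1.0, 1.0)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - r * r))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    # |r| == 1 -> t infinite -> p = 0; report smallest positive float so p in (0,1]
    p = np.where(np.abs(r) >= 1.0, np.nextafter(0.0, 1.0), p)
    return np.minimum(p, 1.0)


# ---------------------------------------------------------------------------
# Vectorized pairwise scan
# ---------------------------------------------------------------------------


@dataclass
class ScanResult:
    scores: list[PairScore]
    n_tests: int
    n_skipped_overlap: int
    n_skipped_constant: int

    def for_anchor(self, anchor_symbol: str) -> list[PairScore]:
        return [s for s in self.scores if s.anchor.symbol == anchor_symbol]


def _anchor_rows(
    matrix: GeneMatrix, anchors: Sequence[str] | None
) -> tuple[list[GeneId], list[Modality], np.ndarray]:
    """Extract (gene ids, modalities, value rows) for the requested anchors."""
    if isinstance(matrix, FeatureMatrix):
        ids, mods, rows = [], [], []
        for i, (g, m) in enumerate(zip(matrix.genes, matrix.modalities)):
            if anchors is None or g.symbol in anchors:
                ids.append(g)
                mods.append(m)
                rows.append(matrix.data.iloc[i].to_numpy(dtype=float))
        return ids, mods, np.asarray(rows, dtype=float)
    default_mod = Modality.rna
    if isinstance(matrix, DependencyMatrix):
        default_mod = Modality.rna  # dependency-vs-dependency scans rank like rna
    symbols = matrix.symbols
    keep = [i for i, s in enumerate(symbols) if anchors is None or s in anchors]
    ids = [matrix.genes[i] for i in keep]
    rows = matrix.data.to_numpy(dtype=float)[keep]
    return ids, [default_mod] * len(ids), rows


def score_pairs(
    anchor_matrix: GeneMatrix,
    target_matrix: GeneMatrix,
    anchors: Sequence[str] | None = None,
    targets: Sequence[str] | None = None,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    exclude_self: bool = True,
) -> ScanResult:
    """Correlate every anchor row against every target row, vectorized.

    Works for expression-vs-dependency (the SLI scan) but equally for
    expression-vs-phenotype or dependency-vs-dependency (co-dependency) scans.
    Missing values are handled pairwise-complete; pairs with fewer than
    ``min_overlap`` complete observations, or with a constant vector on the
    overlap, are skipped and counted. Bonferroni denominator = number of valid
    tests in this scan.
    """
    a_al, t_al, _ = align_matrices(anchor_matrix, target_matrix)
    anchors_set = set(anchors) if anchors is not None else None
    targets_set = set(targets) if targets is not None else None
    a_ids, a_mods, X = _anchor_rows(a_al, anchors_set)
    t_ids, _, Y = _anchor_rows(t_al, targets_set)
    if len(a_ids) == 0 or len(t_ids) == 0:
        raise ValueError("no anchors or no targets to scan")

    Mx = ~np.isnan(X)
    My = ~np.isnan(Y)
    Xz = np.where(Mx, X, 0.0)
    Yz = np.where(My, Y, 0.0)
    MxF = Mx.astype(float)
    MyF = My.astype(float)

    n = MxF @ MyF.T
    Sx = Xz @ MyF.T
    Sy = MxF @ Yz.T
    Sxx = (Xz * Xz) @ MyF.T
    Syy = MxF @ (Yz * Yz).T
    Sxy = Xz @ Yz.T

    with np.errstate(divide="ignore", invalid="ignore"):
        cov = n * Sxy - Sx * Sy
        varx = n * Sxx - Sx * Sx
        vary = n * Syy - Sy * Sy
        r = cov / np.sqrt(varx * vary)

    enough = n >= max(min_overlap, 3)
    # guard tiny negative variances from floating point
    nonconst = (varx > 1e-12 * np.maximum(n * Sxx, 1.0)) & (
        vary > 1e-12 * np.maximum(n * Syy, 1.0)
    )
    universe = np.ones_like(enough, dtype=bool)
    if exclude_self:
        for i, a in enumerate(a_ids):
            for j, t in enumerate(t_ids):
                if a.symbol == t.symbol:
                    universe[i, j] = False
    valid = universe & enough & nonconst & np.isfinite(r)

    n_tests = int(valid.sum())
    if n_tests == 0:
        raise ValueError("no valid anchor-target pairs (all skipped)")
    p = _p_from_r(np.where(valid, r, 0.0), np.maximum(n, 3))
    p_bonf = np.minimum(p * n_tests, 1.0)

    scores: list[PairScore] = []
    ii, jj = np.nonzero(valid)
    for i, j in zip(ii, jj):
        mod = a_mods[i]
        rv = float(np.clip(r[i, j], -1.0, 1.0))
        scores.append(
            PairScore(
                anchor=a_ids[i],
                target=t_ids[j],
                modality=mod,
                r=rv,
                r_directional=_directional_r(rv, mod),
                p=float(p[i, j]),
                p_bonferroni=float(p_bonf[i, j]),
                n=int(n[i, j]),
            )
        )
    # rank within anchor on the directional key
    by_anchor: dict[str, list[PairScore]] = {}
    for s in scores:
        by_anchor.setdefault(s.anchor.symbol, []).append(s)
    for group in by_anchor.values():
        group.sort(key=directional_rank_key)
        for k, s in enumerate(group, start=1):
            s.rank_within_anchor = k

    n_skip_overlap = int((universe & ~enough).sum())
    n_skip_constant = int((universe & enough).sum()) - n_tests
    return ScanResult(
        scores=scores,
        n_tests=n_tests,
        n_skipped_overlap=n_skip_overlap,
        n_skipped_constant=n_skip_constant,
    )


def _directional_r(r: float, modality: Modality) -> float:
    if modality in (Modality.rna, Modality.protein):
        return r
    if modality in (Modality.damaging_mutation, Modality.hotspot_mutation, Modality.methylation):
        return -r
    raise ValueError(f"unknown modality {modality!r}")


def directional_rank_key(score: PairScore):
    """Sort key putting the strongest SLI candidate first.

    RNA/protein anchors rank by descending r (low expression with negative
    gene effect gives positive r); mutation/methylation anchors rank by
    ascending r (more mutation/methylation = less gene activity). Ties break
    on larger n, then anchor symbol, then target symbol.
    """
    return (-_directional_r(score.r, score.modality), -score.n,
            score.anchor.symbol, score.target.symbol)


def known_partner_rank(
    anchor_symbol: str,
    known_target_symbol: str,
    scores: Sequence[PairScore],
    top_fraction: float = 0.05,
) -> tuple[int | None, int, bool]:
    """Rank of a known partner among an anchor's scored targets.

    Positive-control validation: an established SLI should place its known
    target within the top ``top_fraction`` of the anchor's directional
    ranking. Returns ``(rank, n_targets, significant)``; rank is None when the
    known target was not scored (then never significant).
    """
    mine = [s for s in scores if s.anchor.symbol == anchor_symbol]
    n_targets = len(mine)
    mine.sort(key=directional_rank_key)
    rank = None
    for k, s in enumerate(mine, start=1):
        if s.target.symbol == known_target_symbol:
            rank = k
            break
    if rank is None:
        return None, n_targets, False
    cut = math.ceil(top_fraction * n_targets)
    return rank, n_targets, rank <= cut


def build_hit_list(scores: Sequence[PairScore]) -> list[PairScore]:
    """Best pair per anchor, ranked, then de-duplicated on target gene.

    Co-expressed anchors produce near-duplicate pairs sharing a target; only
    the better-ranked pair survives, so a coexpression cluster contributes at
    most one hit. Ties break on larger n, then lexicographically smaller
    anchor symbol. Output ranks are 1..k after removal.
    """
    best: dict[str, PairScore] = {}
    for s in scores:
        cur = best.get(s.anchor.symbol)
        if cur is None or directional_rank_key(s) < directional_rank_key(cur):
            best[s.anchor.symbol] = s
    ranked = sorted(best.values(), key=directional_rank_key)
    seen_targets: set[str] = set()
    out: list[PairScore] = []
    for s in ranked:
        if s.target.symbol in seen_targets:
            continue
        seen_targets.add(s.target.symbol)
        out.append(s)
    for k, s in enumerate(out, start=1):
        s.hit_rank = k
    return out


def classify_dependency(score: float, cfg: CutoffConfig | None = None) -> bool | None:
    """Lethal iff gene effect strictly below the cutoff; None for missing."""
    cfg = cfg or CutoffConfig()
    if score is None or (isinstance(score, float) and math.isnan(score)):
        return None
    return float(score) < cfg.lethal_ceres_below


def classify_expression(
    value: float, gene: str, cfg: CutoffConfig | None = None, mode: str = "low"
) -> bool | None:
    """Classify a log2(TPM+1) value as low (< cutoff) or high (>= cutoff)."""
    cfg = cfg or CutoffConfig()
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if mode == "low":
        table = cfg.low_expression_below
    elif mode == "high":
        table = cfg.high_expression_cutoffs
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if gene not in table:
        raise KeyError(f"no {mode!r}-expression cutoff configured for {gene!r}")
    cutoff = table[gene]
    return float(value) < cutoff if mode == "low" else float(value) >= cutoff
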