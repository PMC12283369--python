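"""Tumor-vs-healthy anchor reduction and calibration-gene normalization.

A candidate anchor is only therapeutically interesting if its expression is
reduced in tumors relative to healthy tissue. The reduction is computed on
the linear TPM scale as ``max(0, 1 - mean_tumor/mean_healthy) * 100`` — an
increase counts as a 0% reduction, never negative.

Cross-dataset comparisons (healthy-tissue atlases vs cell-line panels, or
proteome ratio data) are put on one scale by housekeeping ("calibration")
genes: each calibration gene is first normalized to its own grand-mean
expression, then query genes are divided by the per-sample average (RNA) or
geometric mean (protein ratios) of those normalized calibration values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import ExpressionMatrix, FeatureMatrix, GeneId, Scale

__all__ = [
    "SpecificityRecord",
    "CalibrationSet",
    "anchor_reduction",
    "calibration_normalize_rna",
    "calibration_normalize_protein",
    "group_compare",
    "GroupComparison",
]


@dataclass(frozen=True)
class SpecificityRecord:
    anchor: str
    mean_tumor: float  # linear TPM
    mean_healthy: float  # linear TPM
    reduction_pct: float  # in [0, 100], clipped at 0


@dataclass(frozen=True)
class CalibrationSet:
    """Housekeeping genes used to co-calibrate independent datasets."""

    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.genes) < 2:
            raise ValueError("calibration set needs >= 2 genes")

    def require_in(self, matrix: ExpressionMatrix) -> None:
        missing = [g for g in self.genes if g not in matrix.symbols]
        if missing:
            raise ValueError(f"calibration genes missing from matrix: {missing}")


def anchor_reduction(
    anchor: str | GeneId,
    tumor: ExpressionMatrix,
    healthy: ExpressionMatrix,
) -> SpecificityRecord:
    """Average reduction of anchor expression in tumor vs healthy samples.

    Inputs on a log scale are de-logged first; means are taken over samples on
    linear TPM. A healthy mean of zero leaves the reduction undefined.
    """
    symbol = anchor.symbol if isinstance(anchor, GeneId) else anchor
    vals = {}
    for name, mat in (("tumor", tumor), ("healthy", healthy)):
        if symbol not in mat.symbols:
            raise KeyError(f"anchor {symbol!r} not in {name} matrix")
        lin = mat.to_linear_tpm()
        v = lin.values_for(symbol)
        vals[name] = float(np.nanmean(v))
    if vals["healthy"] == 0:
        raise ValueError(f"healthy mean expression of {symbol!r} is zero; reduction undefined")
    reduction = max(0.0, (1.0 - vals["tumor"] / vals["healthy"])) * 100.0
    return SpecificityRecord(
        anchor=symbol,
        mean_tumor=vals["tumor"],
        mean_healthy=vals["healthy"],
        reduction_pct=reduction,
    )


def calibration_normalize_rna(
    matrices: Sequence[ExpressionMatrix],
    calibration: CalibrationSet,
    query_genes: Sequence[str],
    grand_mean: str = "union",
    reference_means: dict[str, float] | None = None,
) -> tuple[dict[str, pd.DataFrame], list[str]]:
    """Calibration-gene normalization of linear TPM across datasets.

    Steps (arithmetic means throughout):

    1. for each calibration gene g: ``scaled[g,s] = TPM[g,s] / mean_s(TPM[g])``,
       the mean taken over the union of all samples of all supplied matrices
       (``grand_mean='per_dataset'`` switches to per-matrix means for
       sensitivity checks);
    2. per-sample factor ``f[s] = mean over calibration genes of scaled[g,s]``;
    3. normalized query ``q[s] = TPM[q,s] / f[s]``.

    ``reference_means`` freezes the step-1 grand means at externally supplied
    per-gene values (a fixed calibration reference). With frozen means the
    per-sample factor scales exactly with any global rescaling of that
    sample's values, so the normalized query is exactly invariant to
    per-sample depth changes; with recomputed means the invariance is only
    asymptotic in the number of samples.

    Returns one frame of normalized query values per dataset (keyed by
    position, ``"dataset_0"`` ...) plus the ids of samples excluded because
    their factor was 0.
    """
    if grand_mean not in ("union", "per_dataset"):
        raise ValueError("grand_mean must be 'union' or 'per_dataset'")
    linear = [m.to_linear_tpm() for m in matrices]
    for m in linear:
        CalibrationSet(calibration.genes).require_in(m)

    cal = list(calibration.genes)
    if reference_means is not None:
        missing = [g for g in cal if g not in reference_means]
        if missing:
            raise ValueError(f"reference_means missing calibration genes {missing}")
        if any(reference_means[g] == 0 for g in cal):
            raise ValueError("calibration gene with zero reference mean")
        grand = {g: float(reference_means[g]) for g in cal}
    elif grand_mean == "union":
        grand = {}
        for g in cal:
            allvals = np.concatenate([m.values_for(g) for m in linear])
            gm = float(np.nanmean(allvals))
            if gm == 0:
                raise ValueError(f"calibration gene {g!r} has zero grand-mean TPM")
            grand[g] = gm

    out: dict[str, pd.DataFrame] = {}
    excluded: list[str] = []
    for di, m in enumerate(linear):
        if reference_means is None and grand_mean == "per_dataset":
            grand = {}
            for g in cal:
                gm = float(np.nanmean(m.values_for(g)))
                if gm == 0:
                    raise ValueError(f"calibration gene {g!r} has zero mean TPM in dataset {di}")
                grand[g] = gm
        scaled = np.vstack([m.values_for(g) / grand[g] for g in cal])
        f = np.nanmean(scaled, axis=0)
        ok = f != 0
        excluded += [s for s, keep in zip(m.samples, ok) if not keep]
        rows = {}
        for q in query_genes:
            if q not in m.symbols:
                raise KeyError(f"query gene {q!r} missing from dataset {di}")
            qv = m.values_for(q)
            rows[q] = np.where(ok, qv / np.where(ok, f, 1.0), np.nan)
        out[f"dataset_{di}"] = pd.DataFrame(rows, index=m.samples).T
    return out, excluded


def calibration_normalize_protein(
    log2_ratios: FeatureMatrix | pd.DataFrame,
    calibration_proteins: Sequence[str],
    query_protein: str,
) -> tuple[pd.Series, list[str]]:
    """Normalize a query protein's ratios by calibration proteins.

    Input values are log2 ratios to an internal control; they are de-logged
    first. Each calibration protein's ratio is divided by its own
    across-sample average, and the query ratio is divided by the per-sample
    geometric mean of those normalized calibration ratios. Samples missing a
    calibration value are excluded (reported in the second return value).
    """
    if isinstance(log2_ratios, FeatureMatrix):
        frame = log2_ratios.data.copy()
        frame.index = [g.symbol for g in log2_ratios.genes]
    else:
        frame = log2_ratios
    ratios = np.exp2(frame.astype(float))
    for p in list(calibration_proteins) + [query_protein]:
        if p not in ratios.index:
            raise KeyError(f"protein {p!r} missing from ratio table")
    cal = ratios.loc[list(calibration_proteins)]
    cal_norm = cal.div(cal.mean(axis=1, skipna=True), axis=0)
    complete = cal_norm.notna().all(axis=0)
    excluded = [s for s, ok in complete.items() if not ok]
    geo = np.exp(np.log(cal_norm.loc[:, complete]).mean(axis=0))
    query = ratios.loc[query_protein, complete] / geo
    return query, excluded


@dataclass(frozen=True)
class GroupComparison:
    group_a: str
    group_b: str
    percent_change_of_mean: float  # (mean_b/mean_a - 1) * 100
    p: float | None  # None when the omnibus test was not significant


def group_compare(
    values: dict[str, Sequence[float]],
    test: str = "two_group_rank",
    alpha: float = 0.05,
    posthoc_correction: str = "bonferroni",
) -> list[GroupComparison]:
    """Rank-based comparison of normalized expression between groups.

    ``two_group_rank`` runs a two-sided Mann-Whitney U test;
    ``multi_group_rank_with_posthoc`` runs a Kruskal-Wallis omnibus test
    followed, only when significant, by pairwise Dunn tests with the stated
    correction. Percent change is computed on group means of the (linear)
    values.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in values.items()}
    for name, v in groups.items():
        if v.size < 2:
            raise ValueError(f"group {name!r} needs >= 2 values")
    names = list(groups)
    if test == "two_group_rank":
        if len(names) != 2:
            raise ValueError("two_group_rank requires exactly 2 groups")
        a, b = names
        _, p = stats.mannwhitneyu(groups[a], groups[b], alternative="two-sided")
        pct = (np.mean(groups[b]) / np.mean(groups[a]) - 1.0) * 100.0
        return [GroupComparison(a, b, float(pct), float(p))]
    if test != "multi_group_rank_with_posthoc":
        raise ValueError(f"unknown test {test!r}")
    if len(names) < 2:
        raise ValueError("need >= 2 groups")
    _, p_omni = stats.kruskal(*groups.values())
    dunn = _dunn_pairwise(groups, posthoc_correction) if p_omni < alpha else {}
    out = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            pct = (np.mean(groups[b]) / np.mean(groups[a]) - 1.0) * 100.0
            out.append(GroupComparison(a, b, float(pct), dunn.get((a, b))))
    return out


def _dunn_pairwise(
    groups: dict[str, np.ndarray], correction: str
) -> dict[tuple[str, str], float]:
    """Dunn's post-hoc z tests on mean ranks with tie correction.

    Hand-rolled because no installed package provides Dunn's test; verified
    against the standard formulation (z on mean-rank differences with the
    pooled-rank variance and tie adjustment).
    """
    names = list(groups)
    pooled = np.concatenate([groups[n] for n in names])
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    sizes = {n: groups[n].size for n in names}
    mean_ranks = {}
    start = 0
    for n in names:
        k = sizes[n]
        mean_ranks[n] = float(np.mean(ranks[start : start + k]))
        start += k
    # tie correction term
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term
    raw: dict[tuple[str, str], float] = {}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            se = np.sqrt(base_var * (1.0 / sizes[a] + 1.0 / sizes[b]))
            z = (mean_ranks[a] - mean_ranks[b]) / se
            raw[(a, b)] = 2.0 * stats.norm.sf(abs(z))
    m = len(raw)
    if correction == "bonferroni":
        return {k: min(1.0, p * m) for k, p in raw.items()}
    if correction == "none":
        return raw
    raise ValueError(f"unknown correction {correction!r}")
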