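"""Quartile survival analysis and per-lineage classification summaries.

Patients are stratified into quartiles of anchor expression; the lowest and
highest quartiles are compared with the log-rank (Mantel-Cox) test, and the
hazard ratio is reported as the Mantel-Haenszel observed/expected ratio

    HR = (O_low / E_low) / (O_high / E_high)

with a 95% CI on the log scale using variance 1/E_low + 1/E_high. A
Cox-model HR (via lifelines) is available as a cross-check. Lineage
summaries report, per cancer lineage, the percentage of target-lethal lines
and of anchor-low (or marker-high) lines, plus an OLS regression across
lineages for the scatter view.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import SurvivalTable
from .sli_scoring import CutoffConfig, classify_dependency, classify_expression

__all__ = [
    "SurvivalComparison",
    "LineageSummary",
    "stratify_quartiles",
    "logrank_two_group",
    "hazard_ratio_mantel",
    "hazard_ratio_cox",
    "quartile_survival_analysis",
    "lineage_summary",
    "lineage_scatter_stats",
]


@dataclass
class SurvivalComparison:
    observed_low: float
    expected_low: float
    observed_high: float
    expected_high: float
    logrank_chi2: float
    p: float
    hazard_ratio: float
    hr_ci95: tuple[float, float]


@dataclass(frozen=True)
class LineageSummary:
    lineage: str
    n_lines: int
    pct_lethal: float
    pct_low_anchor: float
    pct_high_markers: tuple[tuple[str, float], ...] = ()


def stratify_quartiles(values: Sequence[float], ids: Sequence | None = None) -> np.ndarray:
    """Rank-based quartile labels 1..4 (1 = lowest values).

    Sizes differ by at most one, the remainder going to the bottom quartiles;
    ties resolve by stable order on the id sequence (input order by default).
    All-equal input cannot be stratified and raises.
    """
    v = np.asarray(values, dtype=float)
    n = v.size
    if n < 8:
        raise ValueError(f"need >= 8 values to form quartiles, got {n}")
    if np.ptp(v[~np.isnan(v)]) == 0:
        raise ValueError("all values equal: no quartile stratification possible")
    order = np.argsort(v, kind="stable")
    base, rem = divmod(n, 4)
    sizes = [base + (1 if q < rem else 0) for q in range(4)]
    labels = np.empty(n, dtype=int)
    start = 0
    for q, size in enumerate(sizes, start=1):
        labels[order[start : start + size]] = q
        start += size
    return labels


def _o_e_v(
    time_a: np.ndarray, event_a: np.ndarray, time_b: np.ndarray, event_b: np.ndarray
) -> tuple[float, float, float, float, float]:
    """Observed/expected events per group and hypergeometric variance.

    Standard log-rank accounting: at each distinct event time, expected
    events per group follow the risk-set proportions; censoring at an event
    time keeps the censored subject in that time's risk set (times strictly
    greater are the ones removed beforehand).
    """
    event_times = np.unique(np.concatenate([time_a[event_a == 1], time_b[event_b == 1]]))
    O_a = float(event_a.sum())
    O_b = float(event_b.sum())
    E_a = E_b = V = 0.0
    for t in event_times:
        n_a = float(np.sum(time_a >= t))
        n_b = float(np.sum(time_b >= t))
        n_tot = n_a + n_b
        d_a = float(np.sum((time_a == t) & (event_a == 1)))
        d_b = float(np.sum((time_b == t) & (event_b == 1)))
        d = d_a + d_b
        if n_tot == 0 or d == 0:
            continue
        E_a += d * n_a / n_tot
        E_b += d * n_b / n_tot
        if n_tot > 1:
            V += d * (n_a / n_tot) * (n_b / n_tot) * (n_tot - d) / (n_tot - 1)
    return O_a, E_a, O_b, E_b, V


def logrank_two_group(
    surv_a: SurvivalTable | pd.DataFrame, surv_b: SurvivalTable | pd.DataFrame
) -> SurvivalComparison:
    """Two-group log-rank (Mantel-Cox) test with Mantel-Haenszel HR.

    Group A plays the role of the low-expression (higher-risk) group in the
    reported hazard ratio. Each group must contain at least one event.
    """
    fa = surv_a.frame if isinstance(surv_a, SurvivalTable) else surv_a
    fb = surv_b.frame if isinstance(surv_b, SurvivalTable) else surv_b
    ta, ea = fa["time"].to_numpy(float), fa["event"].to_numpy(int)
    tb, eb = fb["time"].to_numpy(float), fb["event"].to_numpy(int)
    if ea.sum() == 0 or eb.sum() == 0:
        raise ValueError("each group needs at least one event")
    O_a, E_a, O_b, E_b, V = _o_e_v(ta, ea, tb, eb)
    if V <= 0:
        raise ValueError("degenerate risk sets: log-rank variance is zero")
    chi2 = (O_a - E_a) ** 2 / V
    p = float(stats.chi2.sf(chi2, df=1))
    hr, ci = hazard_ratio_mantel_from_oe(O_a, E_a, O_b, E_b)
    return SurvivalComparison(
        observed_low=O_a,
        expected_low=E_a,
        observed_high=O_b,
        expected_high=E_b,
        logrank_chi2=float(chi2),
        p=p,
        hazard_ratio=hr,
        hr_ci95=ci,
    )


def hazard_ratio_mantel_from_oe(
    O_a: float, E_a: float, O_b: float, E_b: float
) -> tuple[float, tuple[float, float]]:
    if E_a <= 0 or E_b <= 0:
        raise ValueError("zero expected events: hazard ratio undefined")
    hr = (O_a / E_a) / (O_b / E_b)
    se = np.sqrt(1.0 / E_a + 1.0 / E_b)
    lo = float(hr * np.exp(-1.959963984540054 * se))
    hi = float(hr * np.exp(+1.959963984540054 * se))
    return float(hr), (lo, hi)


def hazard_ratio_mantel(
    surv_low: SurvivalTable | pd.DataFrame, surv_high: SurvivalTable | pd.DataFrame
) -> tuple[float, tuple[float, float]]:
    """Mantel-Haenszel O/E hazard ratio of the low- vs high-expression group."""
    cmp = logrank_two_group(surv_low, surv_high)
    return cmp.hazard_ratio, cmp.hr_ci95


def hazard_ratio_cox(
    surv_low: SurvivalTable | pd.DataFrame, surv_high: SurvivalTable | pd.DataFrame
) -> float:
    """Cox proportional-hazards HR (low vs high), for cross-checking."""
    from lifelines import CoxPHFitter

    fa = surv_low.frame if isinstance(surv_low, SurvivalTable) else surv_low
    fb = surv_high.frame if isinstance(surv_high, SurvivalTable) else surv_high
    df = pd.concat(
        [
            pd.DataFrame({"time": fa["time"], "event": fa["event"], "low": 1}),
            pd.DataFrame({"time": fb["time"], "event": fb["event"], "low": 0}),
        ],
        ignore_index=True,
    )
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    return float(np.exp(cph.params_["low"]))


def quartile_survival_analysis(table: SurvivalTable) -> SurvivalComparison:
    """Compare lowest vs highest stratifier quartile by log-rank + MH hazard ratio."""
    frame = table.frame
    labels = stratify_quartiles(
        frame["stratifier_value"].to_numpy(float), frame["patient_id"].to_numpy()
    )
    low = frame[labels == 1]
    high = frame[labels == 4]
    return logrank_two_group(low, high)


def lineage_summary(
    dependency_scores: Sequence[float],
    anchor_expression: Sequence[float],
    lineages: Sequence[str],
    anchor_gene: str = "CDS1",
    cfg: CutoffConfig | None = None,
    marker_expression: dict[str, Sequence[float]] | None = None,
) -> list[LineageSummary]:
    """Per-lineage percentages of target-lethal and anchor-low cell lines.

    Lines with missing data are excluded from that percentage's denominator.
    ``marker_expression`` adds percent-high columns per configured marker.
    """
    cfg = cfg or CutoffConfig()
    dep = np.asarray(dependency_scores, dtype=float)
    exp = np.asarray(anchor_expression, dtype=float)
    lineages = list(lineages)
    if not (len(dep) == len(exp) == len(lineages)):
        raise ValueError("inputs must have one entry per cell line")
    out = []
    for lin in sorted(set(lineages)):
        idx = [i for i, l in enumerate(lineages) if l == lin]
        lethal = [classify_dependency(dep[i], cfg) for i in idx]
        low = [classify_expression(exp[i], anchor_gene, cfg, "low") for i in idx]
        markers = []
        if marker_expression:
            for gene, vals in marker_expression.items():
                v = np.asarray(vals, dtype=float)
                high = [classify_expression(v[i], gene, cfg, "high") for i in idx]
                markers.append((gene, _pct(high)))
        out.append(
            LineageSummary(
                lineage=lin,
                n_lines=len(idx),
                pct_lethal=_pct(lethal),
                pct_low_anchor=_pct(low),
                pct_high_markers=tuple(markers),
            )
        )
    return out


def _pct(flags: Sequence[bool | None]) -> float:
    known = [f for f in flags if f is not None]
    if not known:
        return float("nan")
    return 100.0 * sum(known) / len(known)


def lineage_scatter_stats(
    x_pcts: Sequence[float], y_pcts: Sequence[float]
) -> tuple[float, float, float, float]:
    """OLS regression plus Pearson r/p across lineage percentage pairs."""
    x = np.asarray(x_pcts, dtype=float)
    y = np.asarray(y_pcts, dtype=float)
    if x.size < 3:
        raise ValueError("need >= 3 lineages")
    if np.ptp(x) == 0:
        raise ValueError("constant x: regression undefined")
    if np.ptp(y) == 0:
        raise ValueError("constant y: correlation undefined")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue), float(res.pvalue)
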