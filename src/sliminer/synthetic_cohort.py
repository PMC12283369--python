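"""Synthetic cohorts with planted synthetic-lethal structure.

The generator emulates the statistical shape of a DepMap-style cell-line
panel plus matched patient cohorts, so that every pipeline stage can be
exercised against known ground truth:

* lineage-structured, roughly log-normal expression on the log2(TPM+1) scale;
* bimodal anchor expression — an "absent/low" mode (half-normal near 0) and a
  "high" mode around Normal(5, 0.7), mirroring the absent-vs-expressed
  bimodality seen in real anchor genes;
* target dependency that decreases smoothly with anchor expression for the
  planted pairs (a logistic weight between the two expression modes, which is
  what makes Hill-curve recovery possible downstream), independent noise for
  everything else;
* one cluster of decoy anchors co-expressed with a planted anchor, the
  stressor the hit-list de-duplication step must remove;
* tumor cohorts with a configured fractional reduction of anchor expression
  relative to healthy, exponential survival with a quartile-dependent hazard,
  binomial tracker-cell counts, and Ct values derived from expression.

All randomness flows from a single integer seed, split into named substreams
so adding one generator never perturbs another's draws.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core_data import (
    Cohort,
    DependencyMatrix,
    ExpressionMatrix,
    FeatureMatrix,
    GeneId,
    Modality,
    Scale,
    SurvivalTable,
)

__all__ = [
    "PlantedPair",
    "CohortConfig",
    "SyntheticCohort",
    "generate_cell_line_cohort",
    "generate_patient_cohorts",
    "generate_assay_data",
    "anchor_weight",
]

# logistic weight linking anchor expression to target dependency:
# w = 1 at absent anchor, 0 at high anchor, centred between the two modes
W_CENTER = 2.5  # log2(TPM+1) midpoint between the low (~0) and high (~5) modes
W_SCALE = 0.35

LOW_MODE_SD = 0.3  # half-normal width of the absent/low expression mode
HIGH_MODE_MEAN = 5.0
HIGH_MODE_SD = 0.7


def anchor_weight(log2_tpm1: np.ndarray | float) -> np.ndarray | float:
    """Dependency weight w(x): 1 for absent anchor, 0 for highly expressed."""
    return 1.0 / (1.0 + np.exp((np.asarray(log2_tpm1, dtype=float) - W_CENTER) / W_SCALE))


@dataclass(frozen=True)
class PlantedPair:
    """Ground-truth SLI: anchor gene predicts target-gene dependency.

    ``effect`` is the dependency depth at anchor-low (gene-effect units, so
    1.0 means anchor-low lines sit near a CERES of -1); ``low_fraction`` is
    the fraction of cell lines in the anchor's absent/low expression mode.
    """

    anchor: str
    target: str
    effect: float = 1.0
    low_fraction: float = 0.4


def _default_pairs() -> list[PlantedPair]:
    return [
        PlantedPair("ANC1", "TGT1", effect=1.0, low_fraction=0.40),
        PlantedPair("ANC2", "TGT2", effect=0.9, low_fraction=0.35),
        PlantedPair("ANC3", "TGT3", effect=1.1, low_fraction=0.50),
        PlantedPair("ANC4", "TGT4", effect=0.8, low_fraction=0.30),
        PlantedPair("ANC5", "TGT5", effect=1.0, low_fraction=0.45),
    ]


@dataclass
class CohortConfig:
    """Study conditions for the synthetic cohorts.

    Defaults give a desk-scale panel (300 genes x 250 lines, 5 planted pairs,
    dependency noise sd 0.25) on which the scoring stage separates planted
    from background pairs, plus patient cohorts sized so survival and
    specificity estimates are stable (2,000 patients, hazard ratio 1.9 for the
    anchor-low quartile, 64% tumor reduction of anchor expression — the
    magnitudes a strongly cancer-specific anchor shows).
    """

    n_genes: int = 300
    n_cell_lines: int = 250
    n_lineages: int = 4
    planted_pairs: list[PlantedPair] = field(default_factory=_default_pairs)
    coexpression_cluster_size: int = 3
    decoy_noise_sd: float = 0.5  # extra expression noise on co-expressed decoys
    noise_sd_dependency: float = 0.25
    noise_sd_expression: float = 0.4
    lineage_shift_sd: float = 0.3
    tumor_reduction_fraction: float = 0.64
    patient_noise_sd: float = 0.25  # lognormal sigma on patient TPM; 0 = exact means
    n_patients: int = 2000
    n_healthy: int = 400
    hazard_ratio_low_vs_high: float = 1.9
    censoring_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_genes, self.n_cell_lines, self.n_lineages,
            self.n_patients, self.n_healthy,
        )
        if any(c < 1 for c in counts):
            raise ValueError("all counts must be >= 1")
        for p in self.planted_pairs:
            if not 0 < p.low_fraction < 1:
                raise ValueError("low_fraction must lie in (0,1)")
        if self.noise_sd_dependency < 0 or self.noise_sd_expression < 0:
            raise ValueError("noise sds must be >= 0")
        if not 0 <= self.tumor_reduction_fraction < 1:
            raise ValueError("tumor_reduction_fraction must lie in [0,1)")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        needed = 2 * len(self.planted_pairs) + self.coexpression_cluster_size
        if needed > self.n_genes:
            raise ValueError(
                f"planted pairs + decoys need {needed} genes, config has {self.n_genes}"
            )

    def gene_symbols(self) -> list[str]:
        """Deterministic gene naming: planted anchors/targets, decoys, background."""
        syms = []
        for p in self.planted_pairs:
            syms.append(p.anchor)
        for p in self.planted_pairs:
            syms.append(p.target)
        syms += [f"DECOY{i + 1}" for i in range(self.coexpression_cluster_size)]
        n_bg = self.n_genes - len(syms)
        syms += [f"G{i + 1:04d}" for i in range(n_bg)]
        return syms


@dataclass
class SyntheticCohort:
    expression: ExpressionMatrix
    dependency: DependencyMatrix
    features: FeatureMatrix
    tumor_expression: ExpressionMatrix
    healthy_expression: ExpressionMatrix
    survival: SurvivalTable
    truth: list[PlantedPair]
    config: CohortConfig


def _rng(seed: int, stream: str) -> np.random.Generator:
    """Named substream: independent generator derived from (seed, stream name)."""
    return np.random.default_rng([seed, zlib.crc32(stream.encode())])


# ---------------------------------------------------------------------------
# Cell-line cohort
# ---------------------------------------------------------------------------


def generate_cell_line_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate the full synthetic cohort (cell lines + patients + truth)."""
    symbols = config.gene_symbols()
    genes = [GeneId(s, str(1000 + i)) for i, s in enumerate(symbols)]
    samples = [f"CL{i + 1:04d}" for i in range(config.n_cell_lines)]
    lineages = [f"lineage_{i % config.n_lineages + 1}" for i in range(config.n_cell_lines)]

    rng_e = _rng(config.seed, "expression")
    rng_d = _rng(config.seed, "dependency")

    n_g, n_s = config.n_genes, config.n_cell_lines
    anchor_syms = {p.anchor: p for p in config.planted_pairs}
    target_syms = {p.target: p for p in config.planted_pairs}

    # per-gene baseline and lineage shifts
    base_mean = rng_e.uniform(1.0, 8.0, size=n_g)
    lin_shift = rng_e.normal(0.0, config.lineage_shift_sd, size=(n_g, config.n_lineages))
    lin_idx = np.array([i % config.n_lineages for i in range(n_s)])

    expr = np.empty((n_g, n_s))
    for gi, sym in enumerate(symbols):
        if sym in anchor_syms:
            p = anchor_syms[sym]
            low = rng_e.random(n_s) < p.low_fraction
            vals = np.where(
                low,
                np.abs(rng_e.normal(0.0, LOW_MODE_SD, size=n_s)),
                rng_e.normal(HIGH_MODE_MEAN, HIGH_MODE_SD, size=n_s),
            )
            expr[gi] = vals
        else:
            expr[gi] = (
                base_mean[gi]
                + lin_shift[gi, lin_idx]
                + rng_e.normal(0.0, config.noise_sd_expression, size=n_s)
            )
    # decoy anchors co-expressed with the first planted anchor
    if config.coexpression_cluster_size and config.planted_pairs:
        a0 = symbols.index(config.planted_pairs[0].anchor)
        for k in range(config.coexpression_cluster_size):
            gi = symbols.index(f"DECOY{k + 1}")
            expr[gi] = expr[a0] + rng_e.normal(0.0, config.decoy_noise_sd, size=n_s)
    expr = np.clip(expr, 0.0, None)

    # dependency: background independent of expression; planted targets follow
    # -effect * w(anchor expression) + noise
    dep_base = rng_d.normal(-0.2, 0.15, size=n_g)
    dep = dep_base[:, None] + rng_d.normal(
        0.0, config.noise_sd_dependency, size=(n_g, n_s)
    )
    for gi, sym in enumerate(symbols):
        if sym in target_syms:
            p = target_syms[sym]
            ai = symbols.index(p.anchor)
            noise = (
                rng_d.normal(0.0, config.noise_sd_dependency, size=n_s)
                if config.noise_sd_dependency > 0
                else 0.0
            )
            dep[gi] = -p.effect * anchor_weight(expr[ai]) + noise

    ann = pd.DataFrame(
        {"lineage": lineages, "cohort": Cohort.cell_line.value}, index=samples
    )
    expression = ExpressionMatrix(
        genes=genes,
        data=pd.DataFrame(expr, index=symbols, columns=samples),
        scale=Scale.log2_tpm_plus1,
        annotations=ann,
    )
    dependency = DependencyMatrix(
        genes=[GeneId(g.symbol, g.external_id) for g in genes],
        data=pd.DataFrame(dep, index=symbols, columns=samples),
        score_kind="ceres",
    )
    features = _make_features(config, symbols, genes, expr, samples)
    tumor, healthy, survival = generate_patient_cohorts(config)
    return SyntheticCohort(
        expression=expression,
        dependency=dependency,
        features=features,
        tumor_expression=tumor,
        healthy_expression=healthy,
        survival=survival,
        truth=list(config.planted_pairs),
        config=config,
    )


def _make_features(
    config: CohortConfig,
    symbols: list[str],
    genes: list[GeneId],
    expr: np.ndarray,
    samples: list[str],
) -> FeatureMatrix:
    """RNA rows for all genes plus sparse mutation/methylation rows."""
    rng = _rng(config.seed, "features")
    rows: list[tuple[GeneId, Modality, Sequence[float]]] = []
    for g, row in zip(genes, expr):
        rows.append((g, Modality.rna, row))
    n_s = len(samples)
    # background binary mutations (10 genes) and methylation (10 genes)
    for gi in range(0, min(10, len(symbols))):
        mut = (rng.random(n_s) < 0.1).astype(float)
        rows.append((genes[gi], Modality.damaging_mutation, mut))
    for gi in range(0, min(10, len(symbols))):
        meth = np.clip(rng.beta(0.5, 3.0, size=n_s), 0.0, 1.0)
        rows.append((genes[gi], Modality.methylation, meth))
    return FeatureMatrix.from_rows(rows, samples)


# ---------------------------------------------------------------------------
# Patient cohorts
# ---------------------------------------------------------------------------


def generate_patient_cohorts(
    config: CohortConfig,
) -> tuple[ExpressionMatrix, ExpressionMatrix, SurvivalTable]:
    """Matched tumor/healthy expression plus a survival table.

    On the linear TPM scale each planted anchor's tumor mean equals
    ``(1 - tumor_reduction_fraction)`` times its healthy mean; with
    ``patient_noise_sd = 0`` this holds exactly sample-by-sample. Survival
    times are exponential, with the hazard multiplied by
    ``hazard_ratio_low_vs_high`` for patients in the bottom quartile of
    (tumor) anchor expression; censoring is independent exponential.
    """
    symbols = config.gene_symbols()
    genes = [GeneId(s, str(1000 + i)) for i, s in enumerate(symbols)]
    rng = _rng(config.seed, "patients")
    rng_s = _rng(config.seed, "survival")
    anchors = {p.anchor for p in config.planted_pairs}

    n_g = config.n_genes
    healthy_mean_tpm = np.exp2(rng.uniform(1.0, 8.0, size=n_g)) - 1.0 + 0.5

    def _cohort(n: int, reduce_anchors: bool, prefix: str) -> ExpressionMatrix:
        cols = [f"{prefix}{i + 1:05d}" for i in range(n)]
        means = healthy_mean_tpm.copy()
        if reduce_anchors:
            for gi, sym in enumerate(symbols):
                if sym in anchors:
                    means[gi] *= 1.0 - config.tumor_reduction_fraction
        if config.patient_noise_sd > 0:
            sigma = config.patient_noise_sd
            # lognormal with mean exactly `means`
            noise = rng.lognormal(-0.5 * sigma**2, sigma, size=(n_g, n))
            vals = means[:, None] * noise
        else:
            vals = np.tile(means[:, None], (1, n))
        log_vals = np.log2(vals + 1.0)
        ann = pd.DataFrame(
            {"lineage": "pan", "cohort": Cohort.tumor.value if reduce_anchors else Cohort.healthy.value},
            index=cols,
        )
        return ExpressionMatrix(
            genes=[GeneId(g.symbol, g.external_id) for g in genes],
            data=pd.DataFrame(log_vals, index=symbols, columns=cols),
            scale=Scale.log2_tpm_plus1,
            annotations=ann,
        )

    healthy = _cohort(config.n_healthy, reduce_anchors=False, prefix="H")
    tumor = _cohort(config.n_patients, reduce_anchors=True, prefix="T")

    # survival stratified on the first planted anchor's tumor expression
    anchor0 = config.planted_pairs[0].anchor if config.planted_pairs else symbols[0]
    strat = tumor.values_for(anchor0)
    # bottom quartile by rank (stable on patient order)
    order = np.argsort(strat, kind="stable")
    q1_size = int(np.ceil(config.n_patients / 4))
    low_mask = np.zeros(config.n_patients, dtype=bool)
    low_mask[order[:q1_size]] = True

    base_hazard = 1.0 / 1000.0  # events per day; median ~693 days for high group
    hazard = np.where(low_mask, base_hazard * config.hazard_ratio_low_vs_high, base_hazard)
    t_event = rng_s.exponential(1.0 / hazard)
    c_hazard = base_hazard * config.censoring_rate / max(1e-12, 1.0 - config.censoring_rate)
    t_cens = (
        rng_s.exponential(1.0 / c_hazard, size=config.n_patients)
        if config.censoring_rate > 0
        else np.full(config.n_patients, np.inf)
    )
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    frame = pd.DataFrame(
        {
            "patient_id": tumor.samples,
            "time": np.maximum(time, 1e-6),
            "event": event,
            "stratifier_value": strat,
        }
    )
    return tumor, healthy, SurvivalTable(frame)


# ---------------------------------------------------------------------------
# Bench-assay data
# ---------------------------------------------------------------------------


@dataclass
class AssayData:
    """Simulated tracker-count tables and a qPCR plate."""

    tracker_counts: pd.DataFrame  # condition, day, tracked, tracker
    true_lethality: dict[str, float]  # condition -> planted lethality %
    qpcr: pd.DataFrame  # sample, gene, ct_rep1..4
    qpcr_fold_truth: dict[str, float]  # sample -> planted fold change vs reference
    calibration_genes: list[str]
    reference_sample: str


def generate_assay_data(
    config: CohortConfig,
    true_lethality: dict[str, float] | None = None,
    n_cells: int = 10_000,
    qpcr_fold_changes: dict[str, float] | None = None,
    qpcr_noise_sd: float = 0.0,
) -> AssayData:
    """Binomial tracker counts at planted lethality and Ct values from expression.

    Tracker experiments mix a perturbed population with fluorescent reference
    cells; counts at the endpoint are binomial draws at the survival fraction
    implied by the planted lethality. Ct values follow
    ``Ct = intercept - log2(expression) + noise`` for target and calibration
    genes, so a planted fold change of f shifts the target Ct by -log2(f).
    """
    if true_lethality is None:
        true_lethality = {"sgTGT1": 80.0, "sgTGT2": 50.0, "sgControl2": 0.0}
    for cond, pct in true_lethality.items():
        if not 0.0 <= pct <= 100.0:
            raise ValueError(f"lethality for {cond!r} outside [0,100]")
    rng = _rng(config.seed, "assay")

    rows = []
    for cond, pct in true_lethality.items():
        surv = 1.0 - pct / 100.0
        rows.append((cond, 0, n_cells, n_cells))
        tracked_t = int(rng.binomial(n_cells, max(min(surv, 1.0), 0.0)))
        rows.append((cond, 14, tracked_t, n_cells))
    # control condition defining the normalization denominator
    rows.append(("sgControl", 0, n_cells, n_cells))
    rows.append(("sgControl", 14, n_cells, n_cells))
    tracker_counts = pd.DataFrame(rows, columns=["condition", "day", "tracked", "tracker"])

    if qpcr_fold_changes is None:
        qpcr_fold_changes = {"REF": 1.0, "S1": 4.0, "S2": 0.25}
    cal_genes = ["CAL1", "CAL2", "CAL3"]
    reference = next(iter(qpcr_fold_changes))
    qrows = []
    intercept = 30.0
    base_expr = 16.0  # arbitrary linear expression of the target in the reference
    for sample, fold in qpcr_fold_changes.items():
        target_ct = intercept - np.log2(base_expr * fold)
        for gene, ct in [("TARGET", target_ct)] + [(g, 22.0) for g in cal_genes]:
            reps = ct + (
                rng.normal(0.0, qpcr_noise_sd, size=4) if qpcr_noise_sd > 0 else np.zeros(4)
            )
            qrows.append([sample, gene, *np.round(reps, 6)])
    qpcr = pd.DataFrame(
        qrows, columns=["sample", "gene", "ct_rep1", "ct_rep2", "ct_rep3", "ct_rep4"]
    )
    return AssayData(
        tracker_counts=tracker_counts,
        true_lethality=dict(true_lethality),
        qpcr=qpcr,
        qpcr_fold_truth={s: f / qpcr_fold_changes[reference] for s, f in qpcr_fold_changes.items()},
        calibration_genes=cal_genes,
        reference_sample=reference,
    )
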