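"""Config-driven end-to-end runs: ingest -> score -> hit list -> downstream.

The pipeline mirrors the discovery workflow: correlate anchor expression with
target dependency across the cell-line panel, build the de-duplicated hit
list, then (where the relevant inputs are supplied) attach tumor-vs-healthy
specificity, positive-control validation ranks, an escape scan, a
dose-response fit, quartile survival, and lineage summaries. Identical config
and inputs give identical outputs; a manifest records test counts, skip
counts and seeds so the Bonferroni denominator is auditable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .cancer_specificity import SpecificityRecord, anchor_reduction
from .core_data import (
    ExpressionMatrix,
    Scale,
    SurvivalTable,
    align_matrices,
    read_dependency_matrix,
    read_expression_matrix,
    read_sample_annotations,
    write_results_table,
)
from .dose_response import decile_curve, fit_hill, half_max_fraction
from .escape_scan import scan_features
from .sli_scoring import (
    CutoffConfig,
    DEFAULT_MIN_OVERLAP,
    build_hit_list,
    known_partner_rank,
    score_pairs,
)
from .survival_lineage import lineage_summary, quartile_survival_analysis

log = logging.getLogger("sliminer")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "make_report"]


@dataclass
class PipelineConfig:
    expression_path: str
    dependency_path: str
    out_dir: str
    tumor_path: str | None = None
    healthy_path: str | None = None
    annotations_path: str | None = None
    survival_path: str | None = None
    anchors: list[str] | None = None  # None = all genes
    targets: list[str] | None = None
    known_pairs: list[tuple[str, str]] = field(default_factory=list)
    min_overlap: int = DEFAULT_MIN_OVERLAP
    alpha: float = 0.05
    top_fraction: float = 0.05
    cutoffs: CutoffConfig = field(default_factory=CutoffConfig)
    top_k_specificity: int = 10
    escape_scan_hit: bool = False
    dose_response_hit: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0,1)")
        for name in ("expression_path", "dependency_path"):
            if not getattr(self, name):
                raise ValueError(f"pipeline config missing required field {name!r}")


@dataclass
class PipelineResult:
    hit_list: list
    scan_meta: dict
    specificity: list[SpecificityRecord]
    known_partner_ranks: list[dict]
    dose_response: dict | None
    survival: dict | None
    lineages: list
    manifest: dict


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    _setup_logging(out_dir)

    log.info("stage ingest: reading matrices")
    ann = read_sample_annotations(config.annotations_path) if config.annotations_path else None
    expression = read_expression_matrix(config.expression_path, annotations=ann)
    dependency = read_dependency_matrix(config.dependency_path)

    log.info("stage align")
    expr_al, dep_al, align_report = align_matrices(expression, dependency)

    log.info("stage score_pairs")
    scan = score_pairs(
        expr_al, dep_al,
        anchors=config.anchors, targets=config.targets,
        min_overlap=config.min_overlap,
    )
    scan_meta = {
        "n_tests": scan.n_tests,
        "n_skipped_overlap": scan.n_skipped_overlap,
        "n_skipped_constant": scan.n_skipped_constant,
        **align_report,
    }

    log.info("stage build_hit_list")
    hits = build_hit_list(scan.scores)

    specificity: list[SpecificityRecord] = []
    if config.tumor_path and config.healthy_path:
        log.info("stage anchor_reduction")
        tumor = read_expression_matrix(config.tumor_path)
        healthy = read_expression_matrix(config.healthy_path)
        for h in hits[: config.top_k_specificity]:
            try:
                specificity.append(anchor_reduction(h.anchor.symbol, tumor, healthy))
            except (KeyError, ValueError) as exc:
                log.warning("specificity skipped for %s: %s", h.anchor.symbol, exc)

    known_ranks = []
    for anchor, target in config.known_pairs:
        rank, n_targets, significant = known_partner_rank(
            anchor, target, scan.scores, config.top_fraction
        )
        known_ranks.append(
            {"anchor": anchor, "known_target": target, "rank": rank,
             "n_targets": n_targets, "significant": significant}
        )

    dose = None
    if config.dose_response_hit and hits:
        top = hits[0]
        log.info("stage dose_response on top hit %s-%s", top.anchor.symbol, top.target.symbol)
        try:
            x = expr_al.values_for(top.anchor.symbol)
            y = dep_al.values_for(top.target.symbol)
            curve = decile_curve(x, y, input_scale=expr_al.scale)
            fit = fit_hill(curve)
            n_below, n_total, pct = half_max_fraction(x, fit, input_scale=expr_al.scale)
            dose = {
                "anchor": top.anchor.symbol, "target": top.target.symbol,
                "bottom": fit.bottom, "top": fit.top, "ec50": fit.ec50,
                "hill_slope": fit.hill_slope, "fit_r": fit.fit_r,
                "n_below_half_max": n_below, "n_total": n_total,
                "pct_below_half_max": pct,
            }
        except (ValueError, RuntimeError) as exc:
            log.warning("dose-response stage skipped: %s", exc)

    survival = None
    if config.survival_path:
        log.info("stage survival")
        import pandas as pd

        table = SurvivalTable(pd.read_csv(config.survival_path, sep="\t"))
        cmp = quartile_survival_analysis(table)
        survival = {
            "logrank_chi2": cmp.logrank_chi2, "p": cmp.p,
            "hazard_ratio": cmp.hazard_ratio,
            "hr_ci_low": cmp.hr_ci95[0], "hr_ci_high": cmp.hr_ci95[1],
            "observed_low": cmp.observed_low, "expected_low": cmp.expected_low,
            "observed_high": cmp.observed_high, "expected_high": cmp.expected_high,
        }

    lineages = []
    if ann is not None and "lineage" in (ann.columns if ann is not None else []) and hits:
        top = hits[0]
        anchor_sym, target_sym = top.anchor.symbol, top.target.symbol
        lineage_labels = [str(ann.loc[s, "lineage"]) if s in ann.index else "unknown"
                          for s in expr_al.samples]
        try:
            lineages = lineage_summary(
                dep_al.values_for(target_sym),
                expr_al.values_for(anchor_sym),
                lineage_labels,
                anchor_gene=anchor_sym,
                cfg=_cfg_with_anchor(config.cutoffs, anchor_sym),
            )
        except (KeyError, ValueError) as exc:
            log.warning("lineage stage skipped: %s", exc)

    manifest = {
        "sliminer_version": __version__,
        "seed": config.seed,
        "config": _jsonable(config),
        **scan_meta,
        "n_hits": len(hits),
    }

    _write_outputs(out_dir, scan, hits, specificity, known_ranks, dose, survival,
                   lineages, manifest)
    return PipelineResult(
        hit_list=hits,
        scan_meta=scan_meta,
        specificity=specificity,
        known_partner_ranks=known_ranks,
        dose_response=dose,
        survival=survival,
        lineages=lineages,
        manifest=manifest,
    )


def _cfg_with_anchor(cfg: CutoffConfig, anchor: str) -> CutoffConfig:
    if anchor in cfg.low_expression_below:
        return cfg
    out = CutoffConfig(
        lethal_ceres_below=cfg.lethal_ceres_below,
        low_expression_below={**cfg.low_expression_below, anchor: 1.5},
        high_expression_cutoffs=dict(cfg.high_expression_cutoffs),
        top_fraction=cfg.top_fraction,
        alpha=cfg.alpha,
    )
    return out


def _pair_rows(scores) -> list[dict]:
    return [
        {
            "anchor": s.anchor.symbol, "target": s.target.symbol,
            "modality": s.modality.value, "r": s.r,
            "r_directional": s.r_directional, "p": s.p,
            "p_bonferroni": s.p_bonferroni, "n": s.n,
            "rank_within_anchor": s.rank_within_anchor, "hit_rank": s.hit_rank,
        }
        for s in scores
    ]


def _write_outputs(out_dir, scan, hits, specificity, known_ranks, dose, survival,
                   lineages, manifest) -> None:
    cols = ["anchor", "target", "modality", "r", "r_directional", "p",
            "p_bonferroni", "n", "rank_within_anchor", "hit_rank"]
    write_results_table(_pair_rows(scan.scores), out_dir / "pair_scores.tsv", columns=cols)
    write_results_table(_pair_rows(hits), out_dir / "hit_list.tsv", columns=cols)
    write_results_table(
        [dataclasses.asdict(s) for s in specificity],
        out_dir / "specificity.tsv",
        columns=["anchor", "mean_tumor", "mean_healthy", "reduction_pct"],
    )
    write_results_table(
        known_ranks, out_dir / "known_partner_ranks.tsv",
        columns=["anchor", "known_target", "rank", "n_targets", "significant"],
    )
    if dose:
        write_results_table([dose], out_dir / "dose_response.tsv")
    if survival:
        write_results_table([survival], out_dir / "survival.tsv")
    if lineages:
        write_results_table(
            [
                {"lineage": l.lineage, "n_lines": l.n_lines,
                 "pct_lethal": l.pct_lethal, "pct_low_anchor": l.pct_low_anchor}
                for l in lineages
            ],
            out_dir / "lineage_summary.tsv",
        )
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def _setup_logging(out_dir: Path) -> None:
    if not log.handlers:
        log.setLevel(logging.INFO)
        log.addHandler(logging.StreamHandler())
    fh = logging.FileHandler(out_dir / "run.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)


def make_report(result: PipelineResult, top_k: int = 10) -> str:
    """Human-readable markdown summary of a completed (or partial) run."""
    lines = ["# SLI discovery run report", ""]
    if not result.hit_list:
        lines.append("No candidate pairs survived scoring: zero candidates.")
    else:
        spec_by_anchor = {s.anchor: s for s in result.specificity}
        lines.append(f"Top {min(top_k, len(result.hit_list))} candidate pairs "
                     f"(of {len(result.hit_list)}):")
        lines.append("")
        lines.append("| rank | anchor | target | r | p (Bonferroni) | n | tumor reduction % |")
        lines.append("|---|---|---|---|---|---|---|")
        for h in result.hit_list[:top_k]:
            spec = spec_by_anchor.get(h.anchor.symbol)
            red = f"{spec.reduction_pct:.1f}" if spec else "n/a"
            lines.append(
                f"| {h.hit_rank} | {h.anchor.symbol} | {h.target.symbol} "
                f"| {h.r:.3f} | {h.p_bonferroni:.3g} | {h.n} | {red} |"
            )
    lines.append("")
    lines.append(f"Scan: {result.scan_meta.get('n_tests')} valid tests, "
                 f"{result.scan_meta.get('n_skipped_overlap')} skipped (overlap), "
                 f"{result.scan_meta.get('n_skipped_constant')} skipped (constant).")
    if result.known_partner_ranks:
        lines.append("")
        lines.append("Positive-control validation:")
        for kr in result.known_partner_ranks:
            lines.append(
                f"- {kr['anchor']}-{kr['known_target']}: rank {kr['rank']} of "
                f"{kr['n_targets']} ({'significant' if kr['significant'] else 'not significant'})"
            )
    if result.dose_response:
        d = result.dose_response
        lines.append("")
        lines.append(
            f"Dose-response ({d['anchor']}-{d['target']}): half-max expression "
            f"{d['ec50']:.3f} log2(TPM+0.0625); {d['pct_below_half_max']:.1f}% of lines "
            f"({d['n_below_half_max']}/{d['n_total']}) below it; fit r = {d['fit_r']:.3f}."
        )
    else:
        lines.append("")
        lines.append("Dose-response: not run.")
    if result.survival:
        s = result.survival
        lines.append("")
        lines.append(
            f"Survival (lowest vs highest stratifier quartile): HR "
            f"{s['hazard_ratio']:.2f} [{s['hr_ci_low']:.2f}-{s['hr_ci_high']:.2f}], "
            f"log-rank chi2 {s['logrank_chi2']:.2f}, p = {s['p']:.3g}."
        )
    else:
        lines.append("")
        lines.append("Survival: not run.")
    return "\n".join(lines) + "\n"
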