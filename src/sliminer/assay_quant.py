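"""Bench-assay arithmetic: tracker lethality, rescue, and -ddCt qPCR.

Tracker experiments mix a perturbed (tracked) population with fluorescent
reference (tracker) cells; the tracked/tracker ratio, normalized to day 0 and
to a control perturbation, gives a survival percentage and hence

    lethality% = 100 - 100 * (ratio_test_t / ratio_test_0)
                             / (ratio_ctrl_t / ratio_ctrl_0).

Negative lethality (outgrowth) is biologically meaningful and is reported
as-is, flagged rather than clamped. Rescue converts the fold-change of the
synthetic-lethal fraction under treatment into a percentage of lethality
negated. The qPCR path is classic -ddCt against a reference sample, with the
per-sample calibration baseline taken — as specified — as the geometric mean
of the three calibration-gene Ct values (an arithmetic-mean mode is offered,
since Ct is already a log-scale quantity and the arithmetic mean is the more
conventional choice).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TrackerCountRecord",
    "QpcrPlate",
    "tracker_lethality",
    "background_correct",
    "rescue_percent",
    "neg_ddct_fold_change",
]


@dataclass(frozen=True)
class TrackerCountRecord:
    condition: str
    timepoint: str | int
    tracked_count: float  # experimental population (e.g. mCherry-negative)
    tracker_count: float  # fluorescent reference population

    def __post_init__(self) -> None:
        if self.tracked_count < 0 or self.tracker_count < 0:
            raise ValueError("counts must be non-negative")

    @property
    def ratio(self) -> float:
        if self.tracker_count == 0:
            raise ZeroDivisionError("tracker count is zero: ratio undefined")
        return self.tracked_count / self.tracker_count


def tracker_lethality(
    test_t: TrackerCountRecord,
    test_0: TrackerCountRecord,
    control_t: TrackerCountRecord,
    control_0: TrackerCountRecord,
) -> float:
    """Lethality % from four tracked/tracker count records.

    Ratios are normalized to day 0 and to the control condition; survival is
    that double-normalized ratio in percent, lethality is 100 - survival.
    May be negative (outgrowth); returned unclamped.
    """
    for rec, name in ((test_0, "test day 0"), (control_0, "control day 0")):
        if rec.tracked_count == 0:
            raise ZeroDivisionError(f"{name} tracked count is zero")
    survival = 100.0 * (test_t.ratio / test_0.ratio) / (control_t.ratio / control_0.ratio)
    return 100.0 - survival


def background_correct(
    tracked_count: float, tracker_count: float, background_fraction: float
) -> tuple[float, bool]:
    """Subtract the expected tracker-derived background from the tracked count.

    ``background_fraction`` is the fraction of tracker-population cells that
    read out as tracked (measured on unmixed tracker cells). Returns the
    corrected count and a flag marking clamping at zero.
    """
    if not 0.0 <= background_fraction < 1.0:
        raise ValueError("background_fraction must lie in [0, 1)")
    corrected = tracked_count - background_fraction * tracker_count
    if corrected < 0:
        return 0.0, True
    return corrected, False


def rescue_percent(sl_fraction_treated: float, sl_fraction_untreated: float) -> float:
    """Percent of the synthetic-lethal fraction negated by a treatment."""
    if sl_fraction_untreated == 0:
        raise ZeroDivisionError("untreated synthetic-lethal fraction is zero")
    return (1.0 - sl_fraction_treated / sl_fraction_untreated) * 100.0


@dataclass
class QpcrPlate:
    """Replicate Ct values per (sample, gene), plus the calibration design.

    ``records`` needs columns ``sample``, ``gene`` and one or more
    ``ct_rep*`` columns (replicates are averaged arithmetically per gene
    before any further computation).
    """

    records: pd.DataFrame
    calibration_genes: tuple[str, str, str]
    reference_sample: str
    rep_columns: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.rep_columns:
            self.rep_columns = [c for c in self.records.columns if c.startswith("ct_rep")]
        if not self.rep_columns:
            raise ValueError("no ct_rep* replicate columns found")
        cts = self.records[self.rep_columns].to_numpy(dtype=float)
        if np.nanmin(cts) <= 0:
            raise ValueError("Ct values must be positive")
        samples = set(self.records["sample"])
        if self.reference_sample not in samples:
            raise ValueError(f"reference sample {self.reference_sample!r} absent from plate")
        for s in samples:
            have = set(self.records.loc[self.records["sample"] == s, "gene"])
            missing = set(self.calibration_genes) - have
            if missing:
                raise ValueError(f"sample {s!r} missing calibration genes {sorted(missing)}")

    def mean_ct(self, sample: str, gene: str) -> float:
        rows = self.records[(self.records["sample"] == sample) & (self.records["gene"] == gene)]
        if rows.empty:
            raise KeyError(f"no Ct for sample {sample!r}, gene {gene!r}")
        return float(np.nanmean(rows[self.rep_columns].to_numpy(dtype=float)))


def neg_ddct_fold_change(
    plate: QpcrPlate,
    target_gene: str,
    calibration_mean: str = "geometric",
) -> dict[str, float]:
    """-ddCt fold changes of a target gene against the reference sample.

    Per sample: dCt = mean target Ct minus the (geometric, by default) mean
    of the three calibration-gene Cts; ddCt = dCt - dCt(reference);
    fold = 2^(-ddCt). The reference sample's fold is exactly 1.
    """
    if calibration_mean not in ("geometric", "arithmetic"):
        raise ValueError("calibration_mean must be 'geometric' or 'arithmetic'")

    def dct(sample: str) -> float:
        cal = [plate.mean_ct(sample, g) for g in plate.calibration_genes]
        if calibration_mean == "geometric":
            baseline = math.exp(sum(math.log(c) for c in cal) / len(cal))
        else:
            baseline = sum(cal) / len(cal)
        return plate.mean_ct(sample, target_gene) - baseline

    ref = dct(plate.reference_sample)
    out = {}
    for sample in pd.unique(plate.records["sample"]):
        out[str(sample)] = float(2.0 ** -(dct(str(sample)) - ref))
    out[plate.reference_sample] = 1.0
    return out
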