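"""Somatic variant filters and their validation against matched-normal truth.

Three classifiers are implemented:

* :func:`filter_snv_matched` — matched tumor/normal SNV retention: on
  capture target, inside exons or canonical splice sites, variant depth
  >= 5, normal depth >= 10, and no variant reads in the matched normal.
* :func:`filter_microindel_matched` — the seven-rule microindel filter
  (simple-repeat exclusion, depth/strand support, normal depth, >= 5% of
  reads, window base quality >= 25, per-read mismatch count <= 4 and
  mismatch fraction <= 0.2), on top of the same target/region gate and
  normal subtraction.
* :func:`filter_tumor_only` — the two-step protocol used when no matched
  normal exists: (1) drop variants present in any germline allowlist
  (dbSNP-like, population, panel of normals) unless catalogued as a
  somatic cancer mutation (COSMIC rescue); (2) drop variants with allele
  fraction strictly above 0.41, since somatic mutations in an impure
  tumor sit well below 0.5 while germline hets sit at ~0.5 and
  homozygotes at ~1. The VAF step is unconditional — it also applies to
  COSMIC-rescued variants.

Decisions are pure functions of the call, its evidence and the config;
each failure enumerates every violated rule in evaluation order.
:func:`evaluate_against_truth` scores tumor-only decisions against a
somatic/germline truth labelling (matched-pair calls or simulation
ground truth) as a confusion matrix with PPV/NPV/sensitivity/specificity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .variant_io import SNV, DatabaseMembership, NormalEvidence, VariantCall

__all__ = [
    "FilterConfig",
    "FilterDecision",
    "AccuracyMetrics",
    "filter_snv_matched",
    "filter_microindel_matched",
    "filter_tumor_only",
    "evaluate_against_truth",
    "vaf_threshold_sweep",
    "run_matched",
    "run_tumor_only",
]

# reason codes, one per rule
OFF_TARGET = "off_target"
NON_CODING_REGION = "non_coding_region"
LOW_VARIANT_DEPTH = "low_variant_depth"
LOW_NORMAL_DEPTH = "low_normal_depth"
PRESENT_IN_NORMAL = "present_in_normal"
SIMPLE_REPEAT = "simple_repeat"
STRAND_IMBALANCE = "strand_imbalance"
LOW_VARIANT_FRACTION = "low_variant_fraction"
LOW_BASE_QUALITY = "low_base_quality"
EXCESS_MISMATCH_COUNT = "excess_mismatch_count"
EXCESS_MISMATCH_FRACTION = "excess_mismatch_fraction"
GERMLINE_DATABASE = "germline_database"
VAF_ABOVE_THRESHOLD = "vaf_above_threshold"
MISSING_INDEL_EVIDENCE = "missing_indel_evidence"


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for all three filters; defaults are the pipeline values."""

    min_variant_depth: int = 5
    min_normal_depth: int = 10
    min_variant_read_fraction: float = 0.05  # microindels only
    min_indel_base_quality: float = 25.0
    max_read_mismatches: float = 4.0
    max_mismatch_fraction: float = 0.2
    tumor_only_vaf_max: float = 0.41
    require_target: bool = True
    allowed_region_classes: frozenset[str] = frozenset({"exon", "canonical_splice"})
    #: apply the VAF cutoff to indels in tumor-only mode (switchable; the
    #: protocol definition is stated for SNVs and adopted for both here)
    vaf_filter_indels: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.tumor_only_vaf_max < 1:
            raise ValueError("tumor_only_vaf_max must be in (0,1)")
        for name in (
            "min_variant_depth",
            "min_normal_depth",
            "min_variant_read_fraction",
            "min_indel_base_quality",
            "max_read_mismatches",
            "max_mismatch_fraction",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass(frozen=True)
class FilterDecision:
    """Pass/fail with machine-readable reasons in evaluation order."""

    passed: bool
    reasons: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.passed != (len(self.reasons) == 0):
            raise ValueError("passed must hold iff reasons is empty")


def _decision(reasons: list[str]) -> FilterDecision:
    return FilterDecision(passed=not reasons, reasons=tuple(reasons))


def _basic_region_reasons(v, cfg: FilterConfig) -> list[str]:
    reasons = []
    if cfg.require_target and not v.in_capture_target:
        reasons.append(OFF_TARGET)
    if v.region_class not in cfg.allowed_region_classes:
        reasons.append(NON_CODING_REGION)
    return reasons


def filter_snv_matched(
    v: VariantCall, normal: NormalEvidence, cfg: FilterConfig = FilterConfig()
) -> FilterDecision:
    """Matched-pair SNV retention rules (target, region, depths, subtraction)."""
    if normal is None:
        raise ValueError("matched filter requires normal evidence; use the tumor-only path")
    reasons = _basic_region_reasons(v, cfg)
    if v.variant_depth < cfg.min_variant_depth:
        reasons.append(LOW_VARIANT_DEPTH)
    if normal.normal_total_depth < cfg.min_normal_depth:
        reasons.append(LOW_NORMAL_DEPTH)
    if normal.normal_variant_depth > 0:
        reasons.append(PRESENT_IN_NORMAL)
    return _decision(reasons)


def filter_microindel_matched(
    v: VariantCall, normal: NormalEvidence, cfg: FilterConfig = FilterConfig()
) -> FilterDecision:
    """Seven-rule microindel filter; enumerates every violated rule.

    Missing strand counts or indel quality metrics fail closed with the
    distinct ``missing_indel_evidence`` code.
    """
    if normal is None:
        raise ValueError("matched filter requires normal evidence; use the tumor-only path")
    reasons = _basic_region_reasons(v, cfg)
    missing = False
    # (1) not in a simple repeat
    if v.in_simple_repeat:
        reasons.append(SIMPLE_REPEAT)
    # (2) variant depth >= 5 with at least one read on each strand
    if v.variant_depth < cfg.min_variant_depth:
        reasons.append(LOW_VARIANT_DEPTH)
    if v.fwd_variant_reads is None or v.rev_variant_reads is None:
        missing = True
    elif v.fwd_variant_reads < 1 or v.rev_variant_reads < 1:
        reasons.append(STRAND_IMBALANCE)
    # (3) depth in the normal >= 10; matched normals are also subtracted
    if normal.normal_total_depth < cfg.min_normal_depth:
        reasons.append(LOW_NORMAL_DEPTH)
    if normal.normal_variant_depth > 0:
        reasons.append(PRESENT_IN_NORMAL)
    # (4) contained in >= 5% of the reads
    if v.total_depth == 0 or v.vaf < cfg.min_variant_read_fraction:
        reasons.append(LOW_VARIANT_FRACTION)
    # (5) mean base quality inside the indel +/- 5 bases >= 25
    if v.mean_base_quality_window is None:
        missing = True
    elif v.mean_base_quality_window < cfg.min_indel_base_quality:
        reasons.append(LOW_BASE_QUALITY)
    # (6) mean mismatches in supporting reads <= 4
    if v.mean_read_mismatches is None:
        missing = True
    elif v.mean_read_mismatches > cfg.max_read_mismatches:
        reasons.append(EXCESS_MISMATCH_COUNT)
    # (7) mean mismatched-base fraction in supporting reads <= 0.2
    if v.mean_mismatch_fraction is None:
        missing = True
    elif v.mean_mismatch_fraction > cfg.max_mismatch_fraction:
        reasons.append(EXCESS_MISMATCH_FRACTION)
    if missing:
        reasons.append(MISSING_INDEL_EVIDENCE)
    return _decision(reasons)


def filter_tumor_only(
    v: VariantCall, mem: DatabaseMembership, cfg: FilterConfig = FilterConfig()
) -> FilterDecision:
    """Two-step tumor-only somatic classification.

    Order: basic target/region/depth gate, then the germline-database
    step with COSMIC rescue, then the strict ``vaf > tumor_only_vaf_max``
    exclusion (a VAF of exactly 0.41 is retained). The VAF step applies
    to every variant surviving step 1, COSMIC-rescued ones included.
    """
    reasons = _basic_region_reasons(v, cfg)
    if v.variant_depth < cfg.min_variant_depth:
        reasons.append(LOW_VARIANT_DEPTH)
    # step 1: germline allowlists, with COSMIC rescue
    if mem.in_any_germline_db and not mem.in_cosmic:
        reasons.append(GERMLINE_DATABASE)
    # step 2: allele-fraction cutoff (strict >)
    is_indel = v.variant_type != SNV
    if (cfg.vaf_filter_indels or not is_indel) and v.vaf > cfg.tumor_only_vaf_max:
        reasons.append(VAF_ABOVE_THRESHOLD)
    return _decision(reasons)


@dataclass(frozen=True)
class AccuracyMetrics:
    """Confusion matrix of somatic classification against truth labels.

    Rates are ``None`` (absent) when their denominator is zero.
    """

    tp: int
    fp: int
    tn: int
    fn: int

    @staticmethod
    def _rate(num: int, den: int) -> float | None:
        return None if den == 0 else num / den

    @property
    def ppv(self) -> float | None:
        return self._rate(self.tp, self.tp + self.fp)

    @property
    def npv(self) -> float | None:
        return self._rate(self.tn, self.tn + self.fn)

    @property
    def sensitivity(self) -> float | None:
        return self._rate(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> float | None:
        return self._rate(self.tn, self.tn + self.fp)

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "ppv": self.ppv, "npv": self.npv,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
        }


def evaluate_against_truth(
    decisions: Sequence[FilterDecision | bool],
    truth_labels: Sequence[str],
) -> AccuracyMetrics:
    """Score pass/fail decisions against somatic/germline truth.

    TP = somatic retained, FP = germline retained, TN = germline
    excluded, FN = somatic excluded.
    """
    if len(decisions) == 0:
        raise ValueError("no decisions to evaluate")
    if len(decisions) != len(truth_labels):
        raise ValueError("decisions and truth labels differ in length")
    tp = fp = tn = fn = 0
    for dec, label in zip(decisions, truth_labels):
        passed = dec.passed if isinstance(dec, FilterDecision) else bool(dec)
        if label == "somatic":
            tp, fn = (tp + 1, fn) if passed else (tp, fn + 1)
        elif label == "germline":
            fp, tn = (fp + 1, tn) if passed else (fp, tn + 1)
        else:
            raise ValueError(f"unknown truth label {label!r}")
    return AccuracyMetrics(tp=tp, fp=fp, tn=tn, fn=fn)


# ---------------------------------------------------------------------------
# cohort-level drivers (DataFrame in the MAF-like dialect + evidence columns)
# ---------------------------------------------------------------------------

def _membership_from_row(row) -> DatabaseMembership:
    return DatabaseMembership(
        in_dbsnp=bool(row.in_dbsnp),
        in_thousand_genomes=bool(row.in_thousand_genomes),
        in_evs=bool(row.in_evs),
        in_panel_of_normals=bool(row.in_panel_of_normals),
        in_cosmic=bool(row.in_cosmic),
    )


def run_tumor_only(
    variants: pd.DataFrame, cfg: FilterConfig = FilterConfig()
) -> pd.DataFrame:
    """Apply :func:`filter_tumor_only` row-wise to a cohort table.

    Expects the MAF-like columns plus ``vaf`` and the membership flags;
    returns a copy with ``passed`` and ``reasons`` columns appended.
    """
    passed, reasons = [], []
    for row in variants.itertuples(index=False):
        dec = filter_tumor_only(row, _membership_from_row(row), cfg)
        passed.append(dec.passed)
        reasons.append(",".join(dec.reasons))
    out = variants.copy()
    out["passed"] = passed
    out["reasons"] = reasons
    return out


def run_matched(
    variants: pd.DataFrame, cfg: FilterConfig = FilterConfig()
) -> pd.DataFrame:
    """Apply the matched-pair SNV/microindel filters row-wise.

    Expects ``normal_total_depth``/``normal_variant_depth`` columns in
    addition to the MAF-like columns.
    """
    passed, reasons = [], []
    for row in variants.itertuples(index=False):
        normal = NormalEvidence(
            normal_total_depth=int(row.normal_total_depth),
            normal_variant_depth=int(row.normal_variant_depth),
        )
        if row.variant_type == SNV:
            dec = filter_snv_matched(row, normal, cfg)
        else:
            dec = filter_microindel_matched(row, normal, cfg)
        passed.append(dec.passed)
        reasons.append(",".join(dec.reasons))
    out = variants.copy()
    out["passed"] = passed
    out["reasons"] = reasons
    return out


def vaf_threshold_sweep(
    cohort,
    thresholds: Iterable[float],
    cfg: FilterConfig = FilterConfig(),
) -> pd.DataFrame:
    """Operating characteristics of the tumor-only protocol across cutoffs.

    ``cohort`` is a variants DataFrame carrying a ``truth_label`` column
    (or an object exposing one as ``.variants``). Sensitivity is
    nondecreasing and specificity nonincreasing in the threshold.
    """
    variants = getattr(cohort, "variants", cohort)
    if "truth_label" not in variants.columns:
        raise ValueError("cohort variants need a truth_label column")
    rows = []
    for thr in thresholds:
        if not 0 < thr <= 1:
            raise ValueError("thresholds must be in (0,1]")
        decided = run_tumor_only(variants, replace(cfg, tumor_only_vaf_max=min(thr, 1 - 1e-12)))
        m = evaluate_against_truth(
            decided["passed"].tolist(), variants["truth_label"].tolist()
        )
        rows.append({"threshold": thr, **m.as_dict()})
    return pd.DataFrame(rows)
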