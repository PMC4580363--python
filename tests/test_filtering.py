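"""Filter rule semantics, reason-code bookkeeping, validation metrics."""

import numpy as np
import pandas as pd
import pytest

from somaticlens import filtering as flt
from somaticlens.filtering import (
    AccuracyMetrics,
    FilterConfig,
    FilterDecision,
    evaluate_against_truth,
    filter_microindel_matched,
    filter_snv_matched,
    filter_tumor_only,
    run_tumor_only,
    vaf_threshold_sweep,
)
from somaticlens.simulate import SimConfig, simulate_cohort
from somaticlens.variant_io import DatabaseMembership, NormalEvidence, VariantCall


def snv(**kw):
    base = dict(sample_id="S", chrom="1", pos=100, ref="C", alt="T",
                variant_depth=20, total_depth=100)
    base.update(kw)
    return VariantCall(**base)


def indel(**kw):
    base = dict(sample_id="S", chrom="1", pos=100, ref="CA", alt="C",
                variant_type="deletion", variant_depth=6, total_depth=50,
                fwd_variant_reads=3, rev_variant_reads=3,
                mean_base_quality_window=31.0, mean_read_mismatches=1.5,
                mean_mismatch_fraction=0.05)
    base.update(kw)
    return VariantCall(**base)


NORMAL_OK = NormalEvidence(normal_total_depth=50, normal_variant_depth=0)


class TestMatchedSnv:
    def test_clean_call_passes(self):
        assert filter_snv_matched(snv(), NORMAL_OK).passed

    def test_low_variant_depth(self):
        dec = filter_snv_matched(snv(variant_depth=4), NORMAL_OK)
        assert dec.reasons == (flt.LOW_VARIANT_DEPTH,)

    def test_boundary_depths_pass(self):
        assert filter_snv_matched(
            snv(variant_depth=5), NormalEvidence(10, 0)
        ).passed

    def test_present_in_normal(self):
        dec = filter_snv_matched(snv(), NormalEvidence(40, 3))
        assert dec.reasons == (flt.PRESENT_IN_NORMAL,)

    def test_low_normal_depth(self):
        dec = filter_snv_matched(snv(), NormalEvidence(9, 0))
        assert dec.reasons == (flt.LOW_NORMAL_DEPTH,)

    def test_off_target_and_region(self):
        dec = filter_snv_matched(
            snv(in_capture_target=False, region_class="other"), NORMAL_OK
        )
        assert dec.reasons == (flt.OFF_TARGET, flt.NON_CODING_REGION)

    def test_missing_normal_is_contract_violation(self):
        with pytest.raises(ValueError):
            filter_snv_matched(snv(), None)


class TestMatchedMicroindel:
    def test_clean_indel_passes(self):
        assert filter_microindel_matched(indel(), NormalEvidence(30, 0)).passed

    @pytest.mark.parametrize(
        "kw,normal,expected",
        [
            (dict(in_simple_repeat=True), NORMAL_OK, flt.SIMPLE_REPEAT),
            (dict(variant_depth=4, fwd_variant_reads=2, rev_variant_reads=2),
             NORMAL_OK, flt.LOW_VARIANT_DEPTH),
            (dict(fwd_variant_reads=6, rev_variant_reads=0), NORMAL_OK,
             flt.STRAND_IMBALANCE),
            (dict(), NormalEvidence(9, 0), flt.LOW_NORMAL_DEPTH),
            (dict(), NormalEvidence(30, 2), flt.PRESENT_IN_NORMAL),
            (dict(variant_depth=6, total_depth=200, fwd_variant_reads=3,
                  rev_variant_reads=3), NORMAL_OK, flt.LOW_VARIANT_FRACTION),
            (dict(mean_base_quality_window=24.0), NORMAL_OK, flt.LOW_BASE_QUALITY),
            (dict(mean_read_mismatches=4.5), NORMAL_OK, flt.EXCESS_MISMATCH_COUNT),
            (dict(mean_mismatch_fraction=0.25), NORMAL_OK,
             flt.EXCESS_MISMATCH_FRACTION),
        ],
    )
    def test_each_rule_has_its_reason(self, kw, normal, expected):
        dec = filter_microindel_matched(indel(**kw), normal)
        assert dec.reasons == (expected,)

    def test_all_violations_enumerated_not_just_first(self):
        dec = filter_microindel_matched(
            indel(in_simple_repeat=True, mean_mismatch_fraction=0.3),
            NormalEvidence(8, 0),
        )
        assert set(dec.reasons) == {
            flt.SIMPLE_REPEAT, flt.LOW_NORMAL_DEPTH, flt.EXCESS_MISMATCH_FRACTION
        }

    def test_missing_quality_fields_fail_closed(self):
        dec = filter_microindel_matched(
            indel(mean_base_quality_window=None), NORMAL_OK
        )
        assert dec.reasons == (flt.MISSING_INDEL_EVIDENCE,)

    def test_boundary_values_pass(self):
        dec = filter_microindel_matched(
            indel(mean_base_quality_window=25.0, mean_read_mismatches=4.0,
                  mean_mismatch_fraction=0.2),
            NormalEvidence(10, 0),
        )
        assert dec.passed


class TestTumorOnly:
    def test_high_vaf_excluded(self):
        dec = filter_tumor_only(
            snv(variant_depth=50, total_depth=100), DatabaseMembership()
        )
        assert dec.reasons == (flt.VAF_ABOVE_THRESHOLD,)

    def test_boundary_vaf_retained_under_strict_inequality(self):
        dec = filter_tumor_only(
            snv(variant_depth=41, total_depth=100), DatabaseMembership()
        )
        assert dec.passed

    def test_cosmic_rescue_overrides_germline_databases(self):
        dec = filter_tumor_only(
            snv(variant_depth=30, total_depth=100),
            DatabaseMembership(in_dbsnp=True, in_cosmic=True),
        )
        assert dec.passed

    def test_panel_of_normals_alone_excludes(self):
        dec = filter_tumor_only(
            snv(variant_depth=30, total_depth=100),
            DatabaseMembership(in_panel_of_normals=True),
        )
        assert dec.reasons == (flt.GERMLINE_DATABASE,)

    def test_vaf_step_applies_to_cosmic_rescued_variants(self):
        dec = filter_tumor_only(
            snv(variant_depth=55, total_depth=100),
            DatabaseMembership(in_dbsnp=True, in_cosmic=True),
        )
        assert dec.reasons == (flt.VAF_ABOVE_THRESHOLD,)

    def test_known_failure_mode_cosmic_listed_germline_retained(self):
        # a germline variant catalogued as somatic with VAF <= 0.41 is
        # (incorrectly) kept: the rescue rule's documented failure mode
        dec = filter_tumor_only(
            snv(variant_depth=35, total_depth=100),
            DatabaseMembership(in_dbsnp=True, in_cosmic=True),
        )
        assert dec.passed
        metrics = evaluate_against_truth([dec], ["germline"])
        assert metrics.fp == 1

    def test_indel_vaf_filter_switchable(self):
        v = indel(variant_depth=25, total_depth=50,
                  fwd_variant_reads=13, rev_variant_reads=12)
        assert not filter_tumor_only(v, DatabaseMembership()).passed
        cfg = FilterConfig(vaf_filter_indels=False)
        assert filter_tumor_only(v, DatabaseMembership(), cfg).passed

    def test_reasons_accumulate_across_steps(self):
        dec = filter_tumor_only(
            snv(variant_depth=3, total_depth=6),
            DatabaseMembership(in_dbsnp=True),
        )
        assert dec.reasons == (
            flt.LOW_VARIANT_DEPTH, flt.GERMLINE_DATABASE, flt.VAF_ABOVE_THRESHOLD
        )


class TestDecisionInvariants:
    def test_passed_iff_no_reasons(self):
        with pytest.raises(ValueError):
            FilterDecision(passed=True, reasons=("off_target",))
        with pytest.raises(ValueError):
            FilterDecision(passed=False, reasons=())

    def test_decisions_are_order_invariant(self, default_cohort):
        df = default_cohort.variants.head(300)
        fwd = run_tumor_only(df)
        rev = run_tumor_only(df.iloc[::-1])
        merged = fwd.merge(
            rev[["sample_id", "chrom", "pos", "ref", "alt", "passed"]],
            on=["sample_id", "chrom", "pos", "ref", "alt"],
            suffixes=("", "_rev"),
        )
        assert (merged["passed"] == merged["passed_rev"]).all()


class TestAccuracyMetrics:
    def test_definitional_arithmetic(self):
        m = AccuracyMetrics(tp=92, fp=8, tn=96, fn=4)
        assert m.ppv == pytest.approx(0.92)
        assert m.npv == pytest.approx(0.96)
        assert m.sensitivity == pytest.approx(92 / 96)
        assert m.specificity == pytest.approx(96 / 104)

    def test_perfect_classification(self):
        decs = [FilterDecision(True), FilterDecision(False, ("germline_database",))]
        m = evaluate_against_truth(decs, ["somatic", "germline"])
        assert (m.ppv, m.npv, m.sensitivity, m.specificity) == (1, 1, 1, 1)

    def test_undefined_rates_are_absent_not_zero(self):
        m = AccuracyMetrics(tp=0, fp=0, tn=5, fn=2)
        assert m.ppv is None
        assert m.specificity == 1.0

    def test_conservation(self, default_cohort):
        df = default_cohort.variants
        decided = run_tumor_only(df)
        m = evaluate_against_truth(
            decided["passed"].tolist(), df["truth_label"].tolist()
        )
        assert m.n == len(df)

    def test_empty_input_is_error(self):
        with pytest.raises(ValueError):
            evaluate_against_truth([], [])

    def test_metrics_match_direct_counting_oracle(self):
        """PPV/sensitivity agree with brute-force counting on the truth table."""
        cfg = SimConfig(n_samples=8, db_completeness=0.98,
                        purity_range=(0.5, 0.7), depth_mean=130, seed=21)
        truth = simulate_cohort(cfg)
        df = run_tumor_only(truth.variants)
        m = evaluate_against_truth(df["passed"].tolist(), df["truth_label"].tolist())

        # independent vectorized re-derivation of the two-step rule
        germ_db = df[["in_dbsnp", "in_thousand_genomes", "in_evs",
                      "in_panel_of_normals"]].any(axis=1)
        keep = (
            (df["variant_depth"] >= 5)
            & (~germ_db | df["in_cosmic"])
            & (df["vaf"] <= 0.41)
        )
        somatic = df["truth_label"] == "somatic"
        ppv_oracle = (keep & somatic).sum() / keep.sum()
        sens_oracle = (keep & somatic).sum() / somatic.sum()
        assert m.ppv == pytest.approx(ppv_oracle, abs=1e-12)
        assert m.sensitivity == pytest.approx(sens_oracle, abs=1e-12)


class TestThresholdSweep:
    def test_monotone_operating_characteristics(self, default_cohort):
        grid = np.round(np.arange(0.1, 1.0, 0.1), 2)
        table = vaf_threshold_sweep(default_cohort, grid)
        sens = table["sensitivity"].to_numpy(dtype=float)
        spec = table["specificity"].to_numpy(dtype=float)
        assert (np.diff(sens) >= 0).all()
        assert (np.diff(spec) <= 0).all()

    def test_extreme_thresholds(self, default_cohort):
        table = vaf_threshold_sweep(default_cohort, [0.001, 1.0])
        low, high = table.iloc[0], table.iloc[1]
        assert low["sensitivity"] < 0.05  # VAF rule excludes nearly everything
        # at threshold 1.0 sensitivity is limited only by the database step
        df = run_tumor_only(
            default_cohort.variants,
            FilterConfig(tumor_only_vaf_max=1 - 1e-12),
        )
        som = df[df["truth_label"] == "somatic"]
        assert high["sensitivity"] == pytest.approx(som["passed"].mean())
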