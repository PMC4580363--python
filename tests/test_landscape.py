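"""Co-mutation matrix rules, spectrum strand collapsing, chi-square + BH."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2

from somaticlens.landscape import (
    benjamini_hochberg,
    build_matrix,
    compare_frequencies,
    functional_class_breakdown,
    gene_frequencies,
    oncoplot,
    substitution_spectrum,
)
from somaticlens.simulate import SimConfig, simulate_cohort


def _variants(rows):
    base = dict(chrom="1", pos=1, ref="C", alt="T", variant_type="SNV",
                variant_depth=10, total_depth=50)
    return pd.DataFrame([{**base, **r} for r in rows])


class TestBuildMatrix:
    def test_sample_counted_once_per_gene(self):
        df = _variants([
            {"sample_id": "A", "gene": "TP53", "functional_class": "missense"},
            {"sample_id": "A", "gene": "TP53", "functional_class": "missense"},
        ])
        m = build_matrix(df, ["A", "B"])
        assert bool(m.altered.loc["A", "TP53"]) is True
        assert int(m.n_variants.loc["A", "TP53"]) == 2
        assert bool(m.altered.loc["B", "TP53"]) is False

    def test_synonymous_excluded(self):
        df = _variants([
            {"sample_id": "A", "gene": "TP53", "functional_class": "synonymous"},
        ])
        m = build_matrix(df, ["A"])
        assert "TP53" not in m.genes or not m.altered.loc["A"].any()

    def test_empty_variants_full_roster(self):
        m = build_matrix(pd.DataFrame(), ["A", "B", "C"])
        assert m.samples == ["A", "B", "C"]
        assert m.altered.values.sum() == 0

    def test_unknown_sample_is_error(self):
        df = _variants([
            {"sample_id": "Z", "gene": "TP53", "functional_class": "missense"},
        ])
        with pytest.raises(ValueError, match="roster"):
            build_matrix(df, ["A"])

    def test_frequencies_invariant_under_sample_reordering(self):
        df = _variants([
            {"sample_id": s, "gene": g, "functional_class": "missense"}
            for s, g in [("A", "X"), ("B", "X"), ("B", "Y"), ("C", "Y")]
        ])
        f1 = gene_frequencies(build_matrix(df, ["A", "B", "C", "D"]))
        f2 = gene_frequencies(build_matrix(df, ["D", "C", "B", "A"]))
        pd.testing.assert_series_equal(f1.sort_index(), f2.sort_index())

    def test_gene_frequencies_use_full_roster_denominator(self):
        df = _variants([
            {"sample_id": "A", "gene": "X", "functional_class": "missense"},
        ])
        freq = gene_frequencies(build_matrix(df, [f"S{i}" for i in range(9)] + ["A"]))
        assert freq["X"] == pytest.approx(0.1)


class TestFunctionalBreakdown:
    def test_single_variant_is_100pct(self):
        df = _variants([{"sample_id": "A", "gene": "X",
                         "functional_class": "missense"}])
        out = functional_class_breakdown(df)
        assert out.loc[0, "pct"] == pytest.approx(100.0)

    def test_counts_conserve_total_on_simulated_cohort(self, default_cohort):
        df = default_cohort.variants
        out = functional_class_breakdown(df)
        nonsyn = (df["functional_class"] != "synonymous").sum()
        assert out["count"].sum() == nonsyn
        assert out["pct"].sum() == pytest.approx(100.0)


class TestSpectrum:
    def test_cpg_definition(self):
        df = _variants([{"sample_id": "A", "gene": "X", "ref": "C", "alt": "T",
                         "functional_class": "missense", "context": "ACG"}])
        prof = substitution_spectrum(df)
        assert prof.counts["C>T"] == 1
        assert prof.c_to_t_cpg == 1 and prof.c_to_t_other == 0

    def test_purine_strand_collapses(self):
        # G>A in context TGA is C>T in context TCA on the other strand: not CpG
        df = _variants([{"sample_id": "A", "gene": "X", "ref": "G", "alt": "A",
                         "functional_class": "missense", "context": "TGA"}])
        prof = substitution_spectrum(df)
        assert prof.counts["C>T"] == 1
        assert prof.c_to_t_cpg == 0 and prof.c_to_t_other == 1

    def test_collapsing_is_identity_on_pyrimidine_classes(self):
        rows = [
            {"sample_id": "A", "gene": "X", "ref": r, "alt": a,
             "functional_class": "missense", "context": f"A{r}T"}
            for r, a in [("C", "A"), ("C", "G"), ("C", "T"),
                         ("T", "A"), ("T", "C"), ("T", "G")]
        ]
        prof = substitution_spectrum(_variants(rows))
        assert all(prof.counts[c] == 1 for c in prof.counts)
        assert prof.total == 6

    def test_class_counts_conserve_snv_total(self, default_cohort):
        snvs = default_cohort.variants.query("variant_type == 'SNV'")
        prof = substitution_spectrum(snvs)
        assert prof.total == len(snvs)
        assert prof.c_to_t_cpg + prof.c_to_t_other == prof.counts["C>T"]

    def test_bad_context_rejected(self):
        df = _variants([{"sample_id": "A", "gene": "X", "ref": "C", "alt": "T",
                         "functional_class": "missense", "context": "AAG"}])
        with pytest.raises(ValueError, match="inconsistent"):
            substitution_spectrum(df)

    def test_generator_round_trip_recovers_cpg_rate(self):
        probs = {"C>A": 0.1, "C>G": 0.1, "C>T_CpG": 0.4, "C>T_other": 0.1,
                 "T>A": 0.1, "T>C": 0.1, "T>G": 0.1}
        truth = simulate_cohort(
            SimConfig(n_samples=10, substitution_probs=probs, seed=13)
        )
        snvs = truth.variants.query("variant_type == 'SNV'")
        prof = substitution_spectrum(snvs)
        frac = prof.c_to_t_cpg / prof.total
        se = np.sqrt(0.4 * 0.6 / prof.total)
        assert abs(frac - 0.4) < 4 * se


class TestComparison:
    def test_identical_frequencies_p_one(self):
        out = compare_frequencies([10], 60, [29], 174, genes=["G"])
        # 10/60 vs 29/174 are identical proportions
        assert out.loc[0, "chi_square"] == pytest.approx(0.0, abs=1e-12)
        assert out.loc[0, "p"] == pytest.approx(1.0)
        assert out.loc[0, "q"] == pytest.approx(1.0)

    def test_chi_square_matches_direct_formula(self):
        a, n_a, b, n_b = 16, 60, 10, 172
        out = compare_frequencies([a], n_a, [b], n_b, genes=["DST"])
        table = np.array([[a, n_a - a], [b, n_b - b]], dtype=float)
        expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
        stat = ((table - expected) ** 2 / expected).sum()
        assert out.loc[0, "chi_square"] == pytest.approx(stat)
        assert out.loc[0, "p"] == pytest.approx(chi2.sf(stat, df=1))

    def test_low_expected_count_flagged_but_reported(self):
        out = compare_frequencies([1], 60, [0], 5, genes=["G"])
        assert bool(out.loc[0, "low_expected_count"])
        assert np.isfinite(out.loc[0, "p"])

    def test_bh_hand_executed_step_up(self):
        q = benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
        # step-up: q_i = min over j>=i of p_j * m / j = 0.04 for all
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_bh_monotone_and_bounded(self):
        p = [0.001, 0.2, 0.8, 0.04, 0.5]
        q = benjamini_hochberg(p)
        assert (q >= np.array(p) - 1e-15).all()
        assert (q <= 1).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()


def test_oncoplot_renders(tmp_path, default_cohort):
    import matplotlib
    matplotlib.use("Agg")
    from somaticlens.filtering import run_tumor_only

    df = run_tumor_only(default_cohort.variants)
    m = build_matrix(df[df["passed"]], sorted(df["sample_id"].unique()))
    out = tmp_path / "plot.png"
    oncoplot(m, path=str(out))
    assert out.exists() and out.stat().st_size > 0
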