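"""Cohort-level mutation summaries.

Builds the binary samples x genes alteration matrix that drives
per-gene frequencies, pathway calls and survival grouping; tabulates
functional-class breakdowns; classifies single-base substitutions onto
the six pyrimidine-strand classes with a CpG split of C>T; and compares
per-gene mutation frequencies between two cohorts with Pearson
chi-square tests followed by Benjamini-Hochberg correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency
from statsmodels.stats.multitest import multipletests

from .variant_io import NONSYNONYMOUS_CLASSES, VariantCall, variants_to_frame

__all__ = [
    "CohortMutationMatrix",
    "SpectrumProfile",
    "build_matrix",
    "gene_frequencies",
    "functional_class_breakdown",
    "substitution_spectrum",
    "compare_frequencies",
    "benjamini_hochberg",
    "oncoplot",
]

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
SPECTRUM_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")


@dataclass
class CohortMutationMatrix:
    """Binary alteration matrix plus per-cell variant counts.

    ``altered.loc[sample, gene]`` is True when the sample carries >= 1
    passing nonsynonymous variant in the gene; ``n_variants`` counts
    them. Rows cover the full sample roster, including samples with no
    alterations, so frequencies are denominated correctly.
    """

    altered: pd.DataFrame  # bool, samples x genes
    n_variants: pd.DataFrame  # int, same shape

    @property
    def samples(self) -> list[str]:
        return list(self.altered.index)

    @property
    def genes(self) -> list[str]:
        return list(self.altered.columns)


def _as_frame(variants) -> pd.DataFrame:
    if isinstance(variants, pd.DataFrame):
        return variants
    return variants_to_frame(list(variants))


def build_matrix(
    passing_variants,
    sample_list: Sequence[str],
    nonsynonymous_classes: Iterable[str] = NONSYNONYMOUS_CLASSES,
) -> CohortMutationMatrix:
    """Count each sample once per gene, excluding synonymous variants.

    ``passing_variants`` is a variants DataFrame (MAF-like columns) or an
    iterable of :class:`VariantCall`. A variant whose sample is missing
    from ``sample_list`` raises, so denominators cannot silently drift.
    """
    df = _as_frame(passing_variants)
    samples = list(sample_list)
    sample_set = set(samples)
    if len(df):
        extra = set(df["sample_id"]) - sample_set
        if extra:
            raise ValueError(
                f"variants reference samples missing from the roster: {sorted(extra)[:5]}"
            )
        keep = df[df["functional_class"].isin(set(nonsynonymous_classes))]
    else:
        keep = df
    if len(keep):
        counts = (
            keep.groupby(["sample_id", "gene"]).size().unstack(fill_value=0)
        )
        genes = sorted(counts.columns)
        n_variants = counts.reindex(index=samples, columns=genes, fill_value=0)
    else:
        n_variants = pd.DataFrame(0, index=samples, columns=pd.Index([], dtype=object))
    n_variants = n_variants.astype(int)
    return CohortMutationMatrix(altered=n_variants >= 1, n_variants=n_variants)


def gene_frequencies(m: CohortMutationMatrix) -> pd.Series:
    """Fraction of roster samples altered, per gene."""
    if len(m.samples) == 0:
        raise ValueError("matrix has no samples")
    return m.altered.sum(axis=0) / len(m.samples)


def functional_class_breakdown(variants) -> pd.DataFrame:
    """Counts and percentages per functional class among protein-altering calls.

    Synonymous variants are excluded from both numerator and denominator;
    percentages are against the total nonsynonymous count.
    """
    df = _as_frame(variants)
    nonsyn = df[df["functional_class"].isin(NONSYNONYMOUS_CLASSES)]
    total = len(nonsyn)
    counts = nonsyn["functional_class"].value_counts()
    out = pd.DataFrame({
        "functional_class": counts.index,
        "count": counts.values,
    })
    out["pct"] = 100.0 * out["count"] / total if total else np.nan
    out.attrs["total_nonsynonymous"] = total
    return out.reset_index(drop=True)


@dataclass
class SpectrumProfile:
    """Single-base substitution spectrum on the pyrimidine strand."""

    counts: dict[str, int]
    c_to_t_cpg: int
    c_to_t_other: int

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def fractions(self) -> dict[str, float]:
        t = self.total
        return {k: v / t for k, v in self.counts.items()} if t else {}


def _collapse(ref: str, alt: str, context: str) -> tuple[str, str, str]:
    """Map a substitution onto the pyrimidine strand (involution-stable)."""
    if ref in "CT":
        return ref, alt, context
    rc = lambda s: "".join(_COMPLEMENT[b] for b in reversed(s))
    return _COMPLEMENT[ref], _COMPLEMENT[alt], rc(context)


def substitution_spectrum(snvs, contexts: Sequence[str] | None = None) -> SpectrumProfile:
    """Classify SNVs into the six substitution classes with a CpG split.

    Each SNV must come with its reference trinucleotide context (middle
    base = ref allele), either in a ``context`` column/attribute or via
    the parallel ``contexts`` sequence. Purine-reference substitutions
    are reverse-complemented onto the pyrimidine strand first; the CpG
    flag for C>T is true iff the collapsed context is 5'-C followed by G.
    """
    df = _as_frame(snvs)
    df = df[df["variant_type"] == "SNV"] if "variant_type" in df.columns else df
    if contexts is not None:
        if len(contexts) != len(df):
            raise ValueError("contexts length does not match number of SNVs")
        ctx_iter = list(contexts)
    else:
        ctx_iter = list(df["context"])
    counts = {c: 0 for c in SPECTRUM_CLASSES}
    cpg = non_cpg = 0
    for (ref, alt), context in zip(zip(df["ref"], df["alt"]), ctx_iter):
        if not isinstance(context, str) or len(context) != 3:
            raise ValueError(f"invalid trinucleotide context {context!r}")
        if context[1] != ref:
            raise ValueError(
                f"context {context} inconsistent with ref allele {ref}"
            )
        ref_c, alt_c, ctx_c = _collapse(ref, alt, context)
        cls = f"{ref_c}>{alt_c}"
        counts[cls] += 1
        if cls == "C>T":
            if ctx_c[2] == "G":
                cpg += 1
            else:
                non_cpg += 1
    return SpectrumProfile(counts=counts, c_to_t_cpg=cpg, c_to_t_other=non_cpg)


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """Step-up FDR-adjusted q-values across exactly the supplied family."""
    return multipletests(list(pvalues), method="fdr_bh")[1]


def compare_frequencies(
    a_counts: Sequence[int],
    n_a: int,
    b_counts: Sequence[int],
    n_b: int,
    genes: Sequence[str],
    yates_correction: bool = False,
) -> pd.DataFrame:
    """Per-gene 2x2 chi-square between two cohorts, BH-corrected.

    The multiple-testing family is exactly ``genes``. Results with any
    expected cell below 1 are flagged ``low_expected_count`` but still
    reported. Pearson chi-square without continuity correction is the
    default; set ``yates_correction`` for the corrected variant.
    """
    if not (len(a_counts) == len(b_counts) == len(genes)):
        raise ValueError("counts and gene list lengths differ")
    rows = []
    for gene, a, b in zip(genes, a_counts, b_counts):
        if a > n_a or b > n_b:
            raise ValueError(f"{gene}: count exceeds cohort size")
        table = np.array([[a, n_a - a], [b, n_b - b]], dtype=float)
        expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
        low_expected = bool((expected < 1).any())
        if (expected == 0).any():
            stat, p = np.nan, 1.0
        else:
            stat, p, _, _ = chi2_contingency(table, correction=yates_correction)
        rows.append({
            "gene": gene, "count_a": a, "n_a": n_a, "count_b": b, "n_b": n_b,
            "chi_square": stat, "p": p, "low_expected_count": low_expected,
        })
    out = pd.DataFrame(rows)
    out["q"] = benjamini_hochberg(out["p"])
    return out


def oncoplot(m: CohortMutationMatrix, ax=None, path: str | None = None):
    """Waterfall co-mutation plot: genes by descending frequency, samples
    sorted lexicographically by mutation pattern."""
    import matplotlib

    if path is not None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    freq = gene_frequencies(m).sort_values(ascending=False)
    genes = list(freq.index)
    ordered = m.altered[genes]
    sample_order = sorted(
        m.samples, key=lambda s: tuple(-int(v) for v in ordered.loc[s]),
    )
    grid = ordered.loc[sample_order].T.astype(int).values
    if ax is None:
        _, ax = plt.subplots(figsize=(max(6, len(sample_order) * 0.15), max(3, len(genes) * 0.3)))
    ax.imshow(grid, aspect="auto", cmap="Blues", vmin=0, vmax=1, interpolation="nearest")
    ax.set_yticks(range(len(genes)))
    ax.set_yticklabels([f"{g} ({100*freq[g]:.1f}%)" for g in genes], fontsize=7)
    ax.set_xlabel("samples")
    ax.set_xticks([])
    if path is not None:
        ax.figure.savefig(path, bbox_inches="tight", dpi=150)
    return ax
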