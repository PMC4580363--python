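"""Synthetic tumor cohorts with known somatic/germline truth.

The generator emulates two study designs at the variant-call level (no
reads are simulated):

* a *discovery*-style cohort — tumor plus matched normal, where truth is
  available from the normal; and
* a *prevalence*-style cohort — tumor-only, where germline variants must
  be removed by database membership and allele-fraction thresholding.

Each sample gets a purity ``p`` in (0,1]; each variant a local tumor
copy number ``C`` and mutant copy count ``m``. The expected allele
fraction mixes tumor and contaminating normal genomes:

    somatic:   p*m / (p*C + 2*(1-p))
    germline:  (p*g_t + (1-p)*g_n) / (p*C + 2*(1-p))

with ``g_t``/``g_n`` mutant copies in tumor/normal. Observed read
support is binomial at a negative-binomially distributed depth, split
across strands. Germline variants are present in at least one germline
allowlist with probability ``db_completeness``; somatic variants are
COSMIC-listed with probability ``cosmic_fraction``; a small fraction of
germline variants is also COSMIC-listed — the known failure mode of the
rescue rule, which the filter must surface as false positives.

Survival times are exponential, with the hazard multiplied by
``hazard_ratio_pathway`` for samples whose designated pathway carries at
least one nonsynonymous somatic variant, so proportional-hazards
recovery is well-posed by construction.

Defaults mirror the targeted-panel study the generator emulates: 60
samples, a mean of 61 somatic variants per sample, ~136x mean depth,
purity 0.5-0.8, and a pathway hazard ratio of 3.3 on disease-free
survival.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .variant_io import (
    DatabaseMembership,
    NormalEvidence,
    VariantCall,
    variants_to_frame,
)

__all__ = [
    "SimConfig",
    "SimSampleProfile",
    "SimCohortTruth",
    "expected_vaf",
    "simulate_read_support",
    "simulate_cohort",
    "default_gene_universe",
    "NOTCH_PATHWAY",
    "CHROMATIN_REMODELING",
]

# Gene sets mirroring the pathway analyses the cohort design supports:
# eleven Notch-signaling genes and ten chromatin-remodeling genes
# (KMT2A/C/D are the MLL-family histone methyltransferases).
NOTCH_PATHWAY = frozenset({
    "NOTCH1", "NOTCH2", "NOTCH3", "AR", "ARNT", "EP300", "CREBBP",
    "JAK2", "JAK3", "NCOA1", "PARP1",
})
CHROMATIN_REMODELING = frozenset({
    "CREBBP", "EP300", "KAT6A", "KMT2A", "KMT2D", "KMT2C", "NCOA1",
    "NSD1", "SETD2", "WHSC1",
})

# plausible coding lengths (bp) for the named panel genes; fillers cycle
_KNOWN_GENE_LENGTHS = {
    "TP53": 1182, "DST": 23000, "RNF213": 15543, "USH2A": 15609,
    "FAT1": 13767, "KMT2C": 14733, "COL6A6": 6700, "ZFHX4": 10800,
    "PLEC": 14000, "SYNE1": 26000, "NOTCH1": 7668, "NOTCH2": 7416,
    "NOTCH3": 6966, "AR": 2760, "ARNT": 2370, "EP300": 7245,
    "CREBBP": 7329, "JAK2": 3399, "JAK3": 3375, "NCOA1": 4320,
    "PARP1": 3045, "KAT6A": 6075, "KMT2A": 11910, "KMT2D": 16611,
    "NSD1": 8088, "SETD2": 7695, "WHSC1": 4041, "PIK3CA": 3207,
    "CASP8": 1440, "CDKN2A": 471, "HRAS": 570, "EGFR": 3630,
}
_FILLER_LENGTHS = (900, 1200, 1500, 1800, 2400, 3000, 4500)

_SUB_CLASSES = ("C>A", "C>G", "C>T_CpG", "C>T_other", "T>A", "T>C", "T>G")

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def default_gene_universe(n_genes: int = 465) -> list[tuple[str, int]]:
    """Deterministic (symbol, coding length) panel of ``n_genes`` genes.

    Starts with the named recurrent / pathway genes and pads with filler
    symbols whose lengths cycle through a fixed sequence.
    """
    universe = list(_KNOWN_GENE_LENGTHS.items())
    i = 0
    while len(universe) < n_genes:
        universe.append((f"PANEL{i:03d}", _FILLER_LENGTHS[i % len(_FILLER_LENGTHS)]))
        i += 1
    return universe[:n_genes]


@dataclass(frozen=True)
class SimConfig:
    """Knobs of the cohort generator; every probability is in [0,1]."""

    n_samples: int = 60
    n_germline_per_sample: int = 150  # Poisson mean, panel-restricted load
    n_somatic_per_sample: int = 61  # Poisson mean
    db_completeness: float = 0.98
    cosmic_fraction: float = 0.10  # somatic variants catalogued as cancer mutations
    germline_cosmic_fraction: float = 0.01  # germline variants also in COSMIC
    purity_range: tuple[float, float] = (0.5, 0.8)
    depth_mean: float = 136.0
    depth_dispersion: float = 8.0  # negative-binomial size parameter
    normal_depth_mean: float = 93.0
    cn_state_probs: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.10, 2: 0.70, 3: 0.15, 4: 0.05}
    )
    gene_universe: Sequence[tuple[str, int]] = field(
        default_factory=default_gene_universe
    )
    pathway_sets: Mapping[str, frozenset[str]] = field(
        default_factory=lambda: {
            "notch": NOTCH_PATHWAY,
            "chromatin_remodeling": CHROMATIN_REMODELING,
        }
    )
    hazard_pathway: str = "notch"
    hazard_ratio_pathway: float = 3.3
    baseline_hazard_per_month: float = 0.012
    censor_rate: float = 0.30
    indel_fraction: float = 0.09  # share of somatic variants that are indels
    het_fraction: float = 2 / 3  # germline het:hom = 2:1
    substitution_probs: Mapping[str, float] = field(
        default_factory=lambda: {
            "C>A": 0.12, "C>G": 0.15, "C>T_CpG": 0.25, "C>T_other": 0.20,
            "T>A": 0.08, "T>C": 0.12, "T>G": 0.08,
        }
    )
    functional_class_probs: Mapping[str, float] = field(
        default_factory=lambda: {
            "missense": 0.70, "synonymous": 0.14, "nonsense": 0.055,
            "splice_site": 0.028, "other": 0.077,
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("db_completeness", "cosmic_fraction", "germline_cosmic_fraction",
                     "censor_rate", "indel_fraction", "het_fraction"):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise ValueError(f"{name}={p} outside [0,1]")
        lo, hi = self.purity_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("purity_range must lie within (0,1]")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")
        if self.hazard_ratio_pathway <= 0:
            raise ValueError("hazard_ratio_pathway must be positive")
        if len(self.gene_universe) == 0:
            raise ValueError("gene_universe must be nonempty")
        if abs(sum(self.cn_state_probs.values()) - 1) > 1e-9:
            raise ValueError("cn_state_probs must sum to 1")


@dataclass(frozen=True)
class SimSampleProfile:
    """Purity and local copy state behind one variant's expected VAF."""

    sample_id: str
    purity: float
    copy_number: int
    mutant_copies: int

    def __post_init__(self) -> None:
        if not 0 < self.purity <= 1:
            raise ValueError("purity must be in (0,1]")
        if self.copy_number < 0:
            raise ValueError("copy_number must be >= 0")
        if not 1 <= self.mutant_copies <= max(self.copy_number, 2):
            raise ValueError("mutant_copies must be in [1, max(C,2)]")


class DegenerateProfileError(ValueError):
    """Total allele dosage at the locus is zero (no DNA to sample)."""


def expected_vaf(
    profile: SimSampleProfile,
    truth_label: str,
    germline_genotype: str | None = None,
    mutant_copies_normal: int | None = None,
) -> float:
    """Expected allele fraction under purity and copy-number admixture.

    For somatic variants the contaminating normal carries no mutant
    copies; for germline variants the normal contributes ``g_n`` mutant
    copies (1 het, 2 hom) and the tumor ``mutant_copies``.
    """
    p, C, m = profile.purity, profile.copy_number, profile.mutant_copies
    denom = p * C + 2 * (1 - p)
    if denom <= 0:
        raise DegenerateProfileError(
            f"zero allele dosage: purity={p}, copy_number={C}"
        )
    if truth_label == "somatic":
        return p * m / denom
    if truth_label == "germline":
        if mutant_copies_normal is None:
            if germline_genotype not in ("het", "hom"):
                raise ValueError("germline variant needs genotype 'het' or 'hom'")
            mutant_copies_normal = 1 if germline_genotype == "het" else 2
        return (p * m + (1 - p) * mutant_copies_normal) / denom
    raise ValueError(f"unknown truth label {truth_label!r}")


def simulate_read_support(
    vaf: float, depth: int, rng: np.random.Generator
) -> tuple[int, int]:
    """Binomial variant read count at the given depth."""
    if not 0 <= vaf <= 1:
        raise ValueError("vaf must be in [0,1]")
    if depth <= 0:
        raise ValueError("depth must be positive")
    return int(rng.binomial(depth, vaf)), int(depth)


def _draw_depth(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    p = dispersion / (dispersion + mean)
    return max(1, int(rng.negative_binomial(dispersion, p)))


def _germline_tumor_copies(rng: np.random.Generator, C: int, genotype: str) -> int:
    """Mutant copies in the tumor for a germline variant at copy state C.

    The mutant allele rides one parental haplotype; gains/losses hit a
    haplotype at random. Homozygous variants occupy all C copies.
    """
    if genotype == "hom":
        return C
    if C == 2:
        return 1
    if C == 1:
        return int(rng.integers(0, 2))  # lost or retained
    if C == 3:
        return int(rng.integers(1, 3))  # un-amplified or amplified haplotype
    # C == 4: both duplicated (2) or one duplicated twice (1 or 3)
    return int(rng.choice([1, 2, 3], p=[0.25, 0.5, 0.25]))


def _somatic_mutant_copies(rng: np.random.Generator, C: int) -> int:
    """Mutant copies for a somatic variant: one copy, occasionally amplified."""
    if C <= 2:
        return 1
    return 1 if rng.random() < 0.8 else int(rng.integers(2, C))


_CTX_BASES = ("A", "C", "G", "T")


def _draw_snv(rng: np.random.Generator, probs: Mapping[str, float]) -> tuple[str, str, str]:
    """Draw (ref, alt, trinucleotide context) from the substitution-class mix.

    Classes are defined on the pyrimidine strand; half the emitted calls
    are reported on the purine strand to exercise strand collapsing.
    """
    classes = list(probs)
    weights = np.array([probs[c] for c in classes], dtype=float)
    cls = classes[int(rng.choice(len(classes), p=weights / weights.sum()))]
    if cls.startswith("C>T"):
        ref, alt = "C", "T"
        five = _CTX_BASES[rng.integers(0, 4)]
        three = "G" if cls == "C>T_CpG" else _CTX_BASES[rng.integers(0, 3)]  # A/C/G->no G? see below
        if cls == "C>T_other" and three == "G":
            three = "T"
    else:
        # CpG split is tracked for C>T only; other classes may sit at
        # CpG sites freely
        ref, alt = cls.split(">")
        five = _CTX_BASES[rng.integers(0, 4)]
        three = _CTX_BASES[rng.integers(0, 4)]
    context = five + ref + three
    if rng.random() < 0.5:  # report on the purine strand
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        context = "".join(_COMPLEMENT[b] for b in reversed(context))
    return ref, alt, context


@dataclass
class SimCohortTruth:
    """Observed calls + ground truth + survival for one simulated cohort.

    ``variants`` is a MAF-like table extended with truth columns
    (``truth_label``, ``germline_genotype``, expected VAF, purity/copy
    state), matched-normal evidence, and the database membership flags.
    ``survival`` has one row per sample with OS/DFS endpoints and
    covariates.
    """

    variants: pd.DataFrame
    survival: pd.DataFrame
    config: SimConfig

    def variant_calls(self) -> Iterator[tuple[VariantCall, DatabaseMembership, NormalEvidence]]:
        """Dataclass view consumed by the scalar filter API."""
        from .variant_io import MAF_COLUMNS

        for row in self.variants.itertuples(index=False):
            kwargs = {c: getattr(row, c) for c in MAF_COLUMNS}
            for opt in ("fwd_variant_reads", "rev_variant_reads",
                        "mean_base_quality_window", "mean_read_mismatches",
                        "mean_mismatch_fraction", "context"):
                val = kwargs[opt]
                if isinstance(val, float) and np.isnan(val):
                    kwargs[opt] = None
            yield (
                VariantCall(**kwargs),
                DatabaseMembership(
                    in_dbsnp=bool(row.in_dbsnp),
                    in_thousand_genomes=bool(row.in_thousand_genomes),
                    in_evs=bool(row.in_evs),
                    in_panel_of_normals=bool(row.in_panel_of_normals),
                    in_cosmic=bool(row.in_cosmic),
                ),
                NormalEvidence(
                    normal_total_depth=int(row.normal_total_depth),
                    normal_variant_depth=int(row.normal_variant_depth),
                ),
            )

    def write(self, outdir: str | Path) -> None:
        """Write variants.tsv (observed + truth sidecar columns) and survival.tsv."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.variants.to_csv(outdir / "variants.tsv", sep="\t", index=False)
        self.survival.to_csv(outdir / "survival.tsv", sep="\t", index=False)


def simulate_cohort(config: SimConfig) -> SimCohortTruth:
    """Draw one cohort; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    genes = [g for g, _ in config.gene_universe]
    lengths = np.array([l for _, l in config.gene_universe], dtype=float)
    gene_weights = lengths / lengths.sum()
    gene_chrom = {g: str(1 + i % 22) for i, (g, _) in enumerate(config.gene_universe)}
    gene_base = {g: 1_000_000 * (1 + i) for i, (g, _) in enumerate(config.gene_universe)}
    cn_states = np.array(sorted(config.cn_state_probs))
    cn_probs = np.array([config.cn_state_probs[c] for c in cn_states], dtype=float)

    hazard_genes = config.pathway_sets.get(config.hazard_pathway, frozenset())
    lo, hi = config.purity_range

    variant_rows: list[dict] = []
    survival_rows: list[dict] = []

    for i in range(config.n_samples):
        sample_id = f"S{i:03d}"
        purity = float(rng.uniform(lo, hi))
        pathway_hit = False

        n_som = int(rng.poisson(config.n_somatic_per_sample))
        n_germ = int(rng.poisson(config.n_germline_per_sample))

        for truth_label, n_var in (("somatic", n_som), ("germline", n_germ)):
            if n_var == 0:
                continue
            gene_idx = rng.choice(len(genes), size=n_var, p=gene_weights)
            for gi in gene_idx:
                gene = genes[gi]
                C = int(cn_states[rng.choice(len(cn_states), p=cn_probs)])
                genotype = None
                g_n = None
                if truth_label == "germline":
                    genotype = "het" if rng.random() < config.het_fraction else "hom"
                    g_n = 1 if genotype == "het" else 2
                    m = _germline_tumor_copies(rng, C, genotype)
                    ev = (purity * m + (1 - purity) * g_n) / (
                        purity * C + 2 * (1 - purity)
                    )
                else:
                    m = _somatic_mutant_copies(rng, C)
                    profile = SimSampleProfile(sample_id, purity, C, m)
                    ev = expected_vaf(profile, "somatic")
                ev = min(ev, 1.0)

                is_indel = truth_label == "somatic" and rng.random() < config.indel_fraction
                if is_indel:
                    ins = rng.random() < 0.5
                    ref, alt = ("A", "A" + "ACGT"[rng.integers(0, 4)]) if ins else (
                        "A" + "ACGT"[rng.integers(0, 4)], "A")
                    variant_type = "insertion" if ins else "deletion"
                    context = None
                    fclass = "frameshift_indel" if rng.random() < 0.7 else "inframe_indel"
                else:
                    ref, alt, context = _draw_snv(rng, config.substitution_probs)
                    variant_type = "SNV"
                    fclasses = list(config.functional_class_probs)
                    fw = np.array([config.functional_class_probs[c] for c in fclasses])
                    fclass = fclasses[int(rng.choice(len(fclasses), p=fw / fw.sum()))]

                depth = _draw_depth(rng, config.depth_mean, config.depth_dispersion)
                var_depth, depth = simulate_read_support(ev, depth, rng)
                fwd = int(rng.binomial(var_depth, 0.5))

                normal_depth = _draw_depth(rng, config.normal_depth_mean, config.depth_dispersion)
                if truth_label == "germline":
                    normal_var_depth = int(rng.binomial(normal_depth, g_n / 2))
                else:
                    normal_var_depth = 0

                if truth_label == "germline":
                    allowlisted = rng.random() < config.db_completeness
                    in_dbsnp = allowlisted and rng.random() < 0.85
                    in_tg = allowlisted and rng.random() < 0.5
                    in_evs = allowlisted and rng.random() < 0.4
                    in_pon = allowlisted and rng.random() < 0.7
                    if allowlisted and not (in_dbsnp or in_tg or in_evs or in_pon):
                        in_dbsnp = True
                    in_cosmic = rng.random() < config.germline_cosmic_fraction
                else:
                    in_dbsnp = in_tg = in_evs = in_pon = False
                    in_cosmic = rng.random() < config.cosmic_fraction

                region = "canonical_splice" if fclass == "splice_site" else "exon"
                pos = int(gene_base[gene] + rng.integers(0, max(int(lengths[gi]), 1)))

                if (
                    truth_label == "somatic"
                    and gene in hazard_genes
                    and fclass != "synonymous"
                ):
                    pathway_hit = True

                variant_rows.append({
                    "sample_id": sample_id, "chrom": gene_chrom[gene], "pos": pos,
                    "ref": ref, "alt": alt, "variant_type": variant_type,
                    "gene": gene, "functional_class": fclass,
                    "variant_depth": var_depth, "total_depth": depth,
                    "fwd_variant_reads": fwd, "rev_variant_reads": var_depth - fwd,
                    "in_capture_target": True, "region_class": region,
                    "in_simple_repeat": False,
                    "mean_base_quality_window": round(float(rng.normal(32, 3)), 2) if is_indel else None,
                    "mean_read_mismatches": round(float(rng.gamma(2, 0.8)), 2) if is_indel else None,
                    "mean_mismatch_fraction": round(float(rng.beta(1.2, 12)), 4) if is_indel else None,
                    "context": context,
                    "vaf": var_depth / depth,
                    "truth_label": truth_label,
                    "germline_genotype": genotype,
                    "purity": round(purity, 4),
                    "copy_number": C, "mutant_copies": m,
                    "expected_vaf": round(ev, 6),
                    "normal_total_depth": normal_depth,
                    "normal_variant_depth": normal_var_depth,
                    "in_dbsnp": in_dbsnp, "in_thousand_genomes": in_tg,
                    "in_evs": in_evs, "in_panel_of_normals": in_pon,
                    "in_cosmic": in_cosmic,
                })

        # survival: exponential DFS/OS with pathway hazard multiplier
        hr = config.hazard_ratio_pathway if pathway_hit else 1.0
        dfs = float(rng.exponential(1.0 / (config.baseline_hazard_per_month * hr)))
        os_t = float(rng.exponential(1.0 / (0.8 * config.baseline_hazard_per_month * hr)))
        dfs_event, os_event = 1, 1
        if rng.random() < config.censor_rate:
            dfs, dfs_event = dfs * float(rng.uniform()), 0
        if rng.random() < config.censor_rate:
            os_t, os_event = os_t * float(rng.uniform()), 0
        survival_rows.append({
            "sample_id": sample_id,
            "os_months": round(max(os_t, 0.03), 3),
            "os_event": os_event,
            "dfs_months": round(max(dfs, 0.03), 3),
            "dfs_event": dfs_event,
            "age": int(np.clip(rng.normal(58, 13), 21, 89)),
            "smoker": int(rng.random() < 0.517),
            "n_stage_positive": int(rng.random() < 0.467),
            "extracapsular_spread": int(rng.random() < 0.3),
            "pathway_altered": int(pathway_hit),
        })

    variants = pd.DataFrame(variant_rows)
    survival = pd.DataFrame(survival_rows)
    return SimCohortTruth(variants=variants, survival=survival, config=config)
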