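"""Synthetic worked-example cohort tables.

The per-patient mutation tables of the targeted-sequencing cohort this
package's defaults emulate are controlled-access and cannot ship here.
These functions generate *synthetic stand-in* tables from code: they
reproduce only published cohort-level marginal counts (per-gene altered
sample counts, mutually exclusive pathway alteration patterns), with
arbitrary sample-to-gene assignments and placeholder coordinates. They
exist so the landscape/gene-set machinery has a worked example with
known expected output; they are not the study's data.
"""

from __future__ import annotations

import pandas as pd

from .simulate import CHROMATIN_REMODELING, NOTCH_PATHWAY

__all__ = [
    "prevalence_mutation_table",
    "discovery_functional_class_table",
    "PREVALENCE_N_SAMPLES",
]

PREVALENCE_N_SAMPLES = 60

# per-gene altered-sample counts out of 60 (recurrently mutated genes)
_RECURRENT_COUNTS = {
    "TP53": 23,   # 38.3%
    "DST": 16,    # 26.7%
    "RNF213": 10, # 16.7%
    "USH2A": 10,
    "FAT1": 10,
    "KMT2C": 10,  # MLL3
    "COL6A6": 9,  # 15.0%
    "ZFHX4": 9,
    "PLEC": 9,
    "SYNE1": 8,   # 13.3%
}

# mutually exclusive Notch-pathway assignments: 19 distinct samples
_NOTCH_ASSIGNMENTS = {
    "NOTCH1": (0, 1, 2),
    "NOTCH2": (3, 4),
    "NOTCH3": (5, 6),
    "EP300": (7, 8),
    "CREBBP": (9, 10),
    "NCOA1": (11,),
    "JAK2": (12, 13),
    "JAK3": (14,),
    "AR": (15, 16),
    "ARNT": (17,),
    "PARP1": (18,),
}

# chromatin-remodeling assignments: EP300/CREBBP/NCOA1 samples above
# (5 samples) plus 20 more distinct samples = 25 altered samples total
_CHROMATIN_ASSIGNMENTS = {
    "KMT2C": tuple(range(19, 29)),  # also fixes the KMT2C count at 10
    "KMT2D": (29, 30),
    "NSD1": (31, 32),
    "SETD2": (33, 34),
    "KAT6A": (35,),
    "KMT2A": (36, 37),
    "WHSC1": (38,),
}

# remaining recurrent genes: arbitrary contiguous sample blocks
_OTHER_ASSIGNMENTS = {
    "TP53": tuple(range(0, 23)),
    "DST": tuple(range(10, 26)),
    "RNF213": tuple(range(30, 40)),
    "USH2A": tuple(range(35, 45)),
    "FAT1": tuple(range(40, 50)),
    "COL6A6": tuple(range(45, 54)),
    "ZFHX4": tuple(range(48, 57)),
    "PLEC": tuple(range(50, 59)),
    "SYNE1": tuple(range(52, 60)),
}

_CLASS_CYCLE = ("missense", "missense", "missense", "nonsense", "frameshift_indel")


def prevalence_mutation_table() -> pd.DataFrame:
    """Synthetic 60-sample mutation table with fixed marginal counts.

    One row per (sample, gene) alteration, MAF-like columns sufficient
    for :func:`somaticlens.landscape.build_matrix`. By construction:
    TP53 in 23/60 samples, DST 16/60, RNF213/USH2A/FAT1/KMT2C 10/60,
    COL6A6/ZFHX4/PLEC 9/60, SYNE1 8/60; exactly 19 samples carry a
    (mutually exclusive) Notch-pathway alteration and exactly 25 a
    chromatin-remodeling alteration.
    """
    assignments: dict[str, tuple[int, ...]] = {}
    assignments.update(_NOTCH_ASSIGNMENTS)
    assignments.update(_CHROMATIN_ASSIGNMENTS)
    assignments.update(_OTHER_ASSIGNMENTS)

    rows = []
    k = 0
    for gene in sorted(assignments):
        for s in assignments[gene]:
            fclass = _CLASS_CYCLE[k % len(_CLASS_CYCLE)]
            rows.append({
                "sample_id": f"P{s:02d}",
                "chrom": "1",
                "pos": 1000 + k,
                "ref": "C" if fclass != "frameshift_indel" else "CA",
                "alt": "T" if fclass != "frameshift_indel" else "C",
                "variant_type": "SNV" if fclass != "frameshift_indel" else "deletion",
                "gene": gene,
                "functional_class": fclass,
                "variant_depth": 30,
                "total_depth": 100,
            })
            k += 1
    return pd.DataFrame(rows)


def prevalence_sample_roster() -> list[str]:
    return [f"P{s:02d}" for s in range(PREVALENCE_N_SAMPLES)]


def discovery_functional_class_table() -> pd.DataFrame:
    """Synthetic variant table with a fixed functional-class composition.

    1,092 nonsynonymous calls: 888 missense, 68 nonsense, 36 splice-site
    (the 992 SNVs) plus 100 indels (70 frameshift, 30 in-frame). Used as
    the worked example for the functional-class breakdown.
    """
    composition = {
        "missense": 888,
        "nonsense": 68,
        "splice_site": 36,
        "frameshift_indel": 70,
        "inframe_indel": 30,
    }
    rows = []
    i = 0
    for fclass, n in composition.items():
        is_indel = fclass.endswith("indel")
        for _ in range(n):
            rows.append({
                "sample_id": f"D{i % 18:02d}",
                "chrom": "1",
                "pos": 5000 + i,
                "ref": "CA" if is_indel else "C",
                "alt": "C" if is_indel else "A",
                "variant_type": "deletion" if is_indel else "SNV",
                "gene": f"G{i % 750:03d}",
                "functional_class": fclass,
                "variant_depth": 20,
                "total_depth": 80,
            })
            i += 1
    return pd.DataFrame(rows)
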