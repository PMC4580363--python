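"""Variant table I/O, normalization and database-membership annotation.

Two on-disk dialects are supported:

* **VCF 4.x** (read/write, via :mod:`pysam`): one record per variant call,
  genotype columns carry ``AD``/``DP`` read support, and call-level
  annotations travel in INFO (``GENE``, ``FCLASS``, ``RCLASS``, ``TGT``,
  ``SRPT``, ``CTX``, ``SADF``/``SADR`` strand counts, and the microindel
  quality metrics ``IBQ``/``IMM``/``IMF``).
* **MAF-like TSV** (read/write, via :mod:`pandas`): one row per call with
  the columns in :data:`MAF_COLUMNS`, 1-based inclusive coordinates,
  boolean flags encoded 0/1. This dialect is the lossless one — it round
  trips every :class:`VariantCall` field.

Database allowlists (dbSNP-like, population, panel-of-normals) and the
COSMIC-like somatic catalogue are loaded into an exact-match
:class:`AllowlistIndex` keyed on the trimmed, left-shifted representation
of ``(chrom, pos, ref, alt)``. All ref/alt alleles are on the + strand of
the reference, as in VCF.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

__all__ = [
    "VariantCall",
    "NormalEvidence",
    "DatabaseMembership",
    "AllowlistIndex",
    "VariantParseError",
    "normalize_variant",
    "read_variants",
    "write_variants",
    "build_allowlist_index",
    "annotate_membership",
    "variants_to_frame",
    "frame_to_calls",
]

SNV = "SNV"
INSERTION = "insertion"
DELETION = "deletion"

FUNCTIONAL_CLASSES = (
    "missense",
    "nonsense",
    "splice_site",
    "synonymous",
    "frameshift_indel",
    "inframe_indel",
    "other",
)

#: functional classes counted as protein-altering throughout the package
NONSYNONYMOUS_CLASSES = frozenset(
    c for c in FUNCTIONAL_CLASSES if c != "synonymous"
)

REGION_CLASSES = ("exon", "canonical_splice", "other")

#: germline allowlist labels, in the order they appear on DatabaseMembership
GERMLINE_DB_LABELS = ("dbsnp", "thousand_genomes", "evs", "panel_of_normals")
COSMIC_LABEL = "cosmic"


class VariantParseError(ValueError):
    """Raised when a variant file cannot be parsed under its dialect."""


@dataclass
class VariantCall:
    """One observed variant in one tumor sample, with read support.

    ``vaf`` is derived (variant_depth / total_depth); the microindel
    quality fields are ``None`` for SNVs.
    """

    sample_id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    variant_type: str = SNV
    gene: str = ""
    functional_class: str = "other"
    variant_depth: int = 0
    total_depth: int = 0
    fwd_variant_reads: int | None = None
    rev_variant_reads: int | None = None
    in_capture_target: bool = True
    region_class: str = "exon"
    in_simple_repeat: bool = False
    mean_base_quality_window: float | None = None
    mean_read_mismatches: float | None = None
    mean_mismatch_fraction: float | None = None
    context: str | None = None  # reference trinucleotide around an SNV

    def __post_init__(self) -> None:
        self.ref = self.ref.upper()
        self.alt = self.alt.upper()
        if self.variant_depth > self.total_depth:
            raise ValueError(
                f"variant_depth {self.variant_depth} exceeds total_depth "
                f"{self.total_depth} at {self.chrom}:{self.pos}"
            )
        if self.variant_type == SNV and self.ref == self.alt:
            raise ValueError(f"ref == alt for SNV at {self.chrom}:{self.pos}")
        if (
            self.fwd_variant_reads is not None
            and self.rev_variant_reads is not None
            and self.fwd_variant_reads + self.rev_variant_reads != self.variant_depth
        ):
            raise ValueError(
                "strand-split variant reads do not sum to variant_depth "
                f"at {self.chrom}:{self.pos}"
            )

    @property
    def vaf(self) -> float:
        """Variant allele fraction (NaN when total_depth is 0)."""
        if self.total_depth == 0:
            return float("nan")
        return self.variant_depth / self.total_depth

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Normalized (chrom, pos, ref, alt) used for allowlist lookup."""
        return normalize_variant(self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class NormalEvidence:
    """Read support at the same locus in the matched normal sample."""

    normal_total_depth: int
    normal_variant_depth: int = 0

    def __post_init__(self) -> None:
        if self.normal_variant_depth > self.normal_total_depth:
            raise ValueError("normal_variant_depth exceeds normal_total_depth")


@dataclass(frozen=True)
class DatabaseMembership:
    """Per-variant presence flags against the configured databases."""

    in_dbsnp: bool = False
    in_thousand_genomes: bool = False
    in_evs: bool = False
    in_panel_of_normals: bool = False
    in_cosmic: bool = False
    #: ExAC is supported but excluded from annotation by default: filtering
    #: on it removes a large share of true TP53 driver mutations.
    in_exac: bool = False

    @property
    def in_any_germline_db(self) -> bool:
        return (
            self.in_dbsnp
            or self.in_thousand_genomes
            or self.in_evs
            or self.in_panel_of_normals
            or self.in_exac
        )


def normalize_variant(
    chrom: str, pos: int, ref: str, alt: str
) -> tuple[str, int, str, str]:
    """Trim shared allele sequence so equivalent representations key alike.

    Right-trims the common suffix, then left-trims the common prefix while
    advancing ``pos``, always leaving at least one base on each allele —
    the parsimony/left-shift convention used for indel matching across
    dialects. SNVs are returned unchanged (upper-cased).
    """
    ref, alt = ref.upper(), alt.upper()
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return str(chrom), int(pos), ref, alt


def infer_variant_type(ref: str, alt: str) -> str:
    if len(ref) == len(alt) == 1:
        return SNV
    return INSERTION if len(alt) > len(ref) else DELETION


class AllowlistIndex:
    """Exact-match lookup (chrom, pos, ref, alt) -> set of database labels."""

    def __init__(self) -> None:
        self._index: dict[tuple[str, int, str, str], set[str]] = {}
        self.versions: dict[str, str] = {}

    def add(
        self, chrom: str, pos: int, ref: str, alt: str, label: str, version: str = ""
    ) -> None:
        key = normalize_variant(chrom, pos, ref, alt)
        self._index.setdefault(key, set()).add(label)
        if version:
            self.versions.setdefault(label, version)

    def labels(self, chrom: str, pos: int, ref: str, alt: str) -> set[str]:
        return self._index.get(normalize_variant(chrom, pos, ref, alt), set())

    def __contains__(self, key: tuple[str, int, str, str]) -> bool:
        return normalize_variant(*key) in self._index

    def __len__(self) -> int:
        return len(self._index)


# ---------------------------------------------------------------------------
# MAF-like TSV dialect
# ---------------------------------------------------------------------------

MAF_COLUMNS = [
    "sample_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "variant_type",
    "gene",
    "functional_class",
    "variant_depth",
    "total_depth",
    "fwd_variant_reads",
    "rev_variant_reads",
    "in_capture_target",
    "region_class",
    "in_simple_repeat",
    "mean_base_quality_window",
    "mean_read_mismatches",
    "mean_mismatch_fraction",
    "context",
]

_BOOL_COLS = ("in_capture_target", "in_simple_repeat")
_OPT_INT_COLS = ("fwd_variant_reads", "rev_variant_reads")
_OPT_FLOAT_COLS = (
    "mean_base_quality_window",
    "mean_read_mismatches",
    "mean_mismatch_fraction",
)


def variants_to_frame(variants: Iterable[VariantCall]) -> pd.DataFrame:
    """Tabulate calls into the MAF-like dialect (plus a derived vaf column)."""
    rows = []
    for v in variants:
        row = {f.name: getattr(v, f.name) for f in fields(v)}
        row["vaf"] = v.vaf
        rows.append(row)
    df = pd.DataFrame(rows, columns=MAF_COLUMNS + ["vaf"])
    return df


def frame_to_calls(df: pd.DataFrame) -> list[VariantCall]:
    """Inverse of :func:`variants_to_frame` for the MAF-like columns."""
    calls = []
    for row in df.itertuples(index=False):
        kwargs = {}
        for col in MAF_COLUMNS:
            val = getattr(row, col, None)
            if col in ("pos", "variant_depth", "total_depth"):
                val = int(val)
            elif col in _BOOL_COLS:
                val = bool(val)
            elif col in _OPT_INT_COLS:
                val = None if val is None or (isinstance(val, float) and np.isnan(val)) else int(val)
            elif col in _OPT_FLOAT_COLS:
                val = None if val is None or (isinstance(val, float) and np.isnan(val)) else float(val)
            elif col == "context":
                if val is None or (isinstance(val, float) and np.isnan(val)) or val == "":
                    val = None
            kwargs[col] = val
        calls.append(VariantCall(**kwargs))
    return calls


def _read_maf_tsv(path: str | Path) -> list[VariantCall]:
    try:
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise VariantParseError(f"{path}: {exc}") from exc
    missing = {"sample_id", "chrom", "pos", "ref", "alt"} - set(df.columns)
    if missing:
        raise VariantParseError(
            f"{path}: MAF-like TSV missing required columns {sorted(missing)}"
        )
    if df.empty:
        return []
    n_missing_depth = df["total_depth"].isna().sum() if "total_depth" in df else len(df)
    if n_missing_depth:
        warnings.warn(
            f"{path}: skipped {n_missing_depth} records lacking depth fields",
            stacklevel=2,
        )
        df = df.dropna(subset=["total_depth"])
    for col in MAF_COLUMNS:
        if col not in df.columns:
            df[col] = None
    df["variant_type"] = [
        vt if isinstance(vt, str) else infer_variant_type(r, a)
        for vt, r, a in zip(df["variant_type"], df["ref"], df["alt"])
    ]
    df["gene"] = df["gene"].fillna("")
    df["functional_class"] = df["functional_class"].fillna("other")
    df["region_class"] = df["region_class"].fillna("exon")
    df["variant_depth"] = df["variant_depth"].fillna(0)
    df["in_capture_target"] = df["in_capture_target"].fillna(1)
    df["in_simple_repeat"] = df["in_simple_repeat"].fillna(0)
    return frame_to_calls(df)


def _write_maf_tsv(variants: Sequence[VariantCall], path: str | Path) -> None:
    df = variants_to_frame(variants).drop(columns=["vaf"])
    for col in _BOOL_COLS:
        df[col] = df[col].astype(int)
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# VCF dialect
# ---------------------------------------------------------------------------

_VCF_INFO = [
    ("GENE", "1", "String", "Gene symbol"),
    ("FCLASS", "1", "String", "Functional class"),
    ("RCLASS", "1", "String", "Region class (exon/canonical_splice/other)"),
    ("TGT", "1", "Integer", "Inside capture target (0/1)"),
    ("SRPT", "1", "Integer", "Inside simple repeat (0/1)"),
    ("CTX", "1", "String", "Reference trinucleotide context"),
    ("SADF", "1", "Integer", "Variant reads on forward strand"),
    ("SADR", "1", "Integer", "Variant reads on reverse strand"),
    ("IBQ", "1", "Float", "Mean base quality in/around microindel"),
    ("IMM", "1", "Float", "Mean mismatches in microindel-supporting reads"),
    ("IMF", "1", "Float", "Mean mismatched-base fraction in supporting reads"),
]


def _vcf_header(samples: Sequence[str], contigs: Sequence[str]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for contig in contigs:
        header.contigs.add(contig)
    for name, number, vtype, desc in _VCF_INFO:
        header.info.add(name, number, vtype, desc)
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    header.formats.add("DP", "1", "Integer", "Total read depth")
    for s in samples:
        header.add_sample(s)
    return header


def _write_vcf(variants: Sequence[VariantCall], path: str | Path) -> None:
    samples = sorted({v.sample_id for v in variants})
    contigs = sorted({v.chrom for v in variants}, key=str)
    vcf = pysam.VariantFile(str(path), "w", header=_vcf_header(samples, contigs))
    for v in sorted(variants, key=lambda x: (str(x.chrom), x.pos)):
        rec = vcf.new_record(
            contig=v.chrom,
            start=v.pos - 1,
            stop=v.pos - 1 + len(v.ref),
            alleles=(v.ref, v.alt),
        )
        rec.info["GENE"] = v.gene or "."
        rec.info["FCLASS"] = v.functional_class
        rec.info["RCLASS"] = v.region_class
        rec.info["TGT"] = int(v.in_capture_target)
        rec.info["SRPT"] = int(v.in_simple_repeat)
        if v.context:
            rec.info["CTX"] = v.context
        if v.fwd_variant_reads is not None:
            rec.info["SADF"] = v.fwd_variant_reads
        if v.rev_variant_reads is not None:
            rec.info["SADR"] = v.rev_variant_reads
        if v.mean_base_quality_window is not None:
            rec.info["IBQ"] = v.mean_base_quality_window
        if v.mean_read_mismatches is not None:
            rec.info["IMM"] = v.mean_read_mismatches
        if v.mean_mismatch_fraction is not None:
            rec.info["IMF"] = v.mean_mismatch_fraction
        rec.samples[v.sample_id]["AD"] = (v.total_depth - v.variant_depth, v.variant_depth)
        rec.samples[v.sample_id]["DP"] = v.total_depth
        vcf.write(rec)
    vcf.close()


def _read_vcf(path: str | Path) -> list[VariantCall]:
    try:
        vcf = pysam.VariantFile(str(path))
    except Exception as exc:
        raise VariantParseError(f"{path}: {exc}") from exc
    calls: list[VariantCall] = []
    n_skipped = 0
    with vcf:
        for rec in vcf:
            info = rec.info
            alts = rec.alts or ()
            for alt_i, alt in enumerate(alts):
                for sample_id, call in rec.samples.items():
                    dp = call.get("DP")
                    ad = call.get("AD")
                    if dp is None or ad is None or ad[0] is None:
                        continue
                    alt_depth = ad[alt_i + 1]
                    if alt_depth is None:
                        n_skipped += 1
                        continue
                    calls.append(
                        VariantCall(
                            sample_id=sample_id,
                            chrom=rec.chrom,
                            pos=rec.pos,
                            ref=rec.ref,
                            alt=alt,
                            variant_type=infer_variant_type(rec.ref, alt),
                            gene=_info_str(info, "GENE"),
                            functional_class=_info_str(info, "FCLASS") or "other",
                            variant_depth=int(alt_depth),
                            total_depth=int(dp),
                            fwd_variant_reads=_info_opt(info, "SADF", int),
                            rev_variant_reads=_info_opt(info, "SADR", int),
                            in_capture_target=bool(_info_get(info, "TGT", 1)),
                            region_class=_info_str(info, "RCLASS") or "exon",
                            in_simple_repeat=bool(_info_get(info, "SRPT", 0)),
                            mean_base_quality_window=_info_opt(info, "IBQ", float),
                            mean_read_mismatches=_info_opt(info, "IMM", float),
                            mean_mismatch_fraction=_info_opt(info, "IMF", float),
                            context=_info_str(info, "CTX") or None,
                        )
                    )
    if n_skipped:
        warnings.warn(
            f"{path}: skipped {n_skipped} sample-calls lacking depth fields",
            stacklevel=2,
        )
    return calls


def _info_get(info, key, default=None):
    # pysam raises on keys absent from the header; foreign VCFs lack ours
    try:
        return info.get(key, default)
    except (KeyError, ValueError):
        return default


def _info_str(info, key) -> str:
    val = _info_get(info, key)
    if val is None or val == ".":
        return ""
    return str(val)


def _info_opt(info, key, cast):
    val = _info_get(info, key)
    return None if val is None else cast(val)


# ---------------------------------------------------------------------------
# public read/write and annotation
# ---------------------------------------------------------------------------

def read_variants(path: str | Path, format: str = "vcf") -> list[VariantCall]:
    """Read a variant table; one :class:`VariantCall` per alt allele.

    Multi-allelic VCF records are decomposed, coordinates stay 1-based.
    ``format`` is ``"vcf"`` or ``"maf_tsv"``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "vcf":
        return _read_vcf(path)
    if format == "maf_tsv":
        return _read_maf_tsv(path)
    raise ValueError(f"unknown variant format {format!r}")


def write_variants(
    variants: Sequence[VariantCall], path: str | Path, format: str = "vcf"
) -> None:
    """Write calls in one of the supported dialects (see :func:`read_variants`)."""
    if format == "vcf":
        _write_vcf(variants, path)
    elif format == "maf_tsv":
        _write_maf_tsv(variants, path)
    else:
        raise ValueError(f"unknown variant format {format!r}")


def build_allowlist_index(
    sources: Sequence[tuple[str | Path, str | None]],
) -> AllowlistIndex:
    """Load allowlist tables into one exact-match index.

    ``sources`` is a sequence of ``(path, label)``; ``label`` may be None
    for TSVs that carry their own ``db_label`` column. Allowlist TSV
    columns: ``chrom pos ref alt db_label [version]``. VCF sources take
    every record's (decomposed) alleles under the supplied label.
    Duplicate (variant, database) entries collapse silently.
    """
    index = AllowlistIndex()
    for path, label in sources:
        path = Path(path)
        if path.suffix in (".vcf", ".gz") or str(path).endswith(".vcf.gz"):
            if label is None:
                raise ValueError(f"{path}: VCF allowlist requires an explicit label")
            with pysam.VariantFile(str(path)) as vcf:
                for rec in vcf:
                    for alt in rec.alts or ():
                        index.add(rec.chrom, rec.pos, rec.ref, alt, label)
        else:
            df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
            required = {"chrom", "pos", "ref", "alt"}
            if not required <= set(df.columns):
                raise VariantParseError(
                    f"{path}: allowlist TSV needs columns {sorted(required)}"
                )
            has_label_col = "db_label" in df.columns
            if not has_label_col and label is None:
                raise ValueError(f"{path}: no db_label column and no label given")
            for row in df.itertuples(index=False):
                row_label = getattr(row, "db_label", None) if has_label_col else None
                version = str(getattr(row, "version", "") or "")
                index.add(
                    row.chrom, int(row.pos), row.ref, row.alt,
                    str(row_label or label), version,
                )
    return index


def annotate_membership(
    variants: Sequence[VariantCall],
    index: AllowlistIndex,
    include_exac: bool = False,
) -> list[DatabaseMembership]:
    """Look every call up in the allowlists; order-preserving and pure.

    Labels map onto flags as dbsnp/thousand_genomes/evs/panel_of_normals/
    cosmic; unrecognized labels are ignored with a warning. An ``exac``
    allowlist only contributes to the germline OR when ``include_exac``
    is set (it is off by default because it catalogues many recurrent
    TP53 somatic drivers).
    """
    known = set(GERMLINE_DB_LABELS) | {COSMIC_LABEL, "exac"}
    memberships = []
    unknown: set[str] = set()
    for v in variants:
        labels = index.labels(v.chrom, v.pos, v.ref, v.alt)
        unknown |= labels - known
        memberships.append(
            DatabaseMembership(
                in_dbsnp="dbsnp" in labels,
                in_thousand_genomes="thousand_genomes" in labels,
                in_evs="evs" in labels,
                in_panel_of_normals="panel_of_normals" in labels,
                in_cosmic=COSMIC_LABEL in labels,
                in_exac=include_exac and "exac" in labels,
            )
        )
    if unknown:
        warnings.warn(f"ignored unknown allowlist labels: {sorted(unknown)}", stacklevel=2)
    return memberships
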