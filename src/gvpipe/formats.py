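"""Readers and writers for every on-disk artifact the pipeline touches.

The pipeline's file dialects are deliberately plain: single-sample VCF 4.x
(FORMAT fields GT, DP and VD-or-AD), samtools-depth style 3-column TSV, BED3,
tab-separated genotype-status tables with a ``CHROM POS REF ALT <sample...>``
header, two-column patient lists, Annovar "avinput" variant tables and a CSV
clinical table.  All joins and unions across files key on the
:class:`VariantKey` tuple ``(chrom, pos, ref, alt)`` with 1-based positions.

Only single-nucleotide variants are in scope; indel and structural-variant
records are skipped on read and rejected on construction.
"""

from __future__ import annotations

from typing import Iterable, NamedTuple, Optional, Sequence

import pandas as pd
import pysam

__all__ = [
    "HOM_REF",
    "HET",
    "HOM_ALT",
    "UNKNOWN",
    "STATUSES",
    "CALLS",
    "FormatError",
    "RecordError",
    "VariantKey",
    "GenotypeRecord",
    "DepthRecord",
    "VcfVariant",
    "variant_sort_key",
    "sort_variant_keys",
    "read_vcf",
    "write_vcf",
    "filter_pass",
    "read_depth_tsv",
    "write_depth_tsv",
    "write_bed",
    "read_bed_positions",
    "write_annovar_input",
    "read_annovar_keys",
    "read_patient_map",
    "read_status_table",
    "write_status_table",
    "read_clinical",
    "read_population_af",
    "write_population_af",
]

# The four-valued per-sample variant status vocabulary.  ``unknown`` encodes
# insufficient sequencing coverage, not a failed call.
HOM_REF = "Homozygous_ref"
HET = "Heterozygous"
HOM_ALT = "Homozygous_alt"
UNKNOWN = "unknown"
STATUSES = (HOM_REF, HET, HOM_ALT, UNKNOWN)
#: Statuses a variant caller can emit (a caller never reports hom-ref sites).
CALLS = (HET, HOM_ALT)

_VALID_BASES = frozenset("ACGT")


class FormatError(ValueError):
    """A file does not conform to the expected dialect."""


class RecordError(FormatError):
    """A single record within an otherwise well-formed file is unparseable."""


class VariantKey(NamedTuple):
    """Identity of a single-nucleotide variant: ``(chrom, pos, ref, alt)``.

    ``pos`` is 1-based.  This tuple is the join key for every union, merge
    and lookup in the pipeline.
    """

    chrom: str
    pos: int
    ref: str
    alt: str

    @classmethod
    def make(cls, chrom: str, pos: int, ref: str, alt: str) -> "VariantKey":
        """Validated constructor: SNVs only, ``pos >= 1``, ``ref != alt``."""
        pos = int(pos)
        if pos < 1:
            raise ValueError(f"position must be >= 1, got {pos}")
        ref = str(ref).upper()
        alt = str(alt).upper()
        if ref not in _VALID_BASES or alt not in _VALID_BASES:
            raise ValueError(
                f"only single-nucleotide A/C/G/T alleles supported, got {ref}>{alt}"
            )
        if ref == alt:
            raise ValueError(f"ref and alt alleles are identical ({ref})")
        return cls(str(chrom), pos, ref, alt)


class GenotypeRecord(NamedTuple):
    """Per sample-and-variant genotype call with read-depth evidence."""

    sample_id: str
    key: VariantKey
    call: str  # HET or HOM_ALT
    total_depth: int
    variant_depth: int


class DepthRecord(NamedTuple):
    """Read depth at one genomic position (1-based)."""

    chrom: str
    pos: int
    depth: int


class VcfVariant(NamedTuple):
    """One VCF data line: variant key, FILTER label, genotype evidence."""

    key: VariantKey
    filter: str
    genotype: GenotypeRecord


_CHROM_RANK = {f"chr{i}": i for i in range(1, 23)}
_CHROM_RANK.update({"chrX": 23, "chrY": 24, "chrM": 25, "chrMT": 25})


def _chrom_rank(chrom: str) -> tuple:
    """Natural ordering of human chromosome names (chr1..chr22, chrX, chrY)."""
    name = chrom if chrom.startswith("chr") else "chr" + chrom
    if name in _CHROM_RANK:
        return (0, _CHROM_RANK[name], "")
    return (1, 0, chrom)


def variant_sort_key(key: VariantKey) -> tuple:
    return (*_chrom_rank(key.chrom), key.pos, key.ref, key.alt)


def sort_variant_keys(keys: Iterable[VariantKey]) -> list[VariantKey]:
    """Deterministic total ordering by (chrom natural, pos, ref, alt)."""
    return sorted(keys, key=variant_sort_key)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _format_filter(record: "pysam.VariantRecord") -> str:
    labels = list(record.filter.keys())
    if not labels:
        return "."
    return ";".join(labels)


def _genotype_for_alt(gt: tuple, alt_index: int) -> Optional[str]:
    """Map a GT allele tuple to a call for the alt with 1-based index."""
    alleles = [a for a in gt if a is not None]
    if not alleles or alt_index not in alleles:
        return None
    if all(a == alt_index for a in alleles) and len(alleles) > 1:
        return HOM_ALT
    return HET


def read_vcf(path: str) -> list[VcfVariant]:
    """Read a single-sample VCF into a list of :class:`VcfVariant`.

    Genotype is derived from GT (``0/1`` -> Heterozygous, ``1/1`` ->
    Homozygous_alt); total depth from DP and variant depth from VD when
    present, else from the alt entry of AD.  Multi-allelic lines are split
    into one record per alternate allele present in the genotype.  Non-SNV
    alleles are skipped (out of scope).
    """
    try:
        vf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise FormatError(f"{path}: not a readable VCF: {exc}") from exc
    with vf:
        samples = list(vf.header.samples)
        if len(samples) != 1:
            raise FormatError(
                f"{path}: expected a single-sample VCF, found {len(samples)} samples"
            )
        sample_id = samples[0]
        out: list[VcfVariant] = []
        for idx, rec in enumerate(vf.fetch() if vf.index else vf, start=1):
            sample = rec.samples[sample_id]
            try:
                gt = sample.get("GT", (None,))
                dp = sample.get("DP")
                if dp is None:
                    dp = rec.info.get("DP")
                vd = sample.get("VD")
                ad = sample.get("AD")
            except (KeyError, ValueError) as exc:  # pragma: no cover - defensive
                raise RecordError(f"{path}: record {idx}: {exc}") from exc
            if dp is None:
                raise RecordError(
                    f"{path}: record {idx} ({rec.chrom}:{rec.pos}): no DP field"
                )
            alts = rec.alts or ()
            for i, alt in enumerate(alts):
                if len(rec.ref) != 1 or alt is None or len(alt) != 1:
                    continue  # indel / symbolic allele: out of scope
                if rec.ref.upper() not in _VALID_BASES or alt.upper() not in _VALID_BASES:
                    continue
                call = _genotype_for_alt(gt, i + 1)
                if call is None:
                    continue
                if vd is not None:
                    variant_depth = int(vd[0] if isinstance(vd, tuple) else vd)
                elif ad is not None:
                    variant_depth = int(ad[i + 1])
                else:
                    raise RecordError(
                        f"{path}: record {idx} ({rec.chrom}:{rec.pos}): "
                        "neither VD nor AD present"
                    )
                key = VariantKey.make(rec.chrom, rec.pos, rec.ref, alt)
                out.append(
                    VcfVariant(
                        key,
                        _format_filter(rec),
                        GenotypeRecord(sample_id, key, call, int(dp), variant_depth),
                    )
                )
        return out


_VCF_HEADER_LINES = [
    "##fileformat=VCFv4.2",
    '##FILTER=<ID=PASS,Description="All filters passed">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Total read depth">',
    '##FORMAT=<ID=VD,Number=1,Type=Integer,Description="Variant-supporting read depth">',
]

_GT_STRING = {HET: "0/1", HOM_ALT: "1/1"}


def write_vcf(records: Sequence[VcfVariant], path: str, sample_id: Optional[str] = None) -> None:
    """Write records as a single-sample VCF (FORMAT ``GT:DP:VD``)."""
    records = list(records)
    if sample_id is None:
        sample_id = records[0].genotype.sample_id if records else "SAMPLE"
    contigs = []
    for rec in records:
        if rec.key.chrom not in contigs:
            contigs.append(rec.key.chrom)
    with open(path, "w") as fh:
        for line in _VCF_HEADER_LINES:
            fh.write(line + "\n")
        for contig in contigs:
            fh.write(f"##contig=<ID={contig}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample_id + "\n"
        )
        for rec in records:
            g = rec.genotype
            if g.call not in _GT_STRING:
                raise ValueError(f"cannot encode call {g.call!r} in VCF GT")
            fh.write(
                f"{rec.key.chrom}\t{rec.key.pos}\t.\t{rec.key.ref}\t{rec.key.alt}"
                f"\t.\t{rec.filter}\t.\tGT:DP:VD"
                f"\t{_GT_STRING[g.call]}:{g.total_depth}:{g.variant_depth}\n"
            )


def filter_pass(records: Iterable[VcfVariant]) -> list[VcfVariant]:
    """Keep exactly the records whose FILTER label equals ``PASS``."""
    return [rec for rec in records if rec.filter == "PASS"]


# ---------------------------------------------------------------------------
# Depth TSV (samtools-depth dialect: chrom, 1-based pos, depth; no header)
# ---------------------------------------------------------------------------

def read_depth_tsv(path: str) -> list[DepthRecord]:
    out: list[DepthRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise FormatError(
                    f"{path}:{lineno}: expected 3 tab-separated columns, got {len(fields)}"
                )
            chrom, pos_s, depth_s = fields
            try:
                pos, depth = int(pos_s), int(depth_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer pos/depth") from exc
            if depth < 0:
                raise FormatError(f"{path}:{lineno}: negative depth {depth}")
            out.append(DepthRecord(chrom, pos, depth))
    return out


def write_depth_tsv(records: Iterable[DepthRecord], path: str) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f"{rec.chrom}\t{rec.pos}\t{rec.depth}\n")


# ---------------------------------------------------------------------------
# BED3 (0-based half-open) and Annovar avinput (1-based inclusive)
# ---------------------------------------------------------------------------

def write_bed(keys: Sequence[VariantKey], path: str) -> None:
    """Write unique positions as BED3; ``pos`` maps to ``(pos-1, pos)``.

    Multiple alleles at one position collapse to a single BED interval.
    """
    seen: set[tuple[str, int]] = set()
    with open(path, "w") as fh:
        for key in keys:
            loc = (key.chrom, key.pos)
            if loc in seen:
                continue
            seen.add(loc)
            fh.write(f"{key.chrom}\t{key.pos - 1}\t{key.pos}\n")


def read_bed_positions(path: str) -> list[tuple[str, int]]:
    """Read BED3 intervals back as 1-based single positions."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected BED3")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if end != start + 1:
                raise FormatError(
                    f"{path}:{lineno}: expected single-base interval, got {start}-{end}"
                )
            out.append((chrom, end))
    return out


def write_annovar_input(status_table: pd.DataFrame, path: str) -> None:
    """Write a status table as Annovar avinput (chrom, start, end, ref, alt, ...).

    For SNVs the avinput convention is ``start == end == pos`` (1-based
    inclusive).  Any per-sample status columns follow the five key columns.
    """
    df = status_table.reset_index()
    out = pd.DataFrame(
        {
            "CHROM": df["CHROM"],
            "START": df["POS"],
            "END": df["POS"],
            "REF": df["REF"],
            "ALT": df["ALT"],
        }
    )
    for col in status_table.columns:
        out[col] = df[col].values
    out.to_csv(path, sep="\t", index=False)


def read_annovar_keys(path: str) -> list[VariantKey]:
    df = pd.read_csv(path, sep="\t")
    expected = ["CHROM", "START", "END", "REF", "ALT"]
    if list(df.columns[:5]) != expected:
        raise FormatError(f"{path}: expected leading columns {expected}")
    if not (df["START"] == df["END"]).all():
        raise FormatError(f"{path}: SNV avinput requires START == END")
    return [
        VariantKey.make(row.CHROM, row.START, row.REF, row.ALT)
        for row in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# Patient lists (Case_ID <-> sample barcode per data type)
# ---------------------------------------------------------------------------

_PATIENT_COLUMNS = {"normal": "normal", "tumor": "tumor", "rnaseq": "rnaseq"}


def _read_patient_list(path: str, barcode_col: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    expected = ["Case_ID", barcode_col]
    if list(df.columns) != expected:
        raise FormatError(
            f"{path}: expected columns {expected}, found {list(df.columns)}"
        )
    if df["Case_ID"].duplicated().any():
        dup = df.loc[df["Case_ID"].duplicated(), "Case_ID"].iloc[0]
        raise FormatError(f"{path}: duplicate Case_ID {dup!r}")
    return df


def read_patient_map(
    normal_path: Optional[str] = None,
    tumor_path: Optional[str] = None,
    rnaseq_path: Optional[str] = None,
) -> pd.DataFrame:
    """Outer-join the per-data-type patient lists on ``Case_ID``.

    Returns a DataFrame indexed by ``Case_ID`` with columns ``normal``,
    ``tumor`` and ``rnaseq`` holding sample barcodes (NaN where the patient
    has no sample of that data type).
    """
    parts = []
    for path, col in (
        (normal_path, "normal"),
        (tumor_path, "tumor"),
        (rnaseq_path, "rnaseq"),
    ):
        if path is not None:
            parts.append(_read_patient_list(path, col))
    if not parts:
        raise ValueError("at least one patient list is required")
    merged = parts[0]
    for part in parts[1:]:
        merged = merged.merge(part, on="Case_ID", how="outer")
    for col in _PATIENT_COLUMNS:
        if col not in merged.columns:
            merged[col] = pd.NA
    merged = merged.set_index("Case_ID")[list(_PATIENT_COLUMNS)]
    if merged.isna().all(axis=1).any():
        raise FormatError("patient map row with no sample barcode")
    return merged


# ---------------------------------------------------------------------------
# Status tables ("CHROM POS REF ALT <sample...>", tab separated)
# ---------------------------------------------------------------------------

_KEY_COLUMNS = ["CHROM", "POS", "REF", "ALT"]


def write_status_table(matrix: pd.DataFrame, path: str) -> None:
    """Write a variants-by-samples status matrix as a tab-separated table."""
    matrix.reset_index().to_csv(path, sep="\t", index=False)


def read_status_table(path: str) -> pd.DataFrame:
    """Read a status table back into a variants-by-samples DataFrame.

    Rows are indexed by the (CHROM, POS, REF, ALT) MultiIndex; every cell must
    hold one of the four status values.
    """
    df = pd.read_csv(path, sep="\t", dtype={"CHROM": str, "REF": str, "ALT": str})
    if df.empty and list(df.columns[:4]) != _KEY_COLUMNS:
        raise FormatError(f"{path}: expected leading columns {_KEY_COLUMNS}")
    if list(df.columns[:4]) != _KEY_COLUMNS:
        raise FormatError(f"{path}: expected leading columns {_KEY_COLUMNS}")
    matrix = df.set_index(_KEY_COLUMNS)
    bad = ~matrix.isin(STATUSES)
    if bad.any().any():
        col = bad.any()[bad.any()].index[0]
        val = matrix.loc[bad[col], col].iloc[0]
        raise FormatError(f"{path}: invalid status value {val!r} in column {col!r}")
    return matrix


# ---------------------------------------------------------------------------
# Clinical table and population allele-frequency table
# ---------------------------------------------------------------------------

def read_clinical(path: str) -> pd.DataFrame:
    """Read the clinical/survival CSV (OS_months, OS_status, covariates)."""
    df = pd.read_csv(path, skipinitialspace=True)
    for col in ("OS_months", "OS_status"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    if not df["OS_status"].isin([0, 1]).all():
        raise FormatError(f"{path}: OS_status must be 0 (censored) or 1 (event)")
    if (df["OS_months"] < 0).any():
        raise FormatError(f"{path}: negative OS_months")
    return df


def read_population_af(path: str) -> pd.Series:
    """Read a population AF table (chrom, pos, ref, alt, af) keyed by variant."""
    df = pd.read_csv(path, sep="\t", dtype={"CHROM": str, "REF": str, "ALT": str})
    if list(df.columns) != _KEY_COLUMNS + ["AF"]:
        raise FormatError(f"{path}: expected columns {_KEY_COLUMNS + ['AF']}")
    if ((df["AF"] < 0) | (df["AF"] > 1)).any():
        raise FormatError(f"{path}: AF outside [0, 1]")
    return df.set_index(_KEY_COLUMNS)["AF"]


def write_population_af(af: pd.Series, path: str) -> None:
    af.rename("AF").reset_index().to_csv(path, sep="\t", index=False)
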