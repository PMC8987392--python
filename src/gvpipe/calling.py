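"""Simplified per-site candidate variant caller operating on pileup counts.

This caller applies the germline-calling thresholds used throughout the
pipeline — mapping quality strictly greater than 30, base quality strictly
greater than 25, at least 3 reads supporting the variant, variant allele
fraction of at least 5%, PCR-duplicate removal and no structural-variant
calling — directly to per-site read observations.  It stands in for a full
aligner-aware caller (VarDictJava upstream) so that the downstream status,
rescue and association stages can be exercised end to end from plain-text
pileup tables; it deliberately implements none of the realignment or
strand-bias machinery of a production caller.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, NamedTuple, Optional

import pandas as pd

from .formats import HET, HOM_ALT, GenotypeRecord, VariantKey, VcfVariant

__all__ = [
    "ReadObs",
    "PileupSite",
    "CallerParams",
    "dedup_reads",
    "call_from_counts",
    "call_site",
    "call_sample",
    "read_pileup_table",
    "write_pileup_table",
]

#: Deterministic tie-break order when two alt bases have equal support.
_BASE_ORDER = "ACGT"

PILEUP_COLUMNS = ["chrom", "pos", "ref", "base", "baseq", "mapq", "read_start", "strand"]


class ReadObs(NamedTuple):
    """One read's observation of a site: base, qualities, start, strand."""

    base: str
    baseq: int
    mapq: int
    read_start: int
    strand: str  # "+" or "-"


@dataclass(frozen=True)
class PileupSite:
    """All read observations at one genomic position."""

    chrom: str
    pos: int
    ref: str
    observations: tuple[ReadObs, ...]


@dataclass(frozen=True)
class CallerParams:
    """Calling thresholds.

    Quality thresholds are strict ("greater than"): a read at exactly
    ``min_mapq`` or ``min_baseq`` is discarded.  ``homalt_vaf`` is the
    variant-allele-fraction boundary between a heterozygous and a
    homozygous-alternate call; 0.75 is the conventional diploid midpoint
    plus margin.
    """

    min_mapq: int = 30
    min_baseq: int = 25
    min_alt_reads: int = 3
    min_vaf: float = 0.05
    homalt_vaf: float = 0.75
    dedup: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.min_vaf < self.homalt_vaf <= 1):
            raise ValueError(
                f"require 0 < min_vaf < homalt_vaf <= 1, "
                f"got min_vaf={self.min_vaf}, homalt_vaf={self.homalt_vaf}"
            )


def dedup_reads(site: PileupSite) -> PileupSite:
    """Collapse PCR duplicates: keep one read per (start position, strand).

    Among duplicates the observation with the highest base quality is kept
    (first encountered wins ties).  Reads starting at the same position on
    opposite strands are not duplicates of each other.
    """
    best: dict[tuple[int, str], ReadObs] = {}
    order: list[tuple[int, str]] = []
    for obs in site.observations:
        dup_key = (obs.read_start, obs.strand)
        if dup_key not in best:
            best[dup_key] = obs
            order.append(dup_key)
        elif obs.baseq > best[dup_key].baseq:
            best[dup_key] = obs
    return replace(site, observations=tuple(best[k] for k in order))


def call_from_counts(
    total_depth: int, alt_depth: int, params: CallerParams = CallerParams()
) -> Optional[str]:
    """Genotype decision from (total, alt-supporting) read counts.

    Returns ``Heterozygous``/``Homozygous_alt`` when the evidence clears the
    minimum-supporting-reads and minimum-VAF thresholds, else ``None``.
    """
    if total_depth <= 0 or alt_depth < params.min_alt_reads:
        return None
    vaf = alt_depth / total_depth
    if vaf < params.min_vaf:
        return None
    return HOM_ALT if vaf >= params.homalt_vaf else HET


def call_site(
    site: PileupSite, params: CallerParams = CallerParams()
) -> Optional[tuple[VariantKey, str, int, int, str]]:
    """Call the most frequent alternate base at one site, if it qualifies.

    Observations failing the strict MQ/BQ thresholds are discarded first;
    total depth is the count of surviving observations and the VAF is
    computed on those survivors.  Returns ``(key, call, total_depth,
    variant_depth, "PASS")`` or ``None`` when no alt qualifies (zero depth
    included).
    """
    if params.dedup:
        site = dedup_reads(site)
    surviving = [
        obs
        for obs in site.observations
        if obs.mapq > params.min_mapq and obs.baseq > params.min_baseq
    ]
    total_depth = len(surviving)
    if total_depth == 0:
        return None
    counts: dict[str, int] = {}
    for obs in surviving:
        base = obs.base.upper()
        if base != site.ref.upper() and base in _BASE_ORDER:
            counts[base] = counts.get(base, 0) + 1
    if not counts:
        return None
    # single most frequent alt allele; ties broken by base order A<C<G<T
    alt = max(counts, key=lambda b: (counts[b], -_BASE_ORDER.index(b)))
    variant_depth = counts[alt]
    call = call_from_counts(total_depth, variant_depth, params)
    if call is None:
        return None
    key = VariantKey.make(site.chrom, site.pos, site.ref, alt)
    return (key, call, total_depth, variant_depth, "PASS")


def call_sample(
    sites: Iterable[PileupSite],
    sample_id: str,
    params: CallerParams = CallerParams(),
) -> list[VcfVariant]:
    """Run :func:`call_site` over a sample's pileup, in input order."""
    out: list[VcfVariant] = []
    for site in sites:
        result = call_site(site, params)
        if result is None:
            continue
        key, call, dp, vd, flt = result
        out.append(VcfVariant(key, flt, GenotypeRecord(sample_id, key, call, dp, vd)))
    return out


# ---------------------------------------------------------------------------
# Pileup table dialect (TSV with header; one row per read observation)
# ---------------------------------------------------------------------------

def read_pileup_table(path: str) -> list[PileupSite]:
    """Read a pileup TSV into sites, grouped by (chrom, pos) in file order."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "base": str, "strand": str})
    if list(df.columns) != PILEUP_COLUMNS:
        raise ValueError(f"{path}: expected columns {PILEUP_COLUMNS}")
    return pileup_sites_from_frame(df)


def pileup_sites_from_frame(df: pd.DataFrame) -> list[PileupSite]:
    sites: list[PileupSite] = []
    for (chrom, pos, ref), group in df.groupby(["chrom", "pos", "ref"], sort=False):
        obs = tuple(
            ReadObs(row.base, int(row.baseq), int(row.mapq), int(row.read_start), row.strand)
            for row in group.itertuples()
        )
        sites.append(PileupSite(str(chrom), int(pos), str(ref), obs))
    return sites


def write_pileup_table(sites: Iterable[PileupSite], path: str) -> None:
    rows = [
        (s.chrom, s.pos, s.ref, o.base, o.baseq, o.mapq, o.read_start, o.strand)
        for s in sites
        for o in s.observations
    ]
    pd.DataFrame(rows, columns=PILEUP_COLUMNS).to_csv(path, sep="\t", index=False)
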