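"""Per-sample sequencing depth at the union-variant positions.

Depth here is what governs the ten-read status rule downstream: the number
of reads covering a position with mapping quality strictly greater than 30
(base quality is not filtered for coverage, matching how the calling and
coverage stages apply their thresholds).  Positions with no observations are
reported with depth 0, mirroring how per-base depth tools omit zero-coverage
rows from their output.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import pandas as pd

from .calling import PileupSite, dedup_reads
from .formats import FormatError, VariantKey, read_depth_tsv

__all__ = ["depth_at_positions", "load_external_depth", "coverage_series"]


def _position_index(positions: Sequence) -> pd.MultiIndex:
    locs = []
    seen = set()
    for p in positions:
        loc = (p.chrom, p.pos) if isinstance(p, VariantKey) else (p[0], int(p[1]))
        if loc not in seen:
            seen.add(loc)
            locs.append(loc)
    return pd.MultiIndex.from_tuples(locs, names=["CHROM", "POS"])


def coverage_series(depths: dict[tuple[str, int], int], positions: Sequence) -> pd.Series:
    """Arrange a (chrom, pos) -> depth mapping over the queried positions."""
    index = _position_index(positions)
    values = [int(depths.get(loc, 0)) for loc in index]
    return pd.Series(values, index=index, name="depth")


def depth_at_positions(
    sites: Iterable[PileupSite],
    positions: Sequence,
    min_mapq: int = 30,
    dedup: bool = False,
) -> pd.Series:
    """Depth per queried position: reads with MQ > ``min_mapq``.

    ``positions`` may be :class:`~gvpipe.formats.VariantKey` tuples or bare
    ``(chrom, pos)`` pairs; allele information is ignored and duplicate
    positions collapse.  Positions with no observations get depth 0.
    ``dedup`` optionally removes PCR duplicates before counting (off by
    default; calling and coverage are separate passes over the reads).
    """
    if len(positions) == 0:
        raise ValueError("positions must be non-empty")
    wanted = set(_position_index(positions))
    counts: dict[tuple[str, int], int] = {}
    for site in sites:
        loc = (site.chrom, site.pos)
        if loc not in wanted:
            continue
        if dedup:
            site = dedup_reads(site)
        n = sum(1 for obs in site.observations if obs.mapq > min_mapq)
        counts[loc] = counts.get(loc, 0) + n
    return coverage_series(counts, positions)


def load_external_depth(path: str, positions: Sequence) -> pd.Series:
    """Load a samtools-depth TSV, restricted and zero-filled to ``positions``.

    Accepts real ``samtools depth`` output for users who computed coverage
    from BAMs outside this package.
    """
    if len(positions) == 0:
        raise ValueError("positions must be non-empty")
    records = read_depth_tsv(path)
    depths: dict[tuple[str, int], int] = {}
    for rec in records:
        loc = (rec.chrom, rec.pos)
        if loc in depths:
            raise FormatError(f"{path}: duplicate position {rec.chrom}:{rec.pos}")
        depths[loc] = rec.depth
    return coverage_series(depths, positions)
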