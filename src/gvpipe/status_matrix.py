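"""Coverage-corrected variant status and the multi-sample status matrix.

The central object is the status matrix: rows are variants keyed by
``(CHROM, POS, REF, ALT)``, columns are samples, and every cell holds one of
``Homozygous_ref``, ``Heterozygous``, ``Homozygous_alt`` or ``unknown``.
Statuses are corrected for low sequencing coverage with the ten-read rule:
a position covered by fewer than ``min_depth`` reads in a sample is
``unknown`` no matter what was called there, a well-covered position with no
call is ``Homozygous_ref``, and otherwise the call stands.

The depth that governs the rule is the coverage-table depth computed over
the union-variant positions (mapping quality > 30), not the DP the caller
reported; the caller's DP is retained in the VCFs for provenance only.

Large combined tables can be processed in fixed-size row chunks (mirroring
a ``split -d -l 50000 -a 4`` workflow); chunking is an equivalence-preserving
implementation detail and chunked results are byte-identical to unchunked.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd

from .formats import (
    CALLS,
    HET,
    HOM_ALT,
    HOM_REF,
    UNKNOWN,
    VariantKey,
    sort_variant_keys,
    variant_sort_key,
)

__all__ = [
    "StatusPolicy",
    "unique_variants",
    "union_across_datatypes",
    "determine_status",
    "build_sample_status",
    "combine_samples",
    "filter_potential_snps",
    "sort_matrix_rows",
    "split_status_file",
    "process_chunked",
    "matrix_from_statuses",
    "keys_of_matrix",
]

KEY_COLUMNS = ["CHROM", "POS", "REF", "ALT"]


def _key_index(keys: Sequence[VariantKey]) -> pd.MultiIndex:
    if len(keys) == 0:
        return pd.MultiIndex.from_arrays([[], [], [], []], names=KEY_COLUMNS)
    return pd.MultiIndex.from_tuples(keys, names=KEY_COLUMNS)


@dataclass(frozen=True)
class StatusPolicy:
    """Coverage threshold for trusting a genotype status.

    ``min_depth`` reads are required before a status (including the implied
    Homozygous_ref of a no-call) is believed; below it the status is
    ``unknown``.  Depth exactly at the threshold counts as sufficient.
    """

    min_depth: int = 10

    def __post_init__(self) -> None:
        if self.min_depth < 1:
            raise ValueError(f"min_depth must be >= 1, got {self.min_depth}")


def unique_variants(
    per_sample_keys: Mapping[str, Iterable[VariantKey]],
) -> tuple[list[VariantKey], int]:
    """Deduplicate variant keys across one data type's samples.

    Returns the sorted set-union of keys and the total (non-unique) count of
    input records, for audit logging.
    """
    total = 0
    union: set[VariantKey] = set()
    for keys in per_sample_keys.values():
        for key in keys:
            total += 1
            union.add(key)
    return sort_variant_keys(union), total


def union_across_datatypes(*key_sets: Iterable[VariantKey]) -> list[VariantKey]:
    """Full outer union of the per-data-type unique variant sets, sorted."""
    union: set[VariantKey] = set()
    for keys in key_sets:
        union.update(keys)
    return sort_variant_keys(union)


def determine_status(
    call: str | None, depth: int, policy: StatusPolicy = StatusPolicy()
) -> str:
    """Coverage-corrected status for one (sample, variant) cell.

    ``call`` is the caller's genotype (Heterozygous/Homozygous_alt) or None
    when no alternate allele was reported; ``depth`` is the coverage-table
    depth at the position.
    """
    if depth < 0:
        raise ValueError(f"depth must be >= 0, got {depth}")
    if call is not None and call not in CALLS:
        raise ValueError(f"unexpected call {call!r}")
    if depth < policy.min_depth:
        return UNKNOWN
    if call is None:
        return HOM_REF
    return call


def build_sample_status(
    calls: Mapping[VariantKey, str],
    coverage: pd.Series,
    union_keys: Sequence[VariantKey],
    policy: StatusPolicy = StatusPolicy(),
    sample_id: str = "sample",
) -> pd.Series:
    """Status of every union variant in one sample (the merged
    genotype-plus-coverage table, one column per sample).

    ``coverage`` is indexed by (CHROM, POS); positions absent from it count
    as depth 0.
    """
    cov = coverage.to_dict() if not isinstance(coverage, dict) else coverage
    statuses = [
        determine_status(calls.get(key), int(cov.get((key.chrom, key.pos), 0)), policy)
        for key in union_keys
    ]
    index = _key_index(union_keys)
    return pd.Series(statuses, index=index, name=sample_id)


def matrix_from_statuses(
    statuses: Mapping[str, Mapping[VariantKey, str]],
    keys: Sequence[VariantKey],
) -> pd.DataFrame:
    """Assemble a status matrix from per-sample key->status mappings."""
    index = _key_index(keys)
    data = {
        sample: [mapping.get(key, UNKNOWN) for key in keys]
        for sample, mapping in statuses.items()
    }
    return pd.DataFrame(data, index=index)


def keys_of_matrix(matrix: pd.DataFrame) -> list[VariantKey]:
    return [VariantKey(c, int(p), r, a) for c, p, r, a in matrix.index]


def combine_samples(
    per_sample: Mapping[str, pd.Series],
    union_keys: Sequence[VariantKey],
) -> pd.DataFrame:
    """Combine per-sample status columns into one variants-by-samples matrix.

    Columns keep the input sample order; rows follow the deterministic
    variant sort.  Every sample must cover every union key.
    """
    union_keys = sort_variant_keys(union_keys)
    index = _key_index(union_keys)
    columns = {}
    for sample, series in per_sample.items():
        missing = index.difference(series.index)
        if len(missing):
            key = tuple(missing[0])
            raise KeyError(
                f"sample {sample!r} is missing union variant "
                f"{key[0]}:{key[1]} {key[2]}>{key[3]}"
            )
        columns[sample] = series.reindex(index)
    return pd.DataFrame(columns, index=index)


def filter_potential_snps(matrix: pd.DataFrame) -> pd.DataFrame:
    """Keep variants carrying at least one observed alternate allele.

    A row survives iff any cell is Heterozygous or Homozygous_alt; rows that
    are unknown or Homozygous_ref across all samples are removed.
    """
    if matrix.shape[1] == 0:
        return matrix
    has_alt = matrix.isin([HET, HOM_ALT]).any(axis=1)
    return matrix.loc[has_alt]


def sort_matrix_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Deterministic row order: natural chromosome order, then pos/ref/alt."""
    order = sorted(
        range(len(matrix.index)),
        key=lambda i: variant_sort_key(VariantKey(*matrix.index[i])),
    )
    return matrix.iloc[order]


# ---------------------------------------------------------------------------
# Chunked processing of large combined tables
# ---------------------------------------------------------------------------

def split_status_file(
    path: str,
    out_dir: str,
    chunk_rows: int = 50000,
    prefix: str = "segment_",
) -> tuple[str, list[str]]:
    """Split a combined status table into fixed-row chunks plus a header file.

    Chunk files carry a 4-digit numeric suffix (``segment_0000.txt`` ...)
    and no header; the header line is written to ``header.txt`` alongside.
    Returns ``(header_path, chunk_paths)``.
    """
    if chunk_rows < 1:
        raise ValueError("chunk_rows must be >= 1")
    os.makedirs(out_dir, exist_ok=True)
    header_path = os.path.join(out_dir, "header.txt")
    chunk_paths: list[str] = []
    with open(path) as fh:
        header = fh.readline()
        with open(header_path, "w") as hfh:
            hfh.write(header)
        chunk_fh = None
        rows_in_chunk = 0
        for line in fh:
            if chunk_fh is None or rows_in_chunk == chunk_rows:
                if chunk_fh is not None:
                    chunk_fh.close()
                chunk_path = os.path.join(
                    out_dir, f"{prefix}{len(chunk_paths):04d}.txt"
                )
                chunk_paths.append(chunk_path)
                chunk_fh = open(chunk_path, "w")
                rows_in_chunk = 0
            chunk_fh.write(line)
            rows_in_chunk += 1
        if chunk_fh is not None:
            chunk_fh.close()
    return header_path, chunk_paths


def process_chunked(
    path: str,
    op: Callable[[pd.DataFrame], pd.DataFrame],
    chunk_rows: int = 50000,
) -> pd.DataFrame:
    """Apply a row-wise matrix operation to a status table in row chunks.

    ``op`` must be row-wise (each output row depends only on its input row),
    e.g. :func:`filter_potential_snps`; the concatenated result is then
    identical to applying ``op`` to the whole table at once.
    """
    parts: list[pd.DataFrame] = []
    reader = pd.read_csv(
        path,
        sep="\t",
        dtype={"CHROM": str, "REF": str, "ALT": str},
        chunksize=chunk_rows,
    )
    for chunk in reader:
        parts.append(op(chunk.set_index(KEY_COLUMNS)))
    if not parts:
        raise ValueError(f"{path}: empty status table")
    return pd.concat(parts)
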