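"""Rescue of unknown normal-sample statuses from matched tumor and RNA-seq.

Germline variants are inherited, so the tumor exome and tumor RNA-seq of the
same patient carry the same germline genotype and can genotype positions
the normal exome covered too thinly.  For every patient and variant whose
wxs-normal status is ``unknown``, the matched wxs-tumor status is inserted
if known; if still unknown, the matched rnaseq-tumor status is inserted.
Known normal statuses are never modified.  Somatic mutations and RNA-editing
artifacts introduced by the tumor-derived donors are handled downstream by
the population minor-allele-frequency filter, not here.

Patients without a normal sample start from an all-unknown baseline and are
genotyped entirely from their tumor/rnaseq samples, so the approach also
applies to cohorts lacking normal tissue.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .formats import UNKNOWN, write_annovar_input, write_status_table
from .status_matrix import KEY_COLUMNS, filter_potential_snps, sort_matrix_rows

__all__ = ["RescueResult", "fill_unknown", "export_outputs"]


@dataclass
class RescueResult:
    """Outcome of the unknown-fill.

    ``final`` is the combined wxs-rnaseq status matrix (columns are
    Case_IDs, potential-SNP filter re-applied); ``tumor_filled`` is the
    intermediate after the tumor pass only; ``report`` audits per patient:
    unknowns before, filled from tumor, filled from rnaseq, unknowns
    remaining.  ``n_rows_prefilter``/``n_rows_final`` count variants before
    and after the re-applied potential-SNP filter.
    """

    final: pd.DataFrame
    tumor_filled: pd.DataFrame
    report: pd.DataFrame
    n_rows_prefilter: int
    n_rows_final: int


def _donor_column(matrix: pd.DataFrame, barcode, index: pd.MultiIndex, which: str) -> pd.Series:
    """A donor sample's statuses over the union rows (unknown where absent)."""
    if barcode is None or (isinstance(barcode, float) and np.isnan(barcode)) or pd.isna(barcode):
        return pd.Series(UNKNOWN, index=index)
    if barcode not in matrix.columns:
        raise KeyError(
            f"{which} barcode {barcode!r} from the patient map is not a sample "
            f"column of the {which} status matrix"
        )
    return matrix[barcode].reindex(index, fill_value=UNKNOWN)


def fill_unknown(
    normal: pd.DataFrame,
    tumor: pd.DataFrame,
    rnaseq: pd.DataFrame,
    patient_map: pd.DataFrame,
    refilter: bool = True,
) -> RescueResult:
    """Fill unknown wxs-normal statuses from tumor, then from rnaseq.

    The three matrices are per-data-type status matrices whose columns are
    sample barcodes; ``patient_map`` (indexed by Case_ID, columns
    normal/tumor/rnaseq) links them.  The result's columns are Case_IDs.
    Variants absent from a matrix are treated as unknown in that matrix, so
    the output rows are the union of all three row sets.  When ``refilter``
    is true the potential-SNP filter is re-applied after filling.
    """
    union_index = normal.index.union(tumor.index).union(rnaseq.index)

    tumor_cols: dict[str, pd.Series] = {}
    final_cols: dict[str, pd.Series] = {}
    report_rows = []
    for case_id, row in patient_map.iterrows():
        base = _donor_column(normal, row.get("normal"), union_index, "normal")
        donor_t = _donor_column(tumor, row.get("tumor"), union_index, "tumor")
        donor_r = _donor_column(rnaseq, row.get("rnaseq"), union_index, "rnaseq")

        unknowns_before = int((base == UNKNOWN).sum())
        fill_t = (base == UNKNOWN) & (donor_t != UNKNOWN)
        after_tumor = base.mask(fill_t, donor_t)
        fill_r = (after_tumor == UNKNOWN) & (donor_r != UNKNOWN)
        final = after_tumor.mask(fill_r, donor_r)

        tumor_cols[case_id] = after_tumor
        final_cols[case_id] = final
        report_rows.append(
            {
                "Case_ID": case_id,
                "unknowns_before": unknowns_before,
                "filled_from_tumor": int(fill_t.sum()),
                "filled_from_rnaseq": int(fill_r.sum()),
                "unknowns_remaining": int((final == UNKNOWN).sum()),
            }
        )

    tumor_filled = pd.DataFrame(tumor_cols, index=union_index)
    final_matrix = pd.DataFrame(final_cols, index=union_index)
    final_matrix = sort_matrix_rows(final_matrix)
    tumor_filled = sort_matrix_rows(tumor_filled)
    n_prefilter = len(final_matrix)
    if refilter:
        final_matrix = filter_potential_snps(final_matrix)
    report_cols = [
        "Case_ID",
        "unknowns_before",
        "filled_from_tumor",
        "filled_from_rnaseq",
        "unknowns_remaining",
    ]
    report = pd.DataFrame(report_rows, columns=report_cols).set_index("Case_ID")
    return RescueResult(
        final=final_matrix,
        tumor_filled=tumor_filled,
        report=report,
        n_rows_prefilter=n_prefilter,
        n_rows_final=len(final_matrix),
    )


def export_outputs(result: RescueResult, out_dir: str) -> dict[str, str]:
    """Write the four rescue output files.

    (i) the tumor-filled intermediate, (ii) its row/column-sorted
    arrangement, (iii) the final merged wxs-rnaseq status table and (iv) the
    final variants formatted as Annovar avinput.  Returns name -> path.
    """
    import os

    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "combined_normal_unknown_filled": os.path.join(
            out_dir, "combined_normal_unknown_filled.txt"
        ),
        "combined_normal_unknown_filled_arranged": os.path.join(
            out_dir, "combined_normal_unknown_filled_arranged.txt"
        ),
        "final_merged_wxs_rnaseq_variants": os.path.join(
            out_dir, "final_merged_wxs_rnaseq_variants.txt"
        ),
        "final_variantsForAnnovar": os.path.join(out_dir, "final_variantsForAnnovar.txt"),
    }
    write_status_table(result.tumor_filled, paths["combined_normal_unknown_filled"])
    arranged = sort_matrix_rows(result.tumor_filled)[sorted(result.tumor_filled.columns)]
    write_status_table(arranged, paths["combined_normal_unknown_filled_arranged"])
    write_status_table(result.final, paths["final_merged_wxs_rnaseq_variants"])
    write_annovar_input(result.final, paths["final_variantsForAnnovar"])
    return paths
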