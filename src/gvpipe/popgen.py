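"""Cohort allele frequencies, the population-MAF filter and AF concordance.

The cohort allele frequency of a variant is the alt-allele fraction among
genotyped patients,

    AF = (2*#HA + #HT) / (2*#HR + 2*#HT + 2*#HA),

where #HR, #HT and #HA count patients called Homozygous_ref, Heterozygous
and Homozygous_alt; patients with unknown status contribute neither alleles
nor denominator.  The minor-allele-frequency filter keeps only variants
known in a reference population at MAF >= 0.05, which removes somatic
mutations and RNA-editing artifacts carried in from the tumor-derived call
sets.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .formats import HET, HOM_ALT, HOM_REF, UNKNOWN

__all__ = [
    "AlleleCounts",
    "UndefinedAFError",
    "allele_frequency",
    "count_statuses",
    "af_by_variant",
    "maf_filter",
    "af_concordance",
]


class UndefinedAFError(ValueError):
    """No genotyped patients: the allele frequency is undefined."""


class AlleleCounts(NamedTuple):
    """Patient genotype counts at one variant."""

    n_hom_ref: int
    n_het: int
    n_hom_alt: int
    n_unknown: int = 0


def allele_frequency(counts: AlleleCounts) -> float:
    """Alt-allele frequency from genotype counts (unknowns excluded)."""
    n_hr, n_ht, n_ha, _ = counts
    if min(n_hr, n_ht, n_ha) < 0:
        raise ValueError("negative genotype count")
    genotyped = n_hr + n_ht + n_ha
    if genotyped == 0:
        raise UndefinedAFError("all patients unknown; allele frequency undefined")
    return (2 * n_ha + n_ht) / (2 * genotyped)


def count_statuses(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-variant genotype counts from a status matrix."""
    return pd.DataFrame(
        {
            "n_hom_ref": (matrix == HOM_REF).sum(axis=1),
            "n_het": (matrix == HET).sum(axis=1),
            "n_hom_alt": (matrix == HOM_ALT).sum(axis=1),
            "n_unknown": (matrix == UNKNOWN).sum(axis=1),
        }
    )


def af_by_variant(matrix: pd.DataFrame) -> pd.Series:
    """Cohort allele frequency per variant (NaN where no patient genotyped)."""
    counts = count_statuses(matrix)
    genotyped = counts["n_hom_ref"] + counts["n_het"] + counts["n_hom_alt"]
    with np.errstate(invalid="ignore", divide="ignore"):
        af = (2 * counts["n_hom_alt"] + counts["n_het"]) / (2 * genotyped)
    af[genotyped == 0] = np.nan
    return af.rename("AF")


def maf_filter(
    matrix: pd.DataFrame, population_af: pd.Series, threshold: float = 0.05
) -> pd.DataFrame:
    """Keep variants known in the population with minor AF >= ``threshold``.

    ``population_af`` is keyed by (CHROM, POS, REF, ALT).  Variants absent
    from the table are removed: only variants known to segregate in the
    general population are trusted as germline.
    """
    pop = population_af.reindex(matrix.index)
    maf = np.minimum(pop, 1.0 - pop)
    keep = maf >= threshold
    keep[pop.isna()] = False
    return matrix.loc[keep]


def af_concordance(af_a: pd.Series, af_b: pd.Series) -> float:
    """Pearson correlation of two allele-frequency vectors on shared keys."""
    joined = pd.concat([af_a, af_b], axis=1, join="inner", keys=["a", "b"]).dropna()
    if len(joined) < 3:
        raise ValueError(
            f"need >= 3 shared variants with defined AF, got {len(joined)}"
        )
    if joined["a"].nunique() < 2 or joined["b"].nunique() < 2:
        raise ValueError("zero variance in an AF vector; correlation undefined")
    r, _ = stats.pearsonr(joined["a"], joined["b"])
    return float(r)
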