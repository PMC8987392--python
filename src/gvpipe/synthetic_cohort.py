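"""Synthetic cohort generator: every input the pipeline consumes, from seed.

The generator emulates the statistical structure the pipeline assumes, so
all stages are testable without any sequencing data: germline genotypes are
Hardy-Weinberg draws at per-variant allele frequencies; per-sample,
per-variant read depths are negative-binomial (heavier low-coverage tails
than Poisson, so the unknown/rescue path is actually exercised);
alt-supporting read counts are binomial at genotype-dependent variant
allele fractions (0.5 heterozygous, 0.98 homozygous-alternate, 0.005
sequencing-error rate for homozygous-reference); read mapping and base
qualities are drawn so a set fraction of reads fails the caller's quality
thresholds, and PCR duplicates are injected at a set rate.  Overall
survival is exponential with a per-allele log-hazard for one designated
causal variant and independent exponential censoring.

What it does not emulate: read-level sequence context (no FASTQ/BAM),
alignment artifacts, RNA editing, somatic mutation burden, linkage between
variants.  The three data types share a patient's germline genotype by
construction.

Two resolutions are provided: a read-level path (pileup tables -> caller ->
VCFs) for desk-scale cohorts, and a count-level fast path
(:func:`simulate_status_matrices`) that draws (depth, alt-count) pairs
directly for large-cohort statistical checks.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import calling, coverage
from .calling import CallerParams, PileupSite, ReadObs, call_from_counts, call_sample
from .formats import (
    HET,
    HOM_ALT,
    HOM_REF,
    DepthRecord,
    VariantKey,
    write_depth_tsv,
    write_population_af,
    write_status_table,
    write_vcf,
)
from .status_matrix import KEY_COLUMNS, StatusPolicy, determine_status

__all__ = [
    "DATA_TYPES",
    "CohortSimConfig",
    "simulate_genotypes",
    "sample_availability",
    "barcode",
    "simulate_counts",
    "simulate_status_matrices",
    "simulate_reads",
    "simulate_survival",
    "emit_cohort",
]

#: Data-type tags, in rescue priority order after normal.
DATA_TYPES = ("normal", "tumor", "rnaseq")
DTYPE_DIRS = {"normal": "wxs-normal", "tumor": "wxs-tumor", "rnaseq": "rnaseq-tumor"}
_BARCODE_SUFFIX = {"normal": "N", "tumor": "T", "rnaseq": "R"}

_BASES = np.array(list("ACGT"))


def _default_depth_mean() -> dict:
    # wxs-tumor is sequenced deepest, rnaseq shallowest: this ordering is what
    # makes tumor-first rescue sensible.
    return {"normal": 60.0, "tumor": 80.0, "rnaseq": 30.0}


def _default_depth_dispersion() -> dict:
    # negative-binomial size parameter r (var = m + m^2/r).  r=1 at mean 60
    # puts ~15% of wxs-normal sites below 10 reads; rnaseq is more dispersed.
    return {"normal": 1.0, "tumor": 2.0, "rnaseq": 0.7}


def _default_availability() -> dict:
    # mirrors a 5 normal / 7 tumor / 7 rnaseq test cohort
    return {"normal": 5 / 7, "tumor": 1.0, "rnaseq": 1.0}


@dataclass
class CohortSimConfig:
    """Knobs of the synthetic cohort; defaults define the study conditions."""

    n_patients: int = 7
    n_variants: int = 120
    af_low: float = 0.05
    af_high: float = 0.5
    allele_frequencies: Optional[np.ndarray] = None  # overrides the uniform draw
    depth_mean: dict = field(default_factory=_default_depth_mean)
    depth_dispersion: dict = field(default_factory=_default_depth_dispersion)
    availability: dict = field(default_factory=_default_availability)
    vaf_het: float = 0.5
    vaf_hom_alt: float = 0.98
    vaf_error: float = 0.005
    qual_fail_rate: float = 0.05  # fraction of reads failing MQ or BQ cutoffs
    duplicate_rate: float = 0.10  # extra PCR-duplicate reads per kept read
    baseline_hazard: float = 0.02  # events per month
    censoring_rate: float = 0.01  # censoring hazard per month
    causal_beta: float = 0.7  # per-allele log hazard of the causal variant
    causal_variant: int = 0  # column index of the causal variant
    seed: int = 0

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _case_ids(n: int) -> list[str]:
    return [f"CASE-{i:04d}" for i in range(1, n + 1)]


def barcode(case_id: str, data_type: str) -> str:
    return f"{case_id}-{_BARCODE_SUFFIX[data_type]}"


def _make_keys(n_variants: int, rng: np.random.Generator) -> list[VariantKey]:
    keys = []
    used: set[tuple[str, int]] = set()
    for i in range(n_variants):
        chrom = f"chr{(i % 22) + 1}"
        pos = int(rng.integers(10_000, 50_000_000))
        while (chrom, pos) in used:
            pos = int(rng.integers(10_000, 50_000_000))
        used.add((chrom, pos))
        ref, alt = rng.choice(_BASES, size=2, replace=False)
        keys.append(VariantKey.make(chrom, pos, str(ref), str(alt)))
    return keys


def simulate_genotypes(
    config: CohortSimConfig, rng: Optional[np.random.Generator] = None
) -> tuple[pd.DataFrame, list[VariantKey], np.ndarray]:
    """Hardy-Weinberg genotype truth table.

    Returns ``(truth, keys, afs)`` where ``truth`` is patients-by-variants
    with status strings, variants indexed by (CHROM, POS, REF, ALT).
    """
    rng = config.rng() if rng is None else rng
    keys = _make_keys(config.n_variants, rng)
    if config.allele_frequencies is not None:
        afs = np.asarray(config.allele_frequencies, dtype=float)
        if afs.shape != (config.n_variants,):
            raise ValueError("allele_frequencies length must equal n_variants")
    else:
        afs = rng.uniform(config.af_low, config.af_high, size=config.n_variants)
    probs = np.stack([(1 - afs) ** 2, 2 * afs * (1 - afs), afs**2], axis=1)
    draws = np.empty((config.n_patients, config.n_variants), dtype=int)
    for j in range(config.n_variants):
        draws[:, j] = rng.choice(3, size=config.n_patients, p=probs[j])
    statuses = np.array([HOM_REF, HET, HOM_ALT])[draws]
    truth = pd.DataFrame(
        statuses,
        index=_case_ids(config.n_patients),
        columns=pd.MultiIndex.from_tuples(keys, names=KEY_COLUMNS),
    )
    return truth, keys, afs


def sample_availability(
    config: CohortSimConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Which patients have which sample: a patient map with barcodes.

    Per data type, ``round(availability * n_patients)`` patients are chosen
    (so the default 5/7, 1.0, 1.0 yields exactly 5/7/7 samples for a
    7-patient cohort).
    """
    cases = _case_ids(config.n_patients)
    table: dict[str, list] = {}
    for dtype in DATA_TYPES:
        n_avail = int(round(config.availability[dtype] * config.n_patients))
        chosen = set(rng.choice(config.n_patients, size=n_avail, replace=False))
        table[dtype] = [
            barcode(case, dtype) if i in chosen else pd.NA
            for i, case in enumerate(cases)
        ]
    pmap = pd.DataFrame(table, index=pd.Index(cases, name="Case_ID"))
    return pmap


_VAF = {HOM_REF: "vaf_error", HET: "vaf_het", HOM_ALT: "vaf_hom_alt"}


def simulate_counts(
    truth: pd.DataFrame,
    config: CohortSimConfig,
    data_type: str,
    cases: list[str],
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Count-level read model: (depth, alt-count) per patient and variant."""
    m = config.depth_mean[data_type]
    r = config.depth_dispersion[data_type]
    n_var = truth.shape[1]
    depths = rng.negative_binomial(r, r / (r + m), size=(len(cases), n_var))
    vafs = np.vectorize(lambda s: getattr(config, _VAF[s]))(truth.loc[cases].values)
    alts = rng.binomial(depths, vafs)
    depth_df = pd.DataFrame(depths, index=cases, columns=truth.columns)
    alt_df = pd.DataFrame(alts, index=cases, columns=truth.columns)
    return depth_df, alt_df


def simulate_status_matrices(
    config: CohortSimConfig,
    params: CallerParams = CallerParams(),
    policy: StatusPolicy = StatusPolicy(),
    rng: Optional[np.random.Generator] = None,
) -> dict:
    """Fast path: per-data-type status matrices straight from count draws.

    Applies the caller's count thresholds and the coverage-corrected status
    rule per cell, skipping read-level simulation; suitable for
    large-cohort statistical checks.  Returns a dict with ``truth``,
    ``keys``, ``afs``, ``patient_map`` and one status matrix per data type
    (columns are sample barcodes).
    """
    rng = config.rng() if rng is None else rng
    truth, keys, afs = simulate_genotypes(config, rng)
    pmap = sample_availability(config, rng)
    out = {"truth": truth, "keys": keys, "afs": afs, "patient_map": pmap}
    index = pd.MultiIndex.from_tuples(keys, names=KEY_COLUMNS)
    for dtype in DATA_TYPES:
        cases = [c for c in pmap.index if pd.notna(pmap.loc[c, dtype])]
        depth_df, alt_df = simulate_counts(truth, config, dtype, cases, rng)
        cols = {}
        for case in cases:
            d = depth_df.loc[case].values
            a = alt_df.loc[case].values
            statuses = [
                determine_status(call_from_counts(int(di), int(ai), params), int(di), policy)
                for di, ai in zip(d, a)
            ]
            cols[pmap.loc[case, dtype]] = statuses
        out[dtype] = pd.DataFrame(cols, index=index)
    return out


def _site_reads(
    key: VariantKey,
    depth: int,
    alt_count: int,
    config: CohortSimConfig,
    rng: np.random.Generator,
) -> PileupSite:
    """Expand a (depth, alt-count) pair into read observations."""
    bases = [key.alt] * alt_count + [key.ref] * (depth - alt_count)
    obs: list[ReadObs] = []
    starts = rng.integers(max(1, key.pos - 150), key.pos + 1, size=depth)
    strands = rng.choice(["+", "-"], size=depth)
    fail_mq = rng.random(depth) < config.qual_fail_rate
    fail_bq = rng.random(depth) < config.qual_fail_rate
    dup = rng.random(depth) < config.duplicate_rate
    for i, base in enumerate(bases):
        mapq = int(rng.integers(0, 31)) if fail_mq[i] else int(rng.integers(31, 61))
        baseq = int(rng.integers(10, 26)) if fail_bq[i] else int(rng.integers(26, 41))
        read = ReadObs(base, baseq, mapq, int(starts[i]), str(strands[i]))
        obs.append(read)
        if dup[i]:  # PCR duplicate: same start/strand/base, its own BQ
            obs.append(ReadObs(base, int(rng.integers(10, 41)), mapq, read.read_start, read.strand))
    return PileupSite(key.chrom, key.pos, key.ref, tuple(obs))


def simulate_reads(
    truth: pd.DataFrame,
    config: CohortSimConfig,
    patient_map: pd.DataFrame,
    rng: np.random.Generator,
) -> dict:
    """Read-level model: per data type, per sample pileup sites.

    Returns ``{data_type: {barcode: [PileupSite, ...]}}``.  Qualities are
    drawn so roughly ``qual_fail_rate`` of reads fails each of the MQ/BQ
    thresholds, and duplicates are injected to exercise deduplication.
    """
    keys = [VariantKey(*t) for t in truth.columns]
    out: dict[str, dict[str, list[PileupSite]]] = {}
    for dtype in DATA_TYPES:
        cases = [c for c in patient_map.index if pd.notna(patient_map.loc[c, dtype])]
        depth_df, alt_df = simulate_counts(truth, config, dtype, cases, rng)
        samples: dict[str, list[PileupSite]] = {}
        for case in cases:
            sites = [
                _site_reads(key, int(depth_df.loc[case, tuple(key)]), int(alt_df.loc[case, tuple(key)]), config, rng)
                for key in keys
            ]
            samples[patient_map.loc[case, dtype]] = sites
        out[dtype] = samples
    return out


_COVARIATE_DRAWS = {
    "Histology": [1, 2, 3],
    "Grade": [1, 2],
    "IDH_status": [1, 2],
    "Chr7gain_Chr10loss": [1, 2],
    "MGMT_promoter_status": [1, 2],
    "Chr1p19q_codeletion": [1, 2],
    "Treatment_site": [1, 2, 3],
}

_LABEL_NUM = {HOM_REF: 0, HET: 1, HOM_ALT: 2}


def simulate_survival(
    truth: pd.DataFrame,
    config: CohortSimConfig,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Clinical/survival table with genotype-dependent exponential hazard.

    Event times follow ``Exponential(h0 * exp(beta * label))`` where label
    is the 0/1/2 genotype at the designated causal variant; censoring is an
    independent exponential.  Covariates are drawn within their ordinal
    ranges, independent of survival (no covariate effects by default).
    """
    rng = config.rng() if rng is None else rng
    n = len(truth)
    labels = truth.iloc[:, config.causal_variant].map(_LABEL_NUM).values
    hazard = config.baseline_hazard * np.exp(config.causal_beta * labels)
    event_time = rng.exponential(1.0 / hazard)
    if config.censoring_rate > 0:
        censor_time = rng.exponential(1.0 / config.censoring_rate, size=n)
    else:
        censor_time = np.full(n, np.inf)
    os_months = np.minimum(event_time, censor_time)
    os_status = (event_time <= censor_time).astype(int)
    clin = pd.DataFrame({"Case_ID": truth.index})
    clin["OS_months"] = np.round(os_months, 3)
    clin["OS_status"] = os_status
    clin["Age"] = np.round(rng.normal(47, 13, size=n).clip(18, 90), 1)
    clin["Percent_aneuploidy"] = np.round(rng.beta(1.2, 6.0, size=n), 4)
    for col, levels in _COVARIATE_DRAWS.items():
        clin[col] = rng.choice(levels, size=n)
    clin["Mutation_count"] = rng.poisson(45, size=n)
    clin["PC3"] = np.round(rng.normal(0, 1, size=n), 4)
    return clin


def emit_cohort(config: CohortSimConfig, out_dir: str) -> dict:
    """Write a complete synthetic cohort directory tree.

    Emits per-sample pileup tables, caller VCFs, depth TSVs (MQ > 30 counts,
    zero-depth positions omitted), the three patient lists, a population
    allele-frequency table (true AF plus small noise), the clinical CSV and
    the ground-truth genotype table.  Deterministic in ``config.seed``.
    """
    rng = config.rng()
    truth, keys, afs = simulate_genotypes(config, rng)
    pmap = sample_availability(config, rng)
    reads = simulate_reads(truth, config, pmap, rng)

    os.makedirs(out_dir, exist_ok=True)
    paths: dict = {"out_dir": out_dir, "pileups": {}, "vcfs": {}, "depths": {}}
    positions = [(k.chrom, k.pos) for k in keys]
    for dtype in DATA_TYPES:
        ddir = DTYPE_DIRS[dtype]
        for sub in ("pileups", "VCFs_from_VarDict", "variant_coverage"):
            os.makedirs(os.path.join(out_dir, sub, ddir), exist_ok=True)
        paths["pileups"][dtype] = {}
        paths["vcfs"][dtype] = {}
        paths["depths"][dtype] = {}
        for bc, sites in reads[dtype].items():
            ppath = os.path.join(out_dir, "pileups", ddir, f"{bc}.pileup.tsv")
            calling.write_pileup_table(sites, ppath)
            paths["pileups"][dtype][bc] = ppath
            vpath = os.path.join(out_dir, "VCFs_from_VarDict", ddir, f"{bc}.vcf")
            write_vcf(call_sample(sites, bc), vpath, sample_id=bc)
            paths["vcfs"][dtype][bc] = vpath
            dpath = os.path.join(out_dir, "variant_coverage", ddir, f"{bc}.depth.tsv")
            depth = coverage.depth_at_positions(sites, positions)
            write_depth_tsv(
                [
                    DepthRecord(chrom, pos, int(d))
                    for (chrom, pos), d in depth.items()
                    if d > 0
                ],
                dpath,
            )
            paths["depths"][dtype][bc] = dpath

    samples_dir = os.path.join(out_dir, "samples")
    os.makedirs(samples_dir, exist_ok=True)
    for dtype in DATA_TYPES:
        lpath = os.path.join(samples_dir, f"{DTYPE_DIRS[dtype]}_patients.tsv")
        sub = pmap[[dtype]].dropna().reset_index()
        sub.to_csv(lpath, sep="\t", index=False)
        paths[f"patients_{dtype}"] = lpath

    pop_af = pd.Series(
        np.clip(afs + rng.normal(0, 0.005, size=len(afs)), 0.001, 0.999),
        index=pd.MultiIndex.from_tuples(keys, names=KEY_COLUMNS),
    )
    paths["population_af"] = os.path.join(out_dir, "population_af.tsv")
    write_population_af(pop_af.round(4), paths["population_af"])

    clin = simulate_survival(truth, config, rng)
    paths["clinical"] = os.path.join(out_dir, "clinical.csv")
    clin.to_csv(paths["clinical"], index=False)

    paths["truth"] = os.path.join(out_dir, "truth_genotypes.tsv")
    write_status_table(truth.T, paths["truth"])
    return paths
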