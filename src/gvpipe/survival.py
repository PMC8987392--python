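"""Genotype-survival association: KM/log-rank, multivariate Cox, Bonferroni.

Per variant, patient genotypes are encoded on an ordinal 0/1/2 scale
(Homozygous_ref/Heterozygous/Homozygous_alt; unknown -> missing, and such
patients are dropped from that variant's models).  Overall survival is
compared across genotype groups with the log-rank (Mantel-Haenszel) test,
and the genotype enters a multivariate Cox proportional-hazards model as a
single additive ordinal term alongside the clinical covariates (age,
percent aneuploidy, histology, grade, IDH status, mutation count,
chr7-gain/chr10-loss, MGMT promoter status, chr1p/19q codeletion, treatment
site and ancestry PC3 in the default scheme).  Ties are handled with
Efron's approximation.  P-values over many tested variants are corrected by
Bonferroni.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .formats import HET, HOM_ALT, HOM_REF, UNKNOWN

__all__ = [
    "DEFAULT_COVARIATES",
    "encode_labels",
    "KMLogrankResult",
    "km_logrank",
    "plot_km",
    "CoxResult",
    "cox_multivariate",
    "cox_score_test",
    "bonferroni",
    "run_survival_scan",
]

#: Covariates of the default multivariate Cox model, in their ordinal/numeric
#: encodings (e.g. Histology: oligodendroglioma=1, oligoastrocytoma=2,
#: astrocytoma=3; Grade: G2=1, G3=2; IDH_status: mutant=1, WT=2; ...).
DEFAULT_COVARIATES = [
    "Age",
    "Percent_aneuploidy",
    "Histology",
    "Grade",
    "IDH_status",
    "Mutation_count",
    "Chr7gain_Chr10loss",
    "MGMT_promoter_status",
    "Chr1p19q_codeletion",
    "Treatment_site",
    "PC3",
]

_LABEL = {HOM_REF: 0.0, HET: 1.0, HOM_ALT: 2.0, UNKNOWN: np.nan}


def encode_labels(statuses: pd.Series) -> pd.Series:
    """Ordinal genotype labels: hom-ref 0, het 1, hom-alt 2, unknown missing."""
    bad = set(statuses.unique()) - set(_LABEL)
    if bad:
        raise ValueError(f"unexpected status values {sorted(bad)}")
    return statuses.map(_LABEL).astype(float)


@dataclass
class KMLogrankResult:
    """Per-group KM survival curves and the pooled log-rank test."""

    curves: dict  # group label -> survival function DataFrame (index: time)
    group_sizes: dict
    chisq: float
    p_value: float
    df: int


def km_logrank(labels: pd.Series, times: pd.Series, events: pd.Series) -> KMLogrankResult:
    """Kaplan-Meier curves per genotype group plus the log-rank test.

    Missing labels are dropped.  The statistic is the Mantel-Haenszel
    chi-square pooling observed-minus-expected events over distinct event
    times, referred to a chi-square with (groups - 1) degrees of freedom.
    """
    df = pd.DataFrame({"label": labels, "time": times, "event": events}).dropna()
    groups = sorted(df["label"].unique())
    if len(groups) < 2:
        raise ValueError(f"need >= 2 non-empty genotype groups, got {len(groups)}")
    if int(df["event"].sum()) == 0:
        raise ValueError("no events observed; log-rank test undefined")
    test = multivariate_logrank_test(df["time"], df["label"], df["event"])
    curves = {}
    sizes = {}
    for g in groups:
        sub = df[df["label"] == g]
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"], label=str(g))
        curves[g] = kmf.survival_function_
        sizes[g] = len(sub)
    return KMLogrankResult(
        curves=curves,
        group_sizes=sizes,
        chisq=float(test.test_statistic),
        p_value=float(test.p_value),
        df=len(groups) - 1,
    )


def plot_km(result: KMLogrankResult, path: str) -> None:
    """Convenience KM plot (one colored step curve per genotype group)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = ["blue", "orange", "red"]
    fig, ax = plt.subplots(figsize=(6, 5))
    for (group, curve), color in zip(result.curves.items(), colors):
        ax.step(
            curve.index,
            curve.iloc[:, 0],
            where="post",
            color=color,
            label=f"genotype {group:g} (n={result.group_sizes[group]})",
        )
    ax.set_xlabel("Follow up in months")
    ax.set_ylabel("Overall survival")
    ax.set_ylim(0, 1.02)
    ax.legend(loc="best", frameon=False)
    ax.text(
        0.55,
        0.05,
        f"P = {result.p_value:.3g}",
        transform=ax.transAxes,
    )
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


@dataclass
class CoxResult:
    """Multivariate Cox fit: one row per term plus the model log-likelihood."""

    summary: pd.DataFrame  # columns: coef, hazard_ratio, se, z, p
    log_likelihood: float
    n_used: int
    n_dropped: int
    confidence_intervals: pd.DataFrame = field(default_factory=pd.DataFrame)


def cox_multivariate(
    labels: pd.Series,
    clinical: pd.DataFrame,
    covariates: list[str] | None = None,
) -> CoxResult:
    """Cox proportional-hazards regression of survival on genotype + covariates.

    ``labels`` is the ordinal genotype series aligned to ``clinical`` (which
    must carry OS_months, OS_status and the covariate columns).  Complete
    cases only: rows with any missing modeled field are dropped and counted.
    The genotype enters as the single numeric term ``labels``.  Ties are
    handled with Efron's approximation.
    """
    if covariates is None:
        covariates = [c for c in DEFAULT_COVARIATES if c in clinical.columns]
    missing_cols = [c for c in covariates if c not in clinical.columns]
    if missing_cols:
        raise ValueError(f"clinical table lacks covariate columns {missing_cols}")
    data = clinical[["OS_months", "OS_status", *covariates]].copy()
    data.insert(0, "labels", np.asarray(labels, dtype=float))
    n_total = len(data)
    data = data.dropna()
    n_used = len(data)
    for col in ["labels", *covariates]:
        if data[col].nunique() <= 1:
            raise ValueError(f"covariate {col!r} is constant in the complete cases")
    cph = CoxPHFitter()
    cph.fit(data, duration_col="OS_months", event_col="OS_status")
    summ = cph.summary
    out = pd.DataFrame(
        {
            "coef": summ["coef"],
            "hazard_ratio": np.exp(summ["coef"]),
            "se": summ["se(coef)"],
            "z": summ["z"],
            "p": summ["p"],
        }
    )
    ci = pd.DataFrame(
        {
            "coef_lower_95": summ["coef lower 95%"],
            "coef_upper_95": summ["coef upper 95%"],
        }
    )
    return CoxResult(
        summary=out,
        log_likelihood=float(cph.log_likelihood_),
        n_used=n_used,
        n_dropped=n_total - n_used,
        confidence_intervals=ci,
    )


def cox_score_test(x: np.ndarray, times: np.ndarray, events: np.ndarray) -> tuple[float, float]:
    """Partial-likelihood score test of a single Cox covariate at beta = 0.

    Returns ``(chi_square, p_value)`` with 1 degree of freedom.  For a
    binary covariate without tied event times this equals the two-group
    log-rank statistic exactly (the classical equivalence).
    """
    from scipy import stats

    x = np.asarray(x, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    u = 0.0
    v = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        xr = x[at_risk]
        mean = xr.mean()
        var = np.mean(xr**2) - mean**2
        dead = (times == t) & (events == 1)
        u += float(np.sum(x[dead] - mean))
        v += float(dead.sum() * var)
    if v <= 0:
        raise ValueError("zero score-test variance (constant covariate at risk)")
    chisq = u * u / v
    return chisq, float(stats.chi2.sf(chisq, df=1))


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni correction: ``p_adj = min(1, m * p)``.

    ``m`` defaults to the vector length but may be larger when the vector is
    a subset of all variants tested.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError(f"m ({m}) smaller than number of p-values ({p.size})")
    return np.minimum(1.0, m * p)


def run_survival_scan(
    matrix: pd.DataFrame,
    clinical: pd.DataFrame,
    covariates: list[str] | None = None,
    include_logrank: bool = True,
) -> pd.DataFrame:
    """Per-variant association scan over a Case_ID-keyed status matrix.

    Clinical rows are matched to matrix columns by ``Case_ID``.  For each
    variant the ordinal genotype is tested in the multivariate Cox model
    (and optionally by log-rank); variants whose model cannot be fit
    (single genotype group, no events, singular design) get NaN statistics.
    The Bonferroni ``m`` is the number of variants scanned.
    """
    import warnings

    clin = clinical.set_index("Case_ID") if "Case_ID" in clinical.columns else clinical
    cases = [c for c in matrix.columns if c in clin.index]
    if not cases:
        raise ValueError("no overlap between matrix columns and clinical Case_IDs")
    clin = clin.loc[cases]
    rows = []
    for key, statuses in matrix[cases].iterrows():
        labels = encode_labels(statuses)
        labels.index = cases
        rec = {
            "CHROM": key[0],
            "POS": key[1],
            "REF": key[2],
            "ALT": key[3],
            "n_hom_ref": int((labels == 0).sum()),
            "n_het": int((labels == 1).sum()),
            "n_hom_alt": int((labels == 2).sum()),
            "logrank_chisq": np.nan,
            "logrank_p": np.nan,
            "coef": np.nan,
            "hazard_ratio": np.nan,
            "z": np.nan,
            "p": np.nan,
        }
        if include_logrank:
            try:
                lr = km_logrank(labels, clin["OS_months"], clin["OS_status"])
                rec["logrank_chisq"] = lr.chisq
                rec["logrank_p"] = lr.p_value
            except (ValueError, ZeroDivisionError):
                pass
        try:
            with warnings.catch_warnings():
                # small per-variant fits can be ill-conditioned; the scan
                # records NaN for them instead of warning per variant
                warnings.simplefilter("ignore")
                cox = cox_multivariate(labels, clin, covariates)
            term = cox.summary.loc["labels"]
            rec.update(
                coef=term["coef"],
                hazard_ratio=term["hazard_ratio"],
                z=term["z"],
                p=term["p"],
            )
        except Exception:
            pass
        rows.append(rec)
    out = pd.DataFrame(rows)
    m = len(out)
    out["p_bonferroni"] = [
        np.nan if np.isnan(p) else bonferroni([p], m=m)[0] for p in out["p"]
    ]
    return out
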