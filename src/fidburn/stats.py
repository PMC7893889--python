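"""Setup-error statistics for registration-record cohorts.

Three analyses over tables of 6-parameter registration records
(translations RL/CC/AP in mm, rotations about those axes in degrees):

* **Inter-observer error (IOE)** — per-patient inter-quartile range and,
  after subtracting each patient's mean so records pool across patients,
  the pooled SD per parameter; two workflows are compared patient-level
  (paired Wilcoxon on IQRs) and group-level (non-parametric Levene on the
  pooled mean-centered values).
* **Population error decomposition** — per parameter, the population mean
  M (mean of per-patient means), systematic error Sigma (SD of per-patient
  means) and random error sigma (RMS of per-patient SDs), the van Herk
  convention used for margin recipes.
* **Paired workflow differences** — per-fraction differences between two
  workflows' registrations, decomposed the same way, with a Wilcoxon
  signed-rank test of the per-patient mean differences against zero.

The paired Wilcoxon test is implemented here (zero differences dropped,
ties midranked, exact null by enumeration for n <= 15, continuity-corrected
normal approximation otherwise); the non-parametric Levene test is the
Brown-Forsythe variant (ANOVA on absolute deviations from group medians).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

PARAM_COLUMNS = ["tRL_mm", "tCC_mm", "tAP_mm", "rRL_deg", "rCC_deg", "rAP_deg"]

__all__ = [
    "PARAM_COLUMNS",
    "WilcoxonResult",
    "LeveneResult",
    "CohortErrorSummary",
    "IOESummary",
    "paired_wilcoxon",
    "levene_nonparametric",
    "population_errors",
    "ioe_summary",
    "registration_difference_stats",
]


@dataclass
class WilcoxonResult:
    statistic: float  # W+ (sum of ranks of positive differences)
    pvalue: float
    n: int  # non-zero differences used
    method: str  # "exact" or "normal"
    degenerate: bool = False


@dataclass
class LeveneResult:
    statistic: float
    pvalue: float
    degenerate: bool = False


@dataclass
class CohortErrorSummary:
    """Per-parameter M / Sigma / sigma table plus bookkeeping counts."""

    table: pd.DataFrame  # index: parameter; columns: mean, systematic, random
    n_patients: int
    n_records: int
    n_excluded: int = 0  # patients excluded from sigma (single record)
    pvalues: pd.Series | None = None  # optional per-parameter test results


@dataclass
class IOESummary:
    """Inter-observer comparison of two workflows."""

    table: pd.DataFrame  # per parameter: mean IQR + pooled SD per workflow, p-values
    per_patient_iqr: pd.DataFrame  # patient x workflow x parameter IQRs
    workflows: tuple
    n_unpaired_patients: int = 0


def paired_wilcoxon(x, y=None) -> WilcoxonResult:
    """Paired two-sided Wilcoxon signed-rank test.

    Differences of exactly zero are dropped (Wilcoxon's original method,
    matching common SPSS behaviour); tied absolute differences receive
    midranks.  The null distribution of W+ is enumerated exactly for
    n <= 15 non-zero differences (a convolution over the doubled midranks,
    which handles ties exactly) and approximated by a continuity-corrected
    normal with tie-corrected variance otherwise.

    Passing ``y=None`` tests the sample ``x`` of differences against zero.
    """
    x = np.asarray(x, dtype=float)
    d = x - np.asarray(y, dtype=float) if y is not None else x
    if d.ndim != 1:
        raise ValueError("inputs must be 1-D paired samples")
    if y is not None and len(np.atleast_1d(y)) != len(x):
        raise ValueError("paired samples must have equal length")
    if len(d) < 1:
        raise ValueError("need at least one pair")
    d = d[d != 0.0]
    n = len(d)
    if n == 0:
        return WilcoxonResult(0.0, 1.0, 0, "degenerate", degenerate=True)
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= 15:
        # exact: distribution of W+ over all 2^n sign assignments via
        # convolution on doubled midranks (integers even with .5 midranks)
        dr = np.rint(2 * ranks).astype(np.int64)
        total = int(dr.sum())
        counts = np.zeros(total + 1, dtype=np.float64)
        counts[0] = 1.0
        upper = 0
        for r in dr:
            counts[r : upper + r + 1] += counts[: upper + 1]
            upper += int(r)
        counts /= 2.0**n
        w2 = int(np.rint(2 * w_plus))
        p_le = float(counts[: w2 + 1].sum())
        p_ge = float(counts[w2:].sum())
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return WilcoxonResult(w_plus, p, n, "exact")
    mn = n * (n + 1) / 4.0
    _, tie_counts = np.unique(np.abs(d), return_counts=True)
    tie_corr = float(np.sum(tie_counts**3 - tie_counts)) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_corr
    if var <= 0:
        return WilcoxonResult(w_plus, 1.0, n, "degenerate", degenerate=True)
    cc = 0.5 * np.sign(w_plus - mn)
    z = (w_plus - mn - cc) / np.sqrt(var)
    p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
    return WilcoxonResult(w_plus, p, n, "normal")


def levene_nonparametric(*groups, variant: str = "median") -> LeveneResult:
    """Test equality of spread across groups without normality assumptions.

    ``variant="median"`` is the Brown-Forsythe test: a one-way ANOVA on
    absolute deviations from each group's median.  ``variant="rank"``
    rank-transforms the pooled absolute deviations first (some authors'
    reading of "non-parametric Levene").
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) < 2 for g in groups):
        raise ValueError("each group must have at least two values")
    z = [np.abs(g - np.median(g)) for g in groups]
    flat = np.concatenate(z)
    if np.allclose(flat, flat[0]):
        return LeveneResult(0.0, 1.0, degenerate=True)
    if variant == "median":
        stat, p = sps.levene(*groups, center="median")
    elif variant == "rank":
        ranks = sps.rankdata(flat)
        split = np.cumsum([len(g) for g in groups])[:-1]
        stat, p = sps.f_oneway(*np.split(ranks, split))
    else:
        raise ValueError(f"unknown variant {variant!r}")
    return LeveneResult(float(stat), float(p))


def _check_params(records: pd.DataFrame, params) -> None:
    missing = [c for c in params if c not in records.columns]
    if missing:
        raise ValueError(f"records table lacks parameter columns {missing}")


def population_errors(
    records: pd.DataFrame, params=PARAM_COLUMNS
) -> CohortErrorSummary:
    """Population mean M, systematic Sigma and random sigma per parameter.

    Per parameter: patient means m_p and patient SDs s_p (n-1 denominator);
    M = mean of m_p, Sigma = SD of m_p (n-1), sigma = RMS of s_p.  Patients
    with a single record contribute to M and Sigma but are excluded from
    sigma (their SD is undefined) and counted in ``n_excluded``.
    """
    _check_params(records, params)
    by_patient = records.groupby("patient_id", sort=True)[list(params)]
    m_p = by_patient.mean()
    counts = by_patient.size()
    multi = counts[counts >= 2].index
    s_p = by_patient.std(ddof=1).loc[multi]
    table = pd.DataFrame({
        "mean": m_p.mean(),
        "systematic": m_p.std(ddof=1),
        "random": np.sqrt((s_p**2).mean()) if len(s_p) else np.nan,
    })
    table.index.name = "parameter"
    return CohortErrorSummary(
        table=table,
        n_patients=len(m_p),
        n_records=len(records),
        n_excluded=int((counts < 2).sum()),
    )


def _iqr(values: np.ndarray) -> float:
    """Inter-quartile range with linear-interpolation ("type 7") quantiles."""
    q1, q3 = np.percentile(values, [25, 75])
    return float(q3 - q1)


def ioe_summary(
    records: pd.DataFrame, params=PARAM_COLUMNS, workflows=None,
    levene_variant: str = "median",
) -> IOESummary:
    """Inter-observer error comparison between two workflows.

    Per patient and parameter the IQR across observers is computed
    (quantiles by linear interpolation); the patient-level comparison is a
    paired two-sided Wilcoxon signed-rank test on those IQRs.  For the
    group-level comparison each patient's mean is subtracted so records
    pool across patients; the pooled SD (n-1) is reported per workflow and
    compared with the non-parametric Levene test.
    """
    _check_params(records, params)
    if workflows is None:
        workflows = tuple(pd.unique(records["workflow"]))
    if len(workflows) != 2:
        raise ValueError(f"exactly two workflows required, got {workflows}")
    wf_a, wf_b = workflows

    iqr_rows = []
    for (wf, pat), grp in records.groupby(["workflow", "patient_id"], sort=True):
        if len(grp) < 2:
            raise ValueError(
                f"patient {pat} has {len(grp)} record(s) in workflow {wf}; need >= 2"
            )
        row = {"workflow": wf, "patient_id": pat}
        row.update({p: _iqr(grp[p].to_numpy()) for p in params})
        iqr_rows.append(row)
    iqr_df = pd.DataFrame(iqr_rows)

    pat_a = set(iqr_df.loc[iqr_df.workflow == wf_a, "patient_id"])
    pat_b = set(iqr_df.loc[iqr_df.workflow == wf_b, "patient_id"])
    paired_patients = sorted(pat_a & pat_b)
    n_unpaired = len(pat_a ^ pat_b)

    centered = {}
    for wf in workflows:
        sub = records[records.workflow == wf]
        centered[wf] = sub[list(params)] - sub.groupby("patient_id")[list(params)].transform("mean")

    rows = []
    for p in params:
        iqr_a = iqr_df[iqr_df.workflow == wf_a].set_index("patient_id")[p].loc[paired_patients]
        iqr_b = iqr_df[iqr_df.workflow == wf_b].set_index("patient_id")[p].loc[paired_patients]
        wres = paired_wilcoxon(iqr_a.to_numpy(), iqr_b.to_numpy())
        lres = levene_nonparametric(
            centered[wf_a][p].to_numpy(), centered[wf_b][p].to_numpy(),
            variant=levene_variant,
        )
        rows.append({
            "parameter": p,
            f"mean_iqr_{wf_a}": float(iqr_a.mean()),
            f"mean_iqr_{wf_b}": float(iqr_b.mean()),
            "p_patient": wres.pvalue,
            f"pooled_sd_{wf_a}": float(centered[wf_a][p].std(ddof=1)),
            f"pooled_sd_{wf_b}": float(centered[wf_b][p].std(ddof=1)),
            "p_group": lres.pvalue,
        })
    table = pd.DataFrame(rows).set_index("parameter")
    return IOESummary(
        table=table,
        per_patient_iqr=iqr_df,
        workflows=(wf_a, wf_b),
        n_unpaired_patients=n_unpaired,
    )


def registration_difference_stats(
    records: pd.DataFrame, params=PARAM_COLUMNS, workflows=None
) -> CohortErrorSummary:
    """Decompose per-fraction differences between two paired workflows.

    Records are paired by (patient, fraction) across the two workflow
    tags; the first-minus-second per-fraction differences are aggregated
    to per-patient mean and SD and decomposed into M, Sigma and sigma as
    in :func:`population_errors`.  A Wilcoxon signed-rank test of the
    per-patient mean differences against zero is reported per parameter.
    Unpaired fractions are excluded and counted.
    """
    _check_params(records, params)
    if workflows is None:
        workflows = tuple(pd.unique(records["workflow"]))
    if len(workflows) != 2:
        raise ValueError(f"exactly two workflows required, got {workflows}")
    wf_a, wf_b = workflows
    key = ["patient_id", "rater_or_fraction_id"]
    a = records[records.workflow == wf_a].set_index(key)[list(params)]
    b = records[records.workflow == wf_b].set_index(key)[list(params)]
    shared = a.index.intersection(b.index)
    n_unpaired = (len(a) - len(shared)) + (len(b) - len(shared))
    diff = (a.loc[shared] - b.loc[shared]).reset_index()
    summary = population_errors(diff, params=params)
    m_p = diff.groupby("patient_id", sort=True)[list(params)].mean()
    pvals = pd.Series(
        {p: paired_wilcoxon(m_p[p].to_numpy()).pvalue for p in params},
        name="p_mean_vs_zero",
    )
    summary.pvalues = pvals
    summary.n_excluded += n_unpaired
    return summary
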