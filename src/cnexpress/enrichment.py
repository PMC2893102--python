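"""Screening copy-number-associated transcripts in an independent cohort.

Two per-transcript screens are run on a testing cohort of tumor cases and
normal-tissue controls:

* case/control — the Z-score (slope / standard error) of expression
  regressed on the 0/1 case indicator by least squares; transcripts with
  |Z| above a cutoff (default 6) are flagged as disease-associated;
* survival — the Z-score of the expression coefficient in a Cox
  proportional-hazards model adjusted for age and sex, fit on cases with at
  least a minimum follow-up (default 4 months; an early-censoring rule to
  exclude deaths likely driven by co-morbidities); only cancer-specific
  deaths count as events.

Whether a candidate set (e.g., the FDR-selected dosage transcripts) is
enriched for screen signal is tested by comparing its statistic with that of
random same-size transcript sets drawn from the screened universe.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter

__all__ = [
    "ScreenResult",
    "EnrichmentTest",
    "casecontrol_screen",
    "survival_screen",
    "permutation_enrichment",
    "Z_CUTOFF_DEFAULT",
    "SURVIVAL_Z_CUTOFF_DEFAULT",
    "MIN_FOLLOWUP_DEFAULT",
]

Z_CUTOFF_DEFAULT = 6.0
SURVIVAL_Z_CUTOFF_DEFAULT = 1.96
MIN_FOLLOWUP_DEFAULT = 4.0  # months

STATISTICS = ("exceed_count", "mean_abs_z", "ks")


@dataclass
class EnrichmentTest:
    """Permutation enrichment result for one candidate transcript set."""

    statistic: str
    observed: float
    null_statistics: np.ndarray
    empirical_p: float
    n_candidates: int
    n_universe: int


def casecontrol_screen(
    expr_values: pd.DataFrame,
    case_status: pd.Series,
    z_cutoff: float = Z_CUTOFF_DEFAULT,
    signed: bool = False,
) -> pd.DataFrame:
    """Per-transcript Z-score for differential expression, case vs. control.

    Z is the t-statistic of the slope from least-squares regression of
    expression on the 0/1 case indicator (equivalently a pooled-variance
    two-sample t); computed in closed form across all transcripts at once.
    The flag is |Z| > cutoff by default, or Z > cutoff with ``signed``.
    """
    status = case_status.reindex(expr_values.columns)
    if status.isna().any():
        missing = list(status.index[status.isna()])
        raise ValueError(f"samples without case status: {missing[:5]}")
    x = status.to_numpy(dtype=float)
    if len(np.unique(x)) < 2:
        raise ValueError("case/control screen needs both classes present")
    y = expr_values.to_numpy(dtype=float)
    n = x.size
    xc = x - x.mean()
    sxx = float(np.sum(xc**2))
    beta = (y @ xc) / sxx
    intercept = y.mean(axis=1) - beta * x.mean()
    resid = y - (intercept[:, None] + np.outer(beta, x))
    df = n - 2
    sigma2 = np.sum(resid**2, axis=1) / df
    se = np.sqrt(sigma2 / sxx)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / se, 0.0)
    out = pd.DataFrame(
        {"cc_beta": beta, "cc_se": se, "cc_z": z}, index=expr_values.index
    )
    out["oscc_associated"] = (out["cc_z"] > z_cutoff) if signed else (out["cc_z"].abs() > z_cutoff)
    return out


def survival_screen(
    expr_values: pd.DataFrame,
    clinical: pd.DataFrame,
    min_followup: float = MIN_FOLLOWUP_DEFAULT,
    z_cutoff: float = SURVIVAL_Z_CUTOFF_DEFAULT,
) -> pd.DataFrame:
    """Per-transcript Cox Z-score for cancer-specific survival.

    ``clinical`` is indexed by sample id with columns ``followup_months``,
    ``oscc_death``, ``age``, ``sex`` (0/1 dummy); only samples present in
    both tables are used. Event-free subjects with follow-up shorter than
    ``min_followup`` months are excluded; subjects dying of other causes are
    censored at their death time.
    """
    cohort = clinical.loc[clinical.index.intersection(expr_values.columns)].copy()
    cohort = cohort.dropna(subset=["followup_months"])
    keep = (cohort["followup_months"] >= min_followup) | (cohort["oscc_death"] == 1)
    cohort = cohort.loc[keep]
    if not (cohort["followup_months"] > 0).all():
        raise ValueError("non-positive follow-up time in survival cohort")
    n_events = int(cohort["oscc_death"].sum())
    if n_events == 0:
        raise ValueError(
            "no cancer-specific deaths remain after the follow-up filter; "
            "survival screen aborted"
        )
    base = cohort[["followup_months", "oscc_death", "age", "sex"]].astype(float)
    if base["followup_months"].nunique() == 1 and n_events == 0:
        raise ValueError("degenerate cohort: all subjects censored at one time")
    rows = []
    cph = CoxPHFitter()
    for tid in expr_values.index:
        df = base.copy()
        df["expr"] = expr_values.loc[tid, cohort.index].to_numpy(dtype=float)
        try:
            cph.fit(df, duration_col="followup_months", event_col="oscc_death")
            z = float(cph.summary.loc["expr", "z"])
            coef = float(cph.summary.loc["expr", "coef"])
            se = float(cph.summary.loc["expr", "se(coef)"])
        except Exception:
            z, coef, se = np.nan, np.nan, np.nan
        rows.append((tid, coef, se, z))
    out = pd.DataFrame(
        rows, columns=["transcript_id", "surv_coef", "surv_se", "surv_z"]
    ).set_index("transcript_id")
    out["survival_associated"] = out["surv_z"].abs() > z_cutoff
    out.attrs["n_subjects"] = int(len(cohort))
    out.attrs["n_events"] = n_events
    return out


def _set_statistic(z: np.ndarray, statistic: str, cutoff: float, z_rest: np.ndarray) -> float:
    if statistic == "exceed_count":
        return float(np.sum(np.abs(z) > cutoff))
    if statistic == "mean_abs_z":
        return float(np.mean(np.abs(z)))
    if statistic == "ks":
        from scipy.stats import ks_2samp

        return float(ks_2samp(z, z_rest).statistic)
    raise ValueError(f"unknown statistic {statistic!r}; choose from {STATISTICS}")


def permutation_enrichment(
    candidate_ids,
    all_z: pd.Series,
    B: int = 1000,
    statistic: str = "exceed_count",
    z_cutoff: float = Z_CUTOFF_DEFAULT,
    seed: int = 0,
) -> EnrichmentTest:
    """Compare a candidate set's screen statistic with random same-size sets.

    ``B`` subsets of the same size are drawn without replacement from the
    screened universe; the empirical p-value uses the add-one correction
    (1 + #{null >= observed}) / (B + 1), so it is never zero.
    """
    if B < 100:
        raise ValueError(f"need at least 100 permutations, got B={B}")
    z_all = all_z.dropna()
    candidate = pd.Index(candidate_ids).intersection(z_all.index)
    missing = pd.Index(candidate_ids).difference(z_all.index)
    if len(pd.Index(candidate_ids)) > len(z_all):
        raise ValueError("candidate set larger than screened universe")
    k = len(candidate)
    if k == 0:
        raise ValueError("no candidate transcripts present in the screened universe")
    z_values = z_all.to_numpy(dtype=float)
    in_set = z_all.index.isin(candidate)
    observed = _set_statistic(z_values[in_set], statistic, z_cutoff, z_values[~in_set])
    rng = np.random.default_rng(seed)
    null = np.empty(B)
    m = len(z_all)
    for b in range(B):
        pick = rng.choice(m, size=k, replace=False)
        mask = np.zeros(m, dtype=bool)
        mask[pick] = True
        null[b] = _set_statistic(z_values[mask], statistic, z_cutoff, z_values[~mask])
    p = (1.0 + np.sum(null >= observed)) / (B + 1.0)
    return EnrichmentTest(
        statistic=statistic,
        observed=observed,
        null_statistics=null,
        empirical_p=float(p),
        n_candidates=k,
        n_universe=m,
    )
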