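"""PC-summary risk scores and landmark ROC comparison against clinical stage.

The expression of a transcript set is summarized by its first two principal
components; Cox proportional-hazards models over {stage}, {PC1, PC2} and
{stage, PC1, PC2} are fit; per-subject risk scores come from a jackknife
(leave-one-out) evaluation of the Cox linear predictor; and models are
compared by the area under the time-dependent (cumulative-case /
dynamic-control) ROC curve at a survival landmark, 24 months by default.

The ROC estimator is the Kaplan-Meier form of Heagerty, Lumley & Pepe
(2000): with S the KM survivor function of the whole cohort and S_c the KM
survivor function among subjects with score above cutpoint c,

    TPR(c) = (1 - S_c(t)) * P(X > c) / (1 - S(t))
    FPR(c) =      S_c(t)  * P(X > c) /      S(t)

which reduces to the empirical case/control ROC when no one is censored
before the landmark. Nearest-neighbor smoothing is not applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter

__all__ = [
    "PCSummary",
    "CoxSummary",
    "pc_scores",
    "fit_cox",
    "jackknife_risk_scores",
    "time_dependent_roc",
    "compare_auc",
    "LANDMARK_MONTHS_DEFAULT",
]

LANDMARK_MONTHS_DEFAULT = 24.0


@dataclass
class PCSummary:
    """First principal components of a transcript set's expression."""

    transcript_ids: list
    loadings: pd.DataFrame  # transcripts x components
    scores: pd.DataFrame  # samples x components
    variance_explained: np.ndarray


@dataclass
class CoxSummary:
    """Cox fit: coefficients, SEs, hazard ratios with 95% CI."""

    covariates: list
    coef: pd.Series
    se: pd.Series
    hr: pd.Series
    ci_lower: pd.Series
    ci_upper: pd.Series
    z: pd.Series
    log_likelihood: float
    n: int
    n_events: int

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coef,
                "se": self.se,
                "HR": self.hr,
                "HR_95CI_lower": self.ci_lower,
                "HR_95CI_upper": self.ci_upper,
                "z": self.z,
            }
        )


def pc_scores(expr_values: pd.DataFrame, transcript_set, n_components: int = 2) -> PCSummary:
    """PCA summary of a transcript subset (samples are the observations).

    The samples x transcripts matrix is column-centered (per transcript) and
    decomposed by SVD. Loadings are unit-norm and orthogonal; scores are
    mean-zero per component. The sign of each component is fixed so that its
    largest-magnitude loading element is positive.
    """
    ids = [t for t in transcript_set if t in expr_values.index]
    missing = set(transcript_set) - set(ids)
    if missing:
        raise ValueError(f"transcripts absent from expression matrix: {sorted(missing)[:5]}")
    if len(ids) < n_components:
        raise ValueError(
            f"transcript set of size {len(ids)} cannot support {n_components} components"
        )
    X = expr_values.loc[ids].to_numpy(dtype=float).T  # samples x transcripts
    Xc = X - X.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    k = n_components
    loadings = Vt[:k].T  # transcripts x k
    for j in range(k):
        i_max = np.argmax(np.abs(loadings[:, j]))
        if loadings[i_max, j] < 0:
            loadings[:, j] *= -1
            U[:, j] *= -1
    scores = U[:, :k] * s[:k]
    var = s**2 / max(X.shape[0] - 1, 1)
    var_explained = var[:k] / var.sum() if var.sum() > 0 else np.zeros(k)
    comp_names = [f"PC{j + 1}" for j in range(k)]
    return PCSummary(
        transcript_ids=ids,
        loadings=pd.DataFrame(loadings, index=ids, columns=comp_names),
        scores=pd.DataFrame(scores, index=expr_values.columns, columns=comp_names),
        variance_explained=var_explained,
    )


def fit_cox(
    clinical: pd.DataFrame,
    covariates: list[str],
    duration_col: str = "followup_months",
    event_col: str = "oscc_death",
) -> CoxSummary:
    """Cox proportional-hazards fit with Efron tie handling.

    Stage enters as a continuous integer (AJCC I-IV coded 1-4) when listed.
    Raises on a cohort without events or on constant covariates.
    """
    df = clinical[[duration_col, event_col] + list(covariates)].dropna().astype(float)
    n_events = int(df[event_col].sum())
    if n_events == 0:
        raise ValueError("cannot fit a Cox model: no events in cohort")
    for c in covariates:
        if df[c].nunique() == 1:
            raise ValueError(f"degenerate covariate {c!r}: constant across subjects")
    cph = CoxPHFitter()
    cph.fit(df, duration_col=duration_col, event_col=event_col)
    summ = cph.summary
    return CoxSummary(
        covariates=list(covariates),
        coef=summ["coef"],
        se=summ["se(coef)"],
        hr=summ["exp(coef)"],
        ci_lower=np.exp(summ["coef"] - 1.959963984540054 * summ["se(coef)"]),
        ci_upper=np.exp(summ["coef"] + 1.959963984540054 * summ["se(coef)"]),
        z=summ["z"],
        log_likelihood=float(cph.log_likelihood_),
        n=int(len(df)),
        n_events=n_events,
    )


def jackknife_risk_scores(
    clinical: pd.DataFrame,
    covariates: list[str],
    duration_col: str = "followup_months",
    event_col: str = "oscc_death",
) -> pd.Series:
    """Leave-one-out Cox risk scores: subject i's linear predictor from a
    model fit without subject i.

    Covariates are centered on the training subset before evaluating the
    held-out subject, matching the partial-likelihood convention of scoring
    relative to the training-cohort mean. Exactly one score per subject;
    invariant to subject ordering.
    """
    df = clinical[[duration_col, event_col] + list(covariates)].dropna().astype(float)
    if len(df) < 10:
        raise ValueError(f"jackknife needs at least 10 subjects, got {len(df)}")
    scores = {}
    cph = CoxPHFitter()
    for subject in df.index:
        train = df.drop(index=subject)
        try:
            cph.fit(train, duration_col=duration_col, event_col=event_col)
        except Exception as exc:  # pragma: no cover - diagnostic path
            raise RuntimeError(
                f"leave-one-out Cox fit failed with subject {subject!r} held out: {exc}"
            ) from exc
        x = df.loc[subject, covariates].to_numpy(dtype=float)
        x_center = train[covariates].mean().to_numpy(dtype=float)
        beta = cph.params_[covariates].to_numpy(dtype=float)
        scores[subject] = float((x - x_center) @ beta)
    return pd.Series(scores, name="risk_score").loc[df.index]


def _km_survival_at(time: np.ndarray, event: np.ndarray, t: float) -> float:
    """Kaplan-Meier survivor probability at time ``t`` (product-limit form).

    Direct numpy computation: the ROC estimator evaluates KM on many
    score-defined subsets, so this sits in a tight loop.
    """
    if time.size == 0:
        return np.nan
    order = np.argsort(time, kind="mergesort")
    ts, es = time[order], event[order]
    uniq, start = np.unique(ts, return_index=True)
    mask = uniq <= t
    if not mask.any():
        return 1.0
    n = ts.size
    d = np.add.reduceat(es, start)[mask]  # deaths at each event time <= t
    at_risk = (n - start)[mask]
    with np.errstate(divide="ignore", invalid="ignore"):
        surv = np.prod(1.0 - d / at_risk)
    return float(surv)


def time_dependent_roc(
    scores: pd.Series | np.ndarray,
    time: pd.Series | np.ndarray,
    event: pd.Series | np.ndarray,
    landmark: float = LANDMARK_MONTHS_DEFAULT,
) -> tuple[pd.DataFrame, float]:
    """Cumulative-case / dynamic-control ROC at a landmark time.

    Returns (curve, auc): the curve has one row per cutpoint with columns
    ``cutoff``, ``fpr``, ``tpr``; the AUC is the trapezoid area over the
    curve (with (0,0) and (1,1) endpoints), clipped to [0, 1].
    """
    x = np.asarray(scores, dtype=float)
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=float).astype(int)
    if not (x.size == t.size == e.size):
        raise ValueError("scores, time and event must have equal length")
    if landmark <= 0 or landmark > t.max():
        raise ValueError(f"landmark {landmark} outside the observed time range")
    if not np.any((t <= landmark) & (e == 1)):
        raise ValueError("no events before the landmark; ROC undefined")
    s_t = _km_survival_at(t, e, landmark)
    if s_t in (0.0, 1.0):
        raise ValueError("degenerate Kaplan-Meier survival at the landmark")
    cutoffs = np.unique(x)
    rows = []
    for c in cutoffs:
        above = x > c
        p_above = above.mean()
        if p_above == 0:
            tpr = fpr = 0.0
        else:
            s_c = _km_survival_at(t[above], e[above], landmark)
            tpr = (1.0 - s_c) * p_above / (1.0 - s_t)
            fpr = s_c * p_above / s_t
        rows.append((c, fpr, tpr))
    curve = pd.DataFrame(rows, columns=["cutoff", "fpr", "tpr"])
    curve[["fpr", "tpr"]] = curve[["fpr", "tpr"]].clip(0.0, 1.0)
    fpr = np.concatenate(([1.0], curve["fpr"].to_numpy(), [0.0]))
    tpr = np.concatenate(([1.0], curve["tpr"].to_numpy(), [0.0]))
    # round so float jitter cannot split ties, then sort by (fpr, tpr):
    # vertical runs at a tied fpr contribute no area
    fpr, tpr = np.round(fpr, 12), np.round(tpr, 12)
    order = np.lexsort((tpr, fpr))
    auc = float(np.trapezoid(tpr[order], fpr[order]))
    return curve, float(np.clip(auc, 0.0, 1.0))


def compare_auc(
    scores_a,
    scores_b,
    time,
    event,
    landmark: float = LANDMARK_MONTHS_DEFAULT,
    B_boot: int = 2000,
    seed: int = 0,
) -> dict:
    """Paired-bootstrap comparison of two risk scores' landmark AUCs.

    Subjects are resampled with replacement; both AUCs are recomputed on
    each resample; the two-sided p-value is the add-one-corrected fraction
    of bootstrap differences on the opposite side of zero, doubled and
    capped at 1.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=float).astype(int)
    if not (a.size == b.size == t.size == e.size):
        raise ValueError("score vectors must cover the same subjects")
    _, auc_a = time_dependent_roc(a, t, e, landmark)
    _, auc_b = time_dependent_roc(b, t, e, landmark)
    observed = auc_a - auc_b
    rng = np.random.default_rng(seed)
    diffs = []
    n = a.size
    attempts = 0
    while len(diffs) < B_boot and attempts < 4 * B_boot:
        attempts += 1
        idx = rng.integers(0, n, size=n)
        try:
            _, ra = time_dependent_roc(a[idx], t[idx], e[idx], landmark)
            _, rb = time_dependent_roc(b[idx], t[idx], e[idx], landmark)
        except ValueError:  # resample without pre-landmark events: redraw
            continue
        diffs.append(ra - rb)
    diffs = np.asarray(diffs)
    n_le = np.sum(diffs <= 0)
    n_ge = np.sum(diffs >= 0)
    p = min(1.0, 2.0 * (1.0 + min(n_le, n_ge)) / (len(diffs) + 1.0))
    return {
        "auc_a": auc_a,
        "auc_b": auc_b,
        "difference": observed,
        "p_value": float(p),
        "n_bootstrap": int(len(diffs)),
    }
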