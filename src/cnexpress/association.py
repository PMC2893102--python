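"""Per-transcript association between DNA copy number and expression.

Each transcript's expression is regressed on its log2 copy-number ratio with
a robust (Huber M-estimator) linear model; the slope's t-statistic is
converted to a two-sided p-value on N-2 degrees of freedom. Multiplicity is
controlled by Benjamini-Hochberg step-up FDR, the fraction of truly
dosage-responsive transcripts is estimated from the p-value histogram
(Storey's pi0 at lambda = 0.5), and dose-response is summarized over six
copy-number-ratio bins spanning high-level deletion (< 0.5) through
high-level amplification (> 4).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.robust.norms import HuberT
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AssociationResult",
    "robust_regress",
    "associate_all",
    "fdr_select",
    "estimate_signal_proportion",
    "dose_response",
    "log2fc_to_fold",
    "genome_scan_report",
    "bonferroni_threshold",
    "DOSE_BIN_EDGES",
    "DOSE_BIN_LABELS",
]

#: Copy-number-ratio bin edges; bins are half-open, upper-inclusive:
#: (0, 0.5], (0.5, 0.93], (0.93, 1.07], (1.07, 2], (2, 4], (4, inf).
DOSE_BIN_EDGES = (0.5, 0.93, 1.07, 2.0, 4.0)
DOSE_BIN_LABELS = (
    "high_deletion",
    "low_deletion",
    "no_change",
    "low_amplification",
    "medium_amplification",
    "high_amplification",
)
NO_CHANGE_BIN = "no_change"

HUBER_T = 1.345
IRLS_TOL = 1e-8
IRLS_MAXITER = 50


@dataclass
class AssociationResult:
    """Robust-regression summary for one transcript."""

    transcript_id: str
    beta: float
    intercept: float
    se: float
    t: float
    p: float
    r: float  # plain Pearson correlation, reported alongside the robust slope
    n: int

    @property
    def df(self) -> int:
        return self.n - 2


def robust_regress(y: np.ndarray, x: np.ndarray, transcript_id: str = "") -> AssociationResult:
    """Huber IRLS regression of expression ``y`` on copy number ``x``.

    Iteratively reweighted least squares with Huber psi (tuning constant
    1.345) and MAD-based scale re-estimated each iteration; converged when
    the maximum coefficient change drops below 1e-8 (at most 50 iterations).
    The slope's two-sided p-value uses the t distribution with N-2 df.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    n = y.size
    if x.size != n:
        raise ValueError(f"length mismatch: y has {n}, x has {x.size}")
    if n < 4:
        raise ValueError(f"need at least 4 observations, got {n}")
    if np.ptp(x) == 0:
        raise ValueError("degenerate predictor: copy number is constant across samples")
    X = sm.add_constant(x)
    fit = sm.RLM(y, X, M=HuberT(t=HUBER_T)).fit(
        conv="coefs", tol=IRLS_TOL, maxiter=IRLS_MAXITER, scale_est="mad"
    )
    beta = float(fit.params[1])
    se = float(fit.bse[1])
    t = beta / se
    p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    p = max(p, np.finfo(float).tiny)  # keep p in (0, 1]
    r = float(stats.pearsonr(x, y)[0])
    return AssociationResult(
        transcript_id=transcript_id,
        beta=beta,
        intercept=float(fit.params[0]),
        se=se,
        t=float(t),
        p=p,
        r=r,
        n=int(n),
    )


def associate_all(expr_values: pd.DataFrame, cn_log2: pd.DataFrame) -> pd.DataFrame:
    """Run the robust dosage regression for every shared transcript.

    ``expr_values``: transcripts x samples (normalized log2 expression);
    ``cn_log2``: transcripts x samples log2 copy-number ratios. Transcripts
    with a constant copy-number predictor are reported with NaN statistics
    rather than aborting the scan.
    """
    common = expr_values.index.intersection(cn_log2.index)
    samples = expr_values.columns
    if not samples.equals(cn_log2.columns):
        cn_log2 = cn_log2[samples]
    rows = []
    for tid in common:
        y = expr_values.loc[tid].to_numpy(dtype=float)
        x = cn_log2.loc[tid].to_numpy(dtype=float)
        try:
            res = robust_regress(y, x, transcript_id=tid)
            rows.append((tid, res.beta, res.se, res.t, res.p, res.r, res.n))
        except ValueError:
            rows.append((tid, np.nan, np.nan, np.nan, np.nan, np.nan, len(y)))
    out = pd.DataFrame(rows, columns=["transcript_id", "beta", "se", "t", "p", "r", "n"])
    return out.set_index("transcript_id")


def fdr_select(results: pd.DataFrame, q_threshold: float = 0.01) -> tuple[pd.Index, pd.Series]:
    """Benjamini-Hochberg step-up selection at FDR ``q_threshold``.

    Returns the selected transcript index and the per-transcript q-values.
    Lowering the threshold never adds transcripts (step-up monotonicity).
    """
    if not (0 < q_threshold < 1):
        raise ValueError(f"q threshold must be in (0, 1), got {q_threshold}")
    p = results["p"].dropna()
    reject, qvals, _, _ = multipletests(p.values, alpha=q_threshold, method="fdr_bh")
    q = pd.Series(qvals, index=p.index, name="q")
    return p.index[reject], q


def estimate_signal_proportion(p_values, lam: float = 0.5) -> float:
    """Estimated fraction of non-null transcripts, 1 - pi0.

    pi0 = #{p > lambda} / (M * (1 - lambda)) with lambda = 0.5, the
    upper-tail histogram estimator; the result is clipped to [0, 1].
    """
    p = np.asarray(p_values, dtype=float)
    p = p[~np.isnan(p)]
    if p.size < 100:
        raise ValueError(f"need at least 100 p-values, got {p.size}")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values outside [0, 1]")
    pi0 = np.sum(p > lam) / (p.size * (1.0 - lam))
    return float(np.clip(1.0 - pi0, 0.0, 1.0))


def _bin_ratio(ratio: np.ndarray) -> np.ndarray:
    """Bin index 0..5 for each positive copy-number ratio."""
    return np.searchsorted(np.asarray(DOSE_BIN_EDGES), ratio, side="left")


def dose_response(expr_values: pd.DataFrame, cn_ratio: pd.DataFrame) -> pd.DataFrame:
    """Six-bin summary of expression by copy-number ratio.

    Every (transcript, sample) observation falls in exactly one bin; per bin
    the count, quartiles and mean of log2 expression are reported, plus the
    mean difference relative to the no-change bin.
    """
    common = expr_values.index.intersection(cn_ratio.index)
    e = expr_values.loc[common].to_numpy(dtype=float).ravel()
    c = cn_ratio.loc[common][expr_values.columns].to_numpy(dtype=float).ravel()
    ok = ~np.isnan(c)
    e, c = e[ok], c[ok]
    if np.any(c <= 0):
        raise ValueError("non-positive copy-number ratio")
    bins = _bin_ratio(c)
    rows = []
    for b, label in enumerate(DOSE_BIN_LABELS):
        vals = e[bins == b]
        if vals.size:
            q1, q2, q3 = np.quantile(vals, [0.25, 0.5, 0.75])
            rows.append((label, vals.size, float(vals.mean()), float(q1), float(q2), float(q3)))
        else:
            rows.append((label, 0, np.nan, np.nan, np.nan, np.nan))
    out = pd.DataFrame(rows, columns=["bin", "n", "mean", "q1", "median", "q3"]).set_index("bin")
    ref = out.loc[NO_CHANGE_BIN, "mean"]
    out["mean_vs_no_change"] = out["mean"] - ref
    return out


def log2fc_to_fold(delta_log2: float) -> tuple[float, str]:
    """Fold-change equivalent of a log2 expression difference.

    Returns (fold, direction) with fold = 2**|delta| rounded to one decimal;
    direction is "higher", "lower" or "no change".
    """
    fold = round(2.0 ** abs(float(delta_log2)), 1)
    if delta_log2 > 0:
        direction = "higher"
    elif delta_log2 < 0:
        direction = "lower"
    else:
        direction = "no change"
    return fold, direction


def bonferroni_threshold(n_tests: int, alpha: float = 0.01) -> tuple[float, float]:
    """Bonferroni p cutoff alpha/M and its -log10 value."""
    p_cut = alpha / n_tests
    return p_cut, float(-np.log10(p_cut))


def genome_scan_report(
    results: pd.DataFrame,
    transcripts: pd.DataFrame,
    alpha: float = 0.01,
    cluster_k: int = 5,
) -> dict:
    """Genome-ordered -log10 p values with the Bonferroni line and clusters.

    A clustered region is a maximal run of at least ``cluster_k`` consecutive
    transcripts (genome order within one chromosome) whose p-values fall
    below the Bonferroni cutoff alpha/M.
    """
    coords = transcripts.set_index("transcript_id")[["chrom", "start", "end"]]
    scan = results.join(coords, how="inner").dropna(subset=["p"])
    scan = scan.sort_values(["chrom", "start"], kind="mergesort")
    m = len(scan)
    p_cut, neglog10_cut = bonferroni_threshold(m, alpha)
    scan = scan.assign(neglog10_p=-np.log10(scan["p"]), significant=scan["p"] < p_cut)

    regions = []
    for chrom, grp in scan.groupby("chrom", sort=False):
        sig = grp["significant"].to_numpy()
        i = 0
        while i < len(sig):
            if sig[i]:
                j = i
                while j < len(sig) and sig[j]:
                    j += 1
                if j - i >= cluster_k:
                    block = grp.iloc[i:j]
                    regions.append(
                        {
                            "chrom": chrom,
                            "start": int(block["start"].min()),
                            "end": int(block["end"].max()),
                            "n_transcripts": int(j - i),
                            "transcript_ids": list(block.index),
                        }
                    )
                i = j
            else:
                i += 1
    return {
        "n_tests": m,
        "alpha": alpha,
        "p_cutoff": p_cut,
        "neglog10_cutoff": round(neglog10_cut, 2),
        "scan": scan[["chrom", "start", "end", "p", "neglog10_p", "significant"]],
        "regions": regions,
    }
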