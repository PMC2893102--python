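"""Transcript filtering and median-based renormalization of expression data.

Filtering removes transcripts that (1) lack alignment information or a
unique genomic alignment, (2) map to a sex chromosome or the mitochondrial
genome, (3) never exceed log2 expression 3 in at least 3 samples, or
(4) have an inter-quartile range of expression below 0.1.  Rules are
applied in that order and the removal log attributes each transcript to the
first rule it fails; the retained set is order-independent.

Renormalization brings every sample and then every transcript to median 0
and median-absolute-deviation 1:  Y -> (Y - Ymed) / median(|Y - Ymed|),
applied column-wise (samples) then row-wise (transcripts).  A vector whose
absolute deviations have median 0 is centered only and logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix", "filter_transcripts", "renormalize", "iqr"]

logger = logging.getLogger(__name__)

SEX_CHROMS = {"X", "Y"}
MITO_CHROMS = {"MT", "M"}

RULE_NAMES = {
    1: "no_unique_alignment",
    2: "sex_or_mito_chromosome",
    3: "low_expression",
    4: "low_iqr",
}


@dataclass
class ExpressionMatrix:
    """Log2-scale expression values, transcripts x samples."""

    values: pd.DataFrame
    normalized: bool = False

    @property
    def transcript_ids(self) -> list:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list:
        return list(self.values.columns)


def _norm_chrom(chrom: str) -> str:
    c = str(chrom).strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    return c.upper()


def iqr(values) -> float:
    """Inter-quartile range Q3 - Q1 with linear-interpolation quantiles."""
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        raise ValueError(f"need at least 4 values for an IQR, got {v.size}")
    q1, q3 = np.quantile(v, [0.25, 0.75])
    return float(q3 - q1)


def filter_transcripts(
    expr: ExpressionMatrix,
    annot: pd.DataFrame,
    min_log2: float = 3.0,
    min_samples: int = 3,
    min_iqr: float = 0.1,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Apply the four elimination rules; return the retained matrix and a log.

    ``annot`` needs columns ``transcript_id``, ``chrom`` and
    ``unique_alignment`` (boolean / 0-1).  A transcript absent from the
    annotation counts as lacking alignment information (rule 1).  The log has
    columns (transcript_id, rule, rule_name, detail).
    """
    annot = annot.set_index("transcript_id") if "transcript_id" in annot.columns else annot
    removed = []
    keep_mask = pd.Series(True, index=expr.values.index)
    vals = expr.values

    for tid in vals.index:
        if tid not in annot.index:
            removed.append((tid, 1, RULE_NAMES[1], "missing annotation"))
            keep_mask[tid] = False
            continue
        rec = annot.loc[tid]
        if not bool(rec.get("unique_alignment", True)):
            removed.append((tid, 1, RULE_NAMES[1], "non-unique alignment"))
            keep_mask[tid] = False
            continue
        chrom = _norm_chrom(rec["chrom"])
        if chrom in SEX_CHROMS or chrom in MITO_CHROMS:
            removed.append((tid, 2, RULE_NAMES[2], f"chrom={chrom}"))
            keep_mask[tid] = False
            continue
        row = vals.loc[tid].to_numpy(dtype=float)
        n_expressed = int((row > min_log2).sum())
        if n_expressed < min_samples:
            removed.append(
                (tid, 3, RULE_NAMES[3], f"only {n_expressed} samples > {min_log2}")
            )
            keep_mask[tid] = False
            continue
        r_iqr = iqr(row)
        if r_iqr < min_iqr:
            removed.append((tid, 4, RULE_NAMES[4], f"iqr={r_iqr:.4g}"))
            keep_mask[tid] = False

    log = pd.DataFrame(removed, columns=["transcript_id", "rule", "rule_name", "detail"])
    kept = ExpressionMatrix(values=vals.loc[keep_mask].copy(), normalized=expr.normalized)
    return kept, log


def _median_scale(arr: np.ndarray, axis: int) -> tuple[np.ndarray, np.ndarray]:
    """Center by median and scale by median absolute deviation along ``axis``.

    Vectors with MAD 0 are centered only (scale left at 1); their indices
    along the other axis are returned for logging.
    """
    med = np.median(arr, axis=axis, keepdims=True)
    dev = arr - med
    mad = np.median(np.abs(dev), axis=axis, keepdims=True)
    degenerate = np.flatnonzero(mad.ravel() == 0)
    safe = np.where(mad == 0, 1.0, mad)
    return dev / safe, degenerate


def renormalize(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Median-center and MAD-scale each sample, then each transcript.

    After the column pass every sample has median 0 and MAD 1; the row pass
    then enforces the same per transcript. The column pass is idempotent.
    """
    arr = expr.values.to_numpy(dtype=float)
    arr, degen_cols = _median_scale(arr, axis=0)
    for j in degen_cols:
        logger.warning(
            "sample %r has zero median absolute deviation; centered only",
            expr.values.columns[j],
        )
    arr, degen_rows = _median_scale(arr, axis=1)
    for i in degen_rows:
        logger.warning(
            "transcript %r has zero median absolute deviation; centered only",
            expr.values.index[i],
        )
    out = pd.DataFrame(arr, index=expr.values.index, columns=expr.values.columns)
    return ExpressionMatrix(values=out, normalized=True)
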