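"""Per-transcript copy number inferred from nearby SNPs.

A transcript's copy number is the arithmetic mean of the segmented (denoised)
copy-number ratios of a chosen SNP set, picked by a three-rule precedence:

1. ``overlap5``      — >= 5 SNPs fall inside the transcript interval: use all
   overlapping SNPs;
2. ``closest5``      — otherwise, >= 5 SNPs lie within the neighboring window
   (default 250 kb on either side): use the 5 closest;
3. ``all_in_window`` — otherwise, 1-4 SNPs lie in the window: use all of them;
4. ``unmapped``      — no SNP within the window: no value.

Coordinates are 0-based half-open internally; annotation files are declared
1-based inclusive and converted on read (see :mod:`cnexpress.io`). A SNP
inside the interval has distance 0 and is eligible for rule 2; distances to
outside SNPs are measured to the nearer interval boundary. Ties at the
fifth-closest distance break by (position, snp_id).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .copy_number import CopyNumberProfile

__all__ = [
    "TranscriptCN",
    "infer_transcript_cn",
    "mapping_summary",
    "WINDOW_BP_DEFAULT",
    "MIN_SNPS_DEFAULT",
]

WINDOW_BP_DEFAULT = 250_000
MIN_SNPS_DEFAULT = 5

RULE_OVERLAP = "overlap5"
RULE_CLOSEST = "closest5"
RULE_WINDOW = "all_in_window"
RULE_UNMAPPED = "unmapped"


@dataclass
class TranscriptCN:
    """Per-transcript inferred copy number with mapping provenance.

    ``meta`` holds one row per transcript (transcript_id, rule, n_snps);
    ``values`` holds the inferred copy-number ratio per sample for mapped
    transcripts (unmapped transcripts carry NaN throughout).
    """

    meta: pd.DataFrame
    values: pd.DataFrame
    window_bp: int = WINDOW_BP_DEFAULT

    def mapped(self) -> pd.DataFrame:
        keep = self.meta.loc[self.meta["rule"] != RULE_UNMAPPED, "transcript_id"]
        return self.values.loc[keep]

    def log2_values(self) -> pd.DataFrame:
        """Inferred ratios on the log2 scale (dosage-regression predictor)."""
        return np.log2(self.mapped())


def _snp_distances(pos: np.ndarray, start: int, end: int) -> np.ndarray:
    """Distance from each SNP position to the half-open interval [start, end).

    0 inside the interval, otherwise base pairs to the nearer boundary.
    """
    d = np.zeros(pos.shape, dtype=np.int64)
    left = pos < start
    right = pos >= end
    d[left] = start - pos[left]
    d[right] = pos[right] - (end - 1)
    return d


def infer_transcript_cn(
    transcripts: pd.DataFrame,
    profile: CopyNumberProfile,
    window_bp: int = WINDOW_BP_DEFAULT,
    min_snps: int = MIN_SNPS_DEFAULT,
) -> TranscriptCN:
    """Apply the three-rule precedence to every transcript.

    Parameters
    ----------
    transcripts : DataFrame with columns ``transcript_id``, ``chrom``,
        ``start``, ``end`` (0-based half-open).
    profile : segmented copy-number profile; values averaged are the
        segmented ratios (2**segmented log2), not the raw observations.
    window_bp : neighboring-region half-width in bp (default 250,000).
    min_snps : minimum SNP count that triggers rules 1-2 (default 5).

    A transcript on a chromosome with no SNPs is ``unmapped``, not an error.
    """
    if profile.segmented is None:
        raise ValueError("profile must be segmented before transcript mapping")
    bad = transcripts["start"] >= transcripts["end"]
    if bad.any():
        tid = transcripts.loc[bad, "transcript_id"].iloc[0]
        raise ValueError(f"malformed interval (start >= end) for transcript {tid!r}")

    seg_ratio = profile.segmented_ratio().values
    snp_ids = profile.snps["snp_id"].values
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in pd.unique(profile.snps["chrom"].values):
        idx = np.flatnonzero(profile.snps["chrom"].values == chrom)
        by_chrom[chrom] = (profile.snps["pos"].values[idx].astype(np.int64), idx)

    n_samples = seg_ratio.shape[1]
    meta_rows = []
    values = np.full((len(transcripts), n_samples), np.nan)

    for i, row in enumerate(transcripts.itertuples(index=False)):
        chrom, start, end = row.chrom, int(row.start), int(row.end)
        if chrom not in by_chrom:
            meta_rows.append((row.transcript_id, RULE_UNMAPPED, 0))
            continue
        pos, idx = by_chrom[chrom]
        dist = _snp_distances(pos, start, end)
        overlap = np.flatnonzero(dist == 0)
        in_window = np.flatnonzero(dist <= window_bp)
        if overlap.size >= min_snps:
            chosen, rule = overlap, RULE_OVERLAP
        elif in_window.size >= min_snps:
            order = np.lexsort((snp_ids[idx[in_window]], pos[in_window], dist[in_window]))
            chosen, rule = in_window[order[:min_snps]], RULE_CLOSEST
        elif in_window.size >= 1:
            chosen, rule = in_window, RULE_WINDOW
        else:
            meta_rows.append((row.transcript_id, RULE_UNMAPPED, 0))
            continue
        values[i] = seg_ratio[idx[chosen]].mean(axis=0)
        meta_rows.append((row.transcript_id, rule, int(chosen.size)))

    meta = pd.DataFrame(meta_rows, columns=["transcript_id", "rule", "n_snps"])
    vals = pd.DataFrame(
        values, index=meta["transcript_id"].values, columns=profile.log2_ratios.columns
    )
    vals.index.name = "transcript_id"
    return TranscriptCN(meta=meta, values=vals, window_bp=window_bp)


def mapping_summary(table: TranscriptCN) -> dict:
    """Counts per rule and the percentage of mapped transcripts with >= 5 SNPs.

    The percentage denominator is the mapped transcripts only (rules 1-3);
    reported to one decimal. An all-unmapped table is flagged rather than
    dividing by zero.
    """
    counts = table.meta["rule"].value_counts().to_dict()
    out = {
        "n_transcripts": int(len(table.meta)),
        "counts": {
            rule: int(counts.get(rule, 0))
            for rule in (RULE_OVERLAP, RULE_CLOSEST, RULE_WINDOW, RULE_UNMAPPED)
        },
    }
    n_mapped = out["n_transcripts"] - out["counts"][RULE_UNMAPPED]
    out["n_mapped"] = n_mapped
    if n_mapped == 0:
        out["pct_at_least_min_snps"] = None
        out["empty"] = True
        return out
    n_ge5 = out["counts"][RULE_OVERLAP] + out["counts"][RULE_CLOSEST]
    out["pct_at_least_min_snps"] = round(100.0 * n_ge5 / n_mapped, 1)
    return out
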