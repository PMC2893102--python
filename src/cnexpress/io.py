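"""Readers and writers for the plain-text exchange formats.

All tables are delimited text: TSV for annotations and matrices, CSV for the
clinical table, JSON for truth/report bundles. Genomic annotation files are
declared 1-based inclusive (the convention of array annotation files) and
converted to the package's internal 0-based half-open coordinates on read.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

CLINICAL_COLUMNS = [
    "sample_id",
    "case",
    "age",
    "sex",
    "stage",
    "followup_months",
    "dead",
    "oscc_death",
]


def write_snp_annotation(snps: pd.DataFrame, path) -> None:
    """snp_id, chrom, pos — positions written 1-based."""
    out = snps[["snp_id", "chrom", "pos"]].copy()
    out["pos"] = out["pos"].astype(int) + 1
    out.to_csv(path, sep="\t", index=False)


def read_snp_annotation(path) -> pd.DataFrame:
    snps = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "chrom": str})
    snps["pos"] = snps["pos"].astype(int) - 1
    return snps.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def write_transcript_annotation(transcripts: pd.DataFrame, path) -> None:
    """transcript_id, chrom, start, end, unique_alignment — 1-based inclusive."""
    out = transcripts[["transcript_id", "chrom", "start", "end", "unique_alignment"]].copy()
    out["start"] = out["start"].astype(int) + 1
    out["unique_alignment"] = out["unique_alignment"].astype(int)
    out.to_csv(path, sep="\t", index=False)


def read_transcript_annotation(path) -> pd.DataFrame:
    tr = pd.read_csv(path, sep="\t", dtype={"transcript_id": str, "chrom": str})
    tr["start"] = tr["start"].astype(int) - 1
    tr["unique_alignment"] = tr["unique_alignment"].astype(bool)
    return tr


def write_matrix_tsv(matrix: pd.DataFrame, path, index_label: str) -> None:
    matrix.to_csv(path, sep="\t", index_label=index_label)


def read_matrix_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_clinical_csv(clinical: pd.DataFrame, path) -> None:
    out = clinical.reset_index() if clinical.index.name == "sample_id" else clinical.copy()
    out[CLINICAL_COLUMNS].to_csv(path, index=False)


def read_clinical_csv(path) -> pd.DataFrame:
    clin = pd.read_csv(path, dtype={"sample_id": str})
    return clin.set_index("sample_id")


class _NumpyJSONEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.bool_,)):
            return bool(obj)
        return super().default(obj)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, cls=_NumpyJSONEncoder) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
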