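"""End-to-end orchestration: segment -> map -> prep -> associate -> screen ->
survival, from delimited-text inputs to a JSON report.

Every stage writes its intermediate table so that any stage can be re-run
from the persisted artifacts; the report collects the headline numbers
(mapping counts, filter survivors, FDR selections, signal proportion,
Bonferroni cutoff, dose-response bin means with fold-change equivalents,
enrichment p-values, Cox hazard-ratio tables, landmark AUCs and their
comparison p-values).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cnio
from .association import (
    associate_all,
    bonferroni_threshold,
    dose_response,
    estimate_signal_proportion,
    fdr_select,
    genome_scan_report,
    log2fc_to_fold,
)
from .copy_number import (
    THRESHOLDS_DEFAULT,
    CopyNumberProfile,
    call_cna,
    genome_altered_fraction,
    segment_fused_lasso,
)
from .enrichment import (
    MIN_FOLLOWUP_DEFAULT,
    SURVIVAL_Z_CUTOFF_DEFAULT,
    Z_CUTOFF_DEFAULT,
    casecontrol_screen,
    permutation_enrichment,
    survival_screen,
)
from .expression_prep import ExpressionMatrix, filter_transcripts, renormalize
from .survival_model import (
    LANDMARK_MONTHS_DEFAULT,
    compare_auc,
    fit_cox,
    jackknife_risk_scores,
    pc_scores,
    time_dependent_roc,
)
from .transcript_mapping import infer_transcript_cn, mapping_summary

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "validate_inputs"]


@dataclass
class PipelineConfig:
    """All inputs and thresholds of the analysis, serializable to JSON."""

    # inputs
    snp_annotation: str = ""
    transcript_annotation: str = ""
    copy_number_ratios: str = ""
    expression: str = ""
    testing_expression: str = ""
    clinical: str = ""
    out_dir: str = "cnexpress_out"
    # copy number
    cna_lower: float = THRESHOLDS_DEFAULT[0]
    cna_upper: float = THRESHOLDS_DEFAULT[1]
    lambda_sparsity: float = 0.0
    lambda_fusion: float | None = None
    # mapping
    window_bp: int = 250_000
    min_snps: int = 5
    # expression filtering
    min_log2: float = 3.0
    min_samples: int = 3
    min_iqr: float = 0.1
    # association
    fdr_q: float = 0.01
    bonferroni_alpha: float = 0.01
    cluster_k: int = 5
    # screening
    z_cutoff: float = Z_CUTOFF_DEFAULT
    survival_z_cutoff: float = SURVIVAL_Z_CUTOFF_DEFAULT
    min_followup: float = MIN_FOLLOWUP_DEFAULT
    n_permutations: int = 1000
    exclude_samples: list = field(default_factory=list)
    # survival modelling
    landmark_months: float = LANDMARK_MONTHS_DEFAULT
    n_bootstrap: int = 2000
    seed: int = 0

    def to_json(self, path) -> None:
        cnio.write_json(dataclasses.asdict(self), path)

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        return cls(**cnio.read_json(path))

    def validate(self) -> None:
        if not (0 < self.cna_lower < 1 < self.cna_upper):
            raise ValueError("CNA thresholds must satisfy 0 < lower < 1 < upper")
        if not (0 < self.fdr_q < 1) or not (0 < self.bonferroni_alpha < 1):
            raise ValueError("FDR q and Bonferroni alpha must lie in (0, 1)")
        if self.window_bp <= 0 or self.min_snps < 1:
            raise ValueError("mapping parameters out of domain")
        if self.min_followup < 0 or self.landmark_months <= 0:
            raise ValueError("follow-up/landmark parameters out of domain")


def _file_hash(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def validate_inputs(
    snp_annotation=None,
    transcript_annotation=None,
    copy_number_ratios=None,
    expression=None,
    clinical=None,
) -> list[dict]:
    """Schema and sanity diagnostics for the input files; read-only.

    Returns a list of diagnostics ({file, kind, detail}); empty means clean.
    """
    diags: list[dict] = []

    def add(file, kind, detail):
        diags.append({"file": str(file), "kind": kind, "detail": detail})

    if snp_annotation is not None:
        try:
            snps = cnio.read_snp_annotation(snp_annotation)
            dup = snps["snp_id"][snps["snp_id"].duplicated()]
            if len(dup):
                add(snp_annotation, "duplicate_id", f"snp_id {dup.iloc[0]!r}")
            if (snps["pos"] < 0).any():
                add(snp_annotation, "coordinate", "negative SNP position")
        except Exception as exc:
            add(snp_annotation, "unreadable", str(exc))
    if transcript_annotation is not None:
        try:
            tr = cnio.read_transcript_annotation(transcript_annotation)
            dup = tr["transcript_id"][tr["transcript_id"].duplicated()]
            if len(dup):
                add(transcript_annotation, "duplicate_id", f"transcript_id {dup.iloc[0]!r}")
            bad = tr[tr["start"] >= tr["end"]]
            if len(bad):
                add(
                    transcript_annotation,
                    "coordinate",
                    f"start >= end for {bad['transcript_id'].iloc[0]!r}",
                )
        except Exception as exc:
            add(transcript_annotation, "unreadable", str(exc))
    if copy_number_ratios is not None:
        try:
            cn = cnio.read_matrix_tsv(copy_number_ratios)
            if (cn.values <= 0).any():
                add(copy_number_ratios, "domain", "non-positive copy-number ratio")
        except Exception as exc:
            add(copy_number_ratios, "unreadable", str(exc))
    if expression is not None:
        try:
            expr = cnio.read_matrix_tsv(expression)
            if expr.isna().any().any():
                add(expression, "missing", "NaN expression values")
        except Exception as exc:
            add(expression, "unreadable", str(exc))
    if clinical is not None:
        try:
            clin = cnio.read_clinical_csv(clinical)
            for col in ("case", "age", "sex", "stage", "followup_months", "dead", "oscc_death"):
                if col not in clin.columns:
                    add(clinical, "schema", f"missing column {col!r}")
            if "sex" in clin.columns and not clin["sex"].isin([0, 1]).all():
                add(clinical, "domain", "sex outside {0, 1} coding")
            if "stage" in clin.columns:
                cases = clin[clin.get("case", 1) == 1]
                if not cases["stage"].isin([1, 2, 3, 4]).all():
                    add(clinical, "domain", "case stage outside 1-4")
        except Exception as exc:
            add(clinical, "unreadable", str(exc))
    return diags


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the report dict (also written to
    ``out_dir/report.json`` together with every intermediate table)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": dataclasses.asdict(config), "input_hashes": {}}
    for key in ("snp_annotation", "transcript_annotation", "copy_number_ratios", "expression"):
        path = getattr(config, key)
        if path:
            report["input_hashes"][key] = _file_hash(path)

    # --- load & consistency ------------------------------------------------
    snps = cnio.read_snp_annotation(config.snp_annotation)
    transcripts = cnio.read_transcript_annotation(config.transcript_annotation)
    ratios = cnio.read_matrix_tsv(config.copy_number_ratios)
    expr_raw = cnio.read_matrix_tsv(config.expression)
    ratios = ratios.reindex(snps["snp_id"].values)
    if ratios.isna().any().any():
        missing = ratios.index[ratios.isna().any(axis=1)][:5].tolist()
        raise ValueError(f"SNPs in annotation missing from ratio matrix: {missing}")
    shared_samples = ratios.columns.intersection(expr_raw.columns)
    if len(shared_samples) == 0:
        raise ValueError(
            "no samples shared between copy-number and expression matrices; "
            f"copy-number has {list(ratios.columns[:3])}..., expression "
            f"{list(expr_raw.columns[:3])}..."
        )
    stray = transcripts["transcript_id"][~transcripts["transcript_id"].isin(expr_raw.index)]
    if len(stray) == len(transcripts):
        raise ValueError("transcript annotation and expression matrix share no identifiers")

    # --- copy number -------------------------------------------------------
    from .copy_number import to_log2_ratio

    profile = CopyNumberProfile(snps=snps, log2_ratios=to_log2_ratio(ratios[shared_samples]))
    profile = segment_fused_lasso(profile, config.lambda_sparsity, config.lambda_fusion)
    cnio.write_matrix_tsv(profile.segmented, out / "segmented_log2.tsv", "snp_id")
    calls = call_cna(profile, config.cna_lower, config.cna_upper)
    calls.calls.stack().rename("call").rename_axis(["snp_id", "sample"]).reset_index().to_csv(
        out / "cna_calls.tsv", sep="\t", index=False
    )
    gaf = genome_altered_fraction(calls)
    report["genome_altered_fraction"] = {
        "per_sample": gaf.round(4).to_dict(),
        "min": float(gaf.min()),
        "max": float(gaf.max()),
        "mean": float(gaf.mean()),
    }

    # --- transcript mapping ------------------------------------------------
    tcn = infer_transcript_cn(transcripts, profile, config.window_bp, config.min_snps)
    tcn_out = tcn.meta.set_index("transcript_id").join(tcn.values)
    cnio.write_matrix_tsv(tcn_out, out / "transcript_cn.tsv", "transcript_id")
    report["mapping"] = mapping_summary(tcn)

    # --- expression prep ---------------------------------------------------
    expr = ExpressionMatrix(values=expr_raw[shared_samples])
    filtered, removal_log = filter_transcripts(
        expr, transcripts, config.min_log2, config.min_samples, config.min_iqr
    )
    removal_log.to_csv(out / "filter_removals.tsv", sep="\t", index=False)
    normalized = renormalize(filtered)
    cnio.write_matrix_tsv(normalized.values, out / "expression_normalized.tsv", "transcript_id")
    report["filtering"] = {
        "n_input": int(len(expr.values)),
        "n_retained": int(len(filtered.values)),
        "pct_retained": round(100.0 * len(filtered.values) / len(expr.values), 1),
        "removed_by_rule": removal_log["rule"].value_counts().to_dict(),
    }

    # --- association -------------------------------------------------------
    cn_log2 = tcn.log2_values()
    analysis_ids = normalized.values.index.intersection(cn_log2.index)
    results = associate_all(normalized.values.loc[analysis_ids], cn_log2.loc[analysis_ids])
    selected, qvals = fdr_select(results, config.fdr_q)
    results = results.join(qvals)
    cnio.write_matrix_tsv(results, out / "association.tsv", "transcript_id")
    signal_prop = estimate_signal_proportion(results["p"].dropna())
    scan = genome_scan_report(results, transcripts, config.bonferroni_alpha, config.cluster_k)
    cnio.write_matrix_tsv(scan["scan"], out / "genome_scan.tsv", "transcript_id")
    dr = dose_response(normalized.values.loc[analysis_ids], tcn.mapped().loc[analysis_ids])
    report["association"] = {
        "n_tested": int(results["p"].notna().sum()),
        "n_fdr_selected": int(len(selected)),
        "fdr_q": config.fdr_q,
        "signal_proportion": round(signal_prop, 3),
        "bonferroni_neglog10_cutoff": scan["neglog10_cutoff"],
        "bonferroni_p_cutoff": scan["p_cutoff"],
        "n_clustered_regions": len(scan["regions"]),
        "dose_response": {
            bin_label: {
                "n": int(row["n"]),
                "mean": None if np.isnan(row["mean"]) else round(float(row["mean"]), 3),
                "mean_vs_no_change": (
                    None
                    if np.isnan(row["mean_vs_no_change"])
                    else round(float(row["mean_vs_no_change"]), 3)
                ),
                "fold_change": (
                    None
                    if np.isnan(row["mean_vs_no_change"])
                    else list(log2fc_to_fold(row["mean_vs_no_change"]))
                ),
            }
            for bin_label, row in dr.iterrows()
        },
    }
    pd.Series(sorted(selected)).to_csv(
        out / "fdr_selected_transcripts.txt", index=False, header=False
    )

    # --- independent-cohort screening & survival --------------------------
    if config.testing_expression and config.clinical:
        test_expr = cnio.read_matrix_tsv(config.testing_expression)
        clinical = cnio.read_clinical_csv(config.clinical)
        if config.exclude_samples:
            clinical = clinical.drop(index=config.exclude_samples, errors="ignore")
            test_expr = test_expr.drop(columns=config.exclude_samples, errors="ignore")
        shared = clinical.index.intersection(test_expr.columns)
        clinical = clinical.loc[shared]
        test_expr = test_expr[shared]

        cc = casecontrol_screen(test_expr, clinical["case"], config.z_cutoff)
        cases = clinical[clinical["case"] == 1]
        surv = survival_screen(
            test_expr[cases.index], cases, config.min_followup, config.survival_z_cutoff
        )
        screen = cc.join(surv)
        cnio.write_matrix_tsv(screen, out / "screen.tsv", "transcript_id")

        candidate = [t for t in selected if t in screen.index]
        rng = np.random.default_rng(config.seed)
        enr = {}
        for name, z_col, cut in (
            ("casecontrol", "cc_z", config.z_cutoff),
            ("survival", "surv_z", config.survival_z_cutoff),
        ):
            enr[name] = {}
            for stat in ("exceed_count", "mean_abs_z", "ks"):
                test = permutation_enrichment(
                    candidate,
                    screen[z_col],
                    B=config.n_permutations,
                    statistic=stat,
                    z_cutoff=cut,
                    seed=int(rng.integers(2**31)),
                )
                enr[name][stat] = {
                    "observed": round(test.observed, 4),
                    "p": round(test.empirical_p, 6),
                }
        oscc_set = [t for t in candidate if bool(screen.loc[t, "oscc_associated"])]
        surv_set = [t for t in candidate if bool(screen.loc[t, "survival_associated"])]
        report["screening"] = {
            "n_candidates": len(candidate),
            "n_oscc_associated": len(oscc_set),
            "n_survival_associated": len(surv_set),
            "n_survival_subjects": surv.attrs.get("n_subjects"),
            "n_survival_events": surv.attrs.get("n_events"),
            "enrichment": enr,
        }

        # --- PC risk scores & landmark ROC --------------------------------
        surv_cohort = cases.loc[
            (cases["followup_months"] >= config.min_followup) | (cases["oscc_death"] == 1)
        ].copy()
        report["survival_models"] = {}
        model_scores: dict[str, pd.Series] = {}
        cox_df = surv_cohort[["followup_months", "oscc_death", "stage"]].astype(float)
        try:
            stage_fit = fit_cox(cox_df, ["stage"])
            report["survival_models"]["stage"] = {
                "hr_table": json.loads(stage_fit.table().to_json(orient="index"))
            }
            model_scores["stage"] = jackknife_risk_scores(cox_df, ["stage"])
        except ValueError as exc:
            report["survival_models"]["stage"] = {"error": str(exc)}

        for set_name, tr_set in (("oscc_set", oscc_set), ("survival_set", surv_set)):
            if len(tr_set) < 2:
                report["survival_models"][set_name] = {
                    "error": f"transcript set too small (n={len(tr_set)}) for 2 PCs"
                }
                continue
            pcs = pc_scores(test_expr[surv_cohort.index], tr_set, n_components=2)
            df = cox_df.join(pcs.scores)
            for model_name, covs in (
                (f"pc_{set_name}", ["PC1", "PC2"]),
                (f"stage+pc_{set_name}", ["stage", "PC1", "PC2"]),
            ):
                try:
                    fitted = fit_cox(df, covs)
                    model_scores[model_name] = jackknife_risk_scores(df, covs)
                    report["survival_models"][model_name] = {
                        "hr_table": json.loads(fitted.table().to_json(orient="index")),
                        "variance_explained": [round(float(v), 4) for v in pcs.variance_explained],
                    }
                except (ValueError, RuntimeError) as exc:
                    report["survival_models"][model_name] = {"error": str(exc)}

        times = surv_cohort["followup_months"].to_numpy(float)
        events = surv_cohort["oscc_death"].to_numpy(int)
        aucs = {}
        score_table = pd.DataFrame(index=surv_cohort.index)
        for name, sc in model_scores.items():
            sc = sc.reindex(surv_cohort.index)
            score_table[name] = sc
            try:
                curve, auc = time_dependent_roc(
                    sc.to_numpy(float), times, events, config.landmark_months
                )
                aucs[name] = round(auc, 3)
                curve.to_csv(out / f"roc_{name.replace('+', '_')}.tsv", sep="\t", index=False)
            except ValueError as exc:
                aucs[name] = None
                logger.warning("ROC for model %s failed: %s", name, exc)
        cnio.write_matrix_tsv(score_table, out / "risk_scores.tsv", "sample_id")
        comparisons = {}
        if "stage" in model_scores:
            for other in model_scores:
                if other.startswith("stage+pc") and aucs.get(other) is not None:
                    cmp = compare_auc(
                        model_scores[other].reindex(surv_cohort.index).to_numpy(float),
                        model_scores["stage"].reindex(surv_cohort.index).to_numpy(float),
                        times,
                        events,
                        config.landmark_months,
                        B_boot=config.n_bootstrap,
                        seed=int(np.random.default_rng(config.seed + 1).integers(2**31)),
                    )
                    comparisons[f"{other}_vs_stage"] = {
                        "auc_difference": round(cmp["difference"], 4),
                        "p_value": round(cmp["p_value"], 4),
                    }
        report["roc"] = {"landmark_months": config.landmark_months, "auc": aucs,
                         "comparisons": comparisons}

    cnio.write_json(report, out / "report.json")
    return report
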