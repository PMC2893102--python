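# cnexpress

Integrative analysis of DNA copy-number aberrations (CNA) and gene
expression in tumor cohorts, with downstream prioritization of
copy-number-associated transcripts by case/control status and survival.

The package is aimed at analysts working with paired tumor profiling data —
a per-SNP copy-number ratio matrix (tumor vs. diploid normal), a transcript
expression matrix on the same samples, and an independent case/control
cohort with follow-up — who want a reproducible, tested implementation of
the classic dosage-effect analysis chain:

1. **Segmentation.** Per-SNP log2 ratios are denoised per chromosome and
   sample by the fused lasso,
   `argmin_b ½Σ(yᵢ−bᵢ)² + λ₁Σ|bᵢ| + λ₂Σ|bᵢ−bᵢ₋₁|`,
   solved exactly (total-variation denoising by the taut-string algorithm,
   then soft-thresholding). Gains and losses are called on the fitted ratio
   scale (defaults 0.93/1.07; stringent preset 0.7/1.4).
2. **Transcript copy number.** Each transcript inherits the mean segmented
   ratio of (i) all SNPs inside it when ≥ 5 overlap, else (ii) the 5
   closest SNPs within 250 kb, else (iii) all 1–4 SNPs in that window;
   otherwise it is unmapped.
3. **Expression preparation.** Four elimination rules (no unique alignment;
   sex/mitochondrial chromosome; never above log2 = 3 in ≥ 3 samples;
   inter-quartile range < 0.1), then median-centering / MAD-scaling of each
   sample and each transcript.
4. **Dosage association.** Per-transcript robust regression (Huber IRLS,
   c = 1.345) of expression on log2 copy number; two-sided p on N−2 df;
   Benjamini–Hochberg selection at FDR < 1%; signal proportion 1−π̂₀ from
   the p-value histogram; six-bin dose–response summary (ratio < 0.5 up to
   ratio > 4) and a genome scan with the Bonferroni line.
5. **Independent-cohort screening.** Case/control Z-scores (|Z| > 6 flag)
   and age/sex-adjusted Cox Z-scores per transcript; permutation enrichment
   of the FDR-selected set against 1000 random same-size sets.
6. **Risk scores vs. stage.** First two principal components of a flagged
   transcript set feed Cox models ({stage}, {PC1,PC2}, {stage,PC1,PC2});
   per-subject risk scores come from jackknife leave-one-out fits; models
   are compared by the Kaplan–Meier (cumulative/dynamic) time-dependent ROC
   at 24 months with a paired-bootstrap AUC test.

A seeded synthetic-data module generates all inputs with known ground truth
(segmental CNAs, a configurable dosage-responsive fraction, case/control
shifts, proportional-hazards survival), so every stage is covered by
parameter-recovery tests.

## Worked example

Generate a synthetic cohort and run the full pipeline:

```sh
cnexpress simulate --n-chrom 3 --n-snps 1500 --n-transcripts 500 \
    --n-samples 20 --n-cases 120 --n-controls 40 --seed 11 --out-dir synth
python - <<'EOF'
from cnexpress.pipeline import PipelineConfig, run_pipeline
cfg = PipelineConfig(
    snp_annotation="synth/snp_annotation.tsv",
    transcript_annotation="synth/transcript_annotation.tsv",
    copy_number_ratios="synth/copy_number_ratios.tsv",
    expression="synth/expression.tsv",
    testing_expression="synth/testing_expression.tsv",
    clinical="synth/clinical.csv",
    out_dir="synth_out", n_permutations=200, n_bootstrap=200, seed=5)
report = run_pipeline(cfg)
print(report["association"]["n_fdr_selected"],
      report["association"]["signal_proportion"],
      report["roc"]["auc"])
EOF
```

which prints (for this seed):

```
149 0.294 {'stage': 0.465, 'pc_survival_set': 0.866, 'stage+pc_survival_set': 0.869}
```

meaning 149 transcripts passed FDR < 1% for a copy-number–expression
association, the p-value histogram estimates that 29.4% of transcripts are
dosage-responsive (the fixture plants 30%), and the 2-year survival AUC
rises from 0.47 for AJCC stage alone to 0.87 when the PC risk score of the
survival-associated transcript set is added. Every
intermediate table (segmented profiles, calls, transcript copy number,
association statistics, screen Z-scores, risk scores, ROC points) is
written to the output directory alongside `report.json`.

The same stages are available individually as CLI subcommands
(`segment`, `map-cn`, `prep-expr`, `associate`, `screen`, `survival`,
`run`, `validate`).

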