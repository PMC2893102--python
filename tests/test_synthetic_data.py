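"""Generator contracts: determinism, zero-noise limits, truth recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cnexpress import synthetic_data as syn


def p_from_fast_regression(expr, x_log2):
    """Vectorized per-transcript least-squares p-values (test-side helper)."""
    y = expr.to_numpy(float)
    out = np.empty(y.shape[0])
    for i in range(y.shape[0]):
        x = x_log2[i]
        if np.ptp(x) == 0:
            out[i] = np.nan
            continue
        n = x.size
        r = stats.pearsonr(x, y[i])[0]
        t = r * np.sqrt((n - 2) / max(1 - r * r, 1e-300))
        out[i] = 2 * stats.t.sf(abs(t), df=n - 2)
    return out


class TestLayout:
    def test_shape_contract(self):
        layout = syn.simulate_layout(1, 100, 10, seed=7)
        assert len(layout.transcripts) == 10
        assert len(layout.snps) == 100
        pos = layout.snps["pos"].to_numpy()
        assert np.all(np.diff(pos) > 0)  # single chromosome, strictly increasing

    def test_seeded_determinism(self):
        a = syn.simulate_layout(2, 150, 20, seed=3)
        b = syn.simulate_layout(2, 150, 20, seed=3)
        pd.testing.assert_frame_equal(a.snps, b.snps)
        pd.testing.assert_frame_equal(a.transcripts, b.transcripts)
        c = syn.simulate_layout(2, 150, 20, seed=4)
        assert not c.snps.equals(a.snps)

    def test_all_mapping_regimes_present(self):
        """Exhaustive distance scan: some transcript overlaps >=5 SNPs, some
        sees 1-4 in the window, and some sees no SNP within 250 kb."""
        layout = syn.simulate_layout(2, 300, 40, seed=11)
        n_overlap = n_window = n_none = 0
        for tr in layout.transcripts.itertuples(index=False):
            snps = layout.snps[layout.snps["chrom"] == tr.chrom]
            pos = snps["pos"].to_numpy()
            inside = (pos >= tr.start) & (pos < tr.end)
            d = np.where(inside, 0, np.where(pos < tr.start, tr.start - pos,
                                             pos - (tr.end - 1)))
            if inside.sum() >= 5:
                n_overlap += 1
            elif 1 <= (d <= 250_000).sum() <= 4:
                n_window += 1
            elif (d <= 250_000).sum() == 0:
                n_none += 1
        assert n_overlap >= 1 and n_window >= 1 and n_none >= 1

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            syn.simulate_layout(0, 100, 10, seed=1)
        with pytest.raises(ValueError):
            syn.simulate_layout(1, 100, 0, seed=1)


class TestCopyNumber:
    def test_zero_noise_reproduces_truth(self):
        layout = syn.simulate_layout(2, 200, 20, seed=5)
        profile, truth = syn.simulate_copy_number(layout, 6, noise_sd=0.0, seed=6)
        observed = 2.0 ** profile.log2_ratios
        assert np.allclose(observed.to_numpy(), truth.snp_ratio_truth.to_numpy())

    def test_seeded_determinism(self):
        layout = syn.simulate_layout(2, 200, 20, seed=5)
        a, _ = syn.simulate_copy_number(layout, 4, seed=9)
        b, _ = syn.simulate_copy_number(layout, 4, seed=9)
        pd.testing.assert_frame_equal(a.log2_ratios, b.log2_ratios)

    def test_neutral_levels_give_zero_altered_fraction(self):
        layout = syn.simulate_layout(1, 100, 10, seed=5)
        _, truth = syn.simulate_copy_number(
            layout, 3, seed=1, levels=(1.0,), level_probs=(1.0,)
        )
        for s in truth.snp_ratio_truth.columns:
            assert truth.altered_fraction(s) == 0.0

    def test_breakpoint_count_scales_with_rate(self):
        """Doubling the segment rate doubles the expected breakpoint count."""
        layout = syn.simulate_layout(1, 50, 5, seed=2)
        counts = {}
        for rate in (0.1, 0.2):
            n_segments = [
                sum(len(segs) for segs in truth.segment_truth.values())
                for truth in (
                    syn.simulate_copy_number(layout, 1, segment_rate=rate, seed=s)[1]
                    for s in range(120)
                )
            ]
            counts[rate] = np.mean(n_segments) - 1  # segments = breakpoints + 1
        assert counts[0.2] / counts[0.1] == pytest.approx(2.0, rel=0.15)

    def test_empty_layout_rejected(self):
        layout = syn.simulate_layout(1, 100, 10, seed=5)
        layout.snps = layout.snps.iloc[:0]
        with pytest.raises(ValueError, match="no SNPs"):
            syn.simulate_copy_number(layout, 3, seed=0)


@pytest.fixture(scope="module")
def mapped():
    from cnexpress.copy_number import segment_fused_lasso
    from cnexpress.transcript_mapping import infer_transcript_cn

    layout = syn.simulate_layout(2, 300, 50, seed=21)
    profile, truth = syn.simulate_copy_number(layout, 10, noise_sd=0.05, seed=22)
    tcn = infer_transcript_cn(layout.transcripts, segment_fused_lasso(profile))
    return layout, truth, tcn


class TestExpression:

    def test_zero_dosage_fraction_all_null(self, mapped):
        layout, truth, tcn = mapped
        syn.simulate_expression(layout, truth, tcn, dosage_fraction=0.0, seed=1)
        assert (truth.dosage_truth["beta"] == 0).all()
        assert not truth.dosage_truth["responsive"].any()

    def test_zero_noise_tracks_log2_ratio(self, mapped):
        layout, truth, tcn = mapped
        expr = syn.simulate_expression(
            layout, truth, tcn, dosage_fraction=1.0, beta_mean=1.0, noise_sd=0.0, seed=2
        )
        for tid in truth.dosage_truth.index[truth.dosage_truth["responsive"]][:10]:
            y = expr.values.loc[tid].to_numpy()
            x = np.log2(tcn.values.loc[tid].to_numpy(float))
            assert np.allclose(y - y.mean(), x - x.mean(), atol=1e-10)

    def test_mismatched_transcripts_rejected(self, mapped):
        layout, truth, tcn = mapped
        import dataclasses

        bad = dataclasses.replace(tcn, meta=tcn.meta.iloc[:-2], values=tcn.values.iloc[:-2])
        with pytest.raises(ValueError, match="differ"):
            syn.simulate_expression(layout, truth, bad, 0.3, 1.0, 0.3, seed=3)

    def test_signal_proportion_recovered_over_replicates(self):
        """Planted dosage fraction 0.3 recovered within +/-0.1 (50 replicates).

        Uses the true per-transcript copy number as the regressor so the
        check isolates the generator's signal structure.
        """
        layout = syn.simulate_layout(2, 300, 150, seed=30)
        from cnexpress.association import estimate_signal_proportion
        from cnexpress.copy_number import segment_fused_lasso
        from cnexpress.transcript_mapping import infer_transcript_cn

        profile, truth0 = syn.simulate_copy_number(layout, 20, noise_sd=0.05, seed=31)
        tcn = infer_transcript_cn(layout.transcripts, segment_fused_lasso(profile))
        estimates = []
        for rep in range(50):
            expr = syn.simulate_expression(
                layout, truth0, tcn, dosage_fraction=0.3, beta_mean=1.0,
                noise_sd=0.3, seed=100 + rep,
            )
            mapped_ids = tcn.mapped().index
            x = np.log2(tcn.values.loc[mapped_ids].to_numpy(float))
            ps = p_from_fast_regression(expr.values.loc[mapped_ids], x)
            estimates.append(estimate_signal_proportion(ps[~np.isnan(ps)]))
        assert np.mean(estimates) == pytest.approx(0.3, abs=0.1)


class TestClinical:
    def test_null_hazard_gives_standard_normal_z(self):
        """hr_per_unit=1: designated transcripts carry no survival signal."""
        from cnexpress.enrichment import survival_screen

        ids = [f"t{i}" for i in range(60)]
        clin, expr = syn.simulate_clinical(120, 30, ids, ids[:5], hr_per_unit=1.0,
                                           seed=12)
        cases = clin[clin["case"] == 1]
        out = survival_screen(expr.values.loc[:, cases.index], cases)
        z = out["surv_z"].dropna()
        assert stats.kstest(z, "norm").pvalue > 0.01

    def test_no_censoring_means_all_events(self):
        ids = [f"t{i}" for i in range(10)]
        clin, _ = syn.simulate_clinical(50, 10, ids, ids[:2], censor_rate=0.0, seed=13)
        cases = clin[clin["case"] == 1]
        assert (cases["dead"] == 1).all()

    def test_controls_have_no_followup(self):
        ids = [f"t{i}" for i in range(10)]
        clin, _ = syn.simulate_clinical(20, 15, ids, ids[:2], seed=14)
        ctrl = clin[clin["case"] == 0]
        assert ctrl["followup_months"].isna().all()
        assert (ctrl["stage"] == 0).all()

    def test_age_range_and_sex_coding(self):
        ids = [f"t{i}" for i in range(10)]
        clin, _ = syn.simulate_clinical(200, 50, ids, ids[:2], seed=15)
        assert clin["age"].between(23, 84).all()
        assert clin["sex"].isin([0, 1]).all()

    def test_case_shift_recorded_in_truth(self):
        ids = [f"t{i}" for i in range(20)]
        truth = syn.TruthTable()
        clin, expr = syn.simulate_clinical(
            80, 40, ids, ids[:4], case_shift=1.5, seed=16, truth=truth
        )
        assert (truth.casecontrol_truth[ids[:4]] == 1.5).all()
        assert (truth.casecontrol_truth[ids[4:]] == 0.0).all()
        case_cols = clin.index[clin["case"] == 1]
        ctrl_cols = clin.index[clin["case"] == 0]
        gap = (expr.values.loc[ids[0], case_cols].mean()
               - expr.values.loc[ids[0], ctrl_cols].mean())
        assert gap == pytest.approx(1.5, abs=0.6)

    def test_planted_hazard_recovered_within_2se(self):
        """Cox on a single risk transcript recovers log(2) within 2 SE in
        >=90% of replicates."""
        from cnexpress.survival_model import fit_cox

        ids = ["tR", "tN"]
        hits = 0
        n_rep = 60
        for rep in range(n_rep):
            clin, expr = syn.simulate_clinical(
                150, 0, ids, ["tR"], hr_per_unit=2.0, censor_rate=0.01,
                seed=500 + rep,
            )
            cases = clin[clin["case"] == 1]
            df = cases[["followup_months", "oscc_death", "age", "sex"]].astype(float)
            x = expr.values.loc["tR", cases.index].to_numpy(float)
            df["expr"] = (x - x.mean()) / x.std()
            f = fit_cox(df, ["expr", "age", "sex"])
            hits += abs(f.coef["expr"] - np.log(2.0)) < 2 * f.se["expr"]
        assert hits >= 0.9 * n_rep

    def test_zero_cases_rejected(self):
        with pytest.raises(ValueError):
            syn.simulate_clinical(0, 10, ["t0"], [], seed=1)

    def test_unknown_risk_transcript_rejected(self):
        with pytest.raises(ValueError, match="subset"):
            syn.simulate_clinical(10, 5, ["t0"], ["ghost"], seed=1)
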