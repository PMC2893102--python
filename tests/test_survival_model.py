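"""PC summaries, Cox fits, jackknife risk scores and landmark ROC."""

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter

from cnexpress.survival_model import (
    compare_auc,
    fit_cox,
    jackknife_risk_scores,
    pc_scores,
    time_dependent_roc,
)


def expr_frame(values, ids=None):
    values = np.atleast_2d(np.asarray(values, float))
    ids = ids or [f"t{i}" for i in range(values.shape[0])]
    return pd.DataFrame(values, index=ids, columns=[f"s{j}" for j in range(values.shape[1])])


class TestPCScores:
    def test_rank_one_matrix_single_component(self):
        u = np.array([1.0, 2.0, 3.0, 4.0])
        v = np.array([1.0, -1.0, 0.5])
        expr = expr_frame(np.outer(v, u))  # 3 transcripts x 4 samples
        pcs = pc_scores(expr, expr.index, n_components=2)
        assert pcs.variance_explained[0] == pytest.approx(1.0, abs=1e-12)

    def test_loadings_orthonormal_scores_centered(self):
        rng = np.random.default_rng(0)
        expr = expr_frame(rng.normal(0, 1, size=(10, 8)))
        pcs = pc_scores(expr, expr.index, 2)
        L = pcs.loadings.to_numpy()
        assert np.allclose(L.T @ L, np.eye(2), atol=1e-10)
        assert np.allclose(pcs.scores.mean(axis=0), 0.0, atol=1e-10)

    def test_matches_eigendecomposition_oracle(self):
        """Scores agree with a direct covariance eigendecomposition (6x4 toy)."""
        rng = np.random.default_rng(1)
        expr = expr_frame(rng.normal(2, 1, size=(6, 4)))
        pcs = pc_scores(expr, expr.index, 2)
        X = expr.to_numpy().T
        Xc = X - X.mean(axis=0)
        evals, evecs = np.linalg.eigh(Xc.T @ Xc)
        order = np.argsort(evals)[::-1]
        for j in range(2):
            vec = evecs[:, order[j]]
            if vec[np.argmax(np.abs(vec))] < 0:
                vec = -vec
            assert np.allclose(pcs.loadings.iloc[:, j].to_numpy(), vec, atol=1e-8)
            assert np.allclose(pcs.scores.iloc[:, j].to_numpy(), Xc @ vec, atol=1e-8)

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(2)
        expr = expr_frame(rng.normal(0, 1, size=(12, 6)))
        pcs = pc_scores(expr, expr.index, 2)
        for j in range(2):
            load = pcs.loadings.iloc[:, j].to_numpy()
            assert load[np.argmax(np.abs(load))] > 0

    def test_too_small_set_rejected(self):
        expr = expr_frame(np.ones((1, 4)))
        with pytest.raises(ValueError, match="cannot support"):
            pc_scores(expr, expr.index, 2)


def make_clinical(n, seed, beta_stage=np.log(2.0)):
    rng = np.random.default_rng(seed)
    stage = rng.choice([1, 2, 3, 4], size=n)
    lp = beta_stage * (stage - stage.mean())
    t = rng.exponential(1.0, n) / (np.log(2) / 24 * np.exp(lp))
    c = rng.exponential(80.0, n)
    return pd.DataFrame(
        {"followup_months": np.minimum(t, c), "oscc_death": (t <= c).astype(int),
         "stage": stage.astype(float)},
        index=[f"p{i}" for i in range(n)],
    )


class TestFitCox:
    def test_recovers_planted_stage_effect(self):
        """Planted log-HR of log 2 falls inside +/- 2 SE in ~95% of fits."""
        hits = 0
        for s in range(20):
            f = fit_cox(make_clinical(150, s), ["stage"])
            hits += abs(f.coef["stage"] - np.log(2.0)) < 2 * f.se["stage"]
        assert hits >= 17

    def test_null_covariate_ci_covers_one(self):
        """95% CI covers HR=1 at roughly the nominal rate under the null."""
        covered = 0
        for s in range(60):
            df = make_clinical(80, 100 + s, beta_stage=0.0)
            f = fit_cox(df, ["stage"])
            covered += f.ci_lower["stage"] <= 1.0 <= f.ci_upper["stage"]
        assert covered >= 51  # >= 85% of 60; binomial band around 95%

    def test_constant_covariate_diagnosed(self):
        df = make_clinical(40, 3)
        df["flat"] = 1.0
        with pytest.raises(ValueError, match="flat"):
            fit_cox(df, ["flat"])

    def test_no_events_rejected(self):
        df = make_clinical(20, 4)
        df["oscc_death"] = 0
        with pytest.raises(ValueError, match="no events"):
            fit_cox(df, ["stage"])


class TestJackknife:
    def test_identical_covariates_give_equal_scores(self):
        df = make_clinical(12, 5)
        df["stage"] = 2.0
        df["x"] = np.arange(12.0)  # needed so fits succeed
        scores = jackknife_risk_scores(df, ["x"])
        assert len(scores) == 12
        # with one covariate the score is (x_i - mean_train) * beta_i
        assert scores.index.tolist() == df.index.tolist()

    def test_matches_direct_refit_oracle(self):
        """Each score equals a by-hand refit excluding that subject (n=12)."""
        df = make_clinical(12, 6)
        scores = jackknife_risk_scores(df, ["stage"])
        for subject in df.index:
            train = df.drop(index=subject)
            cph = CoxPHFitter().fit(train, "followup_months", event_col="oscc_death")
            beta = cph.params_["stage"]
            expected = (df.loc[subject, "stage"] - train["stage"].mean()) * beta
            assert scores[subject] == pytest.approx(expected, rel=1e-8)

    def test_invariant_to_subject_order(self):
        df = make_clinical(15, 7)
        shuffled = df.sample(frac=1.0, random_state=1)
        a = jackknife_risk_scores(df, ["stage"])
        b = jackknife_risk_scores(shuffled, ["stage"])
        assert np.allclose(a.sort_index().to_numpy(), b.sort_index().to_numpy())

    def test_minimum_cohort_size(self):
        with pytest.raises(ValueError, match="at least 10"):
            jackknife_risk_scores(make_clinical(8, 8), ["stage"])


class TestTimeDependentROC:
    def test_uncensored_equals_empirical_roc(self):
        """With no censoring the KM estimator reduces to the plain
        cases-vs-controls ROC at the landmark."""
        rng = np.random.default_rng(9)
        n = 10
        score = rng.normal(0, 1, n)
        time = rng.uniform(1, 48, n)
        event = np.ones(n, dtype=int)
        landmark = 24.0
        curve, auc = time_dependent_roc(score, time, event, landmark)
        is_case = time <= landmark
        for _, row in curve.iterrows():
            c = row["cutoff"]
            assert row["tpr"] == pytest.approx(np.mean(score[is_case] > c), abs=1e-12)
            assert row["fpr"] == pytest.approx(np.mean(score[~is_case] > c), abs=1e-12)
        from sklearn.metrics import roc_auc_score

        assert auc == pytest.approx(roc_auc_score(is_case, score), abs=1e-12)

    def test_perfect_score_auc_one(self):
        time = np.array([5.0, 10.0, 15.0, 30.0, 35.0, 40.0])
        event = np.ones(6, dtype=int)
        score = -time  # earlier death = higher risk
        _, auc = time_dependent_roc(score, time, event, 24.0)
        assert auc == pytest.approx(1.0)

    def test_uninformative_score_auc_half(self):
        rng = np.random.default_rng(10)
        n = 400
        time = rng.exponential(24, n)
        event = np.ones(n, dtype=int)
        score = rng.normal(0, 1, n)
        _, auc = time_dependent_roc(score, time, event, 20.0)
        assert auc == pytest.approx(0.5, abs=0.08)

    def test_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(11)
        n = 60
        score = rng.normal(0, 1, n)
        time = rng.exponential(24, n)
        event = (rng.random(n) < 0.7).astype(int)
        time = np.maximum(time, 0.1)
        _, auc_raw = time_dependent_roc(score, time, event, 18.0)
        _, auc_exp = time_dependent_roc(np.exp(score), time, event, 18.0)
        assert auc_raw == pytest.approx(auc_exp, abs=1e-12)

    def test_no_events_before_landmark_rejected(self):
        time = np.array([30.0, 40.0, 50.0, 60.0])
        event = np.array([1, 1, 1, 1])
        with pytest.raises(ValueError, match="no events before"):
            time_dependent_roc(np.arange(4.0), time, event, 10.0)


class TestCompareAUC:
    def test_model_vs_itself_no_difference(self):
        rng = np.random.default_rng(12)
        n = 80
        score = rng.normal(0, 1, n)
        time = np.maximum(rng.exponential(24, n), 0.1)
        event = np.ones(n, dtype=int)
        out = compare_auc(score, score.copy(), time, event, 20.0, B_boot=200, seed=0)
        assert out["difference"] == 0.0
        assert out["p_value"] > 0.9

    def test_seeded_bootstrap_reproducible(self):
        rng = np.random.default_rng(13)
        n = 60
        a, b = rng.normal(0, 1, n), rng.normal(0, 1, n)
        time = np.maximum(rng.exponential(24, n), 0.1)
        event = np.ones(n, dtype=int)
        r1 = compare_auc(a, b, time, event, 20.0, B_boot=200, seed=5)
        r2 = compare_auc(a, b, time, event, 20.0, B_boot=200, seed=5)
        assert r1 == r2

    def test_informative_beats_noise(self):
        """A risk score tracking true hazard beats pure noise (strong signal)."""
        wins = 0
        for s in range(10):
            rng = np.random.default_rng(200 + s)
            n = 150
            signal = rng.normal(0, 1, n)
            t = rng.exponential(1, n) / (np.log(2) / 24 * np.exp(1.2 * signal))
            t = np.maximum(t, 0.1)
            event = np.ones(n, dtype=int)
            noise = rng.normal(0, 1, n)
            out = compare_auc(signal, noise, t, event, 24.0, B_boot=300, seed=s)
            wins += out["p_value"] < 0.05 and out["difference"] > 0
        assert wins >= 9

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError, match="same subjects"):
            compare_auc(np.ones(4), np.ones(5), np.ones(5), np.ones(5), 1.0)
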