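"""GP regression, nested LOSO selection, learning curves, clinical utilities."""

import math

import numpy as np
import pandas as pd
import pytest

import kinemarker as km
from kinemarker.modeling import (ClinicalScoreGP, GPModelSpec,
                                 _block_loo_predictions, _kernel_from_sqdist,
                                 gaa_repeats_from_pcr, gp_fit_predict,
                                 learning_curve, permute_labels_across_subjects,
                                 r2_rmse, scafi_composite)
from kinemarker.task_features import CohortTable


def _toy_table(n_subjects=10, n_families=4, dims_per_family=2, noise=0.0,
               seed=0, target_family=None, visits=2, repeats=1):
    """Fabricated cohort table: random features, target optionally planted."""
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subjects):
        sid = f"S{s:02d}"
        base = rng.standard_normal(n_families * dims_per_family)
        for v in range(visits):
            feats = base + 0.1 * rng.standard_normal(len(base))
            for rep in range(1, repeats + 1):
                row = {"subject_id": sid, "visit_id": f"V{v + 1}", "repeat": rep,
                       "group": "patient", "months": 9.0 * v}
                for f in range(n_families):
                    for d in range(dims_per_family):
                        row[f"8MW:F{f + 1}:x{d}"] = feats[f * dims_per_family + d]
                if target_family is None:
                    row["SARA"] = float(base.sum() + noise * rng.standard_normal())
                else:
                    row["SARA"] = float(
                        row[f"8MW:F{target_family}:x0"]
                        + noise * rng.standard_normal())
                row["SCAFI"] = -row["SARA"]
                row["FXN"] = row["SARA"]
                rows.append(row)
    return CohortTable(df=pd.DataFrame(rows))


class TestGPFitPredict:
    def test_matches_sklearn_gp_oracle(self):
        """Closed-form posterior equals sklearn's GP with the same kernel."""
        from sklearn.gaussian_process import GaussianProcessRegressor
        from sklearn.gaussian_process.kernels import RBF
        rng = np.random.default_rng(0)
        Xtr = rng.standard_normal((30, 3))
        y = np.sin(Xtr[:, 0]) + 0.1 * rng.standard_normal(30)
        Xte = rng.standard_normal((8, 3))
        ls, noise = 1.0, 0.1
        mean, sd = gp_fit_predict(Xtr, y, Xte, length_scale=ls, noise=noise)
        # replicate the preprocessing, then hand the same problem to sklearn
        mu, s = Xtr.mean(0), Xtr.std(0)
        Ztr, Zte = (Xtr - mu) / s, (Xte - mu) / s
        ell = ls * math.sqrt(3)
        gpr = GaussianProcessRegressor(kernel=RBF(length_scale=ell), alpha=noise,
                                       optimizer=None, normalize_y=True)
        gpr.fit(Ztr, y)
        ref_mean, ref_sd = gpr.predict(Zte, return_std=True)
        assert np.allclose(mean, ref_mean, atol=1e-6)
        assert np.allclose(sd, ref_sd, rtol=1e-4, atol=1e-6)

    def test_interpolates_smooth_target(self):
        rng = np.random.default_rng(1)
        X = np.linspace(-1, 1, 40)[:, None]
        y = X[:, 0].copy()
        Xte = rng.uniform(-0.9, 0.9, size=(10, 1))
        mean, _ = gp_fit_predict(X, y, Xte, noise=1e-8)
        assert np.abs(mean - Xte[:, 0]).max() < 1e-3

    def test_constant_target_reverts_to_constant(self):
        X = np.random.default_rng(2).standard_normal((20, 2))
        mean, _ = gp_fit_predict(X, np.full(20, 7.0), X[:5] + 10.0)
        assert np.allclose(mean, 7.0)

    def test_duplicated_rows_survive_via_jitter(self):
        X = np.ones((10, 2)) * np.arange(10)[:, None] % 3
        y = X[:, 0]
        mean, _ = gp_fit_predict(X, y, X[:2], noise=1e-6)
        assert np.all(np.isfinite(mean))


class TestBlockLOOIdentity:
    def test_equals_explicit_refitting(self):
        """The one-factorization LOSO identity reproduces per-fold refits."""
        rng = np.random.default_rng(3)
        n_subj, rows_per = 8, 3
        Z = rng.standard_normal((n_subj * rows_per, 4))
        y = Z @ rng.standard_normal(4) + 0.3 * rng.standard_normal(len(Z))
        subj = np.repeat(np.arange(n_subj), rows_per)
        D = ((Z[:, None] - Z[None]) ** 2).sum(-1)
        ell, noise, jitter = 2.0, 0.2, 1e-8
        K = _kernel_from_sqdist(D, ell, "rbf")
        blocks = [np.nonzero(subj == s)[0] for s in range(n_subj)]
        fast = _block_loo_predictions(K, y, blocks, noise, jitter)
        from scipy.linalg import cho_factor, cho_solve
        for b in blocks:
            tr = np.setdiff1d(np.arange(len(y)), b)
            Ktr = K[np.ix_(tr, tr)].copy()
            Ktr[np.diag_indices_from(Ktr)] += noise + jitter
            cf = cho_factor(Ktr, lower=True)
            pred = K[np.ix_(b, tr)] @ cho_solve(cf, y[tr])
            assert np.allclose(fast[b], pred, atol=1e-8)


class TestMetrics:
    def test_hand_arithmetic_example(self):
        r2, rmse = r2_rmse([1, 2, 3], [1, 2, 4])
        assert r2 == pytest.approx(0.5)
        assert rmse == pytest.approx(math.sqrt(1 / 3))

    def test_perfect_and_mean_predictors(self):
        y = np.array([2.0, 4.0, 9.0])
        assert r2_rmse(y, y) == (pytest.approx(1.0), pytest.approx(0.0))
        r2, _ = r2_rmse(y, np.full(3, y.mean()))
        assert r2 == pytest.approx(0.0)

    def test_zero_truth_variance_gives_nan_r2(self):
        r2, rmse = r2_rmse([5, 5, 5], [4, 5, 6])
        assert math.isnan(r2)
        assert rmse == pytest.approx(math.sqrt(2 / 3))


class TestNestedLOSO:
    def test_planted_signal_selects_family_and_fits(self):
        """Target equal to one family's first value, no noise: that family is
        selected and R² is essentially 1."""
        table = _toy_table(n_subjects=10, target_family=3, noise=0.0, seed=4)
        res = ClinicalScoreGP(table, target="SARA", max_subset_size=2).fit()
        assert "F3" in res.selected_subset
        assert res.r2 >= 0.99

    def test_no_leakage_fold_subsets_reproducible(self):
        """Deleting the held-out subject's rows and rerunning the inner
        selection reproduces that fold's proposed subset."""
        table = _toy_table(n_subjects=8, target_family=2, noise=0.3, seed=5)
        res = ClinicalScoreGP(table, target="SARA", max_subset_size=2).fit()
        held_out = "S03"
        reduced = CohortTable(df=table.df[table.df["subject_id"] != held_out]
                              .reset_index(drop=True))
        model = ClinicalScoreGP(reduced, target="SARA", max_subset_size=2)
        cols = model.table.feature_columns("8MW")
        fam_slices = {f: np.asarray([i for i, c in enumerate(cols)
                                     if c.split(":")[1] == f])
                      for f in model.families}
        fam_dims = {f: len(ix) for f, ix in fam_slices.items()}
        X = model.frame[cols].to_numpy(float)
        y = model.frame["y"].to_numpy(float)
        subjects = model.frame["subject_id"].to_numpy()
        subj_list = list(pd.unique(subjects))
        subject_of = np.asarray([subj_list.index(s) for s in subjects])
        Z = model._standardize(X, np.ones(len(X), bool))
        D_all = model._family_sqdists(Z, fam_slices)
        best, _ = model._inner_select(D_all, fam_dims, y, np.arange(len(X)),
                                      subject_of)
        assert best == res.per_fold_subsets[held_out]

    def test_summary_mentions_key_quantities(self):
        table = _toy_table(n_subjects=8, target_family=1, seed=6)
        res = ClinicalScoreGP(table, target="SARA", max_subset_size=2).fit()
        text = res.summary()
        assert "SARA" in text and "R2" in text and "F1" in text

    def test_longitudinal_mode_pairs_baseline_with_later_label(self):
        table = _toy_table(n_subjects=8, noise=0.0, seed=7, visits=2)
        # make visit-2 label distinct so pairing matters
        df = table.df.copy()
        df.loc[df["visit_id"] == "V2", "SARA"] += 5.0
        model = ClinicalScoreGP(CohortTable(df=df), target="SARA",
                                mode="longitudinal", horizon_months=9.0,
                                max_subset_size=1)
        assert np.isclose(model.frame["y"].mean(),
                          df.loc[df["visit_id"] == "V2", "SARA"].mean())

    def test_too_few_subjects_rejected(self):
        table = _toy_table(n_subjects=3)
        with pytest.raises(ValueError, match="4 subjects"):
            ClinicalScoreGP(table, target="SARA")

    def test_permuted_labels_break_prediction(self):
        table = _toy_table(n_subjects=12, noise=0.1, seed=8, target_family=2)
        base = ClinicalScoreGP(table, target="SARA", max_subset_size=2).fit()
        nulls = []
        for s in range(5):
            perm = permute_labels_across_subjects(table, "SARA", seed=s)
            nulls.append(ClinicalScoreGP(perm, target="SARA",
                                         max_subset_size=2).fit().r2)
        assert base.r2 > 0.9
        # single permutations fluctuate at this cohort size; the median is null
        assert np.median(nulls) < 0.1
        assert np.median(nulls) < base.r2 - 0.8


class TestLearningCurve:
    def test_k_equals_n_single_combination_zero_sd(self):
        table = _toy_table(n_subjects=6, seed=9)
        lc = learning_curve(table, "SARA", k_values=[6])
        assert lc.n_combinations == (1,)
        assert lc.sd_rmse[0] == pytest.approx(0.0)

    def test_combination_count_is_binomial(self):
        table = _toy_table(n_subjects=10, seed=10)
        lc = learning_curve(table, "SARA", k_values=[5])
        assert lc.n_combinations == (min(math.comb(10, 5), 1000),)
        assert lc.n_combinations[0] == 252

    def test_small_k_rejected(self):
        table = _toy_table(n_subjects=6, seed=11)
        with pytest.raises(ValueError):
            learning_curve(table, "SARA", k_values=[2])

    def test_mean_rmse_improves_with_cohort_size(self):
        table = _toy_table(n_subjects=12, noise=0.3, seed=12)
        lc = learning_curve(table, "SARA", k_values=[4, 8, 12], seed=0,
                            n_combinations_max=150)
        assert lc.mean_rmse[-1] <= lc.mean_rmse[0]


class TestClinicalUtilities:
    BASE = {"8MW": (1 / 6.0, 0.03), "9HPT": (1 / 20.0, 0.01), "PATA": (30.0, 4.0)}

    def test_baseline_means_score_zero(self):
        score = scafi_composite(6.0, 20.0, 20.0, 30.0, self.BASE)
        assert score == pytest.approx(0.0, abs=1e-12)

    def test_doubling_times_lowers_score(self):
        s0 = scafi_composite(6.0, 20.0, 20.0, 30.0, self.BASE)
        s1 = scafi_composite(12.0, 40.0, 40.0, 30.0, self.BASE)
        assert s1 < s0

    def test_control_like_beats_patient_like(self):
        """Direction matches the study cohort: controls positive, patients
        negative on the composite."""
        control = scafi_composite(5.5, 20.0, 23.0, 32.0, self.BASE)
        patient = scafi_composite(11.5, 59.0, 81.0, 19.0, self.BASE)
        assert control > 0 > patient

    def test_zero_baseline_sd_rejected(self):
        bad = {"8MW": (1 / 6.0, 0.0), "9HPT": (1 / 20.0, 0.01), "PATA": (30.0, 4.0)}
        with pytest.raises(ValueError):
            scafi_composite(6.0, 20.0, 20.0, 30.0, bad)

    @pytest.mark.parametrize("bp,expect", [(282, 0), (582, 100), (285, 1)])
    def test_gaa_repeat_formula(self, bp, expect):
        assert gaa_repeats_from_pcr(bp) == expect

    def test_gaa_short_product_rejected_and_rounding_warns(self):
        with pytest.raises(ValueError):
            gaa_repeats_from_pcr(281)
        with pytest.warns(UserWarning):
            assert gaa_repeats_from_pcr(583) == 100
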