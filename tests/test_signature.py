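import numpy as np
import pandas as pd
import pytest

import oracles
from irgpsig import (
    SignatureModel,
    SimulationConfig,
    classify_samples,
    fit_cox,
    fit_lasso_cox,
    load_packaged_signature,
    load_signature,
    make_candidate_profile,
    save_signature,
    score_samples,
    simulate_cohort,
    univariate_screen,
)
from irgpsig.signature import lasso_path


def _surv(time, event):
    return pd.DataFrame(
        {"time": time, "event": event},
        index=pd.Index([f"S{i}" for i in range(len(time))], name="sample"),
    )


def _profile(rows, index=None):
    rows = np.atleast_2d(rows)
    return pd.DataFrame(
        rows,
        index=index or [f"A{i}|B{i}" for i in range(rows.shape[0])],
        columns=[f"S{i}" for i in range(rows.shape[1])],
    )


class TestUnivariateScreen:
    def test_wald_estimate_matches_grid_search(self):
        surv = _surv([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1])
        profile = _profile([[1, 0, 1, 0]])
        result = univariate_screen(profile, surv)
        beta_grid = oracles.grid_cox_beta(
            np.array([1.0, 0.0, 1.0, 0.0]),
            surv["time"].to_numpy(), surv["event"].to_numpy(),
        )
        assert np.log(result.iloc[0]["hr"]) == pytest.approx(beta_grid, abs=1e-5)
        # Wald p agrees with the independent full Cox fit machinery
        surv["x"] = profile.iloc[0].to_numpy(dtype=float)
        assert result.iloc[0]["p"] == pytest.approx(
            fit_cox(surv, ["x"]).loc["x", "p"], abs=1e-12
        )

    def test_null_pair_hr_near_one_large_n(self):
        rng = np.random.default_rng(0)
        n = 1000
        surv = _surv(rng.exponential(100, n), rng.binomial(1, 0.7, n))
        profile = _profile([rng.binomial(1, 0.5, n)])
        hr = univariate_screen(profile, surv).iloc[0]["hr"]
        assert 0.8 <= hr <= 1.25

    def test_signal_pair_detected_across_seeds(self):
        detected = 0
        for seed in range(20):
            cfg = SimulationConfig(
                n_samples=200, n_genes=12, n_signal_pairs=1, betas=(1.0,),
                seed=200 + seed,
            )
            expr, surv, truth = simulate_cohort(cfg)
            profile = make_candidate_profile(expr, truth, n_pairs=3, seed=seed)
            result = univariate_screen(profile, surv)
            if result.loc[truth["signal_pairs"][0], "candidate"]:
                detected += 1
        assert detected >= 19

    def test_constant_pair_flagged_inestimable(self, toy_surv):
        profile = _profile([np.zeros(len(toy_surv), dtype=int)])
        profile.columns = toy_surv.index
        result = univariate_screen(profile, toy_surv)
        assert not result.iloc[0]["estimable"]
        assert not result.iloc[0]["candidate"]


class TestLassoCox:
    @pytest.fixture(scope="class")
    def small_cohort(self):
        cfg = SimulationConfig(
            n_samples=300, n_genes=20, n_signal_pairs=5,
            betas=(0.8, -0.8, 0.8, -0.8, 0.8), seed=31,
        )
        expr, surv, truth = simulate_cohort(cfg)
        profile = make_candidate_profile(expr, truth, n_pairs=5, seed=31)
        return profile, surv, truth

    def test_near_zero_penalty_matches_unpenalized_fit(self, small_cohort):
        profile, surv, _ = small_cohort
        model = fit_lasso_cox(profile, surv, n_folds=5, seed=0, lambda_grid=[0.0])
        surv_cov = surv.copy()
        for pid in profile.index:
            surv_cov[pid] = profile.loc[pid, surv.index].to_numpy(dtype=float)
        free = fit_cox(surv_cov, list(profile.index))
        fitted = pd.Series(model.coefficients, index=model.pair_ids)
        for pid in profile.index:
            assert fitted.get(pid, 0.0) == pytest.approx(
                free.loc[pid, "coef"], abs=1e-4
            )

    def test_full_shrinkage_raises_empty_signature(self, small_cohort):
        profile, surv, _ = small_cohort
        with pytest.raises(ValueError, match="empty signature"):
            fit_lasso_cox(profile, surv, n_folds=5, seed=0, lambda_grid=[1e3])

    def test_single_lambda_grid_warns(self, small_cohort):
        profile, surv, _ = small_cohort
        with pytest.warns(UserWarning, match="single-lambda"):
            fit_lasso_cox(profile, surv, n_folds=5, seed=0, lambda_grid=[0.01])

    def test_path_sparsity_non_increasing_in_lambda(self, small_cohort):
        profile, surv, _ = small_cohort
        lambdas, coefs = lasso_path(profile, surv)
        nonzero = (coefs != 0).sum(axis=0)
        # lambdas descend along the path, so sparsity decreases monotonically
        assert (np.diff(nonzero) >= 0).all()

    def test_fitted_pairs_are_screened_candidates(self, cohort):
        expr, surv, truth = cohort
        profile = make_candidate_profile(expr, truth, n_pairs=40, seed=7)
        screen = univariate_screen(profile, surv)
        candidates = screen.index[screen["candidate"]]
        model = fit_lasso_cox(profile.loc[candidates], surv, seed=7)
        assert set(model.pair_ids) <= set(candidates)

    def test_no_events_raises(self, small_cohort):
        profile, surv, _ = small_cohort
        dead = surv.copy()
        dead["event"] = 0
        with pytest.raises(ValueError, match="no events"):
            fit_lasso_cox(profile, dead, seed=0)

    def test_deterministic_given_seed(self, small_cohort):
        profile, surv, _ = small_cohort
        m1 = fit_lasso_cox(profile, surv, n_folds=5, seed=3)
        m2 = fit_lasso_cox(profile, surv, n_folds=5, seed=3)
        assert m1.pair_ids == m2.pair_ids
        np.testing.assert_array_equal(m1.coefficients, m2.coefficients)
        assert m1.lambda_ == m2.lambda_


class TestScoring:
    def test_all_zero_profile_scores_zero(self):
        model = SignatureModel(pairs=[("A0", "B0"), ("A1", "B1")],
                               coefficients=[0.5, -0.3])
        profile = _profile(np.zeros((2, 4), dtype=int))
        assert (score_samples(model, profile) == 0).all()

    def test_linearity_over_disjoint_supports(self):
        model = SignatureModel(pairs=[("A0", "B0"), ("A1", "B1")],
                               coefficients=[0.5, -0.3])
        x1 = _profile(np.array([[1, 0], [0, 0]]))
        x2 = _profile(np.array([[0, 0], [1, 1]]))
        combined = _profile(x1.to_numpy() + x2.to_numpy())
        np.testing.assert_allclose(
            score_samples(model, combined),
            score_samples(model, x1) + score_samples(model, x2),
        )

    def test_flipping_one_indicator_changes_score_by_its_coefficient(self):
        model = SignatureModel(pairs=[("A0", "B0"), ("A1", "B1")],
                               coefficients=[0.5, -0.3])
        base = _profile(np.array([[0, 1], [1, 0]]))
        flipped = base.copy()
        flipped.iloc[1, 0] = 0
        delta = score_samples(model, base) - score_samples(model, flipped)
        assert delta.tolist() == pytest.approx([-0.3, 0.0])

    def test_scores_from_expression_on_the_fly(self, toy_expr):
        model = SignatureModel(pairs=[("A", "B")], coefficients=[2.0])
        scores = score_samples(model, toy_expr)
        assert scores.tolist() == [2.0, 0.0]

    def test_missing_genes_listed(self, toy_expr):
        model = SignatureModel(pairs=[("A", "ZZ1"), ("ZZ2", "C")],
                               coefficients=[1.0, 1.0])
        with pytest.raises(ValueError, match=r"\['ZZ1', 'ZZ2'\]"):
            score_samples(model, toy_expr)


class TestClassification:
    def test_packaged_cutoff_classification(self):
        model = load_packaged_signature()
        scores = pd.Series([0.60, 0.538, 0.20], index=["a", "b", "c"])
        groups = classify_samples(scores, model.cutoff)
        assert groups.tolist() == ["high", "low", "low"]

    def test_empty_scores_give_empty_groups(self):
        groups = classify_samples(pd.Series(dtype=float), 0.5)
        assert len(groups) == 0

    def test_nonfinite_cutoff_raises(self):
        with pytest.raises(ValueError, match="finite"):
            classify_samples(pd.Series([1.0], index=["a"]), np.nan)


class TestSerialization:
    def test_round_trip_identity(self, tmp_path):
        model = SignatureModel(
            pairs=[("GZMB", "IL18"), ("CD14", "DKK1")],
            coefficients=[0.25, -0.125],
            cutoff=0.5,
            lambda_=0.01,
            provenance="toy",
        )
        path = tmp_path / "sig.json"
        save_signature(model, path)
        loaded = load_signature(path)
        assert loaded.pairs == model.pairs
        np.testing.assert_array_equal(loaded.coefficients, model.coefficients)
        assert loaded.cutoff == model.cutoff
        assert loaded.lambda_ == model.lambda_
        assert loaded.provenance == model.provenance

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError, match="coefficients"):
            SignatureModel(pairs=[("A", "B")], coefficients=[1.0, 2.0])

    def test_duplicate_pair_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            SignatureModel(pairs=[("A", "B"), ("B", "A")], coefficients=[1.0, 2.0])

    def test_nonfinite_coefficient_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            SignatureModel(pairs=[("A", "B")], coefficients=[np.inf])

    def test_malformed_file_rejected(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text('{"pairs": [{"gene_a": "A"}]}')
        with pytest.raises(ValueError, match="malformed"):
            load_signature(path)
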