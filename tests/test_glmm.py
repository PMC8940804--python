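"""Mixed models: design coding, hurdle likelihood, Laplace fits, Wald
tests and marginal-mean contrasts."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cowjbt.glmm import (
    BetaMixedRegression,
    FixedEffectsDesign,
    HurdleBetaModel,
    MixedLogit,
    MixedResults,
    ModelSpec,
    fit_model,
    hurdle_beta_loglik,
)


def simulate_binary(rng, n_cows=36, n_trials=112, sigma=0.5, betas=(0.0, 1.0, -1.0)):
    """Cow-level random-intercept logit data with a three-level factor."""
    punishers = np.repeat(["AIR", "ELEC", "NOTH"], n_cows // 3)
    b0, b_elec, b_noth = betas
    u = rng.normal(0, sigma, n_cows)
    rows = []
    for i in range(n_cows):
        eta = b0 + (b_elec if punishers[i] == "ELEC" else 0.0)
        eta += b_noth if punishers[i] == "NOTH" else 0.0
        eta += u[i]
        y = (rng.random(n_trials) < 1.0 / (1.0 + np.exp(-eta))).astype(float)
        rows.append(
            pd.DataFrame({"cow_id": f"c{i:03d}", "punisher": punishers[i], "y": y})
        )
    return pd.concat(rows, ignore_index=True)


class TestFixedEffectsDesign:
    def test_treatment_coding_with_interaction(self):
        df = pd.DataFrame(
            {"punisher": ["AIR", "ELEC", "NOTH", "AIR"], "cue": ["N", "P", "P", "P"]}
        )
        d = FixedEffectsDesign(df, ["punisher", "cue"], [("punisher", "cue")])
        assert d.names == [
            "Intercept",
            "punisher[ELEC]",
            "punisher[NOTH]",
            "cue[P]",
            "punisher[ELEC]:cue[P]",
            "punisher[NOTH]:cue[P]",
        ]
        X = d.matrix(df)
        assert X.shape == (4, 6)
        assert X[1].tolist() == [1, 1, 0, 1, 1, 0]

    def test_interaction_requires_main_effects(self):
        df = pd.DataFrame({"punisher": ["AIR", "ELEC"], "cue": ["N", "P"]})
        with pytest.raises(ValueError):
            FixedEffectsDesign(df, ["punisher"], [("punisher", "cue")])

    def test_unseen_level_rejected(self):
        df = pd.DataFrame({"punisher": ["AIR", "ELEC"]})
        d = FixedEffectsDesign(df, ["punisher"])
        with pytest.raises(ValueError):
            d.matrix(pd.DataFrame({"punisher": ["WATER"]}))

    def test_rank_deficiency_detected(self):
        y = [0, 1, 0, 1]
        X = np.ones((4, 2))  # duplicated intercept column
        with pytest.raises(ValueError, match="rank deficient"):
            MixedLogit(y, X, ["a", "b"])


class TestHurdleLoglik:
    def test_zero_contributes_log_p(self):
        ll = hurdle_beta_loglik([0.0], p_zero=[0.2], mu=[0.5], phi=2.0)
        assert ll == pytest.approx(np.log(0.2))

    def test_uniform_beta_density_case(self):
        # Beta(1, 1) density is 1: contribution is log(1 - p) only
        ll = hurdle_beta_loglik([0.3], p_zero=[0.2], mu=[0.5], phi=2.0)
        assert ll == pytest.approx(np.log(0.8), abs=1e-12)

    def test_additivity_under_dataset_doubling(self, rng):
        y = rng.beta(2, 3, 50)
        y[rng.random(50) < 0.3] = 0.0
        p = rng.uniform(0.1, 0.9, 50)
        mu = rng.uniform(0.2, 0.8, 50)
        one = hurdle_beta_loglik(y, p, mu, 4.0)
        two = hurdle_beta_loglik(np.tile(y, 2), np.tile(p, 2), np.tile(mu, 2), 4.0)
        assert two == pytest.approx(2 * one, rel=1e-12)

    def test_matches_independent_density_oracle(self, rng):
        for _ in range(200):
            n = 20
            y = rng.beta(2, 2, n)
            y[rng.random(n) < 0.25] = 0.0
            p = rng.uniform(0.05, 0.95, n)
            mu = rng.uniform(0.05, 0.95, n)
            phi = rng.uniform(0.5, 20)
            ll = hurdle_beta_loglik(y, p, mu, phi)
            oracle = 0.0
            for yi, pi, mi in zip(y, p, mu):
                if yi == 0:
                    oracle += np.log(pi)
                else:
                    oracle += np.log(1 - pi) + stats.beta.logpdf(yi, mi * phi, (1 - mi) * phi)
            assert ll == pytest.approx(oracle, abs=1e-8)

    def test_rejects_invalid_inputs(self):
        with pytest.raises(ValueError):
            hurdle_beta_loglik([1.0], [0.5], [0.5], 2.0)
        with pytest.raises(ValueError):
            hurdle_beta_loglik([0.5], [0.5], [0.5], -1.0)


class TestLaplaceFits:
    def test_zero_variance_reproduces_fixed_effects_fit(self, rng):
        import statsmodels.api as sm

        df = simulate_binary(rng, n_cows=12, n_trials=30, sigma=0.4)
        model = MixedLogit.from_dataframe(df, "y", ["punisher"], ["cow_id"])
        res = model.fit(sigma_fixed={"cow_id": 0.0})
        ref = sm.GLM(
            df["y"].to_numpy(), model.exog, family=sm.families.Binomial()
        ).fit()
        assert res.params == pytest.approx(np.asarray(ref.params), abs=1e-4)
        assert res.vc["cow_id"] == 0.0

    def test_single_level_group_matches_no_random_fit(self, rng):
        import statsmodels.api as sm

        df = simulate_binary(rng, n_cows=12, n_trials=20, sigma=0.0)
        df["all_same"] = "x"
        model = MixedLogit.from_dataframe(df, "y", ["punisher"], ["all_same"])
        res = model.fit()
        ref = sm.GLM(df["y"].to_numpy(), model.exog, family=sm.families.Binomial()).fit()
        assert res.params == pytest.approx(np.asarray(ref.params), abs=1e-3)

    def test_recovers_known_coefficients(self, rng):
        """Short parameter-recovery check at the study's scale."""
        biases = []
        for _ in range(8):
            df = simulate_binary(rng, sigma=0.5, betas=(0.2, 1.0, -1.0))
            res = MixedLogit.from_dataframe(df, "y", ["punisher"], ["cow_id"]).fit()
            est = dict(zip(res.exog_names, res.params))
            biases.append([est["punisher[ELEC]"] - 1.0, est["punisher[NOTH]"] + 1.0])
        mean_bias = np.abs(np.mean(biases, axis=0))
        assert (mean_bias < 0.15).all()

    def test_variance_truth_zero_piles_at_boundary(self, rng):
        at_boundary = 0
        reps = 40
        for _ in range(reps):
            df = simulate_binary(rng, n_cows=12, n_trials=25, sigma=0.0)
            res = MixedLogit.from_dataframe(df, "y", ["punisher"], ["cow_id"]).fit()
            at_boundary += res.vc["cow_id"] == 0.0
        assert at_boundary / reps >= 0.4

    def test_hurdle_parts_factorise(self, rng):
        """Joint hurdle log-likelihood equals the sum of the separately
        maximised part likelihoods evaluated at the fitted parameters."""
        n = 400
        eta_zero = -0.8
        p_zero = 1 / (1 + np.exp(-eta_zero))
        y = rng.beta(3, 2, n)
        y[rng.random(n) < p_zero] = 0.0
        df = pd.DataFrame(
            {
                "remaining": y,
                "punisher": rng.choice(["AIR", "ELEC", "NOTH"], n),
                "cue": rng.choice(["P", "N"], n),
                "batch": "1",
                "group_id": "g1",
                "cow_id": rng.choice([f"c{i}" for i in range(8)], n),
            }
        )
        df["cow_session"] = df["cow_id"] + "s"
        model = HurdleBetaModel(
            df,
            zero_factors=["punisher"],
            zero_groups=["cow_id"],
            positive_factors=["punisher"],
            positive_groups=["cow_id"],
            positive_interactions=[],
        )
        res = model.fit()
        assert res.llf == pytest.approx(res.nogo.llf + res.positive.llf)
        # the zero part is a plain Bernoulli model of the indicator: its
        # fitted probability at zero variance reproduces the zero fraction
        res0 = model.nogo_model.fit(sigma_fixed={"cow_id": 0.0})
        est = dict(zip(res0.exog_names, res0.params))
        frac = (y == 0).mean()
        assert 1 / (1 + np.exp(-est["Intercept"])) == pytest.approx(frac, abs=0.1)

    def test_beta_regression_rejects_boundary_responses(self):
        with pytest.raises(ValueError):
            BetaMixedRegression([0.0, 0.5], np.ones((2, 1)), ["Intercept"])


class TestWaldAndEmm:
    @staticmethod
    def synthetic_results(params, cov, factors=None, interactions=()):
        df = pd.DataFrame(
            {
                "punisher": ["AIR", "ELEC", "NOTH"] * 2,
                "cue": ["N", "N", "N", "P", "P", "P"],
            }
        )
        design = FixedEffectsDesign(df, factors or ["punisher"], interactions)
        X = design.matrix(df)
        model = MixedLogit(np.zeros(len(df)), X, design.names, {}, design=design)
        return MixedResults(
            model=model,
            params=np.asarray(params, float),
            cov_params_arr=np.asarray(cov, float),
            vc={},
            extra=np.array([]),
            llf=0.0,
            converged=True,
            niter=1,
            grad_norm=0.0,
        )

    def test_wald_zero_coefficient(self):
        res = self.synthetic_results([0.5, 0.0, 0.3], np.eye(3) * 0.25)
        w = res.wald_test("punisher[ELEC]")
        assert w.chi2 == 0.0
        assert w.p_value == 1.0

    def test_wald_chi_square_tail(self):
        res = self.synthetic_results([0.0, 1.96, 0.0], np.eye(3))
        w = res.wald_test("punisher[ELEC]")
        assert w.chi2 == pytest.approx(3.8416)
        assert w.p_value == pytest.approx(0.05, abs=1e-3)

    def test_wald_term_block(self):
        res = self.synthetic_results([0.0, 1.0, 1.0], np.eye(3) * 0.5)
        w = res.wald_test("punisher")
        assert w.df == 2
        assert w.chi2 == pytest.approx(4.0)

    def test_emm_odds_ratio_of_log2_difference(self):
        res = self.synthetic_results([0.0, np.log(2.0), 0.0], np.eye(3) * 0.01)
        table = res.emm_pairwise("punisher")
        row = table[table.contrast == "AIR - ELEC"].iloc[0]
        assert row.odds_ratio == pytest.approx(0.5)
        row2 = table[table.contrast == "AIR - NOTH"].iloc[0]
        assert row2.odds_ratio == pytest.approx(1.0)
        assert row2.p_adj == 1.0

    def test_emm_within_level_restricts_averaging(self):
        params = [0.0, 1.0, 0.0, 0.5, 0.7, 0.0]  # interaction ELEC:P = 0.7
        res = self.synthetic_results(
            params, np.eye(6) * 0.01, factors=["punisher", "cue"],
            interactions=[("punisher", "cue")],
        )
        tab_n = res.emm_pairwise("punisher", within=("cue", "N"))
        tab_p = res.emm_pairwise("punisher", within=("cue", "P"))
        d_n = tab_n[tab_n.contrast == "AIR - ELEC"].iloc[0].estimate
        d_p = tab_p[tab_p.contrast == "AIR - ELEC"].iloc[0].estimate
        assert d_n == pytest.approx(-1.0)
        assert d_p == pytest.approx(-1.7)

    def test_single_level_factor_rejected(self):
        df = pd.DataFrame({"punisher": ["AIR", "AIR"]})
        design = FixedEffectsDesign(df, ["punisher"])
        model = MixedLogit(np.zeros(2), design.matrix(df), design.names, {}, design=design)
        res = MixedResults(model, np.zeros(1), np.eye(1), {}, np.array([]), 0.0, True, 1, 0.0)
        with pytest.raises(ValueError):
            res.emm_pairwise("punisher")

    def test_bonferroni_applied_over_contrast_family(self):
        res = self.synthetic_results([0.0, 0.5, 0.5], np.eye(3) * 0.09)
        table = res.emm_pairwise("punisher")
        assert len(table) == 3
        assert np.allclose(table["p_adj"], np.minimum(1.0, table["p_raw"] * 3))


def test_fit_model_front_door_dispatch(rng):
    df = simulate_binary(rng, n_cows=9, n_trials=16, sigma=0.3)
    df["correct"] = df["y"]
    df["batch"] = "1"
    df["cue"] = rng.choice(["P", "N"], len(df))
    df["group_id"] = df["cow_id"].str[:2]
    df["cow_session"] = df["cow_id"] + "s1"
    res = fit_model(ModelSpec(response="binary_correct"), df)
    assert res.converged
    with pytest.raises(ValueError):
        fit_model(ModelSpec(response="nope"), df)
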