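import numpy as np
import pandas as pd
import pytest
import statsmodels.formula.api as smf

from mutualinet.hier_sem import (
    MCMCConfig,
    SEMPosterior,
    SEMSpec,
    bayes_factors,
    fit_sem,
    r2_decomposition,
    run_both_models,
)
from mutualinet.synthetic_data import ScenarioConfig, simulate_sem_table

SPEC = SEMSpec(niche=("niche_p", "niche_a"))
FAST = MCMCConfig.desk(chains=2, iterations=2200, thin=10)


@pytest.fixture(scope="module")
def sem_data():
    return simulate_sem_table(ScenarioConfig(seed=31))


@pytest.fixture(scope="module")
def fitted(sem_data):
    df, truth = sem_data
    return fit_sem(df, spec=SPEC, mcmc=FAST, seed=77), truth


class TestFitSem:
    def test_same_seed_identical_draws(self, sem_data):
        df, _ = sem_data
        tiny = MCMCConfig.desk(chains=2, iterations=1400, thin=20)
        a = fit_sem(df, spec=SPEC, mcmc=tiny, seed=5)
        b = fit_sem(df, spec=SPEC, mcmc=tiny, seed=5)
        assert set(a.draws) == set(b.draws)
        for k in a.draws:
            np.testing.assert_array_equal(a.draws[k], b.draws[k])

    def test_posterior_shapes_and_ranges(self, fitted):
        post, _ = fitted
        assert post.draws["beta[MAT->FD_p]"].shape == (FAST.chains, FAST.draws_per_chain)
        for name in post.draws:
            if name.startswith("gamma["):
                assert set(np.unique(post.draws[name])) <= {0, 1}
            if name.startswith(("sd_", "resid_sd")):
                assert (post.draws[name] > 0).all()
            if name.startswith("resid_cor"):
                assert (np.abs(post.draws[name]) < 1).all()

    def test_strong_paths_recovered(self, fitted):
        """Posterior means of the large true paths land near the truth."""
        post, truth = fitted
        for (src, tgt), val in truth.coefficients.items():
            if val >= 0.5:
                b = post.stacked(f"beta[{src}->{tgt}]")
                g = post.stacked(f"gamma[{src}->{tgt}]")
                mean = b[g == 1].mean()
                sd = b[g == 1].std()
                assert abs(mean - val) < max(3 * sd, 0.3), (src, tgt, mean, val)

    def test_residual_correlation_recovered(self, fitted):
        post, truth = fitted
        rho = post.stacked("resid_cor[FD]")
        lo, hi = np.quantile(rho, [0.025, 0.975])
        assert lo < 0.3 < hi  # generator's true FD residual correlation

    def test_requires_complete_columns(self, sem_data):
        df, _ = sem_data
        with pytest.raises(ValueError, match="lacks columns"):
            fit_sem(df.drop(columns=["FD_p"]), spec=SPEC, mcmc=FAST, seed=0)

    def test_selection_disabled_matches_mixed_model_ml(self):
        """Dual route: flat-ish prior posterior means vs lme4-style ML fit."""
        cfg = ScenarioConfig(
            seed=41,
            n_sites_sem=100,
            mutualism_sd=0.0,
            sem_coefficients={("MAP", "FD_p"): 0.5, ("MAT", "FD_p"): 0.4},
        )
        df, _ = simulate_sem_table(cfg)
        post = fit_sem(
            df,
            spec=SPEC,
            mcmc=MCMCConfig.desk(chains=2, iterations=2600, thin=5),
            seed=3,
            niche_cols=("niche_p", "niche_a"),
        )
        from mutualinet._utils import zscale

        data = df.copy()
        for c in ("MAT", "MAP", "LU", "FD_p"):
            data[c] = zscale(data[c].to_numpy())
        ml = smf.mixedlm("FD_p ~ MAT + MAP + LU", data, groups=data["site_id"]).fit(reml=False)
        for src in ("MAT", "MAP"):
            bayes = post.stacked(f"beta[{src}->FD_p]").mean()
            assert bayes == pytest.approx(ml.params[src], rel=0.05, abs=0.02)


def _fake_posterior(gammas, betas=None, extra=None):
    """Posterior stub with prescribed indicator/coefficient draws."""
    spec = SEMSpec(niche=("niche_p", "niche_a"))
    nd = len(next(iter(gammas.values()))) if gammas else 50
    draws = {}
    for src, tgt in spec.paths:
        g = np.asarray(gammas.get((src, tgt), np.zeros(nd)))
        draws[f"gamma[{src}->{tgt}]"] = g[None, :]
        b = np.asarray(betas.get((src, tgt), g * 0.5)) if betas else g * 0.5
        draws[f"beta[{src}->{tgt}]"] = b[None, :]
        draws[f"theta[{src}->{tgt}]"] = b[None, :]
    for tgt in spec.endogenous:
        draws[f"alpha[{tgt}]"] = np.zeros((1, nd))
        draws[f"sd_site[{tgt}]"] = np.ones((1, nd))
        draws[f"sd_mut[{tgt}]"] = np.ones((1, nd))
        draws[f"resid_sd[{tgt}]"] = np.ones((1, nd))
    draws["resid_cor[FD]"] = np.zeros((1, nd))
    draws["resid_cor[niche]"] = np.zeros((1, nd))
    if extra:
        draws.update(extra)
    return SEMPosterior(draws=draws, spec=spec, config=MCMCConfig.desk(), seed=0, n_obs=126)


class TestBayesFactors:
    def test_even_odds_gives_zero_evidence(self):
        g = np.repeat([0, 1], 500)
        bf = bayes_factors(_fake_posterior({("MAT", "FD_p"): g}))
        row = bf[(bf.source == "MAT") & (bf.target == "FD_p")].iloc[0]
        assert row["two_ln_bf"] == pytest.approx(0.0, abs=1e-12)
        assert row["category"] == "none"

    def test_ninety_percent_inclusion_is_positive_support(self):
        g = np.repeat([1, 0], [900, 100])
        bf = bayes_factors(_fake_posterior({("MAT", "FD_p"): g}))
        row = bf[(bf.source == "MAT") & (bf.target == "FD_p")].iloc[0]
        assert row["two_ln_bf"] == pytest.approx(2 * np.log(9), abs=1e-9)  # 4.394
        assert row["category"] == "positive"

    def test_saturated_inclusion_clipped_and_flagged(self):
        g = np.ones(1000)
        bf = bayes_factors(_fake_posterior({("MAT", "FD_p"): g}))
        row = bf[(bf.source == "MAT") & (bf.target == "FD_p")].iloc[0]
        assert row["saturated"]
        assert row["category"] == "decisive (saturated)"
        assert np.isfinite(row["two_ln_bf"])

    def test_category_thresholds(self):
        for p, cat in ((0.75, "positive"), (0.96, "strong"), (0.995, "decisive")):
            nd = 10_000
            g = np.zeros(nd)
            g[: int(p * nd)] = 1
            bf = bayes_factors(_fake_posterior({("MAT", "FD_p"): g}))
            assert bf.iloc[0]["category"] == cat, p


class TestR2:
    def test_closed_form_fixture(self, sem_data):
        """var_f=1, var_random=1, var_resid=2 -> r2m=0.25, r2c=0.5."""
        df, _ = sem_data
        nd = 50
        g = np.ones(nd)
        extra = {}
        for tgt in ("FD_p", "FD_a", "niche_p", "niche_a"):
            extra[f"sd_site[{tgt}]"] = np.full((1, nd), np.sqrt(0.5))
            extra[f"sd_mut[{tgt}]"] = np.full((1, nd), np.sqrt(0.5))
            extra[f"resid_sd[{tgt}]"] = np.full((1, nd), np.sqrt(2.0))
        post = _fake_posterior(
            {("MAT", "FD_p"): g}, betas={("MAT", "FD_p"): g * 1.0}, extra=extra
        )
        r2, per = r2_decomposition(post, df, niche_cols=("niche_p", "niche_a"))
        row = r2.set_index("target").loc["FD_p"]
        # MAT is z-scaled so the single-path linear predictor has variance 1
        assert row["r2_marginal"] == pytest.approx(0.25, abs=1e-12)
        assert row["r2_conditional"] == pytest.approx(0.5, abs=1e-12)

    def test_no_fixed_effects_zero_marginal(self, sem_data):
        df, _ = sem_data
        post = _fake_posterior({})
        r2, _ = r2_decomposition(post, df, niche_cols=("niche_p", "niche_a"))
        assert (r2["r2_marginal"] == 0).all()

    def test_ordering_holds_on_every_draw(self, fitted, sem_data):
        post, _ = fitted
        df, _ = sem_data
        _, per = r2_decomposition(post, df, niche_cols=("niche_p", "niche_a"))
        for tgt, arr in per.items():
            r2m, r2c = arr
            assert (r2m <= r2c + 1e-12).all()
            assert (r2c <= 1.0 + 1e-12).all()
            assert (r2m >= -1e-12).all()


class TestRunBothModels:
    def test_path_set_and_categories_present(self, sem_data):
        df, _ = sem_data
        df = df.rename(columns={"niche_p": "ln_eH_p", "niche_a": "ln_eH_a"})
        df["dprime_p"] = df["ln_eH_p"] * 0.5 + 0.1
        df["dprime_a"] = df["ln_eH_a"] * 0.5 - 0.1
        tiny = MCMCConfig.desk(chains=2, iterations=1400, thin=20)
        out = run_both_models(df, mcmc=tiny, seed=9)
        assert set(out) == {"eH", "dprime"}
        expected_paths = set(SEMSpec().paths)
        for res in out.values():
            got = set(zip(res["support"]["source"], res["support"]["target"]))
            assert got == expected_paths
            assert res["support"]["category"].notna().all()
            assert set(res["r2"]["target"]) == {"FD_p", "FD_a", "niche_p", "niche_a"}
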