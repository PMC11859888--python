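"""Split-plot ANOVA partition, LSD letter displays, Pearson screens.

Oracles: the sums-of-squares partition identity, a main-plot-means
interaction oracle for the error-a stratum, a fixed-effects linear-model
cross-check (statsmodels) for the subplot-stratum F tests, and a
brute-force all-pairs grouping oracle for the letter display.
"""

import itertools

import numpy as np
import pandas as pd
import pytest

from fertigation.stats import (UnbalancedDesignError, letters_from_nsd,
                               lsd_letters, pearson_matrix, splitplot_anova)
from fertigation.synthetic import SyntheticTruth, make_design, simulate_trial


def random_balanced(rng, r=3, f=4, w=3, effects=True):
    rows = []
    ef = rng.normal(0, 2, f) if effects else np.zeros(f)
    ew = rng.normal(0, 2, w) if effects else np.zeros(w)
    for rep in range(1, r + 1):
        for i in range(f):
            main = rng.normal(0, 1)
            for j in range(w):
                rows.append({"rep": rep, "fert_level": f"F{i+1}",
                             "irr_level": f"W{j+1}",
                             "y": 50 + ef[i] + ew[j] + main + rng.normal(0, 1)})
    return pd.DataFrame(rows)


class TestSplitplotAnova:
    def test_ss_partition_identity(self, rng):
        for _ in range(20):
            df = random_balanced(rng)
            at = splitplot_anova(df, "y")
            t = at.table.set_index("source")
            parts = t.loc[["Rep", "F", "Error-a", "W", "FxW", "Error-b"], "SS"].sum()
            assert parts == pytest.approx(t.loc["Total", "SS"], rel=1e-8)
            assert (t["SS"].dropna() >= -1e-12).all()
            assert t["df"].drop("Total").sum() == t.loc["Total", "df"]

    def test_error_a_matches_mainplot_means_oracle(self, rng):
        # error-a MS must equal w x (Rep x F interaction MS of main-plot means)
        df = random_balanced(rng)
        w = df["irr_level"].nunique()
        at = splitplot_anova(df, "y")
        M = df.groupby(["rep", "fert_level"])["y"].mean().unstack().to_numpy()
        dev = M - M.mean(1, keepdims=True) - M.mean(0, keepdims=True) + M.mean()
        ss_int = w * float((dev ** 2).sum())
        assert at["Error-a"]["SS"] == pytest.approx(ss_int, rel=1e-8)

    def test_subplot_tests_match_fixed_effects_lm(self, rng):
        # treating each main plot as a fixed block reproduces the error-b
        # stratum, so W and FxW tests must agree with an OLS ANOVA
        import statsmodels.api as sm
        import statsmodels.formula.api as smf
        df = random_balanced(rng)
        at = splitplot_anova(df, "y")
        lm = smf.ols("y ~ C(rep)*C(fert_level) + C(irr_level) "
                     "+ C(fert_level):C(irr_level)", data=df).fit()
        aov = sm.stats.anova_lm(lm, typ=1)
        assert at["W"]["F"] == pytest.approx(
            aov.loc["C(irr_level)", "F"], rel=1e-6)
        assert at["W"]["p"] == pytest.approx(
            aov.loc["C(irr_level)", "PR(>F)"], abs=1e-9)
        assert at["FxW"]["F"] == pytest.approx(
            aov.loc["C(fert_level):C(irr_level)", "F"], rel=1e-6)

    def test_all_equal_observations_give_zero_f(self):
        df = random_balanced(np.random.default_rng(0))
        df["y"] = 42.0
        at = splitplot_anova(df, "y")
        for src in ("F", "W", "FxW"):
            assert at[src]["SS"] == pytest.approx(0.0, abs=1e-18)
            assert at[src]["F"] == 0.0

    def test_pure_f_effect_without_noise(self, reference_design):
        truth = SyntheticTruth(sigma_mainplot=0, sigma_subplot=0,
                               sigma_mainplot_brix=0, sigma_subplot_brix=0,
                               yield_surface=(10.0, 0.1, 0, 0, 0, 0), seed=0)
        obs = simulate_trial(reference_design, truth)
        obs = obs[obs.fert_level != "F0"]
        at = splitplot_anova(obs, "yield_t_ha")
        assert at.p_value("F") == pytest.approx(0.0)
        assert at["W"]["F"] == 0.0

    def test_unbalanced_design_is_rejected(self, rng):
        df = random_balanced(rng).iloc[:-1]
        with pytest.raises(UnbalancedDesignError):
            splitplot_anova(df, "y")
        dup = pd.concat([random_balanced(rng)] * 2)
        with pytest.raises(UnbalancedDesignError):
            splitplot_anova(dup, "y")

    def test_detects_effects_on_simulated_reference_trial(self, surface_summary):
        # truth = the published 2020 yield surface, realistic noise: both
        # main effects should be detected in most runs
        row = surface_summary.query("response=='yield' and year==2020").iloc[0]
        coeffs = tuple(row[["b0", "b1", "b2", "b3", "b4", "b5"]])
        design = make_design(include_zero_fert_controls=False)
        hits_f = hits_w = 0
        n_sim = 60
        for s in range(n_sim):
            # noise at the scale of the published replicate SDs (~0.2-2.2)
            truth = SyntheticTruth(yield_surface=coeffs, sigma_mainplot=0.5,
                                   sigma_subplot=1.2, seed=1000 + s)
            obs = simulate_trial(design, truth)
            at = splitplot_anova(obs, "yield_t_ha")
            hits_f += at.p_value("F") < 0.05
            hits_w += at.p_value("W") < 0.01
        assert hits_w / n_sim > 0.9
        assert hits_f / n_sim > 0.6


def brute_force_groups(means: pd.Series, lsd: float):
    """All maximal sets of mutually non-different treatments."""
    names = list(means.index)
    cliques = []
    for k in range(1, len(names) + 1):
        for combo in itertools.combinations(names, k):
            if all(abs(means[a] - means[b]) <= lsd
                   for a, b in itertools.combinations(combo, 2)):
                cliques.append(set(combo))
    return [c for c in cliques
            if not any(c < other for other in cliques)]


class TestLsdLetters:
    def test_two_separated_means(self):
        means = pd.Series({"A": 10.0, "B": 1.0})
        disp = lsd_letters(means, ms_error=1.0, df_error=10, n_per_mean=3)
        assert disp.letters == {"A": "a", "B": "b"}

    def test_all_close_means_share_a(self):
        means = pd.Series({"A": 10.0, "B": 9.9, "C": 10.05})
        disp = lsd_letters(means, ms_error=4.0, df_error=10, n_per_mean=3)
        assert set(disp.letters.values()) == {"a"}
        assert disp.letters["C"] == "a"  # highest mean carries 'a'

    def test_argument_validation(self):
        means = pd.Series({"A": 1.0, "B": 2.0})
        with pytest.raises(ValueError):
            lsd_letters(means, ms_error=0.0, df_error=5, n_per_mean=3)
        with pytest.raises(ValueError):
            lsd_letters(means, ms_error=1.0, df_error=5, n_per_mean=0)
        with pytest.raises(ValueError):
            lsd_letters(means, ms_error=1.0, df_error=5, n_per_mean=3, alpha=1.5)

    @pytest.mark.parametrize("n_means", [5, 8, 12])
    def test_matches_brute_force_grouping_oracle(self, rng, n_means):
        for _ in range(25):
            means = pd.Series(rng.normal(50, 3, n_means),
                              index=[f"T{i}" for i in range(n_means)])
            disp = lsd_letters(means, ms_error=rng.uniform(0.5, 6.0),
                               df_error=22, n_per_mean=3)
            groups = {}
            for t, ls in disp.letters.items():
                for ch in ls:
                    groups.setdefault(ch, set()).add(t)
            expected = brute_force_groups(means, disp.lsd)
            assert sorted(map(sorted, groups.values())) == \
                sorted(map(sorted, expected))

    def test_letters_consistent_with_pairwise_significance(self, rng):
        means = pd.Series(rng.normal(0, 2, 10),
                          index=[f"T{i}" for i in range(10)])
        disp = lsd_letters(means, ms_error=1.2, df_error=18, n_per_mean=3)
        for a, b in itertools.combinations(means.index, 2):
            shares = set(disp.letters[a]) & set(disp.letters[b])
            differs = abs(means[a] - means[b]) > disp.lsd
            if shares:
                assert not differs  # sharing a letter implies no difference
            else:
                assert differs

    def test_annotate_renders_mean_sd_letters(self):
        means = pd.Series({"A": 10.0, "B": 1.0})
        sds = pd.Series({"A": 0.5, "B": 0.4})
        disp = lsd_letters(means, 1.0, 10, 3, sds=sds)
        assert disp.annotate()["A"] == "10.00 ± 0.50 a"


class TestPearson:
    def test_perfect_linear_and_negation(self, rng):
        x = rng.normal(0, 1, 30)
        df = pd.DataFrame({"x": x, "y": 3 * x + 2, "z": -x})
        out = pearson_matrix(df, ["x", "y", "z"]).set_index(["var1", "var2"])
        assert out.loc[("x", "y"), "r"] == pytest.approx(1.0)
        assert out.loc[("x", "y"), "star"] == "**"
        assert out.loc[("x", "z"), "r"] == pytest.approx(-1.0)
        assert out.loc[("x", "x"), "r"] == 1.0

    def test_zero_variance_flagged_not_zeroed(self, rng):
        df = pd.DataFrame({"x": rng.normal(0, 1, 10), "c": np.ones(10)})
        out = pearson_matrix(df, ["x", "c"]).set_index(["var1", "var2"])
        assert np.isnan(out.loc[("x", "c"), "r"])
        assert out.loc[("x", "c"), "star"] == "undef"

    def test_needs_three_observations(self):
        df = pd.DataFrame({"x": [1.0, 2.0], "y": [3.0, 4.0]})
        with pytest.raises(ValueError):
            pearson_matrix(df, ["x", "y"])

    def test_yield_correlates_with_sugar_yield(self, reference_design):
        # near-constant sugar content makes sugar yield track root yield
        truth = SyntheticTruth(brix_surface=(22.0, 0, 0, 0, 0, 0),
                               sigma_mainplot_brix=0.02,
                               sigma_subplot_brix=0.05, seed=8)
        obs = simulate_trial(reference_design, truth)
        obs["sugar_yield"] = obs["yield_t_ha"] * 0.8 * obs["brix_pct"] / 100
        out = pearson_matrix(obs, ["yield_t_ha", "sugar_yield"]).set_index(
            ["var1", "var2"])
        assert out.loc[("yield_t_ha", "sugar_yield"), "r"] > 0.9
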