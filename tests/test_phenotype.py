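"""Three-way ANOVA, residualization, Tukey HSD, planned contrasts."""

import numpy as np
import pandas as pd
import pytest

from rhizodmm import (
    fit_anova3,
    planned_contrast,
    residual_means_by_inoculum,
    residualize,
    simulate_phenotypes,
    tukey_hsd,
)
from rhizodmm.phenotype import compact_letters

RESP = "aboveground_biomass"


@pytest.fixture(scope="module")
def noiseless_inoculum_effect():
    # balanced design, zero noise, one planted inoculum shift
    return simulate_phenotypes(inoculum_effects={"Col-4x": -20.0}, noise_sd=0.0,
                               n_per_cell=8, seed=0)


class TestAnova:
    def test_planted_between_group_ss_exact(self, noiseless_inoculum_effect):
        tbl = fit_anova3(noiseless_inoculum_effect, RESP)
        # 4 cells of 32 plants each; one mean shifted by -20:
        # SS_between = sum_g n_g (ybar_g - ybar)^2 = 32*(20*3/4)^2 + 3*32*(20/4)^2
        expected = 32 * 15.0 ** 2 + 3 * 32 * 5.0 ** 2
        assert tbl.loc["inoculum", "sum_sq"] == pytest.approx(expected, rel=1e-10)
        assert tbl.loc["genotype", "sum_sq"] == pytest.approx(0.0, abs=1e-8)
        assert tbl.loc["block", "sum_sq"] == pytest.approx(0.0, abs=1e-8)

    def test_df_partition(self):
        tbl = fit_anova3(simulate_phenotypes(noise_sd=1.0, n_per_cell=4, seed=2), RESP)
        n = 4 * 4 * 4
        assert tbl["df"].sum() == pytest.approx(n - 1)

    def test_row_order_invariance(self):
        data = simulate_phenotypes(noise_sd=3.0, n_per_cell=4, seed=5)
        t1 = fit_anova3(data, RESP)
        t2 = fit_anova3(data.sample(frac=1, random_state=0), RESP)
        pd.testing.assert_frame_equal(t1, t2)

    def test_constant_response_warns_with_nan_f(self):
        data = simulate_phenotypes(noise_sd=0.0, n_per_cell=4, seed=0)
        with pytest.warns(UserWarning, match="constant response"):
            tbl = fit_anova3(data, RESP)
        assert np.isnan(tbl.loc["inoculum", "F"]) or tbl.loc["inoculum", "sum_sq"] == 0

    def test_sequential_equals_marginal_on_balanced_data(self):
        data = simulate_phenotypes(inoculum_effects={"Ler-2x": 4.0},
                                   genotype_effects={"Col-2x": -3.0},
                                   noise_sd=2.0, n_per_cell=4, seed=7)
        fwd = fit_anova3(data, RESP, factors=("inoculum", "genotype", "block"))
        rev = fit_anova3(data, RESP, factors=("block", "genotype", "inoculum"))
        for term in ("inoculum", "genotype", "block"):
            assert fwd.loc[term, "sum_sq"] == pytest.approx(rev.loc[term, "sum_sq"],
                                                            rel=1e-8)

    def test_single_level_factor_rejected(self):
        data = simulate_phenotypes(n_per_cell=2, seed=1)
        data["block"] = "B1"
        with pytest.raises(ValueError, match="block"):
            fit_anova3(data, RESP)


class TestResidualize:
    def test_zero_nuisance_effects_residuals_are_centered_response(self):
        data = simulate_phenotypes(inoculum_effects={"Col-4x": -10.0}, noise_sd=0.0,
                                   n_per_cell=4, seed=0)
        res = residualize(data, RESP)
        expected = data[RESP] - data[RESP].mean()
        np.testing.assert_allclose(res, expected, atol=1e-9)

    def test_residuals_sum_to_zero(self):
        data = simulate_phenotypes(genotype_effects={"Col-2x": 5.0}, noise_sd=2.0,
                                   n_per_cell=4, seed=3)
        assert residualize(data, RESP).sum() == pytest.approx(0.0, abs=1e-8)

    def test_planted_negative_inoculum_effect_visible_in_residual_means(self):
        delta = -20.0
        data = simulate_phenotypes(inoculum_effects={"Col-4x": delta},
                                   genotype_effects={"Ler-4x": 7.0},
                                   noise_sd=2.0, n_per_cell=24, seed=11)
        means = residual_means_by_inoculum(data, RESP)
        others = means.drop("Col-4x")["mean"].mean()
        se = 2.0 / np.sqrt(24 * 4)
        assert means.loc["Col-4x", "mean"] - others == pytest.approx(delta, abs=6 * se)
        assert means.loc["Col-4x", "mean"] < means.drop("Col-4x")["mean"].min()


class TestTukey:
    def test_matches_r_tukeyhsd_reference(self):
        # frozen oracle: R aov + TukeyHSD on a 3-group one-way fixture
        data = pd.DataFrame({
            "y": [10, 12, 11, 13, 14, 15, 13, 16, 20, 22, 21, 19],
            "g": list("AAAABBBBCCCC"),
        })
        table = tukey_hsd(data, "y", "g", model_factors=())
        expected = {("A", "B"): 0.023173004330634,
                    ("A", "C"): 0.000010764002463,
                    ("B", "C"): 0.000269948342627}
        for row in table.itertuples():
            key = tuple(sorted((row.level_1, row.level_2)))
            assert row.p_adj == pytest.approx(expected[key], abs=1e-6)

    def test_separated_groups_get_distinct_letters(self):
        data = simulate_phenotypes(inoculum_effects={"Col-4x": -50.0}, noise_sd=0.5,
                                   n_per_cell=6, seed=2)
        table = tukey_hsd(data, RESP, "inoculum")
        letters = table.attrs["letters"]
        assert letters["Col-4x"] != letters["Col-2x"]
        assert letters["Col-2x"] == letters["Ler-2x"] == letters["Ler-4x"]

    def test_identical_groups_share_a_letter(self):
        data = simulate_phenotypes(noise_sd=1.0, n_per_cell=6, seed=3)
        letters = tukey_hsd(data, RESP, "inoculum").attrs["letters"]
        assert len(set(letters)) == 1

    def test_adjusted_p_at_least_unadjusted(self):
        data = simulate_phenotypes(inoculum_effects={"Ler-2x": 3.0}, noise_sd=4.0,
                                   n_per_cell=8, seed=4)
        table = tukey_hsd(data, RESP, "inoculum")
        for row in table.itertuples():
            _, _, p_un = planned_contrast(data, RESP, (row.level_1, row.level_2))
            assert row.p_adj >= p_un - 1e-12

    def test_small_level_rejected(self):
        data = simulate_phenotypes(n_per_cell=2, seed=0)
        data = pd.concat([data, pd.DataFrame([{**data.iloc[0].to_dict(),
                                               "inoculum": "lonely"}])])
        with pytest.raises(ValueError, match="lonely"):
            tukey_hsd(data, RESP, "inoculum")


class TestPlannedContrast:
    def test_antisymmetry(self):
        data = simulate_phenotypes(inoculum_effects={"Col-2x": 2.0}, noise_sd=3.0,
                                   n_per_cell=6, seed=6)
        e1, t1, p1 = planned_contrast(data, RESP, ("Col-2x", "Col-4x"))
        e2, t2, p2 = planned_contrast(data, RESP, ("Col-4x", "Col-2x"))
        assert e1 == pytest.approx(-e2) and t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_identical_means_give_near_zero_estimate(self):
        data = simulate_phenotypes(noise_sd=0.0, n_per_cell=4, seed=0)
        data.loc[data.inoculum == "Ler-2x", RESP] += 1e-9  # break exact constancy
        est, t, p = planned_contrast(data, RESP, ("Col-2x", "Col-4x"))
        assert est == pytest.approx(0.0, abs=1e-8)

    def test_power_matches_noncentral_t_closed_form(self):
        # planted difference delta, noise sigma: reject rate at alpha=0.05
        # follows the noncentral-t formula with ncp = delta / (sigma*sqrt(2/n))
        from scipy.stats import nct, t as t_dist

        delta, sigma, n_cell = 3.0, 4.0, 24
        n_reps = 200
        alpha = 0.05
        hits = 0
        for r in range(n_reps):
            data = simulate_phenotypes(inoculum_effects={"Col-4x": delta},
                                       noise_sd=sigma, n_per_cell=n_cell, seed=1000 + r)
            _, _, p = planned_contrast(data, RESP, ("Col-4x", "Col-2x"))
            hits += p < alpha
        n_level = n_cell * 4  # plants per inoculum level
        dfres = 16 * n_cell - 1 - 3 - 3 - 3
        ncp = delta / (sigma * np.sqrt(2 / n_level))
        crit = t_dist.ppf(1 - alpha / 2, dfres)
        power = nct.sf(crit, dfres, ncp) + nct.cdf(-crit, dfres, ncp)
        se_sim = np.sqrt(power * (1 - power) / n_reps)
        assert hits / n_reps == pytest.approx(power, abs=4 * se_sim + 0.01)
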