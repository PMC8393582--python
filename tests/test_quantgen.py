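"""Sib model, EBVs, ANOVA/Duncan, frequencies, effect decomposition."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from slafbsa.config import SimulationConfig
from slafbsa.quantgen import (
    SibModel,
    check_normality,
    compute_frequencies,
    duncan_letters,
    genotype_trait_anova,
    genotypic_effects,
    select_extreme_groups,
)
from slafbsa.simulate import simulate_population


def sib_frame(n_sires=30, dams=4, prog=6, h2=0.29, seed=0, sd=0.5):
    cfg = SimulationConfig(
        n_sires=n_sires, dams_per_sire=dams, progeny_per_dam=prog,
        trait_sd=sd, heritability=h2, n_loci=2, n_causal=0,
        causal_effect_sizes=[], causal_modes=[], female_offset=0.0, seed=seed,
    )
    pop = simulate_population(cfg)
    return pop, pop.progeny[["id", "sire", "dam", "mw"]]


class TestNormalityCheck:
    def test_gaussian_accepted_mostly(self, rng):
        rejections = sum(
            check_normality(rng.normal(size=200))[1] < 0.05 for _ in range(100)
        )
        assert rejections <= 15

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            check_normality([4.1] * 50)

    def test_too_few_observations(self):
        with pytest.raises(ValueError):
            check_normality([1.0, 2.0])

    def test_exponential_detected(self, rng):
        rejections = sum(
            check_normality(rng.exponential(size=200))[1] < 0.05
            for _ in range(40)
        )
        assert rejections >= 38  # >= 95% power


class TestVarianceComponents:
    def test_recovery_of_simulated_heritability(self):
        h2s = []
        for seed in range(15):
            _, d = sib_frame(n_sires=100, dams=5, prog=8, seed=seed)
            h2s.append(SibModel(d).fit().h2)
        assert np.mean(h2s) == pytest.approx(0.29, abs=0.08)

    def test_null_heritability_near_zero(self):
        h2s = []
        for seed in range(10):
            cfg = SimulationConfig(
                n_sires=100, dams_per_sire=5, progeny_per_dam=8,
                heritability=1e-6, n_loci=2, n_causal=0,
                causal_effect_sizes=[], causal_modes=[],
                female_offset=0.0, seed=seed,
            )
            pop = simulate_population(cfg)
            h2s.append(SibModel(pop.progeny[["id", "sire", "dam", "mw"]]).fit().h2)
        assert np.mean(h2s) <= 0.05

    def test_scale_equivariance(self):
        _, d = sib_frame(seed=3)
        r1 = SibModel(d).fit()
        d2 = d.copy()
        d2["mw"] = 2.0 * d2["mw"]
        r2 = SibModel(d2).fit()
        assert r2.vc.sigma2_A == pytest.approx(4.0 * r1.vc.sigma2_A, rel=1e-10)
        assert r2.vc.sigma2_e == pytest.approx(4.0 * r1.vc.sigma2_e, rel=1e-10)
        assert r2.h2 == pytest.approx(r1.h2, rel=1e-10)

    def test_single_family_inestimable(self):
        d = pd.DataFrame(
            {
                "id": ["a", "b", "c"],
                "sire": ["s1"] * 3,
                "dam": ["d1"] * 3,
                "mw": [4.0, 4.1, 4.2],
            }
        )
        with pytest.raises(ValueError):
            SibModel(d)

    def test_h2w_definitions(self):
        _, d = sib_frame(seed=4)
        res_r = SibModel(d).fit("residual")
        res_p = SibModel(d).fit("phenotypic")
        sigma2_p = (
            res_r.vc.sigma2_sire + res_r.vc.sigma2_dam + res_r.vc.sigma2_within
        )
        assert res_r.h2_w == pytest.approx(
            0.5 * res_r.vc.sigma2_A / res_r.vc.sigma2_e, rel=1e-12
        )
        assert res_p.h2_w == pytest.approx(
            0.5 * res_p.vc.sigma2_A / sigma2_p, rel=1e-12
        )


class TestEbv:
    def test_equal_phenotypes_zero_ebv(self):
        _, d = sib_frame(seed=5)
        d = d.copy()
        d["mw"] = 4.11
        res = SibModel(d).fit()
        assert np.allclose(res.ebv["ebv"], 0.0)

    def test_population_mean_near_zero(self, standard_population):
        res = SibModel.from_population(
            standard_population, sex=None, adjust_sex=True
        ).fit()
        assert abs(res.ebv["ebv"].mean()) < 0.02

    def test_correlation_with_true_breeding_value(self, standard_population):
        res = SibModel.from_population(
            standard_population, sex=None, adjust_sex=True
        ).fit()
        merged = res.ebv.merge(
            standard_population.pedigree[["id", "true_bv"]], on="id"
        )
        corr = np.corrcoef(merged["ebv"], merged["true_bv"])[0, 1]
        assert corr >= 0.4

    def test_parent_average_regression(self, standard_population):
        # EBV decomposes into parent-average plus shrunken within-family
        # deviation: regressing EBV on the family-mean EBV gives slope ~ 1
        res = SibModel.from_population(
            standard_population, sex=None, adjust_sex=True
        ).fit()
        ebv = res.ebv.copy()
        fam = ebv.groupby("dam")["ebv"].transform("mean")
        slope = np.polyfit(fam, ebv["ebv"], 1)[0]
        assert slope == pytest.approx(1.0, abs=0.1)

    def test_summary_mentions_components(self, standard_population):
        res = SibModel.from_population(standard_population, "M").fit()
        text = res.summary()
        assert "sigma2_A" in text and "h2" in text


class TestExtremeGroups:
    def test_disjoint_tails(self):
        ebv = pd.DataFrame(
            {"id": [f"i{k}" for k in range(167)],
             "ebv": np.linspace(-1, 1, 167)}
        )
        low, high = select_extreme_groups(ebv, 20)
        assert len(low) == len(high) == 20
        assert not set(low) & set(high)

    def test_min_max_single(self):
        ebv = pd.DataFrame({"id": ["a", "b", "c"], "ebv": [0.3, -0.1, 0.9]})
        low, high = select_extreme_groups(ebv, 1)
        assert low == ["b"] and high == ["c"]

    def test_selection_differential_positive(self, rng):
        ebv = pd.DataFrame(
            {"id": [f"i{k}" for k in range(100)], "ebv": rng.normal(size=100)}
        )
        low, high = select_extreme_groups(ebv, 10)
        lo = ebv.set_index("id").loc[low, "ebv"].mean()
        hi = ebv.set_index("id").loc[high, "ebv"].mean()
        assert hi > lo

    def test_too_large_tail(self):
        ebv = pd.DataFrame({"id": ["a", "b"], "ebv": [0.0, 1.0]})
        with pytest.raises(ValueError):
            select_extreme_groups(ebv, 2)


class TestAnovaDuncan:
    def test_two_groups_reduce_to_t_test(self, rng):
        y1, y2 = rng.normal(4.0, 0.2, 30), rng.normal(4.2, 0.2, 30)
        g = ["AA"] * 30 + ["GG"] * 30
        res = genotype_trait_anova(g, np.concatenate([y1, y2]))
        t, _ = stats.ttest_ind(y1, y2)
        assert res.f == pytest.approx(t**2, abs=1e-9)

    def test_degenerate_zero_variance(self):
        with pytest.raises(ValueError):
            genotype_trait_anova(["AA"] * 5 + ["GG"] * 5, [4.0] * 10)

    def test_small_class_dropped_with_warning(self, rng):
        g = ["AA"] * 20 + ["AG"] * 20 + ["GG"]
        y = rng.normal(4.0, 0.2, 41)
        with pytest.warns(UserWarning, match="GG"):
            res = genotype_trait_anova(g, y)
        assert "GG" not in res.letters

    def test_separated_group_gets_distinct_letter(self, rng):
        distinct = 0
        n_rep = 40
        for _ in range(n_rep):
            y = np.concatenate(
                [
                    rng.normal(4.0, 0.2, 30),
                    rng.normal(4.0, 0.2, 30),
                    rng.normal(4.5, 0.2, 30),
                ]
            )
            g = ["AA"] * 30 + ["AG"] * 30 + ["GG"] * 30
            res = genotype_trait_anova(g, y)
            others = set(res.letters["AA"]) | set(res.letters["AG"])
            if not (set(res.letters["GG"]) & others):
                distinct += 1
        assert distinct >= int(0.95 * n_rep)

    def test_letters_share_when_equal(self, rng):
        y = rng.normal(4.0, 0.2, 60)
        g = ["AA"] * 30 + ["GG"] * 30
        res = genotype_trait_anova(g, y)
        if res.p > 0.2:
            assert set(res.letters["AA"]) & set(res.letters["GG"])

    def test_duncan_letters_order_consistent(self):
        means = pd.Series({"AA": 4.6, "AG": 4.3, "GG": 4.0})
        sizes = pd.Series({"AA": 30, "AG": 30, "GG": 30})
        letters = duncan_letters(means, sizes, ms_error=0.04, df_error=87)
        assert letters["AA"] != letters["GG"]


class TestFrequencies:
    def test_hardy_weinberg_counts(self):
        g = ["AA"] * 25 + ["Aa"] * 50 + ["aa"] * 25
        allele, geno = compute_frequencies(g)
        assert allele["A"] == pytest.approx(0.5)
        assert geno["Aa"] == pytest.approx(0.5)
        assert geno["AA"] == pytest.approx(0.25)

    def test_fixed_locus(self):
        allele, geno = compute_frequencies(["AA"] * 10)
        assert allele == {"A": 1.0} and geno == {"AA": 1.0}

    def test_sums_to_one(self, rng):
        g = rng.choice(["AA", "AG", "GG"], size=500, p=[0.49, 0.42, 0.09])
        allele, geno = compute_frequencies(list(g))
        assert sum(allele.values()) == pytest.approx(1.0, abs=1e-12)
        assert sum(geno.values()) == pytest.approx(1.0, abs=1e-12)

    def test_large_sample_binomial_concentration(self, rng):
        dosage = rng.binomial(2, 0.3, 10000)
        strings = np.array(["AA", "AG", "GG"])[dosage]
        allele, _ = compute_frequencies(list(strings))
        assert allele["G"] == pytest.approx(0.3, abs=0.01)

    def test_all_missing(self):
        with pytest.raises(ValueError):
            compute_frequencies([None, float("nan")])


class TestGenotypicEffects:
    def test_null_trait_no_effects(self, rng):
        dosage = rng.binomial(2, 0.5, 300)
        y = rng.normal(4.0, 0.3, 300)
        eff = genotypic_effects(dosage, y, "L1")
        for fit in (eff.additive, eff.dominance, eff.recessive):
            assert abs(fit.effect) < 0.15 and fit.se > 0

    def test_additive_recovery_and_aic_preference(self, rng):
        est, aic_wins = [], 0
        n_rep = 10
        for _ in range(n_rep):
            dosage = rng.binomial(2, 0.5, 500)
            y = 4.0 + 0.1 * dosage + rng.normal(0, 0.3, 500)
            eff = genotypic_effects(dosage, y, "L1")
            est.append(eff.additive.effect)
            aic_wins += eff.additive.aic < eff.dominance.aic
        assert np.mean(est) == pytest.approx(0.1, abs=0.04)
        assert aic_wins >= int(0.8 * n_rep)

    def test_recessive_without_alt_homozygotes_inestimable(self, rng):
        dosage = np.array([0, 1] * 50)
        y = rng.normal(4.0, 0.2, 100)
        eff = genotypic_effects(dosage, y, "L1")
        assert not eff.recessive.estimable
        assert eff.additive.estimable

    def test_monomorphic_raises(self):
        with pytest.raises(ValueError):
            genotypic_effects([1] * 20, np.random.default_rng(0).normal(size=20))
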