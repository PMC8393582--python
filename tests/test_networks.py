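"""Mode codings, stepwise SNP-network search, Spearman clustering."""

import numpy as np
import pandas as pd
import pytest

from slafbsa.networks import (
    MODE_CODES,
    fit_single_snp_modes,
    spearman_matrix,
    stepwise_network_search,
    substitution_effects,
)


def make_dosages(rng, n=400, n_loci=10, freqs=None):
    freqs = freqs if freqs is not None else rng.uniform(0.2, 0.8, n_loci)
    return pd.DataFrame(
        {f"L{j:02d}": rng.binomial(2, freqs[j], n) for j in range(n_loci)}
    )


class TestModeCodes:
    def test_coding_invariants(self):
        for mode, (c0, c1, c2) in MODE_CODES.items():
            if mode == "additive":
                assert c1 == pytest.approx((c0 + c2) / 2)
            elif mode.startswith("dominant"):
                assert c1 in (c0, c2)
            else:  # over-dominant: het outside the homozygote interval
                assert not min(c0, c2) < c1 < max(c0, c2) or c0 == c2


class TestSingleSnpModes:
    def test_additive_locus_selected(self, rng):
        wins = 0
        n_rep = 20
        for _ in range(n_rep):
            g = rng.binomial(2, 0.5, 400)
            y = 4.0 + 0.15 * g + rng.normal(0, 0.4, 400)
            coding, _ = fit_single_snp_modes(g, y, "L")
            wins += coding.mode == "additive"
        assert wins >= int(0.8 * n_rep)

    def test_dominant_locus_selected(self, rng):
        wins = 0
        n_rep = 20
        for _ in range(n_rep):
            g = rng.binomial(2, 0.5, 400)
            y = 4.0 + 0.3 * (g > 0) + rng.normal(0, 0.4, 400)
            coding, _ = fit_single_snp_modes(g, y, "L")
            wins += coding.mode == "dominant_alt"
        assert wins >= int(0.8 * n_rep)

    def test_null_locus_fails_entry(self, rng):
        fails = 0
        n_rep = 20
        for _ in range(n_rep):
            g = rng.binomial(2, 0.5, 400)
            y = rng.normal(4.0, 0.4, 400)
            _, fit = fit_single_snp_modes(g, y, "L")
            fails += fit["p"][1] >= 0.05
        assert fails >= int(0.7 * n_rep)

    def test_monomorphic_raises(self, rng):
        with pytest.raises(ValueError):
            fit_single_snp_modes([2] * 50, rng.normal(size=50))


class TestStepwiseSearch:
    def plant(self, rng, effects, n=400, n_loci=10):
        dos = make_dosages(rng, n, n_loci)
        y = 4.0 + rng.normal(0, 0.4, n)
        for locus, eff in effects.items():
            y = y + eff * dos[locus].to_numpy()
        return dos, y

    def test_two_causal_loci_recovered(self, rng):
        wins = 0
        n_rep = 25
        for _ in range(n_rep):
            dos, y = self.plant(rng, {"L00": 0.2, "L01": 0.2})
            nets = stepwise_network_search(dos, y, direction="forward")
            if nets and {"L00", "L01"} <= set(nets[0].members):
                wins += 1
        assert wins >= int(0.8 * n_rep)

    def test_single_causal_with_null_partner_forms_no_network(self, rng):
        # one causal locus plus one null partner: a two-locus network should
        # rarely survive the entry/stay threshold
        spurious = 0
        n_rep = 25
        for _ in range(n_rep):
            dos, y = self.plant(rng, {"L00": 0.25}, n_loci=2)
            nets = stepwise_network_search(dos, y, direction="forward")
            if any(n.size >= 2 for n in nets):
                spurious += 1
        assert spurious <= int(0.2 * n_rep)

    def test_forward_backward_agree_on_orthogonal_predictors(self, rng):
        dos, y = self.plant(rng, {"L00": 0.25, "L01": 0.2, "L02": 0.2})
        fwd = stepwise_network_search(dos, y, direction="forward")
        bwd = stepwise_network_search(dos, y, direction="backward")
        assert fwd and bwd
        assert set(fwd[0].members) == set(bwd[0].members)

    def test_nesting_never_hurts_r2(self, rng):
        dos, y = self.plant(rng, {"L00": 0.3, "L01": 0.25, "L02": 0.2})
        nets = stepwise_network_search(dos, y, direction="forward", max_size=4)
        by_members = {frozenset(n.members): n for n in nets}
        for members, net in by_members.items():
            for other, net2 in by_members.items():
                if members < other:
                    assert net2.r2 >= net.r2 - 1e-12

    def test_collinear_duplicate_dropped(self, rng):
        dos, y = self.plant(rng, {"L00": 0.3})
        dos["L01"] = dos["L00"]  # perfect collinearity
        with pytest.warns(UserWarning, match="collinear"):
            nets = stepwise_network_search(
                dos, y, candidate_loci=["L00", "L01"], direction="backward"
            )
        assert all(not {"L00", "L01"} <= set(n.members) for n in nets)


class TestSubstitutionEffects:
    def fit_network(self, rng, effects):
        dos = make_dosages(rng, 600, 6, freqs=[0.5] * 6)
        y = 4.0 + rng.normal(0, 0.3, 600)
        for locus, eff in effects.items():
            y = y + eff * dos[locus].to_numpy()
        nets = stepwise_network_search(dos, y, direction="forward")
        assert nets
        return nets[0]

    def test_additive_effect_doubles_to_grams(self, rng):
        net = self.fit_network(rng, {"L00": 0.1, "L01": 0.15})
        for locus in net.members:
            if net.codings[locus].mode == "additive":
                assert net.substitution_effects_g[locus] == pytest.approx(
                    2000.0 * net.coefficients[locus]
                )

    def test_known_homozygote_gap_recovered(self, rng):
        # planted additive effect 0.15/allele -> homozygote gap 0.3 kg
        net = self.fit_network(rng, {"L00": 0.15, "L01": 0.15})
        subs = [net.substitution_effects_g[m] for m in net.members
                if m in ("L00", "L01")]
        for s in subs:
            assert s == pytest.approx(300.0, abs=60.0)

    def test_orientation_flip_changes_sign_only(self, rng):
        net = self.fit_network(rng, {"L00": 0.15, "L01": 0.12})
        dos = make_dosages(rng, 600, 6, freqs=[0.5] * 6)
        # flipping ref/alt orientation of the dosage flips the effect sign
        y = 4.0 + 0.15 * dos["L00"] + 0.12 * dos["L01"] + rng.normal(0, 0.3, 600)
        flipped = dos.copy()
        flipped["L00"] = 2 - flipped["L00"]
        nets = stepwise_network_search(flipped, y, direction="forward")
        assert nets
        net_f = nets[0]
        if "L00" in net_f.substitution_effects_g and "L00" in net.substitution_effects_g:
            assert np.sign(net_f.substitution_effects_g["L00"]) == -np.sign(
                net.substitution_effects_g["L00"]
            )

    def test_over_dominant_excluded_by_default(self, rng):
        g = rng.binomial(2, 0.5, 500)
        y = 4.0 + 0.4 * (g == 1) + rng.normal(0, 0.2, 500)
        g2 = rng.binomial(2, 0.5, 500)
        y = y + 0.3 * g2
        dos = pd.DataFrame({"L00": g, "L01": g2})
        nets = stepwise_network_search(dos, y, direction="forward")
        assert nets
        net = nets[0]
        od = [m for m in net.members if net.codings[m].mode == "over_dominant"]
        for m in od:
            assert m not in net.substitution_effects_g
            assert substitution_effects(net, include_over_dominant=True)[m] == 0.0


class TestSpearman:
    def test_self_correlation(self, rng):
        x = rng.normal(size=30)
        df = pd.DataFrame({"a": x, "b": x})
        rho, _ = spearman_matrix(df)
        assert rho.loc["a", "b"] == pytest.approx(1.0)

    def test_decreasing_transform(self, rng):
        x = rng.normal(size=30)
        df = pd.DataFrame({"a": x, "b": -(x**3)})
        rho, _ = spearman_matrix(df)
        assert rho.loc["a", "b"] == pytest.approx(-1.0)

    def test_hand_computed_rank_correlation(self):
        df = pd.DataFrame({"x": [1, 2, 3, 4, 5], "y": [2, 1, 4, 3, 5]})
        rho, _ = spearman_matrix(df)
        # sum d^2 = 4 -> rho = 1 - 6*4 / (5*24) = 0.8
        assert rho.loc["x", "y"] == pytest.approx(0.8, abs=1e-12)

    def test_constant_column_missing(self, rng):
        df = pd.DataFrame({"a": rng.normal(size=20), "b": np.ones(20)})
        rho, _ = spearman_matrix(df)
        assert np.isnan(rho.loc["a", "b"])

    def test_cluster_order_is_permutation(self, rng):
        df = pd.DataFrame(rng.normal(size=(40, 5)), columns=list("abcde"))
        rho, order = spearman_matrix(df)
        assert sorted(order) == list("abcde")
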