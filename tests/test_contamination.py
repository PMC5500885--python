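"""The three contamination estimators: printed-count arithmetic, diagnostic
site classification, and parameter recovery on simulated read sets."""

import numpy as np
import pytest

import paleomito as pm
from paleomito.contamination import panel_likelihood_curve


class TestCountBased:
    def test_printed_counts_reproduce_published_estimate(self):
        """239 endogenous vs 23 contaminant reads over the transversion
        sites -> 8.8% with Wald 95% CI 5.4-12.2%."""
        est = pm.count_based_estimate(239, 23)
        assert round(100 * est.point, 1) == 8.8
        assert round(100 * est.ci_low, 1) == 5.4
        assert round(100 * est.ci_high, 1) == 12.2
        assert est.n_support == 262

    def test_zero_contaminant_reads(self):
        est = pm.count_based_estimate(100, 0)
        assert est.point == 0.0
        assert est.ci_low == 0.0

    def test_hand_evaluated_wald_interval(self):
        # p = 13/100, CI = p +/- 1.96*sqrt(p(1-p)/100)
        est = pm.count_based_estimate(87, 13)
        assert round(100 * est.point, 1) == 13.0
        assert round(100 * est.ci_low, 1) == 6.4
        assert round(100 * est.ci_high, 1) == 19.6

    def test_wilson_interval_contains_point(self):
        est = pm.count_based_estimate(87, 13, ci_method="wilson")
        assert est.ci_low < est.point < est.ci_high

    def test_empty_counts_rejected(self):
        with pytest.raises(ValueError):
            pm.count_based_estimate(0, 0)


class TestDiagnosticSites:
    def make_panel(self, column, length=20, pos=5):
        """Panel of haplotypes all 'A' except the given column bases."""
        out = []
        for k, b in enumerate(column):
            seq = list("A" * length)
            seq[pos - 1] = b
            out.append(pm.Haplotype(f"p{k}", "".join(seq)))
        return out

    def test_fixed_panel_difference_is_diagnostic_transversion(self):
        cons = pm.Haplotype("c", "A" * 4 + "C" + "A" * 15)
        panel = self.make_panel(["A"] * 100)
        sites = pm.find_diagnostic_sites(cons, panel)
        assert len(sites) == 1
        s = sites[0]
        assert (s.position, s.endo_base, s.panel_major) == (5, "C", "A")
        assert s.subst_class == "transversion"  # A<->C is purine<->pyrimidine

    def test_shared_base_above_threshold_excluded(self):
        cons = pm.Haplotype("c", "A" * 4 + "C" + "A" * 15)
        panel = self.make_panel(["C"] * 2 + ["A"] * 98)  # 2% share consensus base
        assert pm.find_diagnostic_sites(cons, panel, max_panel_freq=0.01) == []

    def test_transition_site_excluded_from_transversion_subset(self):
        cons = pm.Haplotype("c", "A" * 4 + "C" + "A" * 15)
        panel = self.make_panel(["T"] * 100)  # C<->T transition
        sites = pm.find_diagnostic_sites(cons, panel)
        assert sites[0].subst_class == "transition"
        assert (
            pm.find_diagnostic_sites(cons, panel, transversions_only=True) == []
        )

    def test_misaligned_panel_rejected(self):
        cons = pm.Haplotype("c", "ACGT")
        with pytest.raises(ValueError, match="length"):
            pm.find_diagnostic_sites(cons, [pm.Haplotype("p", "ACG")] * 2)


class TestDamageConditioned:
    def test_recovers_ten_percent_contamination(self, frags_c10, endo, damage_cond_mean_c10):
        est = pm.conditional_damage_estimate(frags_c10, endo)
        assert est.ci_low <= est.point <= est.ci_high
        mean, _ = damage_cond_mean_c10
        assert abs(mean - 0.10) <= 0.03

    def test_near_zero_without_contamination(self, damage_cond_mean_c0):
        mean, _ = damage_cond_mean_c0
        assert mean <= 0.02

    def test_damaged_contaminant_bias_is_marginal(self, endo, cont):
        """A mildly damaged contaminant (terminal rate 0.1) biases the
        estimate downward, but only marginally when the endogenous terminal
        damage is 0.5."""
        frags = pm.simulate_fragments(
            endo,
            cont,
            n=50_000,
            cont_fraction=0.10,
            cont_damage=pm.DamageModel(0.1, 0.1, 0.5),
            seed=77,
        )
        est = pm.conditional_damage_estimate(frags, endo)
        assert abs(est.point - 0.10) <= 0.05

    def test_undamaged_data_has_no_conditioning_set(self, endo):
        frags = pm.simulate_fragments(
            endo, None, n=200, damage=pm.DamageModel.none(), qual=90, seed=1
        )
        with pytest.raises(ValueError, match="conditioned"):
            pm.conditional_damage_estimate(frags, endo)


class TestPanelLikelihood:
    def test_recovers_ten_percent_contamination(
        self, frags_c10, pileup_c10, endo, panel, called_consensus_c10
    ):
        cons, profile = called_consensus_c10
        est = pm.panel_likelihood_estimate(
            frags_c10, cons, panel, damage=profile, pileup=pileup_c10
        )
        assert abs(est.point - 0.10) <= 0.03
        assert est.ci_low <= est.point <= est.ci_high

    def test_near_zero_without_contamination(
        self, frags_c0, pileup_c0, endo, panel
    ):
        profile = pm.estimate_damage_profile(pileup_c0, endo)
        est = pm.panel_likelihood_estimate(
            frags_c0, endo, panel, damage=profile, pileup=pileup_c0
        )
        assert est.point <= 0.02

    def test_likelihood_peaks_near_truth_across_replicates(self, endo, cont, panel):
        """log L(c_true) > log L(c_true + 0.2) in >= 95% of 100 replicates."""
        wins = 0
        for rep in range(100):
            frags = pm.simulate_fragments(
                endo, cont, n=2000, cont_fraction=0.10, seed=3000 + rep
            )
            pu = pm.build_pileup(frags, L=len(endo))
            profile = pm.estimate_damage_profile(pu, endo)
            cs, ll, _ = panel_likelihood_curve(
                frags, endo, panel, damage=profile, grid=0.05, pileup=pu
            )
            i_true = int(np.argmin(np.abs(cs - 0.10)))
            i_off = int(np.argmin(np.abs(cs - 0.30)))
            wins += ll[i_true] > ll[i_off]
        assert wins >= 95

    def test_no_diagnostic_coverage_rejected(self, endo, panel):
        with pytest.raises(ValueError, match="coverage"):
            pm.panel_likelihood_estimate([], endo, panel)


class TestEstimatorConcordance:
    def test_all_three_agree_on_shared_data(
        self, frags_c10, pileup_c10, panel, called_consensus_c10
    ):
        """Mirrors the concordant ~9-12% range across methods on real data."""
        cons, profile = called_consensus_c10
        dam = pm.conditional_damage_estimate(frags_c10, cons)
        tv = pm.find_diagnostic_sites(cons, panel, transversions_only=True)
        n_endo, n_cont = pm.count_reads_at_sites(pileup_c10, tv)
        cnt = pm.count_based_estimate(n_endo, n_cont)
        lik = pm.panel_likelihood_estimate(
            frags_c10, cons, panel, damage=profile, pileup=pileup_c10
        )
        points = [dam.point, cnt.point, lik.point]
        assert max(points) - min(points) <= 0.06  # pairwise within +/-0.03

    def test_ci_width_shrinks_as_root_n(self):
        w = []
        for n in (100, 400, 1600):
            est = pm.count_based_estimate(9 * n // 10, n // 10)
            w.append(est.ci_high - est.ci_low)
        assert w[0] / w[1] == pytest.approx(2.0, rel=0.05)
        assert w[1] / w[2] == pytest.approx(2.0, rel=0.05)

    def test_transversion_restriction_removes_damage_bias(self, endo, cont, panel):
        """Counting transition sites inflates the contaminant fraction on
        damage-heavy data because terminal C->T deamination mimics the modern
        variant; the transversion-only subset is unbiased."""
        frags = pm.simulate_fragments(
            endo,
            cont,
            n=30_000,
            cont_fraction=0.10,
            damage=pm.DamageModel(0.5, 0.5, 0.8),  # slow decay: damage-heavy
            seed=55,
        )
        pu = pm.build_pileup(frags, L=len(endo))
        all_sites = pm.find_diagnostic_sites(endo, panel)
        tv_sites = [s for s in all_sites if s.subst_class == "transversion"]
        n_e, n_c = pm.count_reads_at_sites(pu, all_sites)
        est_all = pm.count_based_estimate(n_e, n_c)
        n_e, n_c = pm.count_reads_at_sites(pu, tv_sites)
        est_tv = pm.count_based_estimate(n_e, n_c)
        assert est_all.point > est_tv.point  # transitions absorb damage
        assert abs(est_tv.point - 0.10) <= 0.03
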