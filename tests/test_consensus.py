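"""Pileup construction, damage-profile estimation, the damage-aware caller
and region masking."""

from collections import Counter

import numpy as np
import pytest

import paleomito as pm
from paleomito.consensus import DamageProfile


def frag(start, bases, strand="+", qual=30):
    return pm.AlignedFragment(
        start=start, strand=strand, bases=bases, quals=np.full(len(bases), qual)
    )


class TestBuildPileup:
    def test_single_linear_fragment_depths(self):
        pu = pm.build_pileup([frag(1, "A" * 30)], L=100, circular=False)
        depth = pu.depth()
        assert depth[1:31].tolist() == [1] * 30
        assert depth[31:].sum() == 0

    def test_circular_wrap_covers_both_ends(self):
        pu = pm.build_pileup([frag(95, "ACGTACGTAC")], L=100, circular=True)
        covered = set(pu.pos.tolist())
        assert covered == {95, 96, 97, 98, 99, 100, 1, 2, 3, 4}

    def test_empty_fragment_list(self):
        pu = pm.build_pileup([], L=50)
        assert len(pu) == 0
        assert pu.depth().sum() == 0

    def test_terminal_distances_follow_strand(self):
        plus = pm.build_pileup([frag(10, "ACGT", "+")], L=100)
        minus = pm.build_pileup([frag(10, "ACGT", "-")], L=100)
        assert plus.dist5.tolist() == [1, 2, 3, 4]
        assert minus.dist5.tolist() == [4, 3, 2, 1]  # read 5' is the right end
        assert plus.dist3.tolist() == [4, 3, 2, 1]

    def test_start_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="start"):
            pm.build_pileup([frag(101, "AC")], L=100)


class TestDamageProfile:
    def test_clean_pileup_gives_zero_rates(self, endo):
        frags = pm.simulate_fragments(
            endo, None, n=500, damage=pm.DamageModel.none(), qual=90, seed=1
        )
        pu = pm.build_pileup(frags, L=len(endo))
        prof = pm.estimate_damage_profile(pu, endo)
        defined = prof.ct5_n > 0
        assert np.all(prof.ct5[defined] == 0.0)
        # zero-denominator distances are flagged undefined, not 0
        assert np.all(np.isnan(prof.ct5[~defined]))

    def test_terminal_rate_recovered_from_simulation(self, endo):
        frags = pm.simulate_fragments(
            endo, None, n=5000, damage=pm.DamageModel(0.5, 0.5, 0.5), seed=2
        )
        pu = pm.build_pileup(frags, L=len(endo))
        prof = pm.estimate_damage_profile(pu, endo)
        for rate, n in ((prof.ct5[0], prof.ct5_n[0]), (prof.ga3[0], prof.ga3_n[0])):
            se = np.sqrt(0.5 * 0.5 / n)
            assert abs(rate - 0.5) < 3 * se
        # geometric decay: interior rates far below the terminal rate
        assert prof.ct5[4] < prof.ct5[0] / 4

    def test_distances_beyond_fragment_contribute_nothing(self):
        pu = pm.build_pileup([frag(1, "C" * 35)], L=100, circular=False)
        prof = pm.estimate_damage_profile(
            pu, pm.Haplotype("r", "C" * 100, circular=False), max_dist=50
        )
        assert np.all(prof.ct5_n[35:] == 0)


class TestCallConsensus:
    def test_clean_pileup_equals_truth(self, endo):
        frags = pm.simulate_fragments(
            endo, None, n=2000, damage=pm.DamageModel.none(), qual=60, seed=3
        )
        pu = pm.build_pileup(frags, L=len(endo))
        cons = pm.call_consensus(pu)
        assert all(
            a == b for a, b in zip(cons.seq, endo.seq) if a != "N"
        )

    def test_damage_aware_call_discounts_terminal_ts(self):
        """3 reads showing T at 5'-terminal distance 1 (ct5[1]=0.5) against 2
        interior reads showing C: the caller must call C, because terminal T
        is half-expected under damage while interior C is near-certain.

        Hand likelihood at e=0.001: per terminal-T read
        P(T|C) = 0.5*(1-e) + 0.5*e/3 ~ 0.5; per interior-C read
        P(C|C) ~ 0.999, while P(C|T) = e/3, so L(C) >> L(T).
        """
        site = 10
        reads = [frag(site, "T" + "A" * 20) for _ in range(3)]  # T at dist5=1
        reads += [frag(site - 5, "G" * 5 + "C" + "G" * 10) for _ in range(2)]
        pu = pm.build_pileup(reads, L=100)
        prof = DamageProfile.zero(25)
        prof.ct5[0] = 0.5
        cons = pm.call_consensus(pu, damage=prof)
        assert cons.seq[site - 1] == "C"
        # without the damage profile the same pileup calls the majority T
        naive = pm.call_consensus(pu, damage=None)
        assert naive.seq[site - 1] == "T"

    def test_coverage_cutoff_masks_singletons(self):
        pu = pm.build_pileup([frag(1, "A" * 30)], L=100, circular=False)
        relaxed = pm.call_consensus(pu, coverage_cutoff=1)
        strict = pm.call_consensus(pu, coverage_cutoff=2)
        assert relaxed.seq[0] == "A"
        assert strict.seq[:30] == "N" * 30

    def test_raising_cutoff_only_masks_never_flips(self, endo):
        frags = pm.simulate_fragments(endo, None, n=800, seed=4)
        pu = pm.build_pileup(frags, L=len(endo))
        prev = pm.call_consensus(pu, coverage_cutoff=1).seq
        for cutoff in (2, 5, 10):
            cur = pm.call_consensus(pu, coverage_cutoff=cutoff).seq
            assert all(c == "N" or c == p for p, c in zip(prev, cur))
            prev = cur

    def test_majority_vote_equivalence_without_damage(self):
        """With an all-zero damage profile and uniform qualities the caller
        reduces to a per-site majority vote (ties -> N)."""
        rng = np.random.default_rng(9)
        L = 40
        reads = [
            frag(int(rng.integers(1, L + 1)), "".join(rng.choice(list("ACGT"), size=8)))
            for _ in range(60)
        ]
        pu = pm.build_pileup(reads, L=L)
        cons = pm.call_consensus(pu, damage=None)
        votes = {}
        for p, b in zip(pu.pos, pu.base):
            votes.setdefault(int(p), []).append("ACGTN"[b])
        for pos in range(1, L + 1):
            counts = Counter(votes.get(pos, []))
            if not counts:
                assert cons.seq[pos - 1] == "N"
                continue
            top = counts.most_common()
            if len(top) > 1 and top[0][1] == top[1][1]:
                assert cons.seq[pos - 1] == "N"  # tie
            else:
                assert cons.seq[pos - 1] == top[0][0]


class TestApplyMasks:
    def test_poly_c_region_masks_13_sites(self):
        cons = pm.Consensus(seq="A" * 600, posterior=np.ones(600))
        masked = pm.apply_masks(cons, [(303, 315, "poly-C")])
        assert masked.seq.count("N") == 13
        assert masked.seq[302:315] == "N" * 13

    def test_empty_region_list_is_identity(self):
        cons = pm.Consensus(seq="ACGT" * 10, posterior=np.ones(40))
        assert pm.apply_masks(cons, []).seq == cons.seq

    def test_overlapping_regions_mask_union(self):
        cons = pm.Consensus(seq="A" * 30, posterior=np.ones(30))
        masked = pm.apply_masks(cons, [(10, 20), (15, 25)])
        assert masked.seq.count("N") == 16

    def test_masking_is_idempotent(self):
        cons = pm.Consensus(seq="A" * 30, posterior=np.ones(30))
        once = pm.apply_masks(cons, [(5, 10, "m")])
        twice = pm.apply_masks(once, [(5, 10, "m")])
        assert twice.seq == once.seq
        assert twice.mask_annotations == once.mask_annotations

    def test_region_outside_reference_rejected(self):
        cons = pm.Consensus(seq="A" * 30, posterior=np.ones(30))
        with pytest.raises(ValueError, match="outside"):
            pm.apply_masks(cons, [(25, 40)])
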