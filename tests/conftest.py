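"""Shared fixtures: synthetic truth haplotypes, modern panel, and the large
contaminated fragment sets used by the parameter-recovery tests.

The heavy simulated datasets are session-scoped so the recovery and
acceptance tests share one realisation. Study conditions: a 3 kb circular
reference, endogenous/contaminant divergence of 60 transitions + 40
transversions (~3%), terminal deamination 0.5 decaying geometrically,
fragment length ~43 +/- 6 bp, contaminant fraction 0.10.
"""

import numpy as np
import pytest

import paleomito as pm

SEED = 7041  # fixed, arbitrary

L_RECOVERY = 3000
N_FRAGMENTS = 50_000


@pytest.fixture(scope="session")
def endo():
    return pm.random_haplotype(L_RECOVERY, seed=SEED, id="endogenous")


@pytest.fixture(scope="session")
def cont(endo):
    return pm.mutate_haplotype(endo, 60, 40, seed=SEED + 1, id="contaminant")


@pytest.fixture(scope="session")
def panel(cont):
    """40 modern-like haplotypes: contaminant plus private mutations."""
    return [
        pm.mutate_haplotype(cont, 5, 2, seed=SEED + 10 + k, id=f"panel{k}")
        for k in range(40)
    ]


@pytest.fixture(scope="session")
def frags_c10(endo, cont):
    """50k fragments at 10% contamination, terminal damage 0.5."""
    return pm.simulate_fragments(
        endo, cont, n=N_FRAGMENTS, cont_fraction=0.10, seed=SEED + 100
    )


@pytest.fixture(scope="session")
def frags_c0(endo):
    """50k uncontaminated fragments."""
    return pm.simulate_fragments(
        endo, None, n=N_FRAGMENTS, cont_fraction=0.0, seed=SEED + 101
    )


@pytest.fixture(scope="session")
def pileup_c10(frags_c10):
    return pm.build_pileup(frags_c10, L=L_RECOVERY, circular=True)


@pytest.fixture(scope="session")
def pileup_c0(frags_c0):
    return pm.build_pileup(frags_c0, L=L_RECOVERY, circular=True)


@pytest.fixture(scope="session")
def called_consensus_c10(pileup_c10):
    """Two-pass damage-aware consensus on the contaminated data."""
    first = pm.call_consensus(pileup_c10)
    profile = pm.estimate_damage_profile(pileup_c10, first.haplotype())
    final = pm.call_consensus(pileup_c10, damage=profile)
    return final.haplotype(), profile


N_DAMAGE_COND_REPS = 5


def _damage_cond_mean(endo, cont, cont_fraction, first_frags, seed0):
    """Mean damage-conditioning estimate over replicate 50k-fragment
    datasets. The estimator's precision is bounded by the size of the
    damage-conditioned fragment subset, so single-draw checks of its
    recovery are noisy; replicate means measure its behaviour under the
    study conditions."""
    points = [pm.conditional_damage_estimate(first_frags, endo).point]
    for i in range(1, N_DAMAGE_COND_REPS):
        frags = pm.simulate_fragments(
            endo, cont, n=N_FRAGMENTS, cont_fraction=cont_fraction, seed=seed0 + i
        )
        points.append(pm.conditional_damage_estimate(frags, endo).point)
    return float(np.mean(points)), points


@pytest.fixture(scope="session")
def damage_cond_mean_c10(endo, cont, frags_c10):
    return _damage_cond_mean(endo, cont, 0.10, frags_c10, SEED + 200)


@pytest.fixture(scope="session")
def damage_cond_mean_c0(endo, frags_c0):
    return _damage_cond_mean(endo, None, 0.0, frags_c0, SEED + 300)
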