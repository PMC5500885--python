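"""Synthetic ancient-DNA generator.

Produces haplotypes and damaged, contaminated fragment sets with the
statistical structure typical of captured ancient mtDNA libraries: short
fragments (mean ~43 bp, discarded below 30 bp), ~50% C->T deamination at the
molecule termini decaying into the read, and a configurable fraction of
undamaged modern-contaminant fragments. Fragments are ungapped
substitution-only reads with exact placement, so no mapper is needed
downstream.
"""

from __future__ import annotations

import numpy as np

from .core import (
    BASES,
    AlignedFragment,
    DamageModel,
    Haplotype,
    decode,
    encode,
    is_transition,
    transition_partner,
)

__all__ = [
    "random_haplotype",
    "mutate_haplotype",
    "simulate_fragments",
]


def random_haplotype(length: int, seed: int, id: str = "random", circular: bool = True) -> Haplotype:
    """Uniform-random A/C/G/T haplotype, for building synthetic truth sets."""
    if length < 1:
        raise ValueError("length must be positive")
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list(BASES), size=length))
    return Haplotype(id=id, seq=seq, circular=circular)


def mutate_haplotype(
    base: Haplotype,
    n_transitions: int,
    n_transversions: int,
    seed: int,
    id: str | None = None,
) -> Haplotype:
    """Introduce exact numbers of transitions and transversions at random sites.

    Creates endogenous/contaminant haplotype pairs with a controlled
    substitution spectrum (e.g. a divergent modern sequence differing mostly
    by transitions, with a handful of transversions). Sites are drawn without
    replacement among non-N positions; the returned haplotype records
    (position, old, new, class) for every change in ``mutations``.
    """
    if n_transitions < 0 or n_transversions < 0:
        raise ValueError("substitution counts must be non-negative")
    rng = np.random.default_rng(seed)
    eligible = [i for i, b in enumerate(base.seq) if b in BASES]
    total = n_transitions + n_transversions
    if total > len(eligible):
        raise ValueError(
            f"requested {total} substitutions but only {len(eligible)} eligible sites"
        )
    sites = rng.choice(len(eligible), size=total, replace=False)
    seq = list(base.seq)
    record = []
    for k, si in enumerate(sites):
        i = eligible[si]
        old = seq[i]
        if k < n_transitions:
            new = transition_partner(old)
            klass = "transition"
        else:
            choices = [b for b in BASES if b != old and not is_transition(old, b)]
            new = choices[rng.integers(len(choices))]
            klass = "transversion"
        seq[i] = new
        record.append((i + 1, old, new, klass))
    record.sort()
    return Haplotype(
        id=id or f"{base.id}_mut",
        seq="".join(seq),
        circular=base.circular,
        mutations=tuple(record),
    )


def _draw_lengths(rng, n, mean_len, len_sd, min_len):
    """Lognormal lengths truncated at min_len by resampling.

    The lognormal shape is moment-matched to (mean, sd); the location is
    then adjusted so that the mean of the *truncated* distribution equals
    mean_len, keeping the configured mean exact under the 30 bp cutoff.
    """
    from scipy.optimize import brentq
    from scipy.stats import norm

    cv2 = (len_sd / mean_len) ** 2
    sigma = np.sqrt(np.log1p(cv2))
    la = np.log(min_len)

    def trunc_mean(mu):
        # E[X | X >= a] for X ~ lognormal(mu, sigma)
        num = np.exp(mu + sigma**2 / 2) * norm.cdf((mu + sigma**2 - la) / sigma)
        den = norm.cdf((mu - la) / sigma)
        return num / den

    mu0 = np.log(mean_len) - sigma**2 / 2.0
    mu = brentq(lambda m: trunc_mean(m) - mean_len, mu0 - 2.0, mu0 + 0.5)
    out = np.rint(rng.lognormal(mu, sigma, size=n)).astype(np.int64)
    for _ in range(1000):
        bad = out < min_len
        if not bad.any():
            break
        out[bad] = np.rint(rng.lognormal(mu, sigma, size=int(bad.sum())))
    out[out < min_len] = min_len
    return out


def simulate_fragments(
    endo: Haplotype,
    cont: Haplotype | None,
    n: int,
    mean_len: float = 43.0,
    len_sd: float = 6.0,
    damage: DamageModel | None = None,
    cont_fraction: float = 0.0,
    cont_damage: DamageModel | None = None,
    qual: int = 30,
    min_len: int = 30,
    seed: int = 0,
) -> list[AlignedFragment]:
    """Simulate a damaged, contaminated aligned-fragment set.

    Each fragment's source is Bernoulli(cont_fraction); starts are uniform on
    the circle; strands are 50/50. Endogenous fragments receive terminal
    deamination per `damage` (C->T from the read 5' end, G->A from the read
    3' end, orientation following the sequenced strand); contaminant
    fragments are undamaged unless `cont_damage` is given. A flat Phred
    model adds uniform sequencing errors at rate 10**(-qual/10).

    Returns AlignedFragment objects with truth labels (`source`,
    `damage_flags`) populated; bases are in reference orientation and may
    wrap the circular origin.
    """
    if not 0.0 <= cont_fraction <= 1.0:
        raise ValueError(f"cont_fraction {cont_fraction} outside [0, 1]")
    if n < 0:
        raise ValueError("n must be non-negative")
    if mean_len < min_len:
        raise ValueError(f"mean_len {mean_len} below minimum fragment length {min_len}")
    if cont_fraction > 0 and cont is None:
        raise ValueError("contaminant haplotype required when cont_fraction > 0")
    if cont is not None and len(cont) != len(endo):
        raise ValueError("endogenous and contaminant haplotypes must be equal length")
    damage = damage if damage is not None else DamageModel()

    L = len(endo)
    rng = np.random.default_rng(seed)
    lengths = _draw_lengths(rng, n, mean_len, len_sd, min_len)
    lengths = np.minimum(lengths, L)  # fragment cannot exceed the molecule
    starts = rng.integers(1, L + 1, size=n)
    is_cont = rng.random(n) < cont_fraction
    is_minus = rng.random(n) < 0.5

    # flat per-fragment layout: one big concatenated base array
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    total = int(offsets[-1])
    frag_of = np.repeat(np.arange(n), lengths)
    within = np.arange(total) - offsets[frag_of]  # 0-based offset inside fragment

    endo2 = np.concatenate([endo.codes()] * 2)
    src2 = endo2 if cont is None else np.concatenate([cont.codes()] * 2)
    refpos0 = starts[frag_of] - 1 + within  # may exceed L-1: circular wrap
    obs = np.where(is_cont[frag_of], src2[refpos0], endo2[refpos0]).astype(np.uint8)

    # read-oriented distances from each terminus, 1-based
    flen = lengths[frag_of]
    minus = is_minus[frag_of]
    d5 = np.where(minus, flen - within, within + 1)
    d3 = np.where(minus, within + 1, flen - within)

    # deamination in reference orientation:
    #   + strand: C->T at rate5(d5), G->A at rate3(d3)
    #   - strand: G->A at rate5(d5), C->T at rate3(d3)
    damage_flags = np.zeros(total, dtype=bool)
    u = rng.random(total)
    for src_mask, model in ((~is_cont[frag_of], damage), (is_cont[frag_of], cont_damage)):
        if model is None:
            continue
        p_ct = np.where(minus, model.rate3(d3), model.rate5(d5))
        p_ga = np.where(minus, model.rate5(d5), model.rate3(d3))
        hit_ct = src_mask & (obs == 1) & (u < p_ct)  # C -> T
        hit_ga = src_mask & (obs == 2) & (u < p_ga)  # G -> A
        obs[hit_ct] = 3
        obs[hit_ga] = 0
        damage_flags |= hit_ct | hit_ga

    # flat sequencing-error model
    err_p = 10.0 ** (-qual / 10.0)
    err = rng.random(total) < err_p
    if err.any():
        shift = rng.integers(1, 4, size=int(err.sum()))
        obs[err] = (obs[err] + shift) % 4

    fragments: list[AlignedFragment] = []
    seq_all = decode(obs)
    for i in range(n):
        a, b = int(offsets[i]), int(offsets[i + 1])
        fragments.append(
            AlignedFragment(
                start=int(starts[i]),
                strand="-" if is_minus[i] else "+",
                bases=seq_all[a:b],
                quals=np.full(b - a, qual, dtype=np.int32),
                source="contaminant" if is_cont[i] else "endogenous",
                damage_flags=damage_flags[a:b].copy(),
            )
        )
    return fragments
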