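"""Damage-aware consensus calling from a fragment pileup.

The caller assigns each site a likelihood per candidate base that folds in
the empirical deamination profile and the per-base Phred error rate, in the
style of endogenous-consensus callers for ancient mtDNA. Contamination is
deliberately not modelled inside the caller (the endogenous fraction is
assumed to be the majority); contamination is estimated afterwards from the
called consensus.

Generative model per aligned base, for candidate true base b:

    P(obs | b) = sum_{b'} P_dmg(b' | b, dist5, dist3) * P_err(obs | b')

where P_dmg substitutes C->T / G->A with the profile rate at the base's
distance from the relevant read terminus (orientation following the strand),
and P_err(obs | b') = 1 - e for obs == b', e/3 otherwise, with e the Phred
error probability. The posterior uses a uniform prior over A/C/G/T; the call
is the argmax, N on ties, below the coverage cutoff, or (if set) below a
posterior cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import AlignedFragment, Haplotype, decode, encode

__all__ = [
    "Pileup",
    "DamageProfile",
    "Consensus",
    "build_pileup",
    "estimate_damage_profile",
    "call_consensus",
    "apply_masks",
]


@dataclass
class Pileup:
    """Column-store pileup: one row per aligned base.

    `dist5`/`dist3` are 1-based distances from the read's 5'/3' termini in
    sequencing orientation; `minus` flags reads from the reverse strand.
    """

    L: int
    circular: bool
    pos: np.ndarray  # 1-based reference position
    base: np.ndarray  # uint8 codes, reference orientation
    qual: np.ndarray
    dist5: np.ndarray
    dist3: np.ndarray
    minus: np.ndarray  # bool
    frag: np.ndarray  # fragment index

    def depth(self) -> np.ndarray:
        """Per-position depth, index 0 unused (1-based positions)."""
        return np.bincount(self.pos, minlength=self.L + 1)

    def at(self, position: int):
        """Rows covering a 1-based position, as index array."""
        return np.nonzero(self.pos == position)[0]

    def __len__(self) -> int:
        return len(self.pos)


def build_pileup(
    fragments: list[AlignedFragment], L: int, circular: bool = True
) -> Pileup:
    """Stack aligned fragments onto reference coordinates.

    Every aligned base appears exactly once with its read-oriented terminal
    distances; fragments may wrap the circular origin. Raises if a fragment
    start lies outside [1, L] or a linear fragment overhangs the end.
    """
    pos_l, base_l, qual_l, d5_l, d3_l, minus_l, frag_l = [], [], [], [], [], [], []
    for fi, fr in enumerate(fragments):
        flen = len(fr)
        if not 1 <= fr.start <= L:
            raise ValueError(f"fragment {fi} start {fr.start} outside [1, {L}]")
        if not circular and fr.start + flen - 1 > L:
            raise ValueError(f"fragment {fi} overhangs linear reference")
        within = np.arange(flen)
        pos = (fr.start - 1 + within) % L + 1
        is_minus = fr.strand == "-"
        d5 = flen - within if is_minus else within + 1
        d3 = within + 1 if is_minus else flen - within
        pos_l.append(pos)
        base_l.append(encode(fr.bases))
        qual_l.append(fr.quals)
        d5_l.append(d5)
        d3_l.append(d3)
        minus_l.append(np.full(flen, is_minus))
        frag_l.append(np.full(flen, fi))
    if not fragments:
        z = np.zeros(0, dtype=np.int64)
        return Pileup(L, circular, z, z.astype(np.uint8), z, z, z, z.astype(bool), z)
    return Pileup(
        L=L,
        circular=circular,
        pos=np.concatenate(pos_l),
        base=np.concatenate(base_l),
        qual=np.concatenate(qual_l),
        dist5=np.concatenate(d5_l),
        dist3=np.concatenate(d3_l),
        minus=np.concatenate(minus_l),
        frag=np.concatenate(frag_l),
    )


@dataclass
class DamageProfile:
    """Observed deamination rates by distance from the read termini.

    ``ct5[d-1]`` is the fraction of T observations among reads whose
    reference base is C at distance d from the 5' end (read orientation);
    ``ga3`` is the analogous G->A rate from the 3' end. Rates with a zero
    denominator are NaN (undefined), never silently 0.
    """

    ct5: np.ndarray
    ga3: np.ndarray
    ct5_n: np.ndarray  # denominators
    ga3_n: np.ndarray

    @classmethod
    def zero(cls, max_dist: int = 25) -> "DamageProfile":
        z = np.zeros(max_dist)
        n = np.ones(max_dist)  # defined, all-zero rates
        return cls(ct5=z.copy(), ga3=z.copy(), ct5_n=n.copy(), ga3_n=n.copy())

    def _lookup(self, rates: np.ndarray, dist: np.ndarray) -> np.ndarray:
        d = np.asarray(dist, dtype=np.int64)
        out = np.zeros(d.shape, dtype=float)
        inside = (d >= 1) & (d <= len(rates))
        vals = rates[np.clip(d - 1, 0, len(rates) - 1)]
        out[inside] = np.nan_to_num(vals[inside])  # undefined -> 0 for calling
        return out

    def rate_ct5(self, dist) -> np.ndarray:
        """C->T rate at 5' distance(s); 0 beyond the profiled window."""
        return self._lookup(self.ct5, dist)

    def rate_ga3(self, dist) -> np.ndarray:
        return self._lookup(self.ga3, dist)


def estimate_damage_profile(
    pileup: Pileup, reference: Haplotype, max_dist: int = 25
) -> DamageProfile:
    """Measure C->T (5') and G->A (3') mismatch rates against a reference
    or called consensus, by read-oriented terminal distance."""
    ref_codes = reference.codes()
    cons = ref_codes[(pileup.pos - 1) % len(reference)]
    obs = pileup.base.astype(np.int64)
    cons = cons.astype(np.int64)
    # read-orientation identities: complement both on the minus strand
    comp = np.array([3, 2, 1, 0, 4])
    obs_r = np.where(pileup.minus, comp[obs], obs)
    cons_r = np.where(pileup.minus, comp[cons], cons)

    ct5 = np.full(max_dist, np.nan)
    ga3 = np.full(max_dist, np.nan)
    ct5_n = np.zeros(max_dist)
    ga3_n = np.zeros(max_dist)

    in5 = (pileup.dist5 >= 1) & (pileup.dist5 <= max_dist) & (cons_r == 1)
    d5 = pileup.dist5[in5] - 1
    ct5_n[:] = np.bincount(d5, minlength=max_dist)
    num5 = np.bincount(d5[obs_r[in5] == 3], minlength=max_dist)
    np.divide(num5, ct5_n, out=ct5, where=ct5_n > 0)

    in3 = (pileup.dist3 >= 1) & (pileup.dist3 <= max_dist) & (cons_r == 2)
    d3 = pileup.dist3[in3] - 1
    ga3_n[:] = np.bincount(d3, minlength=max_dist)
    num3 = np.bincount(d3[obs_r[in3] == 0], minlength=max_dist)
    np.divide(num3, ga3_n, out=ga3, where=ga3_n > 0)

    return DamageProfile(ct5=ct5, ga3=ga3, ct5_n=ct5_n, ga3_n=ga3_n)


@dataclass
class Consensus:
    """Called sequence with per-site posterior of the called base."""

    seq: str
    posterior: np.ndarray
    mask_annotations: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.seq)

    def n_unassigned(self) -> int:
        return self.seq.count("N")

    def haplotype(self, id: str = "consensus", circular: bool = True) -> Haplotype:
        return Haplotype(id=id, seq=self.seq, circular=circular)


def call_consensus(
    pileup: Pileup,
    damage: DamageProfile | None = None,
    coverage_cutoff: int = 1,
    posterior_cutoff: float | None = None,
) -> Consensus:
    """Damage-aware Bayesian consensus call over all reference positions.

    With ``damage=None`` an all-zero profile is used, which (at negligible
    sequencing error) reduces the caller to a per-site majority vote. The
    default ``coverage_cutoff=1`` calls every covered position; ``2`` gives
    the conservative variant that refuses single-read calls.
    """
    if damage is None:
        damage = DamageProfile.zero()
    L = pileup.L
    keep = pileup.base < 4  # drop N observations
    pos = pileup.pos[keep]
    obs = pileup.base[keep].astype(np.int64)
    e = 10.0 ** (-pileup.qual[keep].astype(float) / 10.0)
    minus = pileup.minus[keep]
    d5 = pileup.dist5[keep]
    d3 = pileup.dist3[keep]

    # per-entry deamination rates in reference orientation
    p_ct = np.where(minus, damage.rate_ga3(d3), damage.rate_ct5(d5))
    p_ga = np.where(minus, damage.rate_ct5(d5), damage.rate_ga3(d3))

    def perr(target: int) -> np.ndarray:
        return np.where(obs == target, 1.0 - e, e / 3.0)

    pA, pC, pG, pT = perr(0), perr(1), perr(2), perr(3)
    lik = np.empty((len(pos), 4))
    lik[:, 0] = pA
    lik[:, 1] = (1.0 - p_ct) * pC + p_ct * pT
    lik[:, 2] = (1.0 - p_ga) * pG + p_ga * pA
    lik[:, 3] = pT

    loglik = np.zeros((L + 1, 4))
    np.add.at(loglik, pos, np.log(np.maximum(lik, 1e-300)))
    depth = np.bincount(pos, minlength=L + 1)

    ll = loglik[1:]
    dep = depth[1:]
    m = ll.max(axis=1, keepdims=True)
    post = np.exp(ll - m)
    post /= post.sum(axis=1, keepdims=True)
    call = np.argmax(ll, axis=1)
    # summation-order tolerance: log-likelihoods within 1e-9 count as tied
    tied = (ll >= m - 1e-9).sum(axis=1) > 1

    uncallable = (dep < coverage_cutoff) | tied
    if posterior_cutoff is not None:
        uncallable |= post[np.arange(L), call] < posterior_cutoff
    call = np.where(uncallable, 4, call).astype(np.uint8)
    site_post = np.where(uncallable, np.nan, post[np.arange(L), np.minimum(call, 3)])
    return Consensus(seq=decode(call), posterior=site_post)


def apply_masks(consensus: Consensus, regions: list[tuple]) -> Consensus:
    """Set all bases in the union of 1-based inclusive regions to N.

    Regions are (start, end) or (start, end, label); idempotent; raises if a
    region falls outside the reference.
    """
    L = len(consensus)
    seq = np.array(list(consensus.seq))
    post = consensus.posterior.copy()
    annotations = list(consensus.mask_annotations)
    for region in regions:
        start, end = region[0], region[1]
        label = region[2] if len(region) > 2 else "masked"
        if not (1 <= start <= end <= L):
            raise ValueError(f"mask region ({start}, {end}) outside [1, {L}]")
        seq[start - 1 : end] = "N"
        post[start - 1 : end] = np.nan
        if (start, end, label) not in annotations:
            annotations.append((start, end, label))
    return Consensus(seq="".join(seq), posterior=post, mask_annotations=annotations)
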