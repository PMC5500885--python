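"""Present-day human contamination estimators for ancient mtDNA read sets.

Three independent approaches, mirroring standard aDNA practice:

1. Damage conditioning: ancient molecules carry terminal deamination,
   modern contaminants (mostly) do not. Fragments deaminated at one end are
   selected and the deamination rate re-measured at the opposite end; the
   gap between the unconditioned and conditioned rates gives the fraction of
   undamaged (contaminant) molecules.

2. Diagnostic-site counting: at positions where the endogenous consensus
   differs from (nearly) all modern panel sequences, each covering read is
   assigned to the endogenous or the modern variant; the contaminant read
   fraction is a direct binomial proportion. Restricting to transversions
   avoids counting deamination (which mimics transitions) as contamination.

3. Panel likelihood: a two-component mixture over reads at diagnostic
   sites — endogenous base passed through the damage model versus a base
   drawn from panel frequencies — maximised over the contamination fraction
   on a grid, with a likelihood-ratio 95% interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2
from statsmodels.stats.proportion import proportion_confint

from .core import AlignedFragment, Haplotype, is_transition
from .consensus import DamageProfile, Pileup, build_pileup

__all__ = [
    "ContaminationEstimate",
    "DiagnosticSite",
    "conditional_damage_estimate",
    "find_diagnostic_sites",
    "count_reads_at_sites",
    "count_based_estimate",
    "panel_likelihood_curve",
    "panel_likelihood_estimate",
]


@dataclass
class ContaminationEstimate:
    method: str  # damage_conditioned | diagnostic_count | panel_likelihood
    point: float
    ci_low: float
    ci_high: float
    n_support: int
    detail: dict = field(default_factory=dict)
    warning: str | None = None

    def __post_init__(self):
        self.point = float(np.clip(self.point, 0.0, 1.0))
        self.ci_low = float(np.clip(self.ci_low, 0.0, self.point))
        self.ci_high = float(np.clip(self.ci_high, self.point, 1.0))

    def as_dict(self) -> dict:
        return {
            "method": self.method,
            "point": self.point,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_support": self.n_support,
            "detail": self.detail,
            **({"warning": self.warning} if self.warning else {}),
        }


@dataclass(frozen=True)
class DiagnosticSite:
    """A position where the ancient consensus differs from nearly all modern
    panel sequences, usable to assign reads to endogenous vs contaminant."""

    position: int  # 1-based
    endo_base: str
    panel_major: str
    subst_class: str  # transition | transversion
    panel_freq_of_endo_base: float


def _read_orient(pileup):
    """Observed and reference bases in read orientation (complemented on the
    minus strand), as uint8 codes."""
    comp = np.array([3, 2, 1, 0, 4])
    obs = pileup.base.astype(np.int64)
    obs_r = np.where(pileup.minus, comp[obs], obs)
    return obs_r


def conditional_damage_estimate(
    fragments: list[AlignedFragment],
    consensus: Haplotype,
    measure_dists: tuple = (1, 2, 3),
    condition_window: int = 3,
    pileup: Pileup | None = None,
) -> ContaminationEstimate:
    """Damage-conditioning contamination estimate.

    Fragments showing deamination near one terminus (C->T within
    ``condition_window`` of the read 5' end, or G->A near the 3' end) are
    selected, and deamination rates are re-measured at the opposite end:
    those conditioned rates estimate the endogenous molecules' true damage
    level. For each terminal distance d in ``measure_dists`` the contaminant
    fraction is estimated from the distance-matched pooled ratio

        c = 1 - sum_d k_all(d) / sum_d n_all(d) * d_cond(d)

    where k_all(d)/n_all(d) is the damage rate over all fragments at
    terminal distance d and d_cond(d) the corresponding rate over the
    conditioned subset (both ends and both orientations pooled): the
    numerator is the observed number of damaged terminal bases, the
    denominator the number expected were every fragment endogenous. The 95%
    CI is the delta-method Wald interval, clipped to [0, 1].

    Assumes contaminant DNA is undamaged and that damage at the two ends of
    a molecule is independent; a damaged contaminant biases c downward, an
    effect that stays marginal when endogenous terminal damage is >= ~50%.
    """
    if pileup is None:
        pileup = build_pileup(fragments, L=len(consensus), circular=consensus.circular)
    if len(pileup) == 0:
        raise ValueError("no aligned bases among fragments")
    cons_codes = consensus.codes()
    cons = cons_codes[(pileup.pos - 1) % len(consensus)].astype(np.int64)
    comp = np.array([3, 2, 1, 0, 4])
    obs_r = _read_orient(pileup)
    cons_r = np.where(pileup.minus, comp[cons], cons)

    n_frag = int(pileup.frag.max()) + 1
    is_ct = (cons_r == 1) & (obs_r == 3)
    is_ga = (cons_r == 2) & (obs_r == 0)
    # conditioning events per fragment: damage near either read terminus
    dam5 = np.zeros(n_frag, bool)
    dam3 = np.zeros(n_frag, bool)
    sel5 = is_ct & (pileup.dist5 <= condition_window)
    sel3 = is_ga & (pileup.dist3 <= condition_window)
    dam5[pileup.frag[sel5]] = True
    dam3[pileup.frag[sel3]] = True

    cond_for_5 = dam3[pileup.frag]  # measuring at 5' conditions on 3' damage
    cond_for_3 = dam5[pileup.frag]

    per_dist = []
    observed = 0.0  # damaged terminal bases over all fragments
    expected = 0.0  # expectation under the conditioned (endogenous) rates
    var_obs = 0.0
    var_exp = 0.0
    n_support = 0
    n_conditioned = 0
    for d in measure_dists:
        at5 = (pileup.dist5 == d) & (cons_r == 1)
        at3 = (pileup.dist3 == d) & (cons_r == 2)
        n_all = int(at5.sum() + at3.sum())
        k_all = int((at5 & is_ct).sum() + (at3 & is_ga).sum())
        n_cond = int((at5 & cond_for_5).sum() + (at3 & cond_for_3).sum())
        k_cond = int((at5 & cond_for_5 & is_ct).sum() + (at3 & cond_for_3 & is_ga).sum())
        n_support += n_all
        n_conditioned += n_cond
        if n_all == 0 or n_cond == 0 or k_cond == 0:
            continue
        d_all = k_all / n_all
        d_cond = k_cond / n_cond
        per_dist.append(
            {"dist": d, "d_all": d_all, "d_conditioned": d_cond,
             "n_all": n_all, "n_conditioned": n_cond}
        )
        observed += k_all
        expected += n_all * d_cond
        var_obs += n_all * d_all * (1.0 - d_all)
        var_exp += n_all**2 * d_cond * (1.0 - d_cond) / n_cond
    if n_support == 0:
        raise ValueError("no damage-eligible terminal sites among fragments")
    if not per_dist:
        raise ValueError("no fragments with both-end coverage conditioned on damage")

    c = 1.0 - observed / expected
    se = np.sqrt(
        var_obs / expected**2 + (observed**2 / expected**4) * var_exp
    )
    warning = None
    if c < 0:
        warning = "overall damage exceeds conditioned rate; estimate clipped to 0"
    return ContaminationEstimate(
        method="damage_conditioned",
        point=c,
        ci_low=c - 1.96 * se,
        ci_high=c + 1.96 * se,
        n_support=n_support,
        detail={
            "per_distance": per_dist,
            "condition_window": condition_window,
            "n_conditioned": n_conditioned,
        },
        warning=warning,
    )


def find_diagnostic_sites(
    consensus: Haplotype,
    panel: list[Haplotype],
    max_panel_freq: float = 0.01,
    transversions_only: bool = False,
) -> list[DiagnosticSite]:
    """Positions where the consensus base is rarer than `max_panel_freq` in
    the aligned modern panel. Ns (and gaps normalised to N upstream) are
    excluded from the frequency denominators; sites where the consensus
    itself is N are skipped."""
    if len(panel) < 2:
        raise ValueError("panel must contain at least 2 sequences")
    L = len(consensus)
    for h in panel:
        if len(h) != L:
            raise ValueError(
                f"panel sequence {h.id!r} length {len(h)} != consensus length {L}"
            )
    mat = np.stack([h.codes() for h in panel])  # (n_panel, L)
    cons = consensus.codes()
    counts = np.stack([(mat == b).sum(axis=0) for b in range(4)])  # (4, L)
    totals = counts.sum(axis=0)

    sites: list[DiagnosticSite] = []
    callable_ = (cons < 4) & (totals > 0)
    freq_endo = np.zeros(L)
    np.divide(
        counts[np.minimum(cons, 3), np.arange(L)],
        totals,
        out=freq_endo,
        where=totals > 0,
    )
    major = np.argmax(counts, axis=0)
    for pos0 in np.nonzero(callable_ & (freq_endo < max_panel_freq))[0]:
        endo_b = consensus.seq[pos0]
        major_b = "ACGT"[major[pos0]]
        klass = "transition" if is_transition(endo_b, major_b) else "transversion"
        if transversions_only and klass != "transversion":
            continue
        sites.append(
            DiagnosticSite(
                position=int(pos0) + 1,
                endo_base=endo_b,
                panel_major=major_b,
                subst_class=klass,
                panel_freq_of_endo_base=float(freq_endo[pos0]),
            )
        )
    return sites


def count_reads_at_sites(
    pileup: Pileup, sites: list[DiagnosticSite]
) -> tuple[int, int]:
    """Tally reads carrying the endogenous base versus the modern panel
    variant across diagnostic sites. Reads showing any other base are
    ignored (sequencing error or damage to a third state)."""
    from .core import BASE_TO_CODE

    n_endo = 0
    n_cont = 0
    for s in sites:
        rows = pileup.at(s.position)
        obs = pileup.base[rows]
        n_endo += int((obs == BASE_TO_CODE[s.endo_base]).sum())
        n_cont += int((obs == BASE_TO_CODE[s.panel_major]).sum())
    return n_endo, n_cont


def count_based_estimate(
    n_endogenous: int,
    n_contaminant: int,
    ci_method: str = "wald",
) -> ContaminationEstimate:
    """Binomial proportion of contaminant reads with a 95% CI.

    `wald` is the normal approximation p +/- 1.96*sqrt(p(1-p)/n); `wilson`
    is the score interval. CIs are clipped to [0, 1].
    """
    total = n_endogenous + n_contaminant
    if total <= 0:
        raise ValueError("need at least one classified read")
    if min(n_endogenous, n_contaminant) < 0:
        raise ValueError("counts must be non-negative")
    method = {"wald": "normal", "wilson": "wilson"}.get(ci_method)
    if method is None:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    point = n_contaminant / total
    lo, hi = proportion_confint(n_contaminant, total, alpha=0.05, method=method)
    return ContaminationEstimate(
        method="diagnostic_count",
        point=point,
        ci_low=float(lo),
        ci_high=float(hi),
        n_support=total,
        detail={
            "n_endogenous": n_endogenous,
            "n_contaminant": n_contaminant,
            "ci_method": ci_method,
        },
    )


def panel_likelihood_curve(
    fragments: list[AlignedFragment],
    consensus: Haplotype,
    panel: list[Haplotype],
    damage: DamageProfile | None = None,
    grid: float = 0.001,
    max_panel_freq: float = 0.01,
    pileup: Pileup | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Log-likelihood of the contamination fraction on a grid.

    For each read base at a diagnostic site,

        P(obs | c) = (1-c) P(obs | endo base, damage, e)
                     + c * sum_b f_b P(obs | b, e)

    with f_b the panel base frequencies at the site (the contaminant branch
    carries no damage). Returns (grid values, log-likelihoods, number of
    supporting read observations).
    """
    if damage is None:
        damage = DamageProfile.zero()
    sites = find_diagnostic_sites(consensus, panel, max_panel_freq=max_panel_freq)
    if not sites:
        raise ValueError("no diagnostic sites between consensus and panel")
    L = len(consensus)
    if pileup is None:
        pileup = build_pileup(fragments, L=L, circular=consensus.circular)

    mat = np.stack([h.codes() for h in panel])
    site_pos = np.array([s.position for s in sites])
    endo_code = np.array(["ACGT".index(s.endo_base) for s in sites])
    # panel frequencies per site (4, n_sites)
    cols = mat[:, site_pos - 1]
    fcounts = np.stack([(cols == b).sum(axis=0) for b in range(4)]).astype(float)
    ftot = fcounts.sum(axis=0)
    if (ftot == 0).any():
        raise ValueError("panel has no called bases at some diagnostic site")
    freqs = fcounts / ftot

    sel = np.isin(pileup.pos, site_pos) & (pileup.base < 4)
    if not sel.any():
        raise ValueError("no read coverage at diagnostic sites")
    order = {int(p): i for i, p in enumerate(site_pos)}
    sidx = np.array([order[int(p)] for p in pileup.pos[sel]])
    obs = pileup.base[sel].astype(np.int64)
    e = 10.0 ** (-pileup.qual[sel].astype(float) / 10.0)
    minus = pileup.minus[sel]
    d5 = pileup.dist5[sel]
    d3 = pileup.dist3[sel]
    p_ct = np.where(minus, damage.rate_ga3(d3), damage.rate_ct5(d5))
    p_ga = np.where(minus, damage.rate_ct5(d5), damage.rate_ga3(d3))

    def perr(target):
        return np.where(obs == target, 1.0 - e, e / 3.0)

    pA, pC, pG, pT = perr(0), perr(1), perr(2), perr(3)
    # endogenous branch: known base, damage applied
    endo_b = endo_code[sidx]
    p_endo = np.select(
        [endo_b == 0, endo_b == 1, endo_b == 2, endo_b == 3],
        [pA, (1 - p_ct) * pC + p_ct * pT, (1 - p_ga) * pG + p_ga * pA, pT],
    )
    # contaminant branch: panel mixture, no damage
    f = freqs[:, sidx]  # (4, n_obs)
    p_cont = f[0] * pA + f[1] * pC + f[2] * pG + f[3] * pT

    cs = np.arange(0.0, 1.0 + grid / 2, grid)
    mix = np.outer(1.0 - cs, p_endo) + np.outer(cs, p_cont)  # (n_c, n_obs)
    ll = np.log(np.maximum(mix, 1e-300)).sum(axis=1)
    return cs, ll, int(sel.sum())


def panel_likelihood_estimate(
    fragments: list[AlignedFragment],
    consensus: Haplotype,
    panel: list[Haplotype],
    damage: DamageProfile | None = None,
    grid: float = 0.001,
    max_panel_freq: float = 0.01,
    pileup: Pileup | None = None,
) -> ContaminationEstimate:
    """Grid maximum-likelihood contamination fraction at diagnostic sites
    (see :func:`panel_likelihood_curve` for the mixture model), with a
    likelihood-ratio 95% interval (chi-square, 1 df)."""
    cs, ll, n_obs = panel_likelihood_curve(
        fragments,
        consensus,
        panel,
        damage=damage,
        grid=grid,
        max_panel_freq=max_panel_freq,
        pileup=pileup,
    )
    best = int(np.argmax(ll))
    cutoff = ll[best] - chi2.ppf(0.95, df=1) / 2.0
    inside = np.nonzero(ll >= cutoff)[0]
    n_sites = len(find_diagnostic_sites(consensus, panel, max_panel_freq=max_panel_freq))
    return ContaminationEstimate(
        method="panel_likelihood",
        point=float(cs[best]),
        ci_low=float(cs[inside[0]]),
        ci_high=float(cs[inside[-1]]),
        n_support=n_obs,
        detail={
            "n_sites": n_sites,
            "grid_step": grid,
            "loglik_max": float(ll[best]),
        },
    )
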