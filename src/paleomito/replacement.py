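"""Neutral mtDNA lineage-replacement model.

Closed forms from neutral diffusion theory for a haploid (uniparentally
transmitted) locus with effective size N lineage units:

* mean time to fixation of an allele at initial frequency p, conditional on
  fixation:  T(p) = -2N (1-p) ln(1-p) / p  generations (the autosomal 4N
  coefficient halves for mtDNA);
* fixation probability of a neutral allele = its initial frequency p.

A haploid Wright-Fisher simulator (binomial resampling each generation,
piecewise-constant Ne trajectories, optional continuous admixture inflow)
serves as the brute-force check on the closed forms and computes replacement
probabilities under admixture scenarios. Generations convert to years with
a generation time of 29 years by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ReplacementParams",
    "WFResult",
    "conditional_fixation_time",
    "fixation_time_small_p_limit",
    "fixation_probability",
    "wf_simulate",
    "conditional_fixation_time_sim",
    "replacement_probability_sim",
]

DEFAULT_GENERATION_TIME = 29.0  # years


def initial_count(N: int, p: float) -> int:
    """Integer founding copy number for frequency p in N lineages.

    Rounded to the nearest count, but kept off the absorbing states for
    0 < p < 1 so that every replicate starts segregating. The realized
    initial frequency is initial_count(N, p) / N; simulation oracles should
    be compared to closed forms evaluated at that realized frequency.
    """
    c = int(round(p * N))
    if p > 0.0 and c == 0:
        c = 1
    if p < 1.0 and c == N:
        c = N - 1
    return c


@dataclass(frozen=True)
class ReplacementParams:
    """Model parameters.

    N may be a scalar effective size (mtDNA lineage units) or a
    piecewise-constant trajectory [(duration_generations, N), ...]; the last
    epoch's N persists beyond the stated durations.
    """

    N: int | list = 5000
    p: float = 0.001
    gen_time: float = DEFAULT_GENERATION_TIME

    def __post_init__(self):
        if self.gen_time <= 0:
            raise ValueError("gen_time must be positive")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"initial frequency p={self.p} outside [0, 1]")
        for dur, n in self.epochs():
            if n < 1:
                raise ValueError("N must be >= 1")
            if dur < 0:
                raise ValueError("epoch durations must be non-negative")

    def epochs(self) -> list[tuple]:
        if np.isscalar(self.N):
            return [(np.inf, int(self.N))]
        return [(d, int(n)) for d, n in self.N]

    def scalar_N(self) -> int:
        if not np.isscalar(self.N):
            raise ValueError("operation requires a scalar N")
        return int(self.N)


def conditional_fixation_time(params: ReplacementParams) -> tuple:
    """Mean generations (and years) to fixation of a neutral allele at
    initial frequency p, given that it fixes: T(p) = -2N(1-p)ln(1-p)/p.

    T(1) = 0 by continuity. p = 0 is rejected; the p -> 0+ limit (2N
    generations) is available as :func:`fixation_time_small_p_limit`.
    """
    N = params.scalar_N()
    p = params.p
    if p <= 0.0:
        raise ValueError(
            "p must be in (0, 1]; for the p->0 limit use fixation_time_small_p_limit"
        )
    if p == 1.0:
        generations = 0.0
    else:
        generations = -2.0 * N * (1.0 - p) * np.log1p(-p) / p
    return generations, generations * params.gen_time


def fixation_time_small_p_limit(params: ReplacementParams) -> tuple:
    """The p -> 0+ limit of the conditional fixation time: 2N generations."""
    N = params.scalar_N()
    generations = 2.0 * N
    return generations, generations * params.gen_time


def fixation_probability(p: float) -> float:
    """Neutral fixation probability equals the initial frequency."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p={p} outside [0, 1]")
    return p


@dataclass
class WFResult:
    outcome: str  # 'fixed' | 'lost' | 'unresolved'
    t_absorb: int  # generations to absorption (or the cap if unresolved)
    trajectory: np.ndarray | None = None  # per-generation frequencies


def _epoch_N(epochs, t):
    """Population size at generation t under a piecewise-constant trajectory."""
    acc = 0.0
    for dur, n in epochs:
        acc += dur
        if t < acc:
            return n
    return epochs[-1][1]


def _default_cap(epochs) -> int:
    n_max = max(n for _, n in epochs)
    return 200 * n_max


def wf_simulate(
    params: ReplacementParams,
    seed: int,
    record_trajectory: bool = False,
    max_generations: int | None = None,
) -> WFResult:
    """One haploid Wright-Fisher replicate: the next generation's
    introgressed-lineage count is Binomial(N_t, current frequency)."""
    rng = np.random.default_rng(seed)
    epochs = params.epochs()
    cap = max_generations if max_generations is not None else _default_cap(epochs)
    N = _epoch_N(epochs, 0)
    count = initial_count(N, params.p)
    freqs = [count / N]
    t = 0
    while 0 < count and t < cap:
        freq = count / N
        if freq >= 1.0:
            break
        t += 1
        N = _epoch_N(epochs, t)
        count = rng.binomial(N, freq)
        if record_trajectory:
            freqs.append(count / N)
    freq = count / N
    traj = np.array(freqs) if record_trajectory else None
    if freq <= 0.0:
        return WFResult("lost", t, traj)
    if freq >= 1.0:
        return WFResult("fixed", t, traj)
    return WFResult("unresolved", cap, traj)


def _wf_batch(epochs, p, reps, rng, cap):
    """Vectorised WF replicates; returns (fixed: bool, t_absorb: int) arrays.

    The active set shrinks as replicates absorb, so the cost is dominated by
    the mean absorption time, not the cap.
    """
    N = _epoch_N(epochs, 0)
    counts = np.full(reps, initial_count(N, p), dtype=np.int64)
    t_absorb = np.zeros(reps, dtype=np.int64)
    fixed = counts >= N
    active = np.nonzero((counts > 0) & (counts < N))[0]
    t = 0
    while active.size and t < cap:
        t += 1
        N_prev = N
        N = _epoch_N(epochs, t)
        counts[active] = rng.binomial(N, counts[active] / N_prev)
        done_lost = counts[active] == 0
        done_fixed = counts[active] == N
        done = done_lost | done_fixed
        if done.any():
            idx = active[done]
            t_absorb[idx] = t
            fixed[active[done_fixed]] = True
            active = active[~done]
    if active.size:
        t_absorb[active] = cap  # unresolved; flagged by caller if needed
    return fixed, t_absorb, active.size


def conditional_fixation_time_sim(
    params: ReplacementParams,
    reps: int,
    seed: int,
    max_generations: int | None = None,
) -> tuple:
    """Mean absorption time among replicates that fixed (conditioning on
    fixation), with its standard error and the number of fixed replicates."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    epochs = params.epochs()
    cap = max_generations if max_generations is not None else _default_cap(epochs)
    fixed, times, _ = _wf_batch(epochs, params.p, reps, rng, cap)
    n_fixed = int(fixed.sum())
    if n_fixed == 0:
        raise ValueError(
            f"no replicate fixed in {reps} runs (p={params.p}); increase reps"
        )
    ft = times[fixed].astype(float)
    mean = float(ft.mean())
    se = float(ft.std(ddof=1) / np.sqrt(n_fixed)) if n_fixed > 1 else float("inf")
    return mean, se, n_fixed


def replacement_probability_sim(
    trajectory,
    admixture: dict,
    reps: int,
    seed: int,
    max_generations: int | None = None,
) -> tuple:
    """Probability that an introgressing lineage class replaces the resident
    mtDNA pool, by simulation.

    `trajectory` is a scalar N or [(duration, N), ...]. `admixture` is
    either ``{"pulse": p}`` (a single founding pulse at frequency p) or
    ``{"rate": m, "duration": G}`` (each generation for G generations,
    Binomial(N, m) migrant copies replace randomly chosen residents). After
    any admixture epoch, drift continues to absorption.

    Returns (replacement probability, binomial standard error).
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    epochs = [(np.inf, int(trajectory))] if np.isscalar(trajectory) else [
        (d, int(n)) for d, n in trajectory
    ]
    cap = max_generations if max_generations is not None else _default_cap(epochs)

    if "pulse" in admixture:
        p = float(admixture["pulse"])
        if not 0.0 <= p <= 1.0:
            raise ValueError("pulse fraction outside [0, 1]")
        fixed, _, _ = _wf_batch(epochs, p, reps, rng, cap)
    elif "rate" in admixture:
        m = float(admixture["rate"])
        G = int(admixture.get("duration", 0))
        if not 0.0 <= m <= 1.0:
            raise ValueError("admixture rate outside [0, 1]")
        N = _epoch_N(epochs, 0)
        counts = np.zeros(reps, dtype=np.int64)
        for t in range(1, G + 1):
            N_prev = N
            N = _epoch_N(epochs, t)
            counts = rng.binomial(N, counts / N_prev)
            inflow = rng.binomial(N, m, size=reps)
            # migrants displace randomly chosen residents
            counts += rng.binomial(inflow, 1.0 - counts / N)
            counts = np.minimum(counts, N)
        # drift to absorption from the post-admixture state
        active = np.nonzero((counts > 0) & (counts < N))[0]
        fixed = counts >= N
        t = G
        while active.size and t < cap + G:
            t += 1
            N_prev = N
            N = _epoch_N(epochs, t)
            counts[active] = rng.binomial(N, counts[active] / N_prev)
            done_lost = counts[active] == 0
            done_fixed = counts[active] == N
            done = done_lost | done_fixed
            if done.any():
                fixed[active[done_fixed]] = True
                active = active[~done]
    else:
        raise ValueError("admixture must specify 'pulse' or 'rate'")

    phat = float(fixed.mean())
    se = float(np.sqrt(phat * (1.0 - phat) / reps))
    return phat, se
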