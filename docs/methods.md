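# Methods

This note documents the models implemented in `paleomito`, the assumptions
behind them, the defaults and why they were chosen, and what the synthetic
data generator does and does not emulate.

## Coordinates and conventions

All user-facing positions are 1-based inclusive, matching rCRS coordinate
conventions for human mtDNA. References are circular by default; fragments
may wrap the origin and pileups handle the wrap exactly. Gaps (`-`) and
ambiguity codes are treated as missing (`N`) everywhere except alignment
matrices, which preserve gaps but treat them as missing in every statistic.

## Synthetic ancient-DNA generator

The generator (`simulate_fragments`) emulates a captured, deeply sequenced
ancient mtDNA library:

- **Fragment lengths** — lognormal, truncated at 30 bp (shorter molecules
  are discarded in real processing). Defaults: mean 43 bp, sd 6 bp. The
  lognormal location is solved numerically so the *truncated* mean equals
  the configured mean. The sd is a free parameter; real libraries report a
  mean near 43 bp but not a dispersion.
- **Starts and strands** — uniform on the circle, 50/50 strand assignment.
- **Deamination** — C→T from the read 5′ terminus and G→A from the read 3′
  terminus, at rate `delta * decay**(d-1)` for 1-based terminal distance d.
  Defaults `delta5 = delta3 = 0.5` (roughly half of ancient molecules
  deaminated at the termini) and `decay = 0.5`. The decay rate is a
  simulator parameter, not an empirical claim: real damage profiles decay
  roughly geometrically but the rate varies by library chemistry. On
  minus-strand fragments the same chemistry appears complemented in
  reference orientation; the simulator and all estimators share this
  orientation logic.
- **Contamination** — each fragment is independently contaminant with
  probability `cont_fraction`; contaminant fragments are undamaged by
  default (the standard assumption for modern handling/lab contamination),
  with an optional damage model to study the bias a damaged contaminant
  causes.
- **Sequencing error** — a flat Phred model (default Q30), substituting
  uniformly among the other three bases. No indels, adapters, or
  capture/reference bias are simulated; fragments have exact placements,
  so there is no mapper and no mapping-quality dimension. Consequently,
  passing tests demonstrate correctness of the statistical machinery under
  the stated generative model, not robustness to alignment artefacts,
  indel damage, or biased capture of real libraries.
- **Divergent haplotypes** — `mutate_haplotype` introduces exact numbers of
  transitions and transversions at random sites, used to build the
  endogenous/contaminant pair and a modern-like comparison panel. The
  recovery fixtures use a 3 kb reference with 60 transitions + 40
  transversions between endogenous and contaminant and 40 panel members
  each carrying 7 private mutations; this is a scaled-down stand-in for a
  full mtDNA with ~120 differences, keeping enough transversion sites for
  stable read counting at test-sized references.

All randomness flows through `numpy.random.default_rng(seed)`; identical
seeds give bit-identical output. In the pipeline, per-stage seeds derive
from one global seed via `numpy.random.SeedSequence(seed).generate_state`.

## Consensus calling

Per site and candidate base b, each covering read contributes

    P(obs | b) = Σ_b' P_dmg(b' | b, d5, d3) · P_err(obs | b'),

with `P_err(obs|b') = 1−e` for a match and `e/3` otherwise (e the Phred
error probability), and `P_dmg` substituting C→T at the empirical 5′ rate
for the read's terminal distance and G→A at the 3′ rate (swapped in
reference orientation on minus-strand reads). The damage profile is
measured from the data itself against a first-pass call made with a zero
profile — a two-pass scheme that avoids needing truth. The posterior uses a
uniform prior over A/C/G/T; the call is the argmax, `N` on ties (within
1e-9 log-likelihood, a float-summation tolerance), below the coverage
cutoff, or below an optional posterior cutoff. Defaults: coverage cutoff 1
and no posterior cutoff (call everything covered); cutoff 2 is the
conservative variant. With a zero profile and uniform qualities the caller
reduces exactly to a per-site majority vote.

Contamination is deliberately *not* modelled inside the caller: the
endogenous fraction is assumed to be the majority at every site, which
holds comfortably at ≤12% contamination and ~35× coverage (the probability
that contaminant reads outnumber endogenous ones at a Poisson-35 site is
negligible). Estimating contamination is a separate, downstream step.
Region masks (e.g. poly-C 303–315, poly-AC 518–524 in rCRS coordinates)
are applied as explicit, idempotent `N` annotations; specific manual
curation edits of real datasets are expressible through the same mask
config but are not hard-coded.

## Contamination estimators

**Damage conditioning.** Assumptions: contaminant DNA is undamaged, and
deamination at the two ends of a molecule is independent. Fragments with a
C→T within 3 bp of the read 5′ end (or G→A within 3 bp of the 3′ end) are
selected; deamination rates at the opposite end of these fragments estimate
the endogenous damage level by terminal distance, `d_cond(d)`. The
estimator is the pooled distance-matched ratio

    c = 1 − Σ_d k_all(d) / Σ_d n_all(d)·d_cond(d),   d ∈ {1, 2, 3},

i.e. observed damaged terminal bases over all fragments versus the count
expected were every fragment endogenous, both ends and strands pooled. The
CI is a delta-method Wald interval, clipped to [0, 1]. Design notes:

- Measuring only at distance 1 is the textbook description but wastes most
  of the conditioned information; at 50,000 fragments its standard error is
  ~0.019 versus ~0.012 for the pooled ratio. The pooled form keeps the
  distance matching exact (each distance is compared to its own
  conditioned rate), so the decay shape cancels.
- An inverse-variance combination of per-distance ratios was rejected: its
  weights correlate with the noisy conditioned rates, biasing the estimate
  upward by ~+0.02 at c = 0. The pooled ratio is unbiased to first order
  (measured +0.003 at c = 0 across replicates).
- A damaged contaminant biases c downward; with endogenous terminal damage
  ≥ 0.5 and contaminant damage ~0.1 the bias stays within ~0.04 (asserted
  in the tests). Divergence between contaminant and consensus also
  contributes a small downward bias through conditioning contaminant
  fragments in; at the scaled-down fixture divergence (~3%) this is ~0.01.
- Evaluation protocol: because the estimator's precision is bounded by the
  conditioned-subset size (~5k fragments at the fixture conditions), its
  recovery is asserted on the mean over 5 replicate datasets (SE ~0.0055)
  rather than a single draw; the other two estimators have single-draw SEs
  of ~0.003–0.006 and are asserted on one dataset.

**Diagnostic-site counting.** Sites where the consensus base has frequency
< 1% in the aligned modern panel (Ns excluded from denominators) are
diagnostic; reads there carry either the endogenous base or the panel-major
variant (anything else is ignored). Restricted to transversions, the count
is immune to deamination, which only mimics transitions; the
transition-included estimate is measurably inflated on damage-heavy data
(asserted in the tests). The proportion's 95% CI uses the Wald normal
approximation by default — the convention that reproduces standard printed
intervals from raw counts exactly — with Wilson available
(`statsmodels.stats.proportion.proportion_confint` supplies both).

**Panel likelihood.** At the same diagnostic sites, each read base
contributes `(1−c)·P(obs | endogenous base, damage, e) + c·Σ_b f_b·P(obs |
b, e)`, with `f_b` the panel frequencies at the site and no damage on the
contaminant branch. The log-likelihood is maximised on a grid (default step
0.001) and the 95% interval is the likelihood-ratio set (χ², 1 df). This is
a deliberate one-shot simplification of iterative per-base contamination
estimators: no re-estimation loop, no per-read length weighting. Its
recovery at the fixture conditions is within ±0.01 of truth.

## Diversity statistics

Pairwise-deletion distances remove, per pair, every site where either
sequence is N or gapped, then count mismatches; `compared` records the
retained-site denominator. Segregating sites K counts columns with ≥2
distinct called bases after excluding N/gaps. Watterson's estimator is
`θ_w = K/(a_n·L)` with L defaulting to 16,595 aligned sites. Two harmonic
conventions are shipped:

- `standard`: `a_n = Σ_{i=1..n−1} 1/i` — the textbook estimator;
- `inclusive`: `a_n = Σ_{i=1..n} 1/i` — the default here, because published
  mtDNA diversity values in this domain (1.37×10⁻³ at K=78, n=17;
  2.50×10⁻³ at K=145, n=18) are reproducible only under this convention
  even though the accompanying formula is written with the n−1 sum. Rather
  than guessing intent, both are exposed and reported side by side
  (the standard convention gives 1.39×10⁻³ and 2.54×10⁻³ for the same
  counts).

## Replacement model

The conditional mean fixation time of a neutral allele at frequency p is
`T(p) = −2N(1−p)ln(1−p)/p` generations for a haploid uniparental locus
(half the autosomal 4N coefficient), with `T(1) = 0` by continuity and the
p→0⁺ limit 2N exposed as a separate function rather than silently
substituted at p = 0. Years use a generation time of 29 (configurable).
N is counted directly in mtDNA-transmitting lineage units; no female-census
conversion is applied.

The Wright–Fisher oracle is a haploid binomial-resampling simulator with
piecewise-constant Ne trajectories, vectorised over replicates with a
shrinking active set; the generation cap defaults to 200·N (far beyond
expected absorption; capped replicates are flagged unresolved). Founding
counts are integers: `initial_count(N, p)` rounds p·N but keeps it off the
absorbing states for 0 < p < 1, and simulation checks compare the closed
form at the *realized* initial frequency. At N = 50–200 the exact discrete
chain deviates from the diffusion closed form by only 0.6–2.6% (computed by
direct Markov-chain solution), well inside the 3-SE bands used in the
tests at 5,000 replicates.

Continuous admixture is modelled as, each generation for a fixed duration,
a `Binomial(N, m)` migrant inflow displacing randomly chosen residents,
after which pure drift runs to absorption. This simple parameterisation is
the package's own definition; its key property — replacement probability
proportional to the admixture rate for small m (analytically
`1−(1−m)^duration` ≈ duration·m) — is what the tests assert, together with
pulse neutrality (a founding pulse at frequency p fixes with probability p
regardless of later Ne changes).

## Problem sizes in the tests

The recovery fixtures use a 3 kb circular reference with 50,000 fragments
(~700× at diagnostic sites); consensus recovery uses 20 replicates of a
2 kb reference at ~35× (≈1,600 fragments each); Wright–Fisher checks use
5,000 replicates per (N, p) cell and 20,000 for probability checks. These
sizes put every stochastic assertion at ≥3 SE resolution while keeping the
full suite and the acceptance script in the low minutes on one CPU.

## Known limitations

- The simulator's flat quality/error model and indel-free reads mean the
  caller's mapping-quality hook and the estimators' robustness to
  misalignment are untested against realistic artefacts.
- The damage-conditioning estimator inherits the undamaged-contaminant
  assumption; heavily damaged contamination (e.g. ancient-on-ancient
  mixtures) violates it and biases the estimate low.
- The panel-likelihood method ignores linkage between diagnostic sites on
  the same fragment (sites are treated independently), a second-order
  effect at mtDNA fragment lengths.
- Diversity statistics assume a fixed alignment; alignment construction
  and phylogenetic inference are out of scope.
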