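"""End-to-end pipeline orchestration.

A single config (YAML/JSON mapping) enables stages by presence of their
block; stages run in order simulate -> consensus -> contamination ->
diversity -> replacement. All randomness flows from one global seed:
per-stage integer seeds are drawn from ``numpy.random.SeedSequence(seed)``
(``generate_state``), so an identical config byte-reproduces every output.
Inputs are validated before any stage runs (fail-fast, no partial outputs).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .core import DamageModel, Haplotype
from .consensus import apply_masks, build_pileup, call_consensus, estimate_damage_profile
from .contamination import (
    conditional_damage_estimate,
    count_based_estimate,
    count_reads_at_sites,
    find_diagnostic_sites,
    panel_likelihood_estimate,
)
from .diversity import pairwise_differences, segregating_sites, watterson_theta
from .replacement import (
    ReplacementParams,
    conditional_fixation_time,
    replacement_probability_sim,
)
from .simulate import mutate_haplotype, random_haplotype, simulate_fragments
from . import io as pio

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

STAGES = ("simulate", "consensus", "contamination", "diversity", "replacement")


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "paleomito_out"
    simulate: dict | None = None
    consensus: dict | None = None
    contamination: dict | None = None
    diversity: dict | None = None
    replacement: dict | None = None

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {k: d[k] for k in ("seed", "outdir") if k in d}
        stages = {k: d[k] for k in STAGES if k in d}
        extra = set(d) - set(known) - set(stages)
        if extra:
            raise ValueError(f"unknown config keys: {sorted(extra)}")
        return cls(**known, **stages)

    def enabled(self, stage: str) -> bool:
        return getattr(self, stage) is not None


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        return PipelineConfig.from_dict(yaml.safe_load(fh))


def _validate(cfg: PipelineConfig) -> None:
    """Fail fast: every enabled stage must have its upstream available."""
    for stage in ("consensus", "contamination"):
        block = getattr(cfg, stage)
        if block is None:
            continue
        if not cfg.enabled("simulate"):
            if "fragments" not in block:
                raise ValueError(
                    f"{stage} stage enabled without simulate stage or a 'fragments' input"
                )
            if not Path(block["fragments"]).exists():
                raise FileNotFoundError(block["fragments"])
    if cfg.contamination is not None and not cfg.enabled("simulate"):
        for key in ("consensus_fasta", "panel_fasta"):
            if key in cfg.contamination and not Path(cfg.contamination[key]).exists():
                raise FileNotFoundError(cfg.contamination[key])
    if cfg.diversity is not None and "alignment" in cfg.diversity:
        if not Path(cfg.diversity["alignment"]).exists():
            raise FileNotFoundError(cfg.diversity["alignment"])


def _stage_seeds(seed: int) -> dict:
    state = np.random.SeedSequence(seed).generate_state(len(STAGES))
    return {stage: int(s) for stage, s in zip(STAGES, state)}


def run_pipeline(config: PipelineConfig | dict, outdir: str | None = None) -> dict:
    """Execute the enabled stages and return the machine-readable report.

    All artifacts (FASTA/TSV/JSON) plus ``report.json`` are written under
    the configured output directory. The report records package version,
    seeds, stage parameters and headline numbers, each traceable to a stage
    output file.
    """
    cfg = config if isinstance(config, PipelineConfig) else PipelineConfig.from_dict(config)
    _validate(cfg)
    out = Path(outdir or cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(cfg.seed)
    report: dict = {
        "package": "paleomito",
        "version": __version__,
        "seed": cfg.seed,
        "stage_seeds": seeds,
        "stages": {},
    }

    fragments = None
    endo = cont = None
    panel: list[Haplotype] = []
    L = None

    if cfg.enabled("simulate"):
        s = dict(cfg.simulate)
        L = int(s.get("L", 2000))
        n = int(s.get("n", round(s.get("coverage", 35.0) * L / s.get("mean_len", 43.0))))
        damage = DamageModel(
            delta5=s.get("delta5", 0.5),
            delta3=s.get("delta3", 0.5),
            decay=s.get("decay", 0.5),
        )
        rng_seed = seeds["simulate"]
        endo = random_haplotype(L, seed=rng_seed, id="endogenous")
        cont = mutate_haplotype(
            endo,
            int(s.get("n_transitions", 60)),
            int(s.get("n_transversions", 40)),
            seed=rng_seed + 1,
            id="contaminant",
        )
        panel = [
            mutate_haplotype(
                cont,
                int(s.get("panel_ts", 5)),
                int(s.get("panel_tv", 2)),
                seed=rng_seed + 2 + k,
                id=f"panel{k}",
            )
            for k in range(int(s.get("panel_size", 40)))
        ]
        fragments = simulate_fragments(
            endo,
            cont,
            n=n,
            mean_len=s.get("mean_len", 43.0),
            len_sd=s.get("len_sd", 6.0),
            damage=damage,
            cont_fraction=s.get("cont_fraction", 0.0),
            qual=int(s.get("qual", 30)),
            seed=rng_seed,
        )
        pio.write_fasta([endo, cont], out / "haplotypes.fasta")
        pio.write_fasta(panel, out / "panel.fasta")
        pio.write_fragments_tsv(fragments, out / "fragments.tsv")
        mean_len = float(np.mean([len(f) for f in fragments])) if fragments else 0.0
        report["stages"]["simulate"] = {
            "L": L,
            "n_fragments": n,
            "cont_fraction": s.get("cont_fraction", 0.0),
            "mean_fragment_length": mean_len,
            "outputs": ["haplotypes.fasta", "panel.fasta", "fragments.tsv"],
        }

    consensus_hap = None
    damage_profile = None
    pileup = None
    if cfg.enabled("consensus"):
        c = dict(cfg.consensus)
        if fragments is None:
            fragments = pio.read_fragments_tsv(c["fragments"])
            L = int(c["L"])
        pileup = build_pileup(fragments, L=L, circular=True)
        # two-pass: majority-style first call, damage profile against it,
        # then the damage-aware final call
        first = call_consensus(pileup, damage=None, coverage_cutoff=1)
        damage_profile = estimate_damage_profile(pileup, first.haplotype())
        final = call_consensus(
            pileup,
            damage=damage_profile,
            coverage_cutoff=int(c.get("coverage_cutoff", 1)),
            posterior_cutoff=c.get("posterior_cutoff"),
        )
        masks = [tuple(r) for r in c.get("masks", [])]
        if masks:
            final = apply_masks(final, masks)
        consensus_hap = final.haplotype()
        pio.write_consensus(final, out / "consensus.fasta", out / "consensus_posterior.tsv")
        if final.mask_annotations:
            pio.write_masks_tsv(final.mask_annotations, out / "masks.tsv")
        errors = None
        if endo is not None:
            errors = sum(
                1
                for a, b in zip(final.seq, endo.seq)
                if a != "N" and a != b
            )
        report["stages"]["consensus"] = {
            "n_unassigned": final.n_unassigned(),
            "coverage_cutoff": int(c.get("coverage_cutoff", 1)),
            "mean_depth": float(pileup.depth()[1:].mean()),
            **({"errors_vs_truth": errors} if errors is not None else {}),
            "outputs": ["consensus.fasta", "consensus_posterior.tsv"],
        }

    if cfg.enabled("contamination"):
        k = dict(cfg.contamination)
        if consensus_hap is None:
            consensus_hap = pio.read_fasta(k["consensus_fasta"])[0]
        if not panel:
            panel = pio.read_fasta(k["panel_fasta"])
        if pileup is None:
            pileup = build_pileup(fragments, L=len(consensus_hap), circular=True)
        estimates = {}
        dam_est = conditional_damage_estimate(
            fragments,
            consensus_hap,
            condition_window=int(k.get("condition_window", 3)),
            pileup=pileup,
        )
        estimates["damage_conditioned"] = dam_est.as_dict()
        tv_sites = find_diagnostic_sites(
            consensus_hap,
            panel,
            max_panel_freq=k.get("max_panel_freq", 0.01),
            transversions_only=True,
        )
        n_endo, n_cont = count_reads_at_sites(pileup, tv_sites)
        count_est = count_based_estimate(
            n_endo, n_cont, ci_method=k.get("ci_method", "wald")
        )
        estimates["diagnostic_count"] = {
            **count_est.as_dict(),
            "n_sites": len(tv_sites),
        }
        lik_est = panel_likelihood_estimate(
            fragments,
            consensus_hap,
            panel,
            damage=damage_profile,
            grid=k.get("grid", 0.001),
            max_panel_freq=k.get("max_panel_freq", 0.01),
            pileup=pileup,
        )
        estimates["panel_likelihood"] = lik_est.as_dict()
        pio.write_json(estimates, out / "contamination.json")
        report["stages"]["contamination"] = {
            m: e["point"] for m, e in estimates.items()
        } | {"outputs": ["contamination.json"]}

    if cfg.enabled("diversity"):
        d = dict(cfg.diversity)
        block: dict = {"outputs": []}
        if "alignment" in d:
            aln = pio.load_alignment_fasta(d["alignment"])
            dm = pairwise_differences(aln)
            dm.to_frame().to_csv(out / "distances.tsv", sep="\t")
            K = segregating_sites(aln)
            stats = watterson_theta(
                K,
                aln.n,
                L=int(d.get("L_sites", 16595)),
                convention=d.get("convention", "inclusive"),
            )
            block.update(stats.as_dict())
            block["outputs"].append("distances.tsv")
        elif {"K", "n"} <= set(d):
            stats = watterson_theta(
                int(d["K"]),
                int(d["n"]),
                L=int(d.get("L_sites", 16595)),
                convention=d.get("convention", "inclusive"),
            )
            block.update(stats.as_dict())
        else:
            raise ValueError("diversity stage needs 'alignment' or counts K and n")
        pio.write_json({k: v for k, v in block.items() if k != "outputs"},
                       out / "diversity.json")
        block["outputs"].append("diversity.json")
        report["stages"]["diversity"] = block

    if cfg.enabled("replacement"):
        r = dict(cfg.replacement)
        params = ReplacementParams(
            N=r.get("N", 5000), p=r.get("p", 0.001), gen_time=r.get("gen_time", 29.0)
        )
        block = {
            "N": r.get("N", 5000),
            "p": params.p,
            "gen_time": params.gen_time,
        }
        if np.isscalar(params.N):
            gens, years = conditional_fixation_time(params)
            block.update(
                fixation_generations=gens,
                fixation_years=years,
                fixation_ka=years / 1000.0,
            )
        if "sim" in r:
            sim = dict(r["sim"])
            prob, se = replacement_probability_sim(
                sim.get("trajectory", r.get("N", 5000)),
                sim.get("admixture", {"pulse": params.p}),
                reps=int(sim.get("reps", 1000)),
                seed=seeds["replacement"],
            )
            block["replacement_probability"] = prob
            block["replacement_probability_se"] = se
        pio.write_json(block, out / "replacement.json")
        block["outputs"] = ["replacement.json"]
        report["stages"]["replacement"] = block

    pio.write_json(report, out / "report.json")
    return report
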