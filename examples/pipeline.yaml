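# End-to-end synthetic run: simulate a contaminated aDNA fragment set,
# call the damage-aware consensus, estimate contamination three ways, and
# evaluate the neutral replacement model.
seed: 404
outdir: paleomito_out

simulate:
  L: 2000            # reference length (bp), circular
  coverage: 35.0     # mean fold coverage (sets the fragment count)
  mean_len: 43.0
  len_sd: 6.0
  delta5: 0.5        # terminal C->T rate, 5' end
  delta3: 0.5        # terminal G->A rate, 3' end
  decay: 0.5         # geometric decay of damage into the fragment
  cont_fraction: 0.10
  n_transitions: 60  # endogenous vs contaminant divergence
  n_transversions: 40
  panel_size: 40

consensus:
  coverage_cutoff: 1
  masks:
    - [303, 315, poly-C]
    - [518, 524, poly-AC]

contamination:
  max_panel_freq: 0.01
  ci_method: wald

replacement:
  N: 5000
  p: 0.001
  gen_time: 29.0
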