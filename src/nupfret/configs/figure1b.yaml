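# Two-population smFRET condition: unbound (E = 0.6) and CRM1-bound (E = 0.2)
# molecules at equal weight, with donor-only / acceptor-only contaminants.
seed: 1
stages: [bursts]
bursts:
  n_bursts: 5000
  species:
    e_unbound: 0.6
    e_bound: 0.2
    fraction_bound: 0.5
    donor_only: 0.2
    acceptor_only: 0.05
  pda_states: 2
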