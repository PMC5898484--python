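# K_D titrations: bound-fraction isotherms at the wild-type (35 nM) and
# triple proline-mutant (222 nM) dissociation constants, 2000 bursts/point.
seed: 1
stages: [titration]
titration:
  titrations:
    - name: wildtype
      kd_M: 3.5e-8
      concentrations_M: [5.0e-9, 1.0e-8, 2.0e-8, 4.0e-8, 8.0e-8, 1.5e-7, 3.0e-7, 5.0e-7]
      n_bursts_per_point: 2000
    - name: triple_mutant
      kd_M: 2.22e-7
      concentrations_M: [2.0e-8, 5.0e-8, 1.0e-7, 2.0e-7, 4.0e-7, 8.0e-7, 1.6e-6, 3.0e-6]
      n_bursts_per_point: 2000
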