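# Stopped-flow rate regimes: association series per complex (k_on from the
# k_obs-vs-concentration slope) and chase dissociation traces (k_off,
# half-lives and their ratio).  t_max_s / dt_s apply to the first (lowest)
# concentration and are scaled down proportionally at higher concentrations.
# noise_sd is ~1% of the full signal amplitude (0.05 signal units).
seed: 1
stages: [kinetics]
kinetics:
  regimes:
    - name: nup214_crm1
      k_on: 4.0e+7        # M^-1 s^-1
      k_off: 1.0          # s^-1 (intercept scale)
      concentrations_M: [2.5e-7, 5.0e-7, 7.5e-7, 1.0e-6, 1.25e-6, 1.5e-6, 1.75e-6, 2.0e-6]
      t_max_s: 0.5
      dt_s: 5.0e-4
      noise_sd: 5.0e-4
    - name: nup214_crm1_rangtp
      k_on: 2.1e+7
      k_off: 0.14
      concentrations_M: [2.5e-7, 5.0e-7, 7.5e-7, 1.0e-6, 1.25e-6, 1.5e-6, 1.75e-6, 2.0e-6]
      t_max_s: 1.0
      dt_s: 1.0e-3
      noise_sd: 5.0e-4
    - name: nup153glc_impb
      k_on: 8.5e+8
      k_off: 8.7
      concentrations_M: [2.5e-8, 5.0e-8, 7.5e-8, 1.0e-7, 1.25e-7, 1.5e-7, 1.75e-7, 2.0e-7]
      t_max_s: 0.2
      dt_s: 2.0e-4
      noise_sd: 5.0e-4
  dissociation:
    - name: nup153_impb
      k_off: 8.7          # s^-1 -> half-life 0.08 s
      t_max_s: 0.8
      dt_s: 8.0e-4
      noise_sd: 5.0e-4
    - name: nup214_crm1_rangtp
      k_off: 0.14         # s^-1 -> half-life ~5 s
      t_max_s: 35.0
      dt_s: 3.5e-2
      noise_sd: 5.0e-4
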