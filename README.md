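# nupfret

Quantitative analysis of FG-nucleoporin / nuclear-transport-receptor (NTR)
binding: single-molecule FRET burst analysis with photon distribution
analysis (PDA), stopped-flow association/dissociation kinetics,
titration-based K_D estimation, a multivalent-avidity model for per-motif
dissociation rates, and conformational-ensemble statistics — together with a
seeded synthetic-data generator so the whole pipeline is testable end to end
without any raw photon streams or trajectories.

## The scientific problem

Intrinsically disordered, phenylalanine-glycine-rich nucleoporins (FG-Nups)
form the permeability barrier of the nuclear pore complex. Transport
receptors such as Importin-β and CRM1 cross it in milliseconds by binding FG
motifs — yet a single complex with K_D ≈ 100 nM and k_on ≤ 10⁷ M⁻¹s⁻¹ would
imply k_off = K_D·k_on ≈ 1 s⁻¹, far too slow. Resolving this puzzle requires
measuring global rate constants and inferring per-motif ones, and deciding
whether a given FG-Nup binds as an *archetypal-fuzzy* complex (its
conformational ensemble unchanged on binding) or through *coupled
reconfiguration and binding* (the ensemble expands or compacts). The
experimental signatures are:

- **smFRET with pulse-interleaved excitation.** Each diffusing molecule
  yields a photon burst; the corrected transfer efficiency
  E = F_A/(F_A + γ·F_D) and stoichiometry S = (F_A + γ·F_D)/(F_A + γ·F_D + F_AA)
  place it in a 2D histogram. Double-labelled molecules sit at S ≈ 0.5;
  an efficiency shift of that band on NTR addition (e.g. 0.6 → 0.2) reports
  a conformational change in the bound state.
- **PDA.** With N donor-excitation photons per burst, a single state of
  efficiency E produces a binomial(N, E) acceptor count — a histogram of
  known shot-noise width. Fitting the observed proximity-ratio histogram
  with one versus two states decides how many populations the data support.
- **Pseudo-first-order kinetics.** With receptor in ≥10-fold excess, the
  relaxation is single-exponential with k_obs = k_on·c + k_off; k_on is the
  slope of k_obs versus c. A chase with ~100× unlabelled competitor
  suppresses rebinding so the complex decays at k_off; t½ = ln2/k_off.
- **Titrations.** The bound-burst fraction follows f = c/(c + K_D).
- **Avidity.** An engaged complex with N motifs is a birth–death chain on
  the number k of bound motifs (up-rate (N−k)·k_on,ind·c_local, down-rate
  k·k_off,ind); global dissociation is first passage to k = 0, which can be
  orders of magnitude slower than k_off,ind.

## Worked example

Recover k_on from eight noisy association traces and k_off from a chase
trace, at the slow-complex ground truths (4.0×10⁷ M⁻¹s⁻¹, 0.14 s⁻¹):

```python
import numpy as np
import nupfret as nf

fits = []
for i, c in enumerate(np.linspace(0.25e-6, 2e-6, 8)):
    k_obs = 4.0e7 * c + 1.0
    cfg = nf.KineticGenConfig(k_on=4.0e7, k_off=1.0, ntr_conc=c, probe_conc=c/20,
                              t_max=6/k_obs, dt=6/k_obs/1000, noise_sd=5e-4, seed=10+i)
    fits.append((c, nf.fit_exponential(nf.simulate_association_trace(cfg))))
print(nf.fit_kon(fits).summary())

cfg = nf.KineticGenConfig(k_on=1e7, k_off=0.14, t_max=6/0.14, dt=6/0.14/1000,
                          noise_sd=5e-4, seed=50)
print(nf.fit_koff(nf.simulate_dissociation_trace(cfg)).summary())
```

```
k_obs versus concentration (weighted linear fit)
  k_on        3.998e+07 M^-1 s^-1  (se 8.36e+04)
  intercept   1.004 s^-1      (se 0.0521)
  R^2        0.99997   n = 8

Chase dissociation fit
  k_off      0.1391 s^-1  (se 0.000414)
  half-life  4.985 s  (= ln 2 / k_off)
```

The slope recovers the true association rate constant within its standard
error; the intercept estimates k_off; the chase trace returns the 0.14 s⁻¹
rate, i.e. a ~5 s complex half-life.

The smFRET side, on a 5000-burst two-population mixture (E 0.6/0.2 at equal
weight, plus 20% donor-only and 5% acceptor-only contaminants):

```python
species = nf.two_state_species(e_unbound=0.6, e_bound=0.2, fraction_bound=0.5,
                               donor_only=0.2, acceptor_only=0.05)
bursts = nf.simulate_bursts(species, nf.BurstGenConfig(n_bursts=5000, seed=60))
points = nf.compute_es(bursts)
sel = nf.select_fret_species(points)            # S in [0.3, 0.7]
print(nf.split_populations(sel).fraction_bound) # 0.501
```

and a two-state PDA fit of the same selection reports
`E = 0.199 / 0.598, fractions 0.496 / 0.504, reduced chi2 = 1.5` — both
state efficiencies and the mixing fraction recovered at shot-noise-limited
precision.

The same analyses are scriptable from the shell (`nupfret run --fixture
figure2`, `nupfret fit-kd`, `nupfret avidity invert ...`; see
`nupfret --help`).

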