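# Methods

This note records the models implemented in `nupfret`, their assumptions,
the defaults that matter, and the numerical choices made where the design
was genuinely open. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Synthetic data generation

The generator produces data with exactly the statistical structure each
downstream estimator assumes; it is the test bed for the whole pipeline,
not a physical simulator.

**Bursts.** Each burst draws a species by its population fraction, a total
photon count from a log-normal clipped below at `min_size` (defaults
`size_log_mean = 4.0`, `size_log_sd = 0.5`, `min_size = 30` photons — the
typical brightness law for molecules diffusing through a confocal volume;
no acquisition statistics are available for this system, so these are
explicit stand-ins), and splits photons between donor- and
acceptor-excitation periods binomially with `duty_cycle = 0.5`, which
places double-labelled molecules at stoichiometry S ≈ 0.5. For
double-labelled species the acceptor count under donor excitation is
binomial with success probability equal to the *apparent* efficiency
implied by the true efficiency and the correction factors (so that the
standard correction formula inverts it exactly in expectation). Donor-only
species emit their whole budget in the donor-excitation period; acceptor-
only species in the acceptor-excitation period plus δ-scaled direct
excitation. Default contaminant fractions 20% donor-only / 5% acceptor-only
exercise the stoichiometry filter. Per-channel Poisson background is
available but defaults to zero. What this deliberately does *not* model:
diffusion through the observation volume, dye photophysics (blinking,
bleaching within a burst), interconversion during a burst, or anisotropy
optics. Passing tests therefore demonstrate correctness of the inference
chain under shot-noise statistics, not robustness to those artefacts in
real recordings.

**Kinetic traces.** Association: f(t) = f_eq·(1 − e^{−k_obs t}) with
k_obs = k_on·c + k_off and f_eq = c/(c + K_D); the signal is a generic
linear reporter of bound fraction with additive Gaussian noise (no G-factor
arithmetic, no instrument dead time). Generation refuses receptor excess
below 10-fold, the validity boundary of the pseudo-first-order
approximation. Chase dissociation is a pure exponential — rebinding is
treated as fully suppressed, which is the operational meaning of a ≥10×
(typically 100×) competitor excess; the generator refuses smaller excess.

**Titrations** draw bound counts binomially from p = c/(c + K_D) at each
concentration — the sampling model of counting bound versus unbound bursts.
Ligand depletion is ignored because the labelled probe sits at picomolar
concentration against nano- to micromolar titrant.

**Chain ensembles** are freely jointed chains: fixed bond length (default
0.38 nm, the Cα–Cα distance), isotropic step directions. They provide the
closed forms ⟨R_E²⟩ = (n−1)b² and ⟨R_E²⟩/⟨R_G²⟩ → 6 used as oracles; they
are not meant to reproduce excluded volume, solvent quality, or
sequence-specific effects of real FG-Nup ensembles.

All generators take one integer seed and derive any sub-streams from it
deterministically; a fixed seed gives bit-identical output.

## Burst analysis

Corrections default to γ = 1, α = δ = 0, background 0 — i.e. the raw
proximity ratio — because no correction values are available for this
system; all are configurable, and whether a reported efficiency is
γ-corrected or a proximity ratio is left to the caller (the tests use
γ = 1). The stoichiometry window defaults to [0.3, 0.7], bracketing the
S = 0.5 double-label band while excluding S ≈ 1 and S ≈ 0 contaminants. The
E histogram spans [−0.1, 1.1] in 55 bins (0.022/bin) so correction-induced
out-of-range values stay visible. Bursts whose corrected denominator
vanishes (e.g. acceptor-only bursts with no donor-excitation photons) are
flagged invalid and counted, never silently dropped.

Population splitting offers a threshold method (boundary at the midpoint of
the configured state efficiencies, default 0.4 for the 0.2/0.6 pair) and a
two-Gaussian histogram fit whose bound fraction is the weight of the
lower-E component. The two-Gaussian fit falls back to the threshold, with a
logged notice, when the fitted components touch (|μ₁ − μ₂| < σ₁ + σ₂) —
the operational definition of an unresolved single mode. The threshold
estimator carries a small, known bias from the overlap tails (the fraction
of each population crossing the boundary); at the default state separation
and burst sizes this is below one percentage point, and the unbiasedness
test budgets for it explicitly.

The burst search is an all-photon sliding-window method: any window of
`window_ms = 0.5` containing ≥ `min_rate = 20` photons marks its photons
dense; contiguous dense photons merge, and candidates below
`min_total = 50` photons are discarded. These are stated as package
defaults, chosen at the order of magnitude customary for diffusing-molecule
experiments.

## Photon distribution analysis

The forward model is the shot-noise-limited histogram: for each state and
each burst size N in the *empirical* size distribution of the analysed
bursts (taken as-is, not parameterised — this removes a nuisance
assumption), the acceptor count is binomial(N, E); optional per-channel
Poisson background is convolved exactly over a truncated support
(mean + 10√mean + 10); proximity ratios are binned on 40 uniform bins of
[0, 1] with the last bin right-inclusive, the same convention used when
binning data, so model and data can never disagree by an edge case.

Fitting minimises the Pearson chi-square between observed counts and the
expected histogram scaled to the total, after merging adjacent bins until
each merged bin has expected count ≥ 5 (the classical validity rule).
Free parameters: each state's efficiency, plus one fraction for two states,
mapped through a logistic so the optimiser (Nelder–Mead, fixed tolerances)
stays in (0, 1) — deterministic given the data and initial values. Default
initialisation splits the histogram at the interior valley between the
first and third quartile bins; ties resolve toward equal fractions.
Standard errors come from the curvature of the chi-square at the optimum
(cov = 2H⁻¹, the usual chi-square-as-deviance approximation). A reduced
chi-square ratio > 3 between the one- and two-state fits is the package's
default rule for preferring the richer model. Dynamic PDA (interconversion
within bursts) and global γ/β fitting are out of scope.

## Stopped-flow fitting

Single exponential only — signal = offset + amplitude·e^{−kt} — fitted by
Levenberg–Marquardt with initial values from a log-linear regression of the
detrended signal; standard errors from the fit covariance. Flat or
non-identifiable traces raise instead of returning garbage, and traces
spanning fewer than three relaxation times warn. k_on is the slope of a
weighted linear fit of k_obs versus concentration (weights 1/SE² when the
per-trace errors exist, unit weights otherwise; weighting is configurable
because practice varies); the intercept is reported as a k_off estimate and
is not constrained. A fitted non-positive slope is an error, not a result.

## Binding and avidity

K_D comes from weighted least squares of f = c/(c + K_D), weights from the
binomial variance p(1−p)/n floored at the half-count resolution 1/(4n²) so
saturated endpoints keep finite weight. The fit requires ≥ 4 concentrations
spanning a decade and refuses all-saturated data.

The avidity model treats the engaged complex as a birth–death chain on the
number of simultaneously bound motifs, with independent equivalent motifs:
up-rate (N−k)·k_on,ind·c_local, down-rate k·k_off,ind. This is the minimal
testable formalisation of multivalent rebinding; heterogeneous affinities
and polymer tethering geometry are deliberately excluded, and outputs
derived from it are labelled model-dependent. `c_local` defaults to 50 mM,
the order of the effective phenylalanine concentration inside the pore
barrier; it is a free input for other scenarios. Global dissociation is
first passage to k = 0, computed two ways:

- `single_bond` start (the docking scenario): 1/MFPT from k = 1, with the
  MFPT from the exact positive recursion h_N = 1/μ_N,
  h_k = (1 + λ_k h_{k+1})/μ_k, T_k = Σ_{j≤k} h_j — no cancellation, stable
  to the edge of floating-point range.
- `quasi_stationary` start (what a macroscopic chase measures; the
  default): the decay rate of the quasi-stationary ensemble, i.e. minus the
  dominant eigenvalue of the generator restricted to the transient states.
  When that eigenvalue falls below the numerical noise floor (10⁻¹⁰ times
  the largest rate — extreme rebinding), the code switches to the
  reciprocal mean absorption time from the detailed-balance occupancy,
  which is the limit the eigenvalue approaches exactly in that regime.

Both reduce to k_off,ind at N = 1 and at c_local = 0. Inversion (finding
k_off,ind from a measured global rate) exploits strict monotonicity and
bisects on a log scale within [measured, 10¹²·measured]; amplifications
beyond 10¹² are reported as out of bracket rather than extrapolated.

## Ensemble observables

R_E and R_G are plain Euclidean/centroid quantities (mass-uniform R_G).
RMSF optionally superposes each model on the ensemble mean by Kabsch SVD,
refining the reference twice (mean → fit → new mean) — the standard
deterministic fluctuation analysis. B = (8π²/3)·RMSF² with RMSF converted
to Å, the crystallographic isotropic convention. Helicity uses a
dihedral-basin criterion — φ ∈ [−100°, −30°], ψ ∈ [−67°, −7°], in runs of
≥ 4 consecutive residues — rather than a full secondary-structure
assignment: it needs no hydrogen positions and is exactly testable on
synthetic dihedrals; basin bounds and window are configurable. FRET
averaging uses E = 1/(1 + (r/R₀)⁶) per model under the isotropic
fast-orientational-averaging assumption, with conformations static on the
fluorescence timescale; R₀ defaults to 5.4 nm for the Alexa488/Alexa594
pair (a literature convention, flagged in CLI output because it is not a
measured input). Coordinates are nm internally; PDB I/O (via biotite,
multi-model, Cα-only tolerated) converts from Å.

## Problem sizes and reproducibility

The shipped configurations use sizes at which every estimator is
comfortably converged while runs stay interactive: 8 concentrations and
~1000 samples per kinetic trace with 1% noise; 5000 bursts for population
analysis; 2000 bursts/point × 8 concentrations × 20 seeds for K_D
recovery; 10⁶ bursts for the PDA forward-model oracle; 10⁵ stochastic runs
for the first-passage oracle; 10⁴ conformers for chain statistics. Every
random quantity is driven by a single integer seed, and pipeline runs write
a manifest (parameters, seed, version, outputs) so identical configs
byte-reproduce identical results.

## Known limitations

- The generator's burst model omits diffusion-path brightness variation,
  photophysics and within-burst dynamics; PDA here cannot be validated
  against those artefacts.
- Corrections (γ, α, δ, backgrounds) default to idealised values; analysing
  real data requires calibrating them externally.
- The avidity chain assumes independent, equivalent motifs with a single
  effective local concentration; inferred per-motif rates are estimates
  conditional on that structure and on N and c_local.
- The helicity criterion is a dihedral-basin proxy, not DSSP; absolute
  helical percentages from it are not comparable across assignment methods.
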