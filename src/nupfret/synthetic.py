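"""Seeded synthetic data generators for the smFRET / kinetics pipeline.

Every downstream stage in this package (burst analysis, PDA, stopped-flow
fitting, titration K_D estimation, ensemble statistics) is exercised against
data produced here: two-state FRET photon-count mixtures with shot-noise
statistics, pseudo-first-order association and chase-dissociation traces,
binomial binding titrations, and ideal Gaussian-chain conformer ensembles.

All generators take a single integer seed; sub-streams are derived
deterministically with :func:`numpy.random.default_rng`, so a fixed seed
yields bit-identical output across runs.

Units: concentrations in molar, time in seconds (trace time axes) or
milliseconds (burst durations, stated per field), rates in s^-1 and M^-1 s^-1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np

from .bursts import BurstSet, CorrectionFactors
from .kinetics import KineticTrace
from .binding import TitrationSeries
from .ensemble import ConformerEnsemble

__all__ = [
    "LabelState",
    "FretSpecies",
    "BurstGenConfig",
    "KineticGenConfig",
    "simulate_bursts",
    "simulate_association_trace",
    "simulate_dissociation_trace",
    "simulate_titration",
    "simulate_gaussian_chain",
]


class LabelState(str, Enum):
    """Dye labelling state of a molecular species."""

    DONOR_ACCEPTOR = "donor_acceptor"
    DONOR_ONLY = "donor_only"
    ACCEPTOR_ONLY = "acceptor_only"


@dataclass(frozen=True)
class FretSpecies:
    """One molecular species in a FRET mixture.

    Parameters
    ----------
    e_true : float
        True transfer efficiency in [0, 1].  Ignored (treated as 0) for
        donor-only species, which transfer nothing.
    fraction : float
        Population weight; fractions over a species list must sum to 1.
    label_state : LabelState
        Which dyes are photoactive.
    """

    e_true: float
    fraction: float
    label_state: LabelState = LabelState.DONOR_ACCEPTOR

    def __post_init__(self):
        if not 0.0 <= self.e_true <= 1.0:
            raise ValueError(f"e_true must be in [0, 1], got {self.e_true}")
        if self.fraction < 0:
            raise ValueError("fraction must be nonnegative")


# Default contaminant fractions: dye bleaching / incomplete labelling produce
# donor-only (S ~ 1) and acceptor-only (S ~ 0) molecules alongside the
# double-labelled band at S ~ 0.5.
DEFAULT_DONOR_ONLY_FRACTION = 0.20
DEFAULT_ACCEPTOR_ONLY_FRACTION = 0.05


def two_state_species(
    e_unbound: float = 0.6,
    e_bound: float = 0.2,
    fraction_bound: float = 0.5,
    donor_only: float = 0.0,
    acceptor_only: float = 0.0,
) -> list[FretSpecies]:
    """Convenience builder for the canonical bound/unbound mixture.

    Defaults are the unglycosylated FG-Nup214 efficiencies (unbound 0.6,
    CRM1-bound 0.2).  Contaminant fractions are taken out of the total; the
    remaining double-labelled weight is split ``fraction_bound`` /
    ``1 - fraction_bound``.
    """
    dl = 1.0 - donor_only - acceptor_only
    if dl <= 0:
        raise ValueError("contaminant fractions leave no double-labelled weight")
    species = [
        FretSpecies(e_unbound, dl * (1.0 - fraction_bound)),
        FretSpecies(e_bound, dl * fraction_bound),
    ]
    if donor_only > 0:
        species.append(FretSpecies(0.0, donor_only, LabelState.DONOR_ONLY))
    if acceptor_only > 0:
        species.append(FretSpecies(0.0, acceptor_only, LabelState.ACCEPTOR_ONLY))
    return species


@dataclass
class BurstGenConfig:
    """Acquisition-level parameters for burst simulation.

    Burst sizes follow a clipped log-normal (log-mean ``size_log_mean``,
    log-SD ``size_log_sd``, floor ``min_size``) — the typical brightness law
    for molecules diffusing through a confocal volume.  ``duty_cycle`` is the
    fraction of a burst's photons collected during the donor-excitation
    period of the interleaved excitation cycle; 0.5 gives stoichiometry
    S ~ 0.5 for double-labelled molecules.
    """

    n_bursts: int = 5000
    size_log_mean: float = 4.0
    size_log_sd: float = 0.5
    min_size: int = 30
    duty_cycle: float = 0.5
    background_rates: tuple[float, float, float] = (0.0, 0.0, 0.0)  # photons/burst: D_Dex, A_Dex, A_Aex
    corrections: CorrectionFactors = field(default_factory=CorrectionFactors)
    seed: int = 0

    def __post_init__(self):
        if self.n_bursts < 1:
            raise ValueError("n_bursts must be >= 1")
        if self.min_size < 10:
            raise ValueError("min_size must be >= 10")
        if not 0.0 < self.duty_cycle < 1.0:
            raise ValueError("duty_cycle must be in (0, 1)")


def _apparent_efficiency(e_true: float, corr: CorrectionFactors, aex_over_total: float) -> float:
    """Probability that a donor-excitation photon lands in the acceptor channel.

    Chosen so that the standard corrected-efficiency formula applied to the
    expected counts returns ``e_true``.  With gamma=1, alpha=delta=0 this is
    just ``e_true``.  ``aex_over_total`` is E[n_acceptor_Aex] / E[n_Dex].
    """
    if e_true >= 1.0:
        return 1.0
    c = corr.alpha + corr.gamma * e_true / (1.0 - e_true)
    return (c + corr.delta * aex_over_total) / (1.0 + c)


def simulate_bursts(species: Sequence[FretSpecies], config: BurstGenConfig) -> BurstSet:
    """Simulate a photon-burst set for a mixture of FRET species.

    Per burst: a species is drawn by fraction; the total photon count from a
    clipped log-normal; photons split between donor- and acceptor-excitation
    periods binomially by ``duty_cycle``; for double-labelled species the
    acceptor counts under donor excitation are binomial with success
    probability equal to the apparent efficiency implied by ``e_true`` and the
    correction factors; acceptor-excitation photons appear only when the
    acceptor dye is active; Poisson background is added per channel.

    Returns a :class:`~nupfret.bursts.BurstSet` carrying a ground-truth
    ``species_index`` per burst.
    """
    fractions = np.array([sp.fraction for sp in species], dtype=float)
    if len(fractions) == 0 or abs(fractions.sum() - 1.0) > 1e-9:
        raise ValueError("species fractions must sum to 1 within 1e-9")
    rng = np.random.default_rng(config.seed)
    n = config.n_bursts

    which = rng.choice(len(species), size=n, p=fractions)
    totals = np.rint(np.exp(rng.normal(config.size_log_mean, config.size_log_sd, size=n))).astype(int)
    totals = np.maximum(totals, config.min_size)

    n_dex = rng.binomial(totals, config.duty_cycle)
    n_aex = totals - n_dex

    n_donor_dex = np.zeros(n, dtype=int)
    n_acceptor_dex = np.zeros(n, dtype=int)
    n_acceptor_aex = np.zeros(n, dtype=int)

    corr = config.corrections
    aex_ratio = (1.0 - config.duty_cycle) / config.duty_cycle
    for idx, sp in enumerate(species):
        m = which == idx
        if not m.any():
            continue
        if sp.label_state is LabelState.DONOR_ACCEPTOR:
            p = _apparent_efficiency(sp.e_true, corr, aex_ratio)
            n_acceptor_dex[m] = rng.binomial(n_dex[m], p)
            n_donor_dex[m] = n_dex[m] - n_acceptor_dex[m]
            n_acceptor_aex[m] = n_aex[m]
        elif sp.label_state is LabelState.DONOR_ONLY:
            # no acceptor: the whole detected budget is donor-excitation
            # photons; donor leakage puts a fraction alpha/(1+alpha) of them
            # in the acceptor channel
            p = corr.alpha / (1.0 + corr.alpha)
            n_acceptor_dex[m] = rng.binomial(totals[m], p)
            n_donor_dex[m] = totals[m] - n_acceptor_dex[m]
        else:
            # acceptor only: the detected budget is acceptor-excitation
            # photons plus delta-scaled direct-excitation counts under Dex
            n_acceptor_aex[m] = totals[m]
            n_acceptor_dex[m] = rng.poisson(corr.delta * totals[m])

    bg_d, bg_a, bg_aa = config.background_rates
    if bg_d > 0:
        n_donor_dex = n_donor_dex + rng.poisson(bg_d, size=n)
    if bg_a > 0:
        n_acceptor_dex = n_acceptor_dex + rng.poisson(bg_a, size=n)
    if bg_aa > 0:
        n_acceptor_aex = n_acceptor_aex + rng.poisson(bg_aa, size=n)

    # nominal brightness 50 photons/ms sets the duration scale; only used for
    # background subtraction downstream (zero by default)
    duration_ms = totals / 50.0

    return BurstSet(
        n_donor_dex=n_donor_dex,
        n_acceptor_dex=n_acceptor_dex,
        n_acceptor_aex=n_acceptor_aex,
        duration_ms=duration_ms,
        species_index=which,
    )


@dataclass
class KineticGenConfig:
    """Ground truth and acquisition parameters for a stopped-flow trace.

    Rates in s^-1 / M^-1 s^-1, concentrations in molar.  ``ntr_conc`` is the
    transport-receptor concentration after mixing; pseudo-first-order
    generation requires at least 10-fold excess over ``probe_conc``.
    """

    k_on: float = 4.0e7
    k_off: float = 0.5
    ntr_conc: float = 1e-6
    probe_conc: float = 20e-9
    t_max: float = 1.0
    dt: float = 1e-3
    signal_bound: float = 0.20
    signal_free: float = 0.15
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.k_on <= 0:
            raise ValueError("k_on must be > 0")
        if self.k_off < 0:
            raise ValueError("k_off must be >= 0")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")


def simulate_association_trace(config: KineticGenConfig) -> KineticTrace:
    """Pseudo-first-order association relaxation with Gaussian noise.

    Bound fraction f(t) = f_eq (1 - exp(-k_obs t)) with
    k_obs = k_on * c + k_off and f_eq = c / (c + k_off/k_on); the signal is a
    linear reporter of the bound fraction.
    """
    if config.ntr_conc < 10.0 * config.probe_conc:
        raise ValueError(
            "pseudo-first-order condition violated: ntr_conc must be >= 10 x "
            f"probe_conc (got {config.ntr_conc:g} M vs {config.probe_conc:g} M)"
        )
    t = np.arange(0.0, config.t_max + 0.5 * config.dt, config.dt)
    k_obs = config.k_on * config.ntr_conc + config.k_off
    kd = config.k_off / config.k_on
    f_eq = config.ntr_conc / (config.ntr_conc + kd)
    f = f_eq * (1.0 - np.exp(-k_obs * t))
    signal = config.signal_free + (config.signal_bound - config.signal_free) * f
    if config.noise_sd > 0:
        rng = np.random.default_rng(config.seed)
        signal = signal + rng.normal(0.0, config.noise_sd, size=t.size)
    return KineticTrace(time=t, signal=signal, ntr_conc=config.ntr_conc, kind="association",
                        meta={"seed": config.seed, "k_on_true": config.k_on, "k_off_true": config.k_off})


def simulate_dissociation_trace(config: KineticGenConfig, chase_excess_fold: float = 100.0) -> KineticTrace:
    """Chase dissociation of a preformed complex under excess unlabelled competitor.

    Rebinding of the labelled species is treated as fully suppressed (valid
    for >= 10-fold competitor excess, typically 100x in practice), so the
    bound fraction decays as a pure exponential f(t) = f0 exp(-k_off t).
    """
    if chase_excess_fold < 10:
        raise ValueError(
            "chase approximation invalid: competitor excess must be >= 10-fold "
            f"to suppress rebinding (got {chase_excess_fold:g})"
        )
    t = np.arange(0.0, config.t_max + 0.5 * config.dt, config.dt)
    kd = config.k_off / config.k_on
    f0 = config.ntr_conc / (config.ntr_conc + kd)  # preformed-complex occupancy
    f = f0 * np.exp(-config.k_off * t)
    signal = config.signal_free + (config.signal_bound - config.signal_free) * f
    if config.noise_sd > 0:
        rng = np.random.default_rng(config.seed)
        signal = signal + rng.normal(0.0, config.noise_sd, size=t.size)
    return KineticTrace(time=t, signal=signal, ntr_conc=config.ntr_conc, kind="dissociation",
                        meta={"seed": config.seed, "k_off_true": config.k_off,
                              "chase_excess_fold": chase_excess_fold})


def simulate_titration(
    kd: float,
    concentrations: Sequence[float],
    n_bursts_per_point: int = 2000,
    seed: int = 0,
) -> TitrationSeries:
    """Binomial sampling of bound fractions along a binding isotherm.

    At each receptor concentration c the true bound probability is
    p = c / (c + K_D); the observed bound-burst count is drawn binomially
    from ``n_bursts_per_point`` trials.
    """
    if kd <= 0:
        raise ValueError("kd must be > 0")
    conc = np.asarray(concentrations, dtype=float)
    if conc.size == 0:
        raise ValueError("concentration list must not be empty")
    if (conc < 0).any():
        raise ValueError("concentrations must be >= 0")
    rng = np.random.default_rng(seed)
    p = conc / (conc + kd)
    counts = rng.binomial(n_bursts_per_point, p)
    return TitrationSeries(
        ntr_conc=conc,
        fraction_bound=counts / n_bursts_per_point,
        n_bursts=np.full(conc.size, n_bursts_per_point, dtype=int),
    )


def simulate_gaussian_chain(
    n_residues: int,
    bond_length: float = 0.38,
    n_models: int = 1000,
    seed: int = 0,
) -> ConformerEnsemble:
    """Ideal (freely jointed) chain ensemble: fixed bond length, isotropic steps.

    Serves as the analytically tractable stand-in for disordered-protein
    conformer ensembles: <R_E^2> = (n-1) b^2 and <R_E^2>/<R_G^2> -> 6.
    ``bond_length`` is in nm (default 0.38, the Calpha-Calpha distance).
    """
    if n_residues < 2:
        raise ValueError("n_residues must be >= 2")
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    rng = np.random.default_rng(seed)
    steps = rng.normal(size=(n_models, n_residues - 1, 3))
    steps /= np.linalg.norm(steps, axis=2, keepdims=True)
    coords = np.zeros((n_models, n_residues, 3))
    coords[:, 1:, :] = np.cumsum(bond_length * steps, axis=1)
    return ConformerEnsemble(coords=coords)
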