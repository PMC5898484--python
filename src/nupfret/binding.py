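"""Equilibrium binding: K_D from titrations, the k_off = K_D * k_on identity,
and a multivalent-avidity model linking global and per-motif dissociation.

An FG-nucleoporin engages a transport receptor through many individually
weak phenylalanine-glycine motifs.  The macroscopically measured (global)
dissociation rate of such a complex can be orders of magnitude slower than
the per-motif rate, because a complex that loses one motif contact usually
rebinds locally before the last contact breaks.  :class:`AvidityModel`
formalizes this as a birth-death chain on the number of simultaneously
engaged motifs; global dissociation is first passage to zero engaged motifs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import bisect, curve_fit

__all__ = [
    "TitrationSeries",
    "BindingIsotherm",
    "KdFitResults",
    "fit_kd",
    "koff_from_kd",
    "AvidityModel",
    "kd_individual_from_fractions",
]


@dataclass
class TitrationSeries:
    """Bound fractions versus receptor concentration.

    ``ntr_conc`` in molar (distinct, >= 0), ``fraction_bound`` in [0, 1],
    ``n_bursts`` the number of bursts behind each fraction (for binomial
    weighting).
    """

    ntr_conc: np.ndarray
    fraction_bound: np.ndarray
    n_bursts: np.ndarray

    def __post_init__(self):
        self.ntr_conc = np.asarray(self.ntr_conc, float)
        self.fraction_bound = np.asarray(self.fraction_bound, float)
        self.n_bursts = np.asarray(self.n_bursts, int)
        if not (self.ntr_conc.size == self.fraction_bound.size == self.n_bursts.size):
            raise ValueError("titration columns must have equal length")
        if (self.ntr_conc < 0).any():
            raise ValueError("concentrations must be >= 0")
        if np.unique(self.ntr_conc).size != self.ntr_conc.size:
            raise ValueError("concentrations must be distinct")
        if ((self.fraction_bound < 0) | (self.fraction_bound > 1)).any():
            raise ValueError("fractions must lie in [0, 1]")

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({"conc_M": self.ntr_conc,
                             "fraction_bound": self.fraction_bound,
                             "n": self.n_bursts})

    @classmethod
    def from_csv(cls, path) -> "TitrationSeries":
        import pandas as pd

        df = pd.read_csv(path, comment="#")
        return cls(df["conc_M"].to_numpy(), df["fraction_bound"].to_numpy(),
                   df["n"].to_numpy())


@dataclass
class KdFitResults:
    """Hyperbolic-isotherm fit results."""

    kd: float
    kd_se: float
    ssr: float
    n_points: int

    def summary(self) -> str:
        return (
            "Binding isotherm fit  f = c / (c + K_D)\n"
            f"  K_D  {self.kd:.4g} M  (se {self.kd_se:.3g})\n"
            f"  weighted SSR {self.ssr:.4g}   n = {self.n_points}"
        )


class BindingIsotherm:
    """Single-site binding isotherm f = c / (c + K_D) fitted to a titration.

    Points are weighted by the binomial variance p(1-p)/n of the observed
    fraction (with a small floor so endpoint fractions keep finite weight).
    Ligand depletion is neglected: the labelled probe is at picomolar
    concentration against nano-to-micromolar titrant.
    """

    def __init__(self, series: TitrationSeries):
        if series.ntr_conc.size < 4:
            raise ValueError("need at least 4 concentrations")
        pos = series.ntr_conc[series.ntr_conc > 0]
        if pos.size and pos.max() / pos.min() < 10:
            raise ValueError("concentrations must span at least one decade")
        f = series.fraction_bound
        if (f < 0.02).all() or (f > 0.98).all():
            raise ValueError("all fractions saturated near 0 or 1: K_D not identifiable")
        self.series = series

    def fit(self) -> KdFitResults:
        c = self.series.ntr_conc
        f = self.series.fraction_bound
        n = self.series.n_bursts
        var = f * (1.0 - f) / np.maximum(n, 1)
        var = np.maximum(var, 1.0 / (4.0 * np.maximum(n, 1) ** 2))  # floor at half-count resolution
        sigma = np.sqrt(var)

        def isotherm(cc, kd):
            return cc / (cc + kd)

        # midpoint-crossing initial guess
        order = np.argsort(c)
        k0 = float(np.interp(0.5, f[order], c[order])) if (f.min() < 0.5 < f.max()) else float(np.median(c))
        k0 = max(k0, 1e-15)
        popt, pcov = curve_fit(isotherm, c, f, p0=[k0], sigma=sigma,
                               absolute_sigma=True, bounds=(1e-18, np.inf), maxfev=10000)
        kd = float(popt[0])
        resid = (f - isotherm(c, kd)) / sigma
        return KdFitResults(kd=kd, kd_se=float(np.sqrt(pcov[0, 0])),
                            ssr=float(resid @ resid), n_points=c.size)


def fit_kd(series: TitrationSeries) -> KdFitResults:
    """Weighted least-squares K_D from a bound-fraction titration."""
    return BindingIsotherm(series).fit()


def koff_from_kd(kd: float, k_on: float) -> float:
    """Dissociation rate implied by detailed balance, k_off = K_D * k_on."""
    if kd < 0 or k_on <= 0:
        raise ValueError("kd must be >= 0 and k_on > 0")
    return kd * k_on


def kd_individual_from_fractions(f_bound: float, c_eff: float) -> float:
    """Per-motif K_D read off an occupancy at effective motif concentration.

    Single-site equilibrium: f = c_eff / (c_eff + K_D), inverted to
    K_D = c_eff (1 - f) / f.  Used to turn bound/unbound fractions of an
    individual FG motif (e.g. from simulation trajectories) into a local
    dissociation constant.
    """
    if not 0.0 < f_bound < 1.0:
        raise ValueError("f_bound must lie strictly inside (0, 1)")
    if c_eff <= 0:
        raise ValueError("c_eff must be > 0")
    return c_eff * (1.0 - f_bound) / f_bound


@dataclass
class AvidityModel:
    """Birth-death chain on the number of simultaneously engaged FG motifs.

    States k = 0..N count the bound motifs of an engaged complex; the
    up-rate from k is (N - k) * k_on_ind * c_local (free motifs rebinding at
    the local effective concentration) and the down-rate is k * k_off_ind.
    Global dissociation is first passage to k = 0.

    The default ``c_local`` of 50 mM reflects the very high effective
    phenylalanine concentration inside the nuclear-pore permeability barrier.

    Notes
    -----
    Motifs are treated as independent and equivalent; no heterogeneous
    affinities or polymer-tethering geometry.  Results that depend on N and
    c_local are therefore model-dependent estimates.
    """

    n_motifs: int
    k_on_ind: float
    k_off_ind: float
    c_local: float = 0.050

    def __post_init__(self):
        if self.n_motifs < 1:
            raise ValueError("n_motifs must be >= 1")
        if self.k_on_ind <= 0 or self.k_off_ind <= 0 or self.c_local < 0:
            raise ValueError("rates must be > 0 and c_local >= 0")

    @property
    def kd_individual(self) -> float:
        return self.k_off_ind / self.k_on_ind

    def _rates(self):
        k = np.arange(1, self.n_motifs + 1, dtype=float)
        up = (self.n_motifs - k) * self.k_on_ind * self.c_local
        down = k * self.k_off_ind
        return up, down

    def _restricted_generator(self) -> np.ndarray:
        """Generator on transient states 1..N (state 0 absorbing)."""
        up, down = self._rates()
        n = self.n_motifs
        q = np.zeros((n, n))
        for i in range(n):
            q[i, i] = -(up[i] + down[i])
            if i + 1 < n:
                q[i, i + 1] = up[i]
            if i - 1 >= 0:
                q[i, i - 1] = down[i]
        return q

    def mean_first_passage_times(self) -> np.ndarray:
        """Mean time to full dissociation (k = 0) from each state 1..N.

        Uses the exact birth-death recursion on the mean one-step descent
        times h_k (time from k to k-1): h_N = 1/down_N,
        h_k = (1 + up_k h_{k+1}) / down_k, and T_k = sum_{j<=k} h_j.  All
        terms are positive, so the recursion is numerically stable without
        cancellation.
        """
        up, down = self._rates()
        n = self.n_motifs
        h = np.empty(n)
        h[n - 1] = 1.0 / down[n - 1]
        for k in range(n - 2, -1, -1):
            h[k] = (1.0 + up[k] * h[k + 1]) / down[k]
        t = np.cumsum(h)
        if not np.all(np.isfinite(t)):
            raise OverflowError(
                "mean first-passage time exceeds the floating-point range; "
                "rate ratio too extreme — use global_koff(log_domain=True)")
        return t

    def _detailed_balance_weights(self) -> np.ndarray:
        """Detailed-balance occupancy over states 1..N (log-space normalised).

        pi_{k+1}/pi_k = up_k/down_{k+1}; this is the stationary law of the
        chain with the absorbing exit removed and the strong-rebinding limit
        of the quasi-stationary distribution.
        """
        up, down = self._rates()
        logw = np.zeros(self.n_motifs)
        for k in range(1, self.n_motifs):
            if up[k - 1] == 0:
                logw[k:] = -np.inf
                break
            logw[k] = logw[k - 1] + math.log(up[k - 1]) - math.log(down[k])
        w = np.exp(logw - logw.max())
        return w / w.sum()

    def quasi_stationary_distribution(self) -> tuple[np.ndarray, float]:
        """QSD over states 1..N and its exponential decay rate.

        The QSD is the left eigenvector of the restricted generator for its
        dominant (least negative) eigenvalue lambda_1; conditioned on
        survival, the chain settles into this distribution and absorbs at
        rate -lambda_1.

        When the decay rate falls below the eigenvalue noise floor
        (machine epsilon times the largest rate in the chain, as happens
        under extreme rebinding), the detailed-balance occupancy replaces
        the eigenvector and the rate is taken as the reciprocal of the mean
        absorption time from it — exact in the limit that makes the
        eigenvalue unresolvable.
        """
        q = self._restricted_generator()
        vals, vecs = np.linalg.eig(q.T)
        i = int(np.argmax(vals.real))
        rate = float(-vals[i].real)
        noise_floor = 1e-10 * float(np.abs(np.diag(q)).max())
        if rate > noise_floor and np.isfinite(rate):
            dist = np.abs(vecs[:, i].real)
            dist /= dist.sum()
            return dist, rate
        dist = self._detailed_balance_weights()
        return dist, 1.0 / float(dist @ self.mean_first_passage_times())

    def global_koff(
        self,
        start: Literal["single_bond", "quasi_stationary"] = "quasi_stationary",
        log_domain: bool = False,
    ) -> float:
        """Global dissociation rate of the engaged complex.

        ``single_bond``: 1 / (mean first-passage time from k = 1) — the
        docking scenario, where the complex has just formed its first
        contact.  ``quasi_stationary``: the decay rate of the
        quasi-stationary (conditioned on not-yet-dissociated) ensemble —
        what a macroscopic chase experiment measures.  Both reduce to
        k_off_ind at N = 1 and at c_local = 0 (no rebinding).

        ``log_domain`` rescales rates to order unity before solving, for
        extreme k_on_ind * c_local / k_off_ind ratios.
        """
        if log_domain:
            scale = math.sqrt(self.k_off_ind * max(self.k_on_ind * max(self.c_local, 1e-300), self.k_off_ind))
            scaled = AvidityModel(self.n_motifs, self.k_on_ind / scale, self.k_off_ind / scale,
                                  self.c_local)
            return scaled.global_koff(start=start) * scale
        if start == "single_bond":
            return 1.0 / float(self.mean_first_passage_times()[0])
        if start == "quasi_stationary":
            _, rate = self.quasi_stationary_distribution()
            return rate
        raise ValueError(f"unknown start mode {start!r}")

    def mfpt_from(self, start_distribution: Sequence[float]) -> float:
        """Mean first-passage time to k = 0 from an arbitrary start over 1..N."""
        p = np.asarray(start_distribution, float)
        if p.size != self.n_motifs or abs(p.sum() - 1) > 1e-9 or (p < 0).any():
            raise ValueError("start distribution must be a probability vector over states 1..N")
        return float(p @ self.mean_first_passage_times())

    def with_koff_ind(self, k_off_ind: float) -> "AvidityModel":
        return AvidityModel(self.n_motifs, self.k_on_ind, k_off_ind, self.c_local)

    def invert_koff_individual(
        self,
        k_off_global_measured: float,
        start: Literal["single_bond", "quasi_stationary"] = "quasi_stationary",
        rtol: float = 1e-6,
    ) -> float:
        """Per-motif k_off that reproduces a measured global dissociation rate.

        The global rate is strictly increasing in k_off_ind, so a bracketing
        root search converges; the bracket is
        [measured, 1e12 * measured] (rebinding can only slow global
        dissociation below the per-motif rate).
        """
        if k_off_global_measured <= 0:
            raise ValueError("measured rate must be > 0")
        lo = k_off_global_measured
        hi = 1e12 * k_off_global_measured

        def f(log_k):
            # deviation of log global rate from the target; an underflowing
            # global rate counts as "far below target" (monotonicity)
            try:
                g = self.with_koff_ind(math.exp(log_k)).global_koff(start=start)
            except OverflowError:
                return -1e30
            if not math.isfinite(g) or g <= 0:
                return -1e30
            return math.log(g) - math.log(k_off_global_measured)

        flo, fhi = f(math.log(lo)), f(math.log(hi))
        if abs(flo) < 1e-12:
            return lo
        if flo * fhi > 0:
            raise ValueError(
                "no bracket for k_off_ind within [measured, 1e12 x measured]; "
                "model incompatible with the measured global rate")
        root = bisect(f, math.log(lo), math.log(hi), xtol=min(rtol, 1e-6) / 10)
        return float(math.exp(root))
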