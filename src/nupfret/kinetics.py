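"""Stopped-flow kinetics: k_obs from single-exponential traces, k_on from the
concentration dependence of k_obs, k_off from chase-dissociation traces.

Under pseudo-first-order conditions (receptor in >= 10-fold excess over the
labelled probe) a two-state binding reaction relaxes single-exponentially
with observed rate k_obs = k_on * c + k_off; k_on is the slope of k_obs
versus receptor concentration c.  Chase dissociation against excess
unlabelled competitor suppresses rebinding, so the complex decays at k_off
and the half-life is ln 2 / k_off.

The fitting API follows the model/results convention: build a model object
from data, call ``.fit()``, read estimates and standard errors off the
results object (or print ``.summary()``).  Thin functional wrappers
(:func:`fit_exponential`, :func:`fit_kon`, :func:`fit_koff`) are provided.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "KineticTrace",
    "SingleExponentialDecay",
    "ExponentialFitResults",
    "KobsRegression",
    "KonFitResults",
    "KoffResult",
    "fit_exponential",
    "fit_kon",
    "fit_koff",
    "half_life_ratio",
]


@dataclass
class KineticTrace:
    """A time-stamped stopped-flow signal.

    ``time`` in seconds (strictly increasing, >= 20 samples), ``signal`` in
    arbitrary units, ``ntr_conc`` the post-mix receptor concentration in
    molar, ``kind`` either ``"association"`` or ``"dissociation"``.
    """

    time: np.ndarray
    signal: np.ndarray
    ntr_conc: float = float("nan")
    kind: str = "association"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time = np.asarray(self.time, float)
        self.signal = np.asarray(self.signal, float)
        if self.time.size != self.signal.size:
            raise ValueError("time and signal must have equal length")
        if self.time.size < 20:
            raise ValueError("trace must have at least 20 samples")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if self.kind not in ("association", "dissociation"):
            raise ValueError("kind must be 'association' or 'dissociation'")


class NonIdentifiableError(RuntimeError):
    """Raised when a trace carries no resolvable exponential component."""


@dataclass
class ExponentialFitResults:
    """Results of a single-exponential relaxation fit.

    Model: signal(t) = offset + amplitude * exp(-k_obs * t).
    ``bse`` holds standard errors from the covariance of the nonlinear
    least-squares fit, keyed like ``params``.
    """

    k_obs: float
    amplitude: float
    offset: float
    k_obs_se: float
    amplitude_se: float
    offset_se: float
    ssr: float
    trace: KineticTrace | None = None

    @property
    def params(self) -> dict:
        return {"k_obs": self.k_obs, "amplitude": self.amplitude, "offset": self.offset}

    @property
    def bse(self) -> dict:
        return {"k_obs": self.k_obs_se, "amplitude": self.amplitude_se, "offset": self.offset_se}

    def summary(self) -> str:
        lines = ["Single-exponential relaxation fit",
                 "  signal(t) = offset + amplitude * exp(-k_obs t)", ""]
        for name in ("k_obs", "amplitude", "offset"):
            lines.append(f"  {name:<10} {self.params[name]: .6g}  (se {self.bse[name]:.3g})")
        lines.append(f"  SSR        {self.ssr:.6g}")
        return "\n".join(lines)


class SingleExponentialDecay:
    """Single-exponential relaxation model for one stopped-flow trace.

    Initial values come from a log-linear regression of the detrended signal
    (|signal - tail mean| versus t), then refined by nonlinear least squares.
    """

    def __init__(self, trace: KineticTrace):
        self.trace = trace

    def _initial_guess(self):
        t, y = self.trace.time, self.trace.signal
        n_tail = max(5, t.size // 10)
        offset0 = float(np.mean(y[-n_tail:]))
        resid = y - offset0
        amp0 = float(resid[0])
        # log-linearize on the early part where the residual keeps its sign
        mask = np.sign(resid) == np.sign(amp0 if amp0 != 0 else 1.0)
        mask &= np.abs(resid) > 1e-3 * max(abs(amp0), np.std(y), 1e-300)
        if mask.sum() >= 3:
            slope = np.polyfit(t[mask], np.log(np.abs(resid[mask])), 1)[0]
            k0 = max(-slope, 1e-12)
        else:
            k0 = 1.0 / max(t[-1] - t[0], 1e-12)
        return k0, amp0, offset0

    def fit(self) -> ExponentialFitResults:
        t, y = self.trace.time, self.trace.signal
        spread = float(np.std(y))
        if spread == 0.0 or abs(y[0] - np.mean(y[-max(5, t.size // 10):])) < 1e-12 * max(1.0, abs(y[0])):
            raise NonIdentifiableError("trace is flat: no exponential component to fit")
        k0, amp0, off0 = self._initial_guess()

        def model(tt, k, a, c):
            return c + a * np.exp(-k * tt)

        try:
            popt, pcov = curve_fit(model, t, y, p0=[k0, amp0, off0], maxfev=20000)
        except RuntimeError as err:
            raise RuntimeError(f"exponential fit did not converge: {err}") from err
        k, a, c = popt
        if k <= 0:
            raise NonIdentifiableError(f"fitted rate is non-positive ({k:g} 1/s)")
        se = np.sqrt(np.clip(np.diag(pcov), 0, None))
        resid = y - model(t, *popt)
        duration = t[-1] - t[0]
        if duration < 3.0 / k:
            warnings.warn(
                f"trace spans only {duration * k:.2f} relaxation times (< 3); "
                "k_obs may be poorly determined", stacklevel=2)
        return ExponentialFitResults(
            k_obs=float(k), amplitude=float(a), offset=float(c),
            k_obs_se=float(se[0]), amplitude_se=float(se[1]), offset_se=float(se[2]),
            ssr=float(resid @ resid), trace=self.trace,
        )


@dataclass
class KonFitResults:
    """Weighted linear fit of k_obs versus receptor concentration.

    ``k_on`` (M^-1 s^-1) is the slope; the intercept (s^-1) estimates k_off.
    """

    k_on: float
    intercept: float
    k_on_se: float
    intercept_se: float
    r_squared: float
    n_points: int

    def summary(self) -> str:
        return (
            "k_obs versus concentration (weighted linear fit)\n"
            f"  k_on       {self.k_on: .4g} M^-1 s^-1  (se {self.k_on_se:.3g})\n"
            f"  intercept  {self.intercept: .4g} s^-1      (se {self.intercept_se:.3g})\n"
            f"  R^2        {self.r_squared:.5f}   n = {self.n_points}"
        )


class KobsRegression:
    """Linear model k_obs = k_on * c + k_off over a concentration series.

    Points are weighted by the inverse variance of their k_obs estimates
    when standard errors are available (unit weights otherwise).
    """

    def __init__(self, concentrations: Sequence[float], k_obs: Sequence[float],
                 k_obs_se: Sequence[float] | None = None, weighted: bool = True):
        self.c = np.asarray(concentrations, float)
        self.k_obs = np.asarray(k_obs, float)
        if len(np.unique(self.c)) < 3:
            raise ValueError("need at least 3 distinct concentrations")
        if k_obs_se is not None and weighted:
            se = np.asarray(k_obs_se, float)
            se = np.where(se > 0, se, np.nan)
            if np.isnan(se).all():
                self.w = np.ones_like(self.c)
            else:
                se = np.where(np.isnan(se), np.nanmax(se), se)
                self.w = 1.0 / se**2
        else:
            self.w = np.ones_like(self.c)

    def fit(self) -> KonFitResults:
        X = np.column_stack([self.c, np.ones_like(self.c)])
        sw = np.sqrt(self.w)
        beta, *_ = np.linalg.lstsq(X * sw[:, None], self.k_obs * sw, rcond=None)
        slope, intercept = beta
        if slope <= 0:
            raise ValueError("fitted slope (k_on) is non-positive: linear binding model violated")
        resid = self.k_obs - X @ beta
        dof = max(len(self.c) - 2, 1)
        # scale covariance by weighted residual variance
        xtx_inv = np.linalg.inv((X * self.w[:, None]).T @ X)
        s2 = float((self.w * resid**2).sum() / dof)
        cov = xtx_inv * s2
        ybar = np.average(self.k_obs, weights=self.w)
        ss_tot = float((self.w * (self.k_obs - ybar) ** 2).sum())
        r2 = 1.0 - float((self.w * resid**2).sum()) / ss_tot if ss_tot > 0 else float("nan")
        return KonFitResults(
            k_on=float(slope), intercept=float(intercept),
            k_on_se=float(np.sqrt(cov[0, 0])), intercept_se=float(np.sqrt(cov[1, 1])),
            r_squared=r2, n_points=len(self.c),
        )


@dataclass
class KoffResult:
    """Dissociation rate and complex half-life from a chase experiment."""

    k_off: float
    k_off_se: float
    half_life: float
    fit: ExponentialFitResults | None = None

    def summary(self) -> str:
        return (
            "Chase dissociation fit\n"
            f"  k_off      {self.k_off:.4g} s^-1  (se {self.k_off_se:.3g})\n"
            f"  half-life  {self.half_life:.4g} s  (= ln 2 / k_off)"
        )


def fit_exponential(trace: KineticTrace) -> ExponentialFitResults:
    """Fit signal = offset + amplitude exp(-k_obs t) to a trace."""
    return SingleExponentialDecay(trace).fit()


def fit_kon(fits: Sequence[tuple[float, ExponentialFitResults]], weighted: bool = True) -> KonFitResults:
    """k_on from the slope of k_obs versus receptor concentration.

    ``fits`` is a sequence of (concentration in M, exponential-fit results).
    """
    conc = [c for c, _ in fits]
    kobs = [f.k_obs for _, f in fits]
    se = [f.k_obs_se for _, f in fits]
    return KobsRegression(conc, kobs, se, weighted=weighted).fit()


def fit_koff(trace: KineticTrace) -> KoffResult:
    """k_off and half-life from a chase-dissociation trace."""
    if trace.kind != "dissociation":
        raise ValueError("fit_koff requires a dissociation trace")
    res = fit_exponential(trace)
    return KoffResult(k_off=res.k_obs, k_off_se=res.k_obs_se,
                      half_life=math.log(2) / res.k_obs, fit=res)


def half_life_ratio(a: KoffResult, b: KoffResult) -> float:
    """Ratio of complex half-lives, half_life(a)/half_life(b) = k_off(b)/k_off(a)."""
    if a.k_off <= 0 or b.k_off <= 0:
        raise ValueError("both k_off values must be > 0")
    return b.k_off / a.k_off
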