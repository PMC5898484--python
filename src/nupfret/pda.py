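"""Photon distribution analysis (PDA) of shot-noise-limited FRET histograms.

A molecule with a fixed transfer efficiency still produces a broad
proximity-ratio histogram, because each burst carries finitely many photons:
with N donor-excitation photons the acceptor count is binomial(N, E).  PDA
exploits this by predicting the full histogram expected from a set of
discrete efficiency states and the measured burst-size distribution, so that
the number of conformational populations can be decided on statistical
grounds — one state whose shot-noise width matches the data, versus a
genuine mixture.

The forward model lives in :func:`pda_expected_histogram`; fitting follows
the model/results convention via :class:`PdaFit`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.optimize import minimize

__all__ = [
    "PdaModel",
    "PdaFit",
    "PdaFitResults",
    "pda_expected_histogram",
    "pda_fit",
    "proximity_ratio_histogram",
    "empirical_size_distribution",
]


def proximity_ratio_bins(n_bins: int) -> np.ndarray:
    return np.linspace(0.0, 1.0, n_bins + 1)


def _bin_indices(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Bin proximity ratios on [0, 1]; last bin right-inclusive."""
    edges = proximity_ratio_bins(n_bins)
    idx = np.searchsorted(edges, values, side="right") - 1
    return np.clip(idx, 0, n_bins - 1)


def proximity_ratio_histogram(n_acceptor: np.ndarray, n_donor: np.ndarray, n_bins: int = 40) -> np.ndarray:
    """Histogram of raw proximity ratios nA / (nA + nD) over uniform [0,1] bins."""
    n_acceptor = np.asarray(n_acceptor, float)
    n_donor = np.asarray(n_donor, float)
    tot = n_acceptor + n_donor
    pr = n_acceptor[tot > 0] / tot[tot > 0]
    return np.bincount(_bin_indices(pr, n_bins), minlength=n_bins).astype(float)


def empirical_size_distribution(dex_totals: Sequence[int]) -> tuple[np.ndarray, np.ndarray]:
    """Empirical probability over donor-excitation burst sizes."""
    sizes, counts = np.unique(np.asarray(dex_totals, int), return_counts=True)
    if sizes.size == 0:
        raise ValueError("burst-size distribution is empty")
    return sizes, counts / counts.sum()


@dataclass
class PdaModel:
    """States plus burst-size distribution defining an expected PDA histogram.

    ``states`` is a list of (apparent efficiency, fraction) pairs summing to
    1; ``sizes``/``size_probs`` the empirical distribution over total
    donor-excitation photons per burst; ``background`` mean Poisson counts
    per burst in (donor, acceptor) channels.
    """

    states: list[tuple[float, float]]
    sizes: np.ndarray
    size_probs: np.ndarray
    background: tuple[float, float] = (0.0, 0.0)
    n_bins: int = 40

    def __post_init__(self):
        self.sizes = np.asarray(self.sizes, int)
        self.size_probs = np.asarray(self.size_probs, float)
        if self.sizes.size == 0:
            raise ValueError("burst-size distribution is empty")
        if abs(self.size_probs.sum() - 1.0) > 1e-9:
            raise ValueError("size probabilities must sum to 1")
        if abs(sum(f for _, f in self.states) - 1.0) > 1e-9:
            raise ValueError("state fractions must sum to 1")


def _poisson_support(mean: float) -> np.ndarray:
    if mean <= 0:
        return np.array([0])
    hi = int(np.ceil(mean + 10.0 * np.sqrt(mean) + 10))
    return np.arange(hi + 1)


def pda_expected_histogram(model: PdaModel) -> np.ndarray:
    """Expected proximity-ratio histogram (probability per bin, sums to 1).

    For each state and each burst size N the acceptor count is
    binomial(N, e); independent Poisson backgrounds are convolved into each
    channel; ratios are binned and states mixed by their fractions.
    """
    bg_d, bg_a = model.background
    out = np.zeros(model.n_bins)
    ka = _poisson_support(bg_a)
    kd = _poisson_support(bg_d)
    pa_bg = stats.poisson.pmf(ka, bg_a) if bg_a > 0 else np.array([1.0])
    pd_bg = stats.poisson.pmf(kd, bg_d) if bg_d > 0 else np.array([1.0])
    for e, frac in model.states:
        if frac == 0:
            continue
        for n, pn in zip(model.sizes, model.size_probs):
            a = np.arange(n + 1)
            pmf = stats.binom.pmf(a, n, e)
            if bg_a == 0 and bg_d == 0:
                pr = a / n
                w = pmf
            else:
                # joint over (signal acceptor, bg acceptor, bg donor)
                a3 = a[:, None, None]
                w = (pmf[:, None, None] * pa_bg[None, :, None] * pd_bg[None, None, :]).ravel()
                num = (a3 + ka[None, :, None]).astype(float)
                den = num + (n - a3) + kd[None, None, :]
                pr = (num / den).ravel()
            out += frac * pn * np.bincount(_bin_indices(pr, model.n_bins),
                                           weights=w, minlength=model.n_bins)
    s = out.sum()
    if abs(s - 1.0) > 1e-9:
        out = out / s
    return out


@dataclass
class PdaFitResults:
    """Fitted PDA states with uncertainties and goodness of fit.

    ``states`` is a list of (efficiency, fraction); ``state_se`` the matching
    standard errors (fraction SE only meaningful for two states).  Reduced
    chi-square near 1 indicates that shot noise alone explains the histogram
    width for the fitted number of states.
    """

    states: list[tuple[float, float]]
    state_se: list[tuple[float, float]]
    chi2: float
    reduced_chi2: float
    n_free_parameters: int
    dof: int
    expected: np.ndarray

    @property
    def efficiencies(self) -> list[float]:
        return [e for e, _ in self.states]

    @property
    def fractions(self) -> list[float]:
        return [f for _, f in self.states]

    def summary(self) -> str:
        lines = [f"PDA fit: {len(self.states)} state(s), "
                 f"{self.n_free_parameters} free parameter(s)"]
        for i, ((e, f), (ese, fse)) in enumerate(zip(self.states, self.state_se)):
            lines.append(f"  state {i}: E = {e:.4f} (se {ese:.3g}), "
                         f"fraction = {f:.4f} (se {fse:.3g})")
        lines.append(f"  chi2 = {self.chi2:.4g}, reduced chi2 = {self.reduced_chi2:.4g} "
                     f"(dof = {self.dof})")
        return "\n".join(lines)


def _merge_low_bins(observed: np.ndarray, expected: np.ndarray, min_expected: float = 5.0):
    """Merge adjacent bins until every merged bin has expected >= min_expected."""
    obs_m, exp_m = [], []
    o_acc = e_acc = 0.0
    for o, e in zip(observed, expected):
        o_acc += o
        e_acc += e
        if e_acc >= min_expected:
            obs_m.append(o_acc)
            exp_m.append(e_acc)
            o_acc = e_acc = 0.0
    if e_acc > 0 and exp_m:
        obs_m[-1] += o_acc
        exp_m[-1] += e_acc
    elif e_acc > 0:
        obs_m.append(o_acc)
        exp_m.append(e_acc)
    return np.array(obs_m), np.array(exp_m)


class PdaConvergenceError(RuntimeError):
    def __init__(self, message, last_iterate=None, gradient_norm=None):
        super().__init__(message)
        self.last_iterate = last_iterate
        self.gradient_norm = gradient_norm


class PdaFit:
    """Fit a one- or two-state PDA model to an observed histogram.

    Parameters
    ----------
    observed : counts per proximity-ratio bin (uniform bins on [0, 1]).
    dex_totals : donor-excitation photon totals of the analysed bursts; the
        empirical size distribution is taken from these directly.
    n_states : 1 or 2.
    background : mean Poisson background counts per burst (donor, acceptor).

    The objective is the Pearson chi-square between observed counts and the
    expected histogram scaled to the total, with expected-count < 5 bins
    merged; free parameters are each state's efficiency plus, for two
    states, one fraction.  The optimiser is deterministic given the data and
    initial values (Nelder-Mead on a logit-bounded parametrisation).
    """

    def __init__(self, observed: np.ndarray, dex_totals: Sequence[int],
                 n_states: int = 2, background: tuple[float, float] = (0.0, 0.0)):
        self.observed = np.asarray(observed, float)
        self.n_bins = self.observed.size
        self.total = float(self.observed.sum())
        if self.total < 200:
            raise ValueError("need at least 200 bursts for a PDA fit")
        if n_states not in (1, 2):
            raise ValueError("n_states must be 1 or 2")
        self.n_states = n_states
        self.sizes, self.size_probs = empirical_size_distribution(dex_totals)
        self.background = background

    # parameters are mapped through a logistic to keep them in (0, 1)
    @staticmethod
    def _expand(z):
        return 1.0 / (1.0 + np.exp(-z))

    @staticmethod
    def _collapse(p):
        p = np.clip(p, 1e-6, 1 - 1e-6)
        return np.log(p / (1.0 - p))

    def _states_from(self, theta: np.ndarray) -> list[tuple[float, float]]:
        if self.n_states == 1:
            return [(float(theta[0]), 1.0)]
        e1, e2, f1 = theta
        return [(float(e1), float(f1)), (float(e2), float(1.0 - f1))]

    def _chi2(self, theta: np.ndarray) -> float:
        model = PdaModel(self._states_from(theta), self.sizes, self.size_probs,
                         self.background, self.n_bins)
        expected = pda_expected_histogram(model) * self.total
        obs_m, exp_m = _merge_low_bins(self.observed, expected)
        return float(np.sum((obs_m - exp_m) ** 2 / exp_m))

    def _default_init(self) -> np.ndarray:
        """Valley split of the observed histogram; ties toward equal fractions."""
        centers = (np.arange(self.n_bins) + 0.5) / self.n_bins
        mean = float(np.sum(self.observed * centers) / self.total)
        if self.n_states == 1:
            return np.array([mean])
        # find the interior minimum between the two largest separated peaks
        smooth = np.convolve(self.observed, np.ones(3) / 3.0, mode="same")
        lo_q = np.sum(np.cumsum(self.observed) < 0.25 * self.total)
        hi_q = np.sum(np.cumsum(self.observed) < 0.75 * self.total)
        if hi_q > lo_q:
            valley = lo_q + int(np.argmin(smooth[lo_q:hi_q + 1]))
        else:
            valley = self.n_bins // 2
        below = self.observed[: valley + 1]
        above = self.observed[valley + 1:]
        f1 = float(below.sum() / self.total) if 0 < below.sum() < self.total else 0.5
        e1 = float(np.sum(below * centers[: valley + 1]) / below.sum()) if below.sum() else mean - 0.1
        e2 = float(np.sum(above * centers[valley + 1:]) / above.sum()) if above.sum() else mean + 0.1
        return np.array([e1, e2, f1])

    def fit(self, init: Sequence[float] | None = None) -> PdaFitResults:
        theta0 = np.asarray(init, float) if init is not None else self._default_init()
        z0 = self._collapse(theta0)

        def objective(z):
            return self._chi2(self._expand(z))

        res = minimize(objective, z0, method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000})
        theta = self._expand(res.x)
        if not res.success and res.fun > objective(z0):
            grad = np.linalg.norm(np.gradient([objective(res.x + d) for d in np.eye(len(res.x)) * 1e-5]))
            raise PdaConvergenceError("PDA fit did not converge",
                                      last_iterate=theta, gradient_norm=float(grad))
        # order two-state solutions by efficiency for stable reporting
        states = self._states_from(theta)
        if self.n_states == 2 and states[0][0] > states[1][0]:
            states = [states[1], states[0]]
            theta = np.array([states[0][0], states[1][0], states[0][1]])

        chi2 = self._chi2(theta)
        model = PdaModel(states, self.sizes, self.size_probs, self.background, self.n_bins)
        expected = pda_expected_histogram(model) * self.total
        _, exp_m = _merge_low_bins(self.observed, expected)
        n_free = len(theta)
        dof = max(exp_m.size - n_free - 1, 1)
        se = self._standard_errors(theta)
        if self.n_states == 1:
            state_se = [(se[0], 0.0)]
        else:
            state_se = [(se[0], se[2]), (se[1], se[2])]
        return PdaFitResults(states=states, state_se=state_se, chi2=chi2,
                             reduced_chi2=chi2 / dof, n_free_parameters=n_free,
                             dof=dof, expected=expected)

    def _standard_errors(self, theta: np.ndarray) -> np.ndarray:
        """SEs from the curvature of chi2 at the optimum (cov = 2 H^-1)."""
        k = theta.size
        h = np.zeros((k, k))
        step = 1e-4
        f0 = self._chi2(theta)

        def at(d):
            return self._chi2(np.clip(theta + d, 1e-9, 1 - 1e-9))

        for i in range(k):
            ei = np.zeros(k)
            ei[i] = step
            h[i, i] = (at(ei) - 2 * f0 + at(-ei)) / step**2
            for j in range(i + 1, k):
                ej = np.zeros(k)
                ej[j] = step
                h[i, j] = h[j, i] = (at(ei + ej) - at(ei - ej) - at(-ei + ej) + at(-ei - ej)) / (4 * step**2)
        try:
            cov = 2.0 * np.linalg.inv(h)
            se = np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:
            se = np.full(k, np.nan)
        return se


def pda_fit(observed: np.ndarray, dex_totals: Sequence[int], n_states: int = 2,
            init: Sequence[float] | None = None,
            background: tuple[float, float] = (0.0, 0.0)) -> PdaFitResults:
    """Convenience wrapper around :class:`PdaFit`."""
    return PdaFit(observed, dex_totals, n_states, background).fit(init=init)
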