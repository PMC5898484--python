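"""Burst selection, corrected FRET efficiency / stoichiometry, and
population splitting for pulse-interleaved-excitation (PIE) smFRET data.

Each burst carries three photon counts: donor and acceptor channel under
donor excitation (Dex) and acceptor channel under acceptor excitation (Aex).
From these the corrected transfer efficiency E and the label stoichiometry S
are computed; S separates double-labelled molecules (S ~ 0.5) from donor-only
(S ~ 1) and acceptor-only (S ~ 0) contaminants, and the E histogram of the
S-selected slice resolves bound (low-E) from unbound (high-E) populations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PhotonBurst",
    "BurstSet",
    "CorrectionFactors",
    "ESPoints",
    "PopulationSplit",
    "find_bursts",
    "compute_es",
    "build_es_histogram",
    "select_fret_species",
    "split_populations",
    "DEFAULT_S_WINDOW",
    "DEFAULT_E_EDGES",
]

#: Default stoichiometry window bracketing the S = 0.5 double-label band.
DEFAULT_S_WINDOW = (0.3, 0.7)

#: Default E-histogram edges: [-0.1, 1.1] in 55 bins (0.022 per bin) so that
#: correction-induced out-of-range efficiencies stay visible.
DEFAULT_E_EDGES = np.linspace(-0.1, 1.1, 56)


@dataclass(frozen=True)
class PhotonBurst:
    """Photon counts of a single burst under PIE excitation."""

    n_donor_dex: int
    n_acceptor_dex: int
    n_acceptor_aex: int
    duration_ms: float = 1.0

    def __post_init__(self):
        if min(self.n_donor_dex, self.n_acceptor_dex, self.n_acceptor_aex) < 0:
            raise ValueError("photon counts must be >= 0")
        if self.n_donor_dex + self.n_acceptor_dex + self.n_acceptor_aex < 1:
            raise ValueError("burst must contain at least one photon")


@dataclass
class BurstSet:
    """Column-oriented collection of bursts (one numpy array per channel)."""

    n_donor_dex: np.ndarray
    n_acceptor_dex: np.ndarray
    n_acceptor_aex: np.ndarray
    duration_ms: np.ndarray
    species_index: np.ndarray | None = None  # ground truth when synthetic

    def __post_init__(self):
        n = len(self.n_donor_dex)
        for arr in (self.n_acceptor_dex, self.n_acceptor_aex, self.duration_ms):
            if len(arr) != n:
                raise ValueError("all burst columns must have equal length")

    def __len__(self) -> int:
        return len(self.n_donor_dex)

    @property
    def totals(self) -> np.ndarray:
        return self.n_donor_dex + self.n_acceptor_dex + self.n_acceptor_aex

    @property
    def dex_totals(self) -> np.ndarray:
        """Total photons collected under donor excitation."""
        return self.n_donor_dex + self.n_acceptor_dex

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "burst_id": np.arange(len(self)),
                "n_donor_Dex": self.n_donor_dex,
                "n_acceptor_Dex": self.n_acceptor_dex,
                "n_acceptor_Aex": self.n_acceptor_aex,
                "duration_ms": self.duration_ms,
            }
        )
        if self.species_index is not None:
            df["species_index"] = self.species_index
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "BurstSet":
        return cls(
            n_donor_dex=df["n_donor_Dex"].to_numpy(int),
            n_acceptor_dex=df["n_acceptor_Dex"].to_numpy(int),
            n_acceptor_aex=df["n_acceptor_Aex"].to_numpy(int),
            duration_ms=df["duration_ms"].to_numpy(float),
            species_index=df["species_index"].to_numpy(int) if "species_index" in df else None,
        )

    @classmethod
    def from_csv(cls, path) -> "BurstSet":
        return cls.from_dataframe(pd.read_csv(path, comment="#"))


@dataclass(frozen=True)
class CorrectionFactors:
    """Standard smFRET corrections.

    gamma : detection-efficiency / quantum-yield ratio correction (>0)
    alpha : donor leakage fraction into the acceptor channel
    delta : acceptor direct-excitation fraction under donor excitation
    background : per-channel background rates (photons/ms), order
        (donor_Dex, acceptor_Dex, acceptor_Aex)
    """

    gamma: float = 1.0
    alpha: float = 0.0
    delta: float = 0.0
    background: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if not (0.0 <= self.alpha < 1.0 and 0.0 <= self.delta < 1.0):
            raise ValueError("alpha and delta must be in [0, 1)")


@dataclass
class ESPoints:
    """Corrected (E, S) coordinates per burst, with a validity mask.

    Bursts whose corrected total signal vanishes are flagged invalid rather
    than silently dropped; ``valid`` indexes the usable bursts.
    """

    e: np.ndarray
    s: np.ndarray
    valid: np.ndarray

    def __len__(self) -> int:
        return len(self.e)

    def selected(self) -> "ESPoints":
        """Return only the valid points."""
        return ESPoints(self.e[self.valid], self.s[self.valid], np.ones(self.valid.sum(), bool))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"E": self.e, "S": self.s, "valid": self.valid})


def compute_es(bursts: BurstSet | PhotonBurst, corr: CorrectionFactors | None = None) -> ESPoints:
    """Corrected transfer efficiency and stoichiometry per burst.

    After per-channel background subtraction (rates x duration), the
    corrected acceptor signal under donor excitation is

        F_A = n_acceptor_Dex - alpha * n_donor_Dex - delta * n_acceptor_Aex

    and then E = F_A / (F_A + gamma n_donor_Dex),
    S = (F_A + gamma n_donor_Dex) / (F_A + gamma n_donor_Dex + n_acceptor_Aex).

    With gamma = 1, alpha = delta = 0 and zero background these are the raw
    proximity ratio and raw stoichiometry, both in [0, 1]; corrected values
    may fall slightly outside and are retained.
    """
    if corr is None:
        corr = CorrectionFactors()
    if isinstance(bursts, PhotonBurst):
        bursts = BurstSet(
            n_donor_dex=np.array([bursts.n_donor_dex]),
            n_acceptor_dex=np.array([bursts.n_acceptor_dex]),
            n_acceptor_aex=np.array([bursts.n_acceptor_aex]),
            duration_ms=np.array([bursts.duration_ms]),
        )
    bg_d, bg_a, bg_aa = corr.background
    d = bursts.n_donor_dex - bg_d * bursts.duration_ms
    a = bursts.n_acceptor_dex - bg_a * bursts.duration_ms
    aa = bursts.n_acceptor_aex - bg_aa * bursts.duration_ms

    f_a = a - corr.alpha * d - corr.delta * aa
    total_dex = f_a + corr.gamma * d
    total_all = total_dex + aa

    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.where(total_dex != 0, f_a / total_dex, np.nan)
        s = np.where(total_all != 0, total_dex / total_all, np.nan)
    valid = np.isfinite(e) & np.isfinite(s)
    n_bad = int((~valid).sum())
    if n_bad:
        logger.warning("%d bursts flagged: zero denominator after corrections", n_bad)
    return ESPoints(e=e, s=s, valid=valid)


def find_bursts(
    times_ms: np.ndarray,
    channels: np.ndarray,
    window_ms: float = 0.5,
    min_rate: int = 20,
    min_total: int = 50,
) -> BurstSet:
    """All-photon sliding-window burst search on a time-stamped photon stream.

    A photon belongs to a dense region if any length-``window_ms`` window
    containing it holds at least ``min_rate`` photons.  Contiguous dense
    photons are merged into candidate bursts, which are kept if they contain
    at least ``min_total`` photons.

    Parameters
    ----------
    times_ms : array of photon arrival times in ms, sorted ascending.
    channels : integer array, same length; 0 = donor/Dex, 1 = acceptor/Dex,
        2 = acceptor/Aex.
    """
    times_ms = np.asarray(times_ms, float)
    channels = np.asarray(channels, int)
    if times_ms.size and np.any(np.diff(times_ms) < 0):
        raise ValueError("photon stream must be time-sorted")
    empty = BurstSet(*(np.empty(0, int) for _ in range(3)), duration_ms=np.empty(0))
    if times_ms.size == 0:
        return empty

    n = times_ms.size
    # photon i starts a dense window if >= min_rate photons lie in [t_i, t_i + w)
    right = np.searchsorted(times_ms, times_ms + window_ms, side="left")
    starts_dense = (right - np.arange(n)) >= min_rate
    # mark every photon covered by a dense window
    dense = np.zeros(n + 1, dtype=int)
    idx = np.flatnonzero(starts_dense)
    np.add.at(dense, idx, 1)
    np.add.at(dense, right[idx], -1)
    in_burst = np.cumsum(dense[:-1]) > 0

    if not in_burst.any():
        return empty
    # contiguous runs of in-burst photons
    edges = np.flatnonzero(np.diff(np.concatenate(([0], in_burst.astype(int), [0]))))
    run_starts, run_stops = edges[::2], edges[1::2]

    cols = {0: [], 1: [], 2: []}
    durations = []
    for lo, hi in zip(run_starts, run_stops):
        if hi - lo < min_total:
            continue
        ch = channels[lo:hi]
        for c in (0, 1, 2):
            cols[c].append(int((ch == c).sum()))
        durations.append(times_ms[hi - 1] - times_ms[lo])
    if not durations:
        return empty
    return BurstSet(
        n_donor_dex=np.array(cols[0]),
        n_acceptor_dex=np.array(cols[1]),
        n_acceptor_aex=np.array(cols[2]),
        duration_ms=np.array(durations),
    )


def build_es_histogram(
    points: ESPoints,
    e_edges: np.ndarray | None = None,
    s_edges: np.ndarray | None = None,
    s_window: tuple[float, float] = DEFAULT_S_WINDOW,
):
    """2D (E, S) histogram plus the 1D E marginal of the S-selected slice.

    Returns ``(hist2d, e_edges, s_edges, e_marginal)`` where ``hist2d`` has
    shape (len(e_edges)-1, len(s_edges)-1) and ``e_marginal`` is the E
    histogram of points with S inside ``s_window``.
    """
    if e_edges is None:
        e_edges = DEFAULT_E_EDGES
    if s_edges is None:
        s_edges = np.linspace(-0.1, 1.1, 25)
    e_edges = np.asarray(e_edges, float)
    s_edges = np.asarray(s_edges, float)
    if np.any(np.diff(e_edges) <= 0) or np.any(np.diff(s_edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    pts = points.selected()
    hist2d, _, _ = np.histogram2d(pts.e, pts.s, bins=[e_edges, s_edges])
    sl = select_fret_species(pts, s_window, warn_empty=False)
    e_marginal, _ = np.histogram(sl.e, bins=e_edges)
    return hist2d, e_edges, s_edges, e_marginal


def select_fret_species(
    points: ESPoints,
    s_window: tuple[float, float] = DEFAULT_S_WINDOW,
    warn_empty: bool = True,
) -> ESPoints:
    """Retain bursts with stoichiometry inside ``s_window`` (FRET species).

    The default window [0.3, 0.7] brackets the double-label S ~ 0.5 band
    while excluding donor-only (S ~ 1) and acceptor-only (S ~ 0) molecules.
    """
    s_low, s_high = s_window
    if not 0.0 <= s_low < s_high <= 1.0:
        raise ValueError("require 0 <= s_low < s_high <= 1")
    pts = points.selected()
    keep = (pts.s >= s_low) & (pts.s <= s_high)
    if warn_empty and not keep.any():
        warnings.warn("stoichiometry selection returned no bursts", stacklevel=2)
    return ESPoints(pts.e[keep], pts.s[keep], np.ones(int(keep.sum()), bool))


@dataclass
class PopulationSplit:
    """Bound/unbound burst split of an S-selected E distribution."""

    n_bound: int
    n_unbound: int
    boundary_e: float | None = None
    components: dict | None = None  # two-Gaussian fit summary when used
    method: str = "threshold"

    @property
    def fraction_bound(self) -> float:
        total = self.n_bound + self.n_unbound
        return self.n_bound / total if total else float("nan")


def split_populations(
    points: ESPoints,
    method: Literal["threshold", "two_gaussian"] = "threshold",
    boundary_e: float = 0.4,
    e_edges: np.ndarray | None = None,
) -> PopulationSplit:
    """Split an E distribution into bound (low-E) and unbound (high-E) bursts.

    ``threshold``: count bursts below/above ``boundary_e`` (default 0.4, the
    midpoint of the 0.2 bound / 0.6 unbound state efficiencies).
    ``two_gaussian``: fit a two-component Gaussian mixture to the 1D E
    histogram; the bound fraction is the weight of the lower-mean component.
    Degenerate single-mode data fall back to the threshold with a logged
    notice.
    """
    pts = points.selected()
    if len(pts) < 20:
        raise ValueError("need at least 20 bursts to split populations")
    if method == "threshold":
        n_bound = int((pts.e < boundary_e).sum())
        return PopulationSplit(n_bound=n_bound, n_unbound=len(pts) - n_bound,
                               boundary_e=boundary_e, method="threshold")
    if method != "two_gaussian":
        raise ValueError(f"unknown method {method!r}")

    from scipy.optimize import curve_fit

    if e_edges is None:
        e_edges = DEFAULT_E_EDGES
    counts, edges = np.histogram(pts.e, bins=e_edges)
    centers = 0.5 * (edges[:-1] + edges[1:])

    def two_gauss(x, w, mu1, s1, mu2, s2):
        g1 = np.exp(-0.5 * ((x - mu1) / s1) ** 2) / (s1 * np.sqrt(2 * np.pi))
        g2 = np.exp(-0.5 * ((x - mu2) / s2) ** 2) / (s2 * np.sqrt(2 * np.pi))
        return len(pts) * np.diff(edges) * (w * g1 + (1 - w) * g2)

    lo, hi = np.quantile(pts.e, [0.15, 0.85])
    try:
        popt, _ = curve_fit(
            two_gauss, centers, counts,
            p0=[0.5, lo, 0.08, hi, 0.08],
            bounds=([0, -0.1, 1e-3, -0.1, 1e-3], [1, 1.1, 0.5, 1.1, 0.5]),
            maxfev=20000,
        )
    except RuntimeError:
        logger.info("two-Gaussian fit failed to converge; falling back to threshold")
        return split_populations(points, "threshold", boundary_e)
    w, mu1, s1, mu2, s2 = popt
    if abs(mu1 - mu2) < s1 + s2:  # components touch: unresolved single mode
        logger.info("two-Gaussian components degenerate; falling back to threshold")
        return split_populations(points, "threshold", boundary_e)
    # bound = lower-E component
    frac_low = w if mu1 < mu2 else 1.0 - w
    n_bound = int(round(frac_low * len(pts)))
    comp = {"weight_low": frac_low,
            "mu_low": min(mu1, mu2), "mu_high": max(mu1, mu2),
            "sigma_low": s1 if mu1 < mu2 else s2,
            "sigma_high": s2 if mu1 < mu2 else s1}
    return PopulationSplit(n_bound=n_bound, n_unbound=len(pts) - n_bound,
                           components=comp, method="two_gaussian")
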