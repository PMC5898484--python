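"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's analytic code paths: first-passage
times come from direct stochastic (Gillespie) simulation, and expected FRET
histograms from elementary per-burst sampling.
"""

from __future__ import annotations

import numpy as np


def gillespie_first_passage(
    n_motifs: int,
    k_on_c: float,
    k_off_ind: float,
    n_runs: int,
    start_state: int = 1,
    seed: int = 0,
) -> np.ndarray:
    """First-passage times to 0 bound motifs, by direct stochastic simulation.

    Vectorised over runs: at each step every still-active walker draws an
    exponential dwell time at its total rate and moves up with probability
    up/(up+down).
    """
    rng = np.random.default_rng(seed)
    state = np.full(n_runs, start_state, dtype=int)
    t = np.zeros(n_runs)
    active = state > 0
    while active.any():
        k = state[active]
        up = (n_motifs - k) * k_on_c
        down = k * k_off_ind
        total = up + down
        t[active] += rng.exponential(1.0 / total)
        move_up = rng.random(k.size) < up / total
        state[active] = k + np.where(move_up, 1, -1)
        active = state > 0
    return t


def brute_force_pr_histogram(
    states: list[tuple[float, float]],
    dex_sizes: np.ndarray,
    n_bursts: int,
    n_bins: int,
    seed: int = 0,
) -> np.ndarray:
    """Monte-Carlo proximity-ratio histogram by naive per-burst sampling.

    Sizes are drawn from the empirical ``dex_sizes`` pool, a state by its
    fraction, and the acceptor count binomially — nothing shared with the
    analytic forward model beyond the binning convention.
    """
    rng = np.random.default_rng(seed)
    sizes = rng.choice(np.asarray(dex_sizes, int), size=n_bursts)
    es = np.array([e for e, _ in states])
    fr = np.array([f for _, f in states])
    which = rng.choice(len(states), size=n_bursts, p=fr)
    acc = rng.binomial(sizes, es[which])
    pr = acc / sizes
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.searchsorted(edges, pr, side="right") - 1, 0, n_bins - 1)
    return np.bincount(idx, minlength=n_bins).astype(float)
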