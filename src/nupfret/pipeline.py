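"""End-to-end pipeline runs: simulate -> analyze -> fit -> report.

A run is described by a config mapping (usually loaded from YAML) naming the
stages to execute and their parameter blocks.  Each run writes its outputs
plus a ``manifest.json`` recording inputs, parameters, seed and package
version, so identical configs byte-reproduce identical numbers.

Shipped fixture configs (``figure1b``, ``figure2``, ``figure6``) encode the
study's headline conditions: the two-population smFRET mixture (E 0.6
unbound / 0.2 bound), the three stopped-flow rate regimes, and the
35 / 222 nM titrations.
"""

from __future__ import annotations

import json
import logging
import sys
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .bursts import compute_es, select_fret_species, split_populations, build_es_histogram
from .binding import fit_kd
from .io import write_trace, write_titration
from .kinetics import fit_exponential, fit_kon, fit_koff, half_life_ratio
from .pda import PdaFit, proximity_ratio_histogram
from .synthetic import (
    BurstGenConfig,
    KineticGenConfig,
    simulate_bursts,
    simulate_association_trace,
    simulate_dissociation_trace,
    simulate_titration,
    two_state_species,
)

logger = logging.getLogger(__name__)

FIXTURE_NAMES = ("figure1b", "figure2", "figure6")


def load_fixture_config(name: str) -> dict:
    """Load one of the shipped named fixture configs."""
    if name not in FIXTURE_NAMES:
        raise ValueError(f"unknown fixture {name!r}; available: {FIXTURE_NAMES}")
    text = resources.files("nupfret").joinpath(f"configs/{name}.yaml").read_text()
    return yaml.safe_load(text)


def load_config(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())


def _stage_bursts(params: dict, seed: int, outdir: Path) -> dict:
    sp = params.get("species", {})
    species = two_state_species(
        e_unbound=sp.get("e_unbound", 0.6),
        e_bound=sp.get("e_bound", 0.2),
        fraction_bound=sp.get("fraction_bound", 0.5),
        donor_only=sp.get("donor_only", 0.2),
        acceptor_only=sp.get("acceptor_only", 0.05),
    )
    cfg = BurstGenConfig(n_bursts=params.get("n_bursts", 5000), seed=seed)
    bursts = simulate_bursts(species, cfg)
    bursts.to_csv(outdir / "bursts.csv")

    points = compute_es(bursts)
    sel = select_fret_species(points)
    hist2d, e_edges, s_edges, e_marginal = build_es_histogram(points)
    np.savetxt(outdir / "es_hist2d.csv", hist2d, delimiter=",",
               header="rows: E bins [-0.1,1.1]x55, cols: S bins [-0.1,1.1]x24")
    split = split_populations(sel)
    result = {
        "n_bursts": len(bursts),
        "n_selected": len(sel),
        "fraction_bound_threshold": split.fraction_bound,
        "e_marginal_modal_bin_center": float(
            0.5 * (e_edges[int(np.argmax(e_marginal))] + e_edges[int(np.argmax(e_marginal)) + 1])
        ),
    }
    n_states = params.get("pda_states", 2)
    if n_states:
        sel_mask = (points.valid
                    & (points.s >= 0.3) & (points.s <= 0.7))
        dex = (bursts.n_donor_dex + bursts.n_acceptor_dex)[sel_mask]
        na = bursts.n_acceptor_dex[sel_mask]
        nd = bursts.n_donor_dex[sel_mask]
        observed = proximity_ratio_histogram(na, nd)
        fit = PdaFit(observed, dex, n_states=n_states).fit()
        result["pda"] = {
            "states": [{"e": e, "fraction": f} for e, f in fit.states],
            "reduced_chi2": fit.reduced_chi2,
        }
    return result


def _stage_kinetics(params: dict, seed: int, outdir: Path) -> dict:
    out: dict = {"regimes": [], "dissociation": []}
    for i, reg in enumerate(params.get("regimes", [])):
        fits = []
        for j, conc in enumerate(reg["concentrations_M"]):
            cfg = KineticGenConfig(
                k_on=reg["k_on"], k_off=reg.get("k_off", 0.0),
                ntr_conc=conc, probe_conc=reg.get("probe_conc_M", conc / 20),
                t_max=reg.get("t_max_s", 1.0) * reg["concentrations_M"][0] / conc,
                dt=reg.get("dt_s", 1e-3) * reg["concentrations_M"][0] / conc,
                noise_sd=reg.get("noise_sd", 0.0),
                seed=seed + 1000 * i + j,
            )
            trace = simulate_association_trace(cfg)
            write_trace(trace, outdir / f"assoc_{reg['name']}_{j}.csv")
            fits.append((conc, fit_exponential(trace)))
        kon = fit_kon(fits)
        out["regimes"].append({"name": reg["name"], "k_on_true": reg["k_on"],
                               "k_on_fit": kon.k_on, "k_on_se": kon.k_on_se,
                               "intercept": kon.intercept, "r_squared": kon.r_squared})
    koffs = {}
    for i, dis in enumerate(params.get("dissociation", [])):
        cfg = KineticGenConfig(
            k_on=dis.get("k_on", 1e7), k_off=dis["k_off"],
            ntr_conc=dis.get("ntr_conc_M", 1e-6), probe_conc=dis.get("probe_conc_M", 20e-9),
            t_max=dis.get("t_max_s", 5.0 / dis["k_off"]), dt=dis.get("dt_s", 5.0 / dis["k_off"] / 1000),
            noise_sd=dis.get("noise_sd", 0.0), seed=seed + 5000 + i,
        )
        trace = simulate_dissociation_trace(cfg, chase_excess_fold=dis.get("chase_excess_fold", 100))
        write_trace(trace, outdir / f"dissoc_{dis['name']}.csv")
        res = fit_koff(trace)
        koffs[dis["name"]] = res
        out["dissociation"].append({"name": dis["name"], "k_off_true": dis["k_off"],
                                    "k_off_fit": res.k_off, "half_life_s": res.half_life})
    if len(koffs) == 2:
        a, b = koffs.values()
        slow, fast = (a, b) if a.k_off < b.k_off else (b, a)
        out["half_life_ratio_slow_over_fast"] = half_life_ratio(slow, fast)
    return out


def _stage_titration(params: dict, seed: int, outdir: Path) -> dict:
    out = []
    for i, tit in enumerate(params.get("titrations", [])):
        series = simulate_titration(
            kd=tit["kd_M"], concentrations=tit["concentrations_M"],
            n_bursts_per_point=tit.get("n_bursts_per_point", 2000), seed=seed + 100 * i,
        )
        write_titration(series, outdir / f"titration_{tit['name']}.csv")
        fit = fit_kd(series)
        out.append({"name": tit["name"], "kd_true_M": tit["kd_M"],
                    "kd_fit_M": fit.kd, "kd_se_M": fit.kd_se})
    return {"titrations": out}


_STAGES = {"bursts": _stage_bursts, "kinetics": _stage_kinetics, "titration": _stage_titration}


def run_pipeline(config: dict, outdir: str | Path, seed: int | None = None) -> dict:
    """Execute the configured stages in order; write results and a manifest.

    Returns the results mapping (also written as ``results.json``).  A seed
    given here overrides the config's.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0)) if seed is None else int(seed)
    stages = config.get("stages", [])
    results: dict = {}
    for stage in stages:
        if stage not in _STAGES:
            raise ValueError(f"unknown stage {stage!r}")
        logger.info("[%s] running", stage)
        try:
            results[stage] = _STAGES[stage](config.get(stage, {}), seed, outdir)
        except Exception as err:
            raise RuntimeError(f"stage {stage!r} failed: {err}") from err
    manifest = {
        "package": "nupfret", "version": __version__,
        "seed": seed, "stages": list(stages),
        "parameters": {s: config.get(s, {}) for s in stages},
        "outputs": sorted(p.name for p in outdir.iterdir()),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=float))
    (outdir / "results.json").write_text(json.dumps(results, indent=2, default=float))
    return results
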