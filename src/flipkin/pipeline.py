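"""End-to-end analysis pipeline: generate -> titration -> exponential -> global fit.

Each stage logs one structured line with its timing and seed; outputs are a
parameter CSV, JSON reports per stage and a provenance record (config hash,
seed, library versions) so a run is reproducible from its config alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .expfit import fit_exponential, summarize_kobs
from .globalfit import bootstrap_uncertainty, build_global_problem, run_global_fit
from .io import dump_json, write_trace_set
from .mechanism import MechanismVariant, relaxation_rates_approx
from .synth import (
    make_ground_truth,
    simulate_association_dataset,
    simulate_dissociation_dataset,
    simulate_titration_dataset,
)
from .titration import fit_titration
from .traces import REGIME_BALANCED, REGIME_FINE

log = logging.getLogger("flipkin")

__all__ = ["run_pipeline"]


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.model_dump(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _stage(name, t0, **info):
    log.info("stage=%s elapsed=%.2fs %s", name, time.perf_counter() - t0,
             " ".join(f"{k}={v}" for k, v in info.items()))


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full synthetic-data analysis described by *config*.

    Returns the result bundle as a dict and writes all artifacts under
    ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    regime = REGIME_BALANCED if config.instrument.regime == "balanced" else REGIME_FINE
    results: dict = {"config_hash": _config_hash(config), "seed": config.seed}

    # -- generate ------------------------------------------------------
    t0 = time.perf_counter()
    truths = {}
    datasets = {}
    base = make_ground_truth("HM", seed=config.seed, regime=regime,
                             noise_sd=config.instrument.noise_sd)
    for scen in config.scenarios:
        truth = base.to_scenario(scen)
        truths[scen] = truth
        datasets[scen] = simulate_association_dataset(
            truth, Pt_series_uM=config.pt_series_uM, Nt_uM=config.nt_uM,
            group_size=config.group_size,
        )
        write_trace_set(datasets[scen], out / "traces", f"{scen.lower()}_assoc")
    _stage("generate", t0, scenarios=",".join(config.scenarios))
    results["ground_truth"] = {
        s: truths[s].rates.as_dict() for s in config.scenarios
    }

    # -- titration fits ------------------------------------------------
    t0 = time.perf_counter()
    titration = {}
    rng = np.random.default_rng(config.seed)
    for scen in config.scenarios + ["G448D"]:
        truth = truths.get(scen, base.to_scenario(scen))
        curve = simulate_titration_dataset(truth, Nt_uM=config.titration_nt_uM,
                                           seed=int(rng.integers(2**31)))
        fit = fit_titration(curve)
        titration[scen] = {"Ka_M": fit.params.Ka, "Ka_stderr": fit.stderr["Ka"],
                           "r_d": fit.params.r_d, "r_t": fit.params.r_t,
                           "R": fit.params.R}
    _stage("titration", t0, **{f"Ka_{s}": f"{v['Ka_M']:.3g}" for s, v in titration.items()})
    results["titration"] = titration

    # -- exponential fits ----------------------------------------------
    t0 = time.perf_counter()
    expo = {}
    for scen in config.scenarios:
        phases = 2 if MechanismVariant.for_scenario(scen) is MechanismVariant.THREE_STEP else 1
        fits = [fit_exponential(tr, n_phases=phases)
                for tr in datasets[scen] if tr.kind == "association"]
        pts = [tr.metadata["Pt_uM"] * 1e-6 for tr in datasets[scen] if tr.kind == "association"]
        summ1 = summarize_kobs(fits, pts, phase=1)
        entry = {"kobs1_mean": summ1.mean_kobs,
                 "kobs1_concentration_independent": summ1.concentration_independent}
        if phases == 2:
            summ2 = summarize_kobs(fits, pts, phase=2)
            entry.update(kobs2_mean=summ2.mean_kobs,
                         kobs2_concentration_independent=summ2.concentration_independent)
        expo[scen] = entry
    _stage("exponential", t0)
    results["exponential"] = expo

    # -- dissociation --------------------------------------------------
    t0 = time.perf_counter()
    dissoc = {}
    diss_traces = []
    for scen in config.scenarios:
        traces = simulate_dissociation_dataset(truths[scen], Nt_uM=config.nt_uM)
        diss_traces.append(traces[0])
        fit = fit_exponential(traces[0], n_phases=1)
        dissoc[scen] = {"kobs_off": fit.kobs1}
    _stage("dissociation", t0, **{s: f"{v['kobs_off']:.3g}" for s, v in dissoc.items()})
    results["dissociation"] = dissoc

    # -- global fit ----------------------------------------------------
    t0 = time.perf_counter()
    all_traces = [tr for scen in config.scenarios for tr in datasets[scen]]
    constants = {"K_G448D": titration["G448D"]["Ka_M"]}
    if "NM" in titration:
        constants["K_NM"] = titration["NM"]["Ka_M"]
    if "HM" in titration:
        constants["K_HM"] = titration["HM"]["Ka_M"]
    constants.setdefault("K_NM", constants["K_G448D"] * 5)
    problem = build_global_problem(all_traces, constants, k1_fixed=config.k1_M,
                                   dissociation_traces=diss_traces)
    report = run_global_fit(problem)
    _stage("global_fit", t0, success=report.success, cost=f"{report.cost:.3g}")
    results["global_fit"] = {
        "rates": report.rates.as_dict(),
        "stderr": report.stderr,
        "kobs_approx": report.kobs_approx,
        "success": report.success,
        "flags": report.flags,
    }

    # -- optional bootstrap --------------------------------------------
    if config.n_boot >= 20:
        t0 = time.perf_counter()
        boot = bootstrap_uncertainty(problem, report, n_boot=config.n_boot,
                                     seed=config.seed)
        results["bootstrap"] = {k: list(v) for k, v in boot.intervals.items()}
        _stage("bootstrap", t0, n_boot=config.n_boot)

    # -- reports -------------------------------------------------------
    rows = []
    for name, val in report.rates.as_dict().items():
        rows.append({"parameter": name, "estimate": val,
                     "stderr": report.stderr.get(name), "unit": "M^-1 s^-1" if name == "k1" else "s^-1"})
    pd.DataFrame(rows).to_csv(out / "parameters.csv", index=False, float_format="%.10g")
    dump_json(results, out / "report.json")
    dump_json({"config": config.model_dump(), "config_hash": results["config_hash"],
               "seed": config.seed,
               "versions": {"flipkin": __version__, "numpy": np.__version__}},
              out / "provenance.json")
    return results
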