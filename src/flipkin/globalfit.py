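"""Constrained global fit of the reaction scheme to trace ensembles.

Numerically integrates the mass-action scheme for every trace of an
ensemble (HM and NM duplexes, several protein concentrations) and fits the
shared rate constants and species responses by Levenberg–Marquardt least
squares — the same strategy as numerical kinetic-fitting software built
around mechanism integration (Dynafit-style analysis).

Conventions mirrored from the experimental analysis:

* the bimolecular constant k1 is fixed (default 3e9 M^-1 s^-1; a
  sensitivity mode refits at the bounding values 5e8 and 1e10),
* the free-duplex response I0 is anchored by dividing the buffer-control
  intensity by the duplex concentration,
* equilibrium constants from titrations provide *initial estimates* only —
  all rate constants except k1 float freely,
* rates are parameterised linearly with a lower bound of zero, so that a
  confidence interval on k3 can legitimately cover zero (the
  model-discrimination test between the two- and three-step schemes).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import lmfit

from .mechanism import (
    MechanismVariant,
    RateConstants,
    SolverError,
    bound_chain_slowest_rate,
    equilibrium_constants_from_rates,
    initial_rates_from_constants,
    relaxation_rates_approx,
    simulate_ensemble,
)
from .traces import KineticTrace, SpeciesResponses
from .expfit import fit_exponential

__all__ = [
    "GlobalFitProblem",
    "GlobalFitReport",
    "BootstrapResult",
    "build_global_problem",
    "run_global_fit",
    "bootstrap_uncertainty",
    "k1_sensitivity",
]

_RATE_NAMES = ("k_m1", "k2", "k_m2", "k3", "k_m3")
_RESP_NAMES = ("Ins", "Ifl", "Ist")


@dataclass
class GlobalFitProblem:
    """A ready-to-fit ensemble: data, shared grid, starts and weights."""

    variants: list
    Pt_uM: np.ndarray
    Nt_uM: float
    t_eval: np.ndarray                 # union time grid, seconds
    data: np.ndarray                   # (n_traces, n_times), NaN where absent
    weights: np.ndarray                # per-trace weight, mean 1
    start_rates: RateConstants
    start_responses: SpeciesResponses
    I0: float
    k1_fixed: float = 3e9
    labels: list = field(default_factory=list)
    # (variant, observed kobs, sd): chase-dissociation decay rates used as
    # constraint observables (they pin k_m3, which association traces leave
    # nearly degenerate with k3 and the NPst response along fixed kobs2)
    dissociation_constraints: list = field(default_factory=list)

    @property
    def n_traces(self) -> int:
        return len(self.variants)

    @property
    def has_three_step(self) -> bool:
        return any(v is MechanismVariant.THREE_STEP for v in self.variants)

    def copy_with_data(self, data: np.ndarray) -> "GlobalFitProblem":
        return replace(self, data=data)


def _variant_for_trace(trace: KineticTrace) -> MechanismVariant:
    duplex = str(trace.metadata.get("duplex", "")).upper()
    if duplex == "HM":
        return MechanismVariant.THREE_STEP
    if duplex == "NM":
        return MechanismVariant.TWO_STEP
    raise ValueError(f"trace metadata must declare duplex HM or NM, got {duplex!r}")


def build_global_problem(
    traces: list[KineticTrace],
    titration_constants: dict,
    steady_state_ratios: tuple[float, float, float] = (1.25, 2.5, 5.5),
    k1_fixed: float = 3e9,
    kobs1: float | None = None,
    kobs2: float | None = None,
    k_m3_dissociation: float | None = None,
    dissociation_traces: list[KineticTrace] | None = None,
) -> GlobalFitProblem:
    """Assemble a global-fit problem from traces and equilibrium constants.

    *titration_constants* maps scenario labels to association constants
    (M^-1): ``K_G448D`` and ``K_NM`` required, ``K_HM`` required when the
    ensemble contains HM traces.  *steady_state_ratios* are the emission
    fold-changes of (NPns, NPfl, NPst) over free duplex used to initialise
    the responses.  A buffer-control trace (kind "buffer") must be present
    to anchor the free-duplex response I0.  When kobs estimates are not
    supplied they are obtained by exponential fits of the highest-
    concentration traces.

    *dissociation_traces* (competitor-chase decays, kind "dissociation")
    are fitted mono-exponentially and their observed rates enter the global
    fit as constraint observables on the model's rate-limiting dissociation
    rate; this is what renders k_m3 identifiable.
    """
    controls = [tr for tr in traces if tr.kind == "buffer"]
    assoc = [tr for tr in traces if tr.kind == "association"]
    if not controls:
        raise ValueError("missing buffer-control trace: free-duplex response I0 cannot be anchored")
    if not assoc:
        raise ValueError("no association traces in ensemble")

    K_G = titration_constants["K_G448D"]
    K_NM = titration_constants["K_NM"]
    K_HM = titration_constants.get("K_HM")
    if K_NM < K_G:
        raise ValueError(
            f"inconsistent constraints: K_NM ({K_NM:.3g}) < K_G448D ({K_G:.3g}) "
            "violates K_NM = K_G448D * K2 with stabilising step 2"
        )
    if K_HM is not None and K_HM < K_NM:
        raise ValueError(
            f"inconsistent constraints: K_HM ({K_HM:.3g}) < K_NM ({K_NM:.3g}) "
            "violates K_HM = K_NM * K3 with stabilising step 3"
        )

    variants = [_variant_for_trace(tr) for tr in assoc]
    Nt_vals = {float(tr.metadata["Nt_uM"]) for tr in assoc}
    if len(Nt_vals) != 1:
        raise ValueError("all association traces must share the same duplex concentration")
    Nt_uM = Nt_vals.pop()
    Pt_uM = np.array([float(tr.metadata["Pt_uM"]) for tr in assoc])
    for v in (MechanismVariant.THREE_STEP, MechanismVariant.TWO_STEP):
        n_conc = len({p for p, vv in zip(Pt_uM, variants) if vv is v})
        if n_conc == 1:
            warnings.warn(f"only one protein concentration for {v.value} traces", stacklevel=2)
    if Pt_uM.size < 2:
        raise ValueError("need >= 2 protein concentrations in the ensemble")

    has_hm = MechanismVariant.THREE_STEP in variants
    if has_hm and K_HM is None and kobs2 is None and k_m3_dissociation is None:
        raise ValueError("HM traces present: need K_HM, kobs2 or a dissociation k_m3")

    # kobs starting estimates from the data themselves if not supplied
    if kobs1 is None:
        i = int(np.argmax(Pt_uM))
        fit = fit_exponential(assoc[i], n_phases=2 if variants[i] is MechanismVariant.THREE_STEP else 1)
        kobs1 = fit.kobs1
        if has_hm and kobs2 is None and fit.kobs2 is not None:
            kobs2 = fit.kobs2
    if has_hm and kobs2 is None:
        cand = [j for j, v in enumerate(variants) if v is MechanismVariant.THREE_STEP]
        i = cand[int(np.argmax(Pt_uM[cand]))]
        fit = fit_exponential(assoc[i], n_phases=2)
        kobs2 = fit.kobs2

    # dissociation decays: fit the asymptotic tail of each (the early decay
    # still carries fast-mode content that biases the rate-limiting rate)
    diss_constraints = []
    for tr in dissociation_traces or []:
        if tr.kind != "dissociation":
            continue
        dvar = _variant_for_trace(tr)
        t_cut = max(10.0 / kobs1, tr.time[0]) if kobs1 else tr.time[0]
        tail = tr.time >= t_cut
        dfit = fit_exponential(
            KineticTrace(tr.time[tail], tr.intensity[tail], tr.metadata), n_phases=1
        )
        if dfit.kobs1 is None:
            raise ValueError("dissociation trace could not be fitted mono-exponentially")
        sd = dfit.stderr.get("kobs1") or 0.0
        # floor at 0.5% run-to-run reproducibility: keeps the constraint
        # residual well-scaled while still pinning the exit rate sharply
        sd = max(sd, 5e-3 * dfit.kobs1)
        diss_constraints.append((dvar, float(dfit.kobs1), float(sd)))
    if has_hm and k_m3_dissociation is None:
        hm_rates = [k for v, k, _ in diss_constraints if v is MechanismVariant.THREE_STEP]
        if hm_rates:
            k_m3_dissociation = hm_rates[0]

    start_rates = initial_rates_from_constants(
        K_G, K_NM, K_HM, k1_fixed=k1_fixed, kobs1=kobs1,
        kobs2=kobs2 if has_hm else None,
        k_m3_from_dissociation=k_m3_dissociation if has_hm else None,
    )

    # union grid + per-trace data matrix
    t_eval = assoc[0].time
    same = all(tr.time.size == t_eval.size and np.allclose(tr.time, t_eval) for tr in assoc)
    if same:
        data = np.vstack([tr.intensity for tr in assoc])
    else:
        t_eval = np.unique(np.concatenate([tr.time for tr in assoc]))
        data = np.full((len(assoc), t_eval.size), np.nan)
        for i, tr in enumerate(assoc):
            idx = np.searchsorted(t_eval, tr.time)
            data[i, idx] = tr.intensity

    ctrl = controls[0]
    ctrl_nt = float(ctrl.metadata.get("Nt_uM", Nt_uM))
    I0 = float(np.mean(ctrl.intensity)) / ctrl_nt
    ns_f, fl_f, st_f = steady_state_ratios
    start_responses = SpeciesResponses(I0, ns_f * I0, fl_f * I0, st_f * I0)

    # per-trace inverse-variance weights from the final 5% of points
    w = np.empty(len(assoc))
    for i, tr in enumerate(assoc):
        tail = tr.intensity[-max(3, len(tr) // 20):]
        w[i] = 1.0 / max(np.var(tail), 1e-300)
    w = np.minimum(w, 1e12 * w.min())  # cap in the noiseless limit
    w /= w.mean()

    labels = [f"{tr.metadata.get('duplex','?')}_Pt{p:g}uM" for tr, p in zip(assoc, Pt_uM)]
    return GlobalFitProblem(
        variants=variants, Pt_uM=Pt_uM, Nt_uM=Nt_uM, t_eval=t_eval, data=data,
        weights=w, start_rates=start_rates, start_responses=start_responses,
        I0=I0, k1_fixed=k1_fixed, labels=labels,
        dissociation_constraints=diss_constraints,
    )


@dataclass
class GlobalFitReport:
    """Fitted rate constants, uncertainties and diagnostics."""

    rates: RateConstants
    responses: SpeciesResponses
    stderr: dict
    per_trace_residual_norm: np.ndarray
    kobs_approx: tuple[float, float]
    K_final_state: object
    K_total_bound: object
    success: bool
    cost: float
    nfev: int
    flags: list = field(default_factory=list)
    message: str = ""

    def ci95(self, name: str) -> tuple[float, float] | None:
        """Normal-theory 95% interval for a fitted parameter (rate or response)."""
        se = self.stderr.get(name)
        if se is None or not np.isfinite(se):
            return None
        val = getattr(self.rates, name, None)
        if val is None:
            val = getattr(self.responses, name)
        return (val - 1.96 * se, val + 1.96 * se)

    def k3_consistent_with_zero(self) -> bool:
        """True when the third step is statistically dispensable."""
        if "k3 unidentifiable" in self.flags:
            return True
        ci = self.ci95("k3")
        return ci is None or ci[0] <= 0.0


def _model_matrix(problem: GlobalFitProblem, rates: RateConstants,
                  responses: SpeciesResponses, rtol=1e-9, atol=1e-12) -> np.ndarray:
    traj = simulate_ensemble(
        [rates] * problem.n_traces, problem.variants,
        np.full(problem.n_traces, problem.Nt_uM), problem.Pt_uM,
        problem.t_eval, rtol=rtol, atol=atol,
    )
    resp = np.array([responses.I0, 0.0, responses.Ins, responses.Ifl, responses.Ist])
    return traj @ resp


def run_global_fit(
    problem: GlobalFitProblem,
    max_nfev: int = 500,
    restarts: int = 5,
    xtol: float = 1e-8,
    ftol: float = 1e-8,
) -> GlobalFitReport:
    """Levenberg–Marquardt minimisation of the weighted ensemble residual.

    On non-convergence the starting values are perturbed multiplicatively
    (x3 / /3, alternating) up to ``restarts`` times; a fit that still fails
    is returned with ``success=False`` and diagnostics, never silently.
    """
    fit_mask = ~np.isnan(problem.data)
    sqrtw = np.sqrt(problem.weights)[:, None]
    free_step3 = problem.has_three_step

    def make_params(scale: float = 1.0) -> lmfit.Parameters:
        pars = lmfit.Parameters()
        sr = problem.start_rates
        for name in _RATE_NAMES:
            val = getattr(sr, name)
            if name in ("k3", "k_m3") and not free_step3:
                pars.add(name, value=0.0, vary=False)
            else:
                pars.add(name, value=max(val, 1e-6) * scale, min=0.0)
        resp = problem.start_responses
        pars.add("Ins", value=resp.Ins * scale, min=0.0)
        pars.add("Ifl", value=resp.Ifl * scale, min=0.0)
        pars.add("Ist", value=resp.Ist * scale if free_step3 else 0.0,
                 min=0.0, vary=free_step3)
        return pars

    def resid(p):
        rates = RateConstants(
            problem.k1_fixed, p["k_m1"].value, p["k2"].value,
            p["k_m2"].value, p["k3"].value, p["k_m3"].value,
        )
        responses = SpeciesResponses(problem.I0, p["Ins"].value, p["Ifl"].value, p["Ist"].value)
        try:
            model = _model_matrix(problem, rates, responses)
        except SolverError:
            return np.full(fit_mask.sum() + len(problem.dissociation_constraints), 1e8)
        res = (((model - np.nan_to_num(problem.data)) * sqrtw)[fit_mask]).ravel()
        if problem.dissociation_constraints:
            extra = [
                (bound_chain_slowest_rate(rates, v) - kobs) / sd
                for v, kobs, sd in problem.dissociation_constraints
            ]
            res = np.concatenate([res, extra])
        return res

    out = None
    for attempt in range(restarts + 1):
        scale = 3.0 ** ((attempt + 1) // 2) if attempt % 2 else (1.0 / 3.0) ** (attempt // 2)
        if attempt == 0:
            scale = 1.0
        try:
            cand = lmfit.minimize(resid, make_params(scale), method="leastsq",
                                  max_nfev=max_nfev, xtol=xtol, ftol=ftol)
        except Exception:
            continue
        if np.isfinite(cand.chisqr):
            if out is None or cand.chisqr < out.chisqr:
                out = cand
            if cand.success:
                break
    if out is None:
        raise SolverError("global fit failed on all restarts")

    p = out.params
    rates = RateConstants(problem.k1_fixed, p["k_m1"].value, p["k2"].value,
                          p["k_m2"].value, p["k3"].value, p["k_m3"].value)
    responses = SpeciesResponses(problem.I0, p["Ins"].value, p["Ifl"].value, p["Ist"].value)
    stderr = {name: p[name].stderr for name in (*_RATE_NAMES, *_RESP_NAMES) if p[name].vary}

    model = _model_matrix(problem, rates, responses)
    res = np.where(fit_mask, model - np.nan_to_num(problem.data), 0.0)
    per_trace = np.sqrt(np.nansum(res ** 2, axis=1))

    flags = []
    for name in ("k3", "k_m3"):
        if p[name].vary:
            se = p[name].stderr
            if se is None or not np.isfinite(se) or (p[name].value > 0 and se > 10 * p[name].value):
                flags.append(f"{name} unidentifiable")
    try:
        K_fs = equilibrium_constants_from_rates(rates, "final_state")
        K_tb = equilibrium_constants_from_rates(rates, "total_bound")
    except ZeroDivisionError:
        K_fs = K_tb = None

    return GlobalFitReport(
        rates=rates, responses=responses, stderr=stderr,
        per_trace_residual_norm=per_trace,
        kobs_approx=relaxation_rates_approx(rates),
        K_final_state=K_fs, K_total_bound=K_tb,
        success=bool(out.success), cost=float(out.chisqr), nfev=int(out.nfev),
        flags=flags, message=str(out.message),
    )


@dataclass
class BootstrapResult:
    """Residual-resampling bootstrap intervals for the fitted parameters."""

    intervals: dict            # name -> (lo, hi), percentile 2.5/97.5
    samples: dict              # name -> ndarray of bootstrap estimates
    n_boot: int
    seed: int


def bootstrap_uncertainty(
    problem: GlobalFitProblem,
    report: GlobalFitReport,
    n_boot: int = 200,
    seed: int = 0,
    max_nfev: int = 200,
) -> BootstrapResult:
    """Residual-resampling bootstrap around a converged global fit.

    Residuals are resampled with replacement within each trace, added back
    to the fitted model, and the fit is re-run warm-started from the point
    estimate.  Percentile intervals are reported per free parameter; a
    fixed seed reproduces the intervals exactly.
    """
    if n_boot < 20:
        raise ValueError("n_boot must be >= 20 for percentile intervals")
    rng = np.random.default_rng(seed)
    model = _model_matrix(problem, report.rates, report.responses)
    residuals = problem.data - model

    warm = replace(problem, start_rates=report.rates,
                   start_responses=report.responses)
    names = [n for n in (*_RATE_NAMES, *_RESP_NAMES) if n in report.stderr]
    samples = {n: [] for n in names}
    for _ in range(n_boot):
        boot = model + np.apply_along_axis(
            lambda r: rng.choice(r, size=r.size, replace=True), 1, residuals
        )
        prob_b = warm.copy_with_data(boot)
        rep = run_global_fit(prob_b, max_nfev=max_nfev, restarts=0)
        for n in names:
            val = getattr(rep.rates, n, None)
            if val is None:
                val = getattr(rep.responses, n)
            samples[n].append(val)
    samples = {n: np.asarray(v) for n, v in samples.items()}
    intervals = {n: tuple(np.percentile(v, [2.5, 97.5])) for n, v in samples.items()}
    return BootstrapResult(intervals=intervals, samples=samples, n_boot=n_boot, seed=seed)


def k1_sensitivity(
    problem: GlobalFitProblem,
    k1_values: tuple = (5e8, 1e10),
    max_nfev: int = 400,
) -> dict:
    """Refit with k1 fixed at alternative values (instrument lower bound and
    the diffusion limit) to demonstrate insensitivity of the unimolecular
    constants to the arbitrary k1 choice."""
    out = {}
    for k1 in k1_values:
        scale = k1 / problem.k1_fixed
        start = problem.start_rates.replace(k1=k1, k_m1=problem.start_rates.k_m1 * scale)
        prob = replace(problem, k1_fixed=k1, start_rates=start)
        out[k1] = run_global_fit(prob, max_nfev=max_nfev)
    return out
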