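"""Synthetic stopped-flow and titration experiments with known ground truth.

Emulates the experimental design end-to-end so every analysis module can be
exercised without instrument data: association ensembles at 0.3 uM duplex
and 1.5–9 uM protein, chase-dissociation traces against 750 uM (nucleotide)
competitor DNA, and anisotropy titrations at 1 uM duplex.  Rate constants
are drawn within the experimentally characterised ranges (k2 400–550 s^-1,
k_m2 80–110 s^-1, k3 14–35 s^-1, k_m3 3–18 s^-1; k1 fixed at 3e9 M^-1 s^-1
with k_m1 = k1/K_G448D, K_G448D = 5e5 M^-1).

All randomness flows from a single master seed through spawned generators,
so any artifact is reproducible from (seed, scenario).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .mechanism import (
    MechanismVariant,
    RateConstants,
    equilibrium_state,
    simulate_timecourse,
)
from .titration import TitrationCurve, TitrationParams, anisotropy_model
from .traces import (
    InstrumentModel,
    KineticTrace,
    REGIME_BALANCED,
    SpeciesResponses,
    apply_instrument,
    predict_dissociation_trace,
    predict_fluorescence_trace,
    reduce_by_group,
)

__all__ = [
    "GroundTruth",
    "RATE_RANGES",
    "K_G448D_TARGET",
    "K1_FIXED",
    "make_ground_truth",
    "simulate_association_dataset",
    "simulate_dissociation_dataset",
    "simulate_titration_dataset",
]

K1_FIXED = 3e9          # M^-1 s^-1, the fixed bimolecular constant
K_G448D_TARGET = 5e5    # M^-1, encounter-step association constant

# experimentally characterised rate ranges (s^-1) for the unimolecular steps
RATE_RANGES = {
    "k2": (400.0, 550.0),
    "k_m2": (80.0, 110.0),
    "k3": (14.0, 35.0),
    "k_m3": (3.0, 18.0),
}

# steady-state emission fold-changes over free duplex used for the species
# responses: non-specific complex ~1.25x, flipped intermediate ~2.5x,
# stabilised complex ~5.5x (label position 7)
_DEFAULT_FOLDS = {"ns": 1.25, "fl": 2.5, "st": 5.5}

# anisotropy end points and per-scenario quantum-yield ratios
_TITRATION_DEFAULTS = {"r_d": 0.10, "r_t": 0.25}
_SCENARIO_R = {"HM": 5.5, "NM": 2.5, "G448D": 1.25}


@dataclass(frozen=True)
class GroundTruth:
    """Complete generating model for one synthetic scenario."""

    scenario: str                 # HM | NM | G448D
    rates: RateConstants
    responses: SpeciesResponses
    instrument: InstrumentModel
    noise_sd: float
    seed: int

    @property
    def variant(self) -> MechanismVariant:
        return MechanismVariant.for_scenario(self.scenario)

    def to_scenario(self, scenario: str) -> "GroundTruth":
        """Same underlying rates restricted to another scenario's steps.

        The encounter and flipping steps are shared between duplex types, so
        an NM ground truth is the HM one with the third step removed.
        """
        variant = MechanismVariant.for_scenario(scenario)
        return replace(self, scenario=scenario.upper(), rates=variant.apply(self.rates))


def make_ground_truth(
    scenario: str,
    seed: int = 0,
    noise_sd: float | None = None,
    regime: tuple = REGIME_BALANCED,
    I0: float = 1.0,
) -> GroundTruth:
    """Reproducible draw of a generating model for one scenario.

    The unimolecular rates are drawn uniformly within the characterised
    ranges; steps absent from the scenario are zero.  Detector noise
    defaults to 1% of the free-duplex signal level I0*Nt at the standard
    0.3 uM duplex concentration.
    """
    variant = MechanismVariant.for_scenario(scenario)
    rng = np.random.default_rng(seed)
    draw = {k: rng.uniform(*b) for k, b in RATE_RANGES.items()}
    rates = variant.apply(
        RateConstants(K1_FIXED, K1_FIXED / K_G448D_TARGET, draw["k2"], draw["k_m2"],
                      draw["k3"], draw["k_m3"])
    )
    responses = SpeciesResponses.from_fold_changes(
        I0, _DEFAULT_FOLDS["ns"], _DEFAULT_FOLDS["fl"], _DEFAULT_FOLDS["st"]
    )
    if noise_sd is None:
        noise_sd = 0.01 * I0 * 0.3
    instrument = InstrumentModel(dead_time=2.7e-3, regimes=regime, noise_sd=noise_sd)
    return GroundTruth(scenario.upper(), rates, responses, instrument, noise_sd, seed)


def _dense_grid(t_end: float) -> np.ndarray:
    """Simulation grid covering [0, t_end] densely enough for interpolation."""
    early = np.linspace(0.0, 1e-3, 201)
    rest = np.geomspace(1e-3, t_end, 2000)
    return np.unique(np.concatenate([early, rest]))


def simulate_association_dataset(
    truth: GroundTruth,
    Pt_series_uM=(1.5, 3.0, 4.5, 7.5, 9.0),
    Nt_uM: float = 0.3,
    group_size: int = 4,
) -> list[KineticTrace]:
    """Association ensemble: one trace per protein concentration plus a
    buffer-control trace (Pt = 0), each passed through the instrument model
    and block-averaged by ``group_size``."""
    instr = truth.instrument
    sample_t = instr.sample_times()
    traces = []
    child = np.random.default_rng(truth.seed).spawn(len(Pt_series_uM) + 1)
    for i, Pt in enumerate(Pt_series_uM):
        t_grid = np.unique(np.concatenate([[0.0], sample_t]))
        traj = simulate_timecourse(truth.rates, truth.variant, Nt_uM, Pt,
                                   t_grid, units="uM")
        f = predict_fluorescence_trace(traj, truth.responses)
        meta = {"duplex": truth.scenario, "protein": "SRA", "kind": "association",
                "Nt_uM": Nt_uM, "Pt_uM": Pt}
        tr = apply_instrument(t_grid, f, instr, seed=child[i], metadata=meta)
        traces.append(reduce_by_group(tr, group_size))
    # buffer control: free duplex only
    f0 = np.full(sample_t.size + 1, truth.responses.I0 * Nt_uM)
    t0 = np.unique(np.concatenate([[0.0], sample_t]))
    meta0 = {"duplex": truth.scenario, "protein": "buffer", "kind": "buffer",
             "Nt_uM": Nt_uM, "Pt_uM": 0.0}
    ctrl = apply_instrument(t0, f0, instr, seed=child[-1], metadata=meta0)
    traces.append(reduce_by_group(ctrl, group_size))
    return traces


def simulate_dissociation_dataset(
    truth: GroundTruth,
    Nt_uM: float = 0.3,
    Pt_uM: float | None = None,
    competitor_uM: float = 750.0,
    trap_rate: float = 3e9,
    site_size_nt: int = 12,
    t_end: float | None = None,
    group_size: int = 4,
) -> list[KineticTrace]:
    """Chase-dissociation experiment: pre-equilibrated complex mixed with
    excess competitor, plus a competitor-free control (flat trace).

    The protein concentration defaults to the complex-preparation design
    (0.75 uM for HM, 1.5 uM for NM after mixing).  The acquisition window
    stretches automatically for slowly dissociating complexes.
    """
    if Pt_uM is None:
        Pt_uM = 0.75 if truth.scenario == "HM" else 1.5
    if t_end is None:
        t_end = 2.0 if truth.scenario == "HM" else 1.0
    regimes = ((2000, 0.0, 0.1 * t_end), (9000, 0.1 * t_end, t_end))
    instr = InstrumentModel(truth.instrument.dead_time, regimes, truth.instrument.noise_sd)
    t_grid = np.unique(np.concatenate([[0.0], instr.sample_times()]))
    child = np.random.default_rng(truth.seed).spawn(2)
    out = []
    for rng, comp in zip(child, (competitor_uM, 0.0)):
        ideal = predict_dissociation_trace(
            truth.rates, truth.variant, truth.responses,
            complex_prep=(Nt_uM, Pt_uM), competitor=(comp, trap_rate),
            t_grid=t_grid, site_size_nt=site_size_nt, units="uM",
        )
        meta = dict(ideal.metadata)
        meta.update(duplex=truth.scenario, protein="SRA",
                    kind="dissociation" if comp > 0 else "buffer")
        tr = apply_instrument(t_grid, ideal.intensity, instr, seed=rng, metadata=meta)
        out.append(reduce_by_group(tr, group_size))
    return out


def simulate_titration_dataset(
    truth: GroundTruth,
    Nt_uM: float = 1.0,
    Pt_grid_uM=None,
    r_d: float | None = None,
    r_t: float | None = None,
    R: float | None = None,
    noise_sd_r: float = 0.003,
    n_measurements: int = 10,
    seed: int | None = None,
) -> TitrationCurve:
    """Anisotropy titration generated from the full mechanism's equilibrium.

    The bound fraction at each protein concentration counts *all* bound
    species (what anisotropy physically reports), then the quantum-yield-
    corrected anisotropy mixing is applied.  Note this total-bound
    convention deliberately differs from the stepwise-product closure used
    when reading equilibrium constants off fitted rates.

    ``noise_sd_r`` is the single-measurement anisotropy noise; each recorded
    point is the average of ``n_measurements`` raw readings (the acquisition
    protocol), so its effective standard deviation is noise_sd_r/sqrt(n).
    """
    if Pt_grid_uM is None:
        Pt_grid_uM = np.concatenate([[0.0], np.geomspace(0.1, 30.0, 11)])
    Pt_grid_uM = np.asarray(Pt_grid_uM, dtype=float)
    r_d = _TITRATION_DEFAULTS["r_d"] if r_d is None else r_d
    r_t = _TITRATION_DEFAULTS["r_t"] if r_t is None else r_t
    R = _SCENARIO_R[truth.scenario] if R is None else R
    theta = np.array([
        equilibrium_state(truth.rates, truth.variant, Nt_uM, Pt, units="uM").bound_fraction
        for Pt in Pt_grid_uM
    ])
    params = TitrationParams(Ka=1.0, r_d=r_d, r_t=r_t, R=R)  # Ka unused by the mixing model
    r = anisotropy_model(params, theta)
    sd_point = noise_sd_r / np.sqrt(max(n_measurements, 1))
    if noise_sd_r > 0:
        rng = np.random.default_rng(truth.seed if seed is None else seed)
        r = r + rng.normal(0.0, sd_point, size=r.size)
        r = np.clip(r, -0.19, 0.39)
    sd = np.full(r.size, sd_point if noise_sd_r > 0 else 1e-6)
    return TitrationCurve(Pt=Pt_grid_uM * 1e-6, r=r, Nt=Nt_uM * 1e-6, sd=sd,
                          label=f"{truth.scenario} synthetic titration")
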