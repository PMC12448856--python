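"""Observable stopped-flow fluorescence traces from species trajectories.

The fluorescence of a mixture is linear in the species concentrations,
F(t) = I0*[N] + Ins*[NPns] + Ifl*[NPfl] + Ist*[NPst], with per-species
response factors (intensity per micromolar).  The instrument model samples
the ideal signal on the acquisition-regime grids, discards everything before
the mixing dead time, and adds homoscedastic Gaussian detector noise.
Competition ("chase") dissociation is modelled by a pseudo-first-order trap
consuming free protein, emulating a large excess of unlabelled competitor
DNA that prevents rebinding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .mechanism import (
    MechanismVariant,
    RateConstants,
    SolverError,
    StateVector,
    Trajectory,
    equilibrium_state,
    to_micromolar,
)

__all__ = [
    "SpeciesResponses",
    "InstrumentModel",
    "KineticTrace",
    "REGIME_FINE",
    "REGIME_BALANCED",
    "predict_fluorescence_trace",
    "apply_instrument",
    "reduce_by_group",
    "predict_dissociation_trace",
    "write_trace_csv",
    "read_trace_csv",
]

# Acquisition regimes used on the stopped-flow instrument: the maximum
# point count in the first 0.1 s plus 9000 points to 1 s, or a sparser
# 2000-point early window that eases visualisation of the fast phase.
REGIME_FINE = ((10000, 0.0, 0.1), (9000, 0.1, 1.0))
REGIME_BALANCED = ((2000, 0.0, 0.1), (9000, 0.1, 1.0))


@dataclass(frozen=True)
class SpeciesResponses:
    """Fluorescence response per micromolar of N, NPns, NPfl and NPst.

    Defaults anchor the bound-species responses to the steady-state emission
    fold-changes: ~1.25x for the non-specific complex (the binding-only
    mutant), ~2.5x for the flipped intermediate (NM duplex) and ~5.5x for
    the stabilised complex (HM duplex, position 7).
    """

    I0: float
    Ins: float
    Ifl: float
    Ist: float

    def __post_init__(self):
        for name in ("I0", "Ins", "Ifl", "Ist"):
            if getattr(self, name) < 0:
                raise ValueError(f"response {name} must be >= 0")

    @classmethod
    def from_fold_changes(cls, I0: float = 1.0, ns_fold: float = 1.25,
                          fl_fold: float = 2.5, st_fold: float = 5.5) -> "SpeciesResponses":
        return cls(I0, ns_fold * I0, fl_fold * I0, st_fold * I0)

    def as_array(self) -> np.ndarray:
        return np.array([self.I0, self.Ins, self.Ifl, self.Ist])


@dataclass(frozen=True)
class InstrumentModel:
    """Stopped-flow acquisition model: dead time, regimes, detector noise."""

    dead_time: float = 2.7e-3            # s
    regimes: tuple = REGIME_BALANCED     # ((n_points, t_start, t_end), ...)
    noise_sd: float = 0.0                # intensity units, additive Gaussian

    def __post_init__(self):
        if self.dead_time <= 0:
            raise ValueError("dead_time must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        prev_end = -np.inf
        for n, t0, t1 in self.regimes:
            if n < 1 or t1 <= t0 or t0 < prev_end:
                raise ValueError("regimes must be ordered, non-overlapping, non-empty")
            prev_end = t1

    def sample_times(self) -> np.ndarray:
        """Acquisition grid (seconds) after discarding the dead time."""
        chunks = []
        for n, t0, t1 in self.regimes:
            dt = (t1 - t0) / n
            chunks.append(t0 + dt * np.arange(1, n + 1))
        t = np.concatenate(chunks)
        return t[t >= self.dead_time]

    @property
    def t_end(self) -> float:
        return self.regimes[-1][2]


@dataclass
class KineticTrace:
    """A sampled fluorescence time series with experiment metadata.

    Metadata keys follow the experimental design: ``duplex`` (HM/NM),
    ``position`` (label site: 5, 7, 6p, 8p), ``protein`` (SRA/G448D),
    ``Nt_uM``, ``Pt_uM`` and ``kind`` (association | dissociation | buffer).
    """

    time: np.ndarray
    intensity: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.time.shape != self.intensity.shape:
            raise ValueError("time and intensity must have equal length")
        if self.time.size and np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")

    def __len__(self):
        return self.time.size

    @property
    def kind(self) -> str:
        return self.metadata.get("kind", "association")


def predict_fluorescence_trace(trajectory: Trajectory, responses: SpeciesResponses) -> np.ndarray:
    """Ideal fluorescence F(t) from a species trajectory (micromolar)."""
    return (
        responses.I0 * trajectory.N
        + responses.Ins * trajectory.NPns
        + responses.Ifl * trajectory.NPfl
        + responses.Ist * trajectory.NPst
    )


def apply_instrument(
    t_ideal: np.ndarray,
    f_ideal: np.ndarray,
    instrument: InstrumentModel,
    seed: int | None = None,
    metadata: dict | None = None,
) -> KineticTrace:
    """Sample an ideal trace through the acquisition model.

    The ideal trace must cover the full acquisition span; samples before the
    dead time are discarded and Gaussian noise of sd ``instrument.noise_sd``
    is added with the given seed (same seed, same realisation).
    """
    t_ideal = np.asarray(t_ideal, dtype=float)
    f_ideal = np.asarray(f_ideal, dtype=float)
    if instrument.t_end > t_ideal[-1] + 1e-12 or instrument.regimes[0][1] < t_ideal[0] - 1e-12:
        raise ValueError(
            f"acquisition regimes span [{instrument.regimes[0][1]}, {instrument.t_end}] s "
            f"but the ideal trace covers [{t_ideal[0]}, {t_ideal[-1]}] s"
        )
    t = instrument.sample_times()
    f = np.interp(t, t_ideal, f_ideal)
    if instrument.noise_sd > 0:
        rng = np.random.default_rng(seed)
        f = f + rng.normal(0.0, instrument.noise_sd, size=f.size)
    return KineticTrace(t, f, dict(metadata or {}))


def reduce_by_group(trace: KineticTrace, group_size: int = 4) -> KineticTrace:
    """Block-average consecutive points in time and intensity.

    Non-overlapping blocks of ``group_size`` points; a trailing remainder is
    averaged as a short block.  Used to condense raw acquisitions before
    fitting, as done on the instrument software.
    """
    if group_size < 1:
        raise ValueError("group_size must be >= 1")
    if group_size == 1:
        return KineticTrace(trace.time.copy(), trace.intensity.copy(), dict(trace.metadata))
    n = len(trace)
    edges = np.arange(0, n, group_size)
    t = np.add.reduceat(trace.time, edges) / np.diff(np.append(edges, n))
    f = np.add.reduceat(trace.intensity, edges) / np.diff(np.append(edges, n))
    return KineticTrace(t, f, dict(trace.metadata))


def predict_dissociation_trace(
    rates: RateConstants,
    variant: MechanismVariant,
    responses: SpeciesResponses,
    complex_prep: tuple[float, float],
    competitor: tuple[float, float],
    t_grid: np.ndarray,
    site_size_nt: int = 12,
    units: str = "M",
    rtol: float = 1e-9,
    atol: float = 1e-12,
) -> KineticTrace:
    """Chase-dissociation kinetics of a pre-equilibrated complex.

    The complex is pre-formed at ``complex_prep = (Nt, Pt)`` via the scheme's
    equilibrium, then mixed with unlabelled competitor DNA given as
    ``competitor = (nucleotide_concentration, bimolecular_trap_rate)``.  The
    competitor acts as a pseudo-first-order sink on free protein with rate
    trap_rate * [sites], where [sites] = nucleotides / site_size_nt.  The
    returned fluorescence comes from the labelled-duplex species only.

    A warning is issued when the trap is less than 10x faster than rebinding
    (k1*Nt), i.e. when the competition is not effective.
    """
    Nt, Pt = complex_prep
    comp_conc, trap_rate = competitor
    Nt_uM = to_micromolar(Nt, units)
    Pt_uM = to_micromolar(Pt, units)
    comp_uM = to_micromolar(comp_conc, units)
    eq = equilibrium_state(rates, variant, Nt_uM, Pt_uM, units="uM")
    r = variant.apply(rates)
    k1u, km1, k2, km2, k3, km3 = (
        r.k1 * 1e-6, r.k_m1, r.k2, r.k_m2, r.k3, r.k_m3,
    )
    trap_eff = trap_rate * 1e-6 * (comp_uM / site_size_nt)  # s^-1
    rebind = k1u * Nt_uM
    if 0 < trap_eff < 10.0 * rebind:
        warnings.warn(
            f"competition not effective: trap rate {trap_eff:.3g} s^-1 is less than "
            f"10x the rebinding rate k1*Nt = {rebind:.3g} s^-1",
            stacklevel=2,
        )

    # 6th species: protein sequestered on competitor (keeps conservation closed)
    def rhs(t, y):
        n, p, ns, fl, st, trapped = y
        v1 = k1u * n * p - km1 * ns
        v2 = k2 * ns - km2 * fl
        v3 = k3 * fl - km3 * st
        vt = trap_eff * p
        return [-v1, -v1 - vt, v1 - v2, v2 - v3, v3, vt]

    def jac(t, y):
        n, p = y[0], y[1]
        a, b = k1u * p, k1u * n
        return np.array([
            [-a, -b, km1, 0, 0, 0],
            [-a, -b - trap_eff, km1, 0, 0, 0],
            [a, b, -(km1 + k2), km2, 0, 0],
            [0, 0, k2, -(km2 + k3), km3, 0],
            [0, 0, 0, k3, -km3, 0],
            [0, trap_eff, 0, 0, 0, 0],
        ])

    t_grid = np.asarray(t_grid, dtype=float)
    y0 = np.append(eq.as_array(), 0.0)
    sol = solve_ivp(rhs, (t_grid[0], t_grid[-1]), y0, method="LSODA",
                    t_eval=t_grid, jac=jac, rtol=rtol, atol=atol)
    if not sol.success:
        raise SolverError(f"dissociation integration failed near t = {sol.t[-1]:.3e} s")
    y = np.clip(sol.y, 0.0, None)
    f = (responses.I0 * y[0] + responses.Ins * y[2]
         + responses.Ifl * y[3] + responses.Ist * y[4])
    meta = {"kind": "dissociation", "Nt_uM": Nt_uM, "Pt_uM": Pt_uM,
            "competitor_uM": comp_uM, "variant": variant.value}
    return KineticTrace(t_grid, f, meta)


# ---------------------------------------------------------------------------
# delimited-text I/O

def write_trace_csv(trace: KineticTrace, path) -> None:
    """CSV with '# key: value' metadata header and columns time_s, intensity."""
    with open(path, "w") as fh:
        for key, val in trace.metadata.items():
            fh.write(f"# {key}: {val}\n")
        pd.DataFrame({"time_s": trace.time, "intensity": trace.intensity}).to_csv(
            fh, index=False
        )


def read_trace_csv(path) -> KineticTrace:
    meta = {}
    body = []
    with open(path) as fh:
        for ln in fh:
            if ln.startswith("#"):
                key, _, val = ln[1:].partition(":")
                meta[key.strip()] = _coerce(val.strip())
            else:
                body.append(ln)
    from io import StringIO

    df = pd.read_csv(StringIO("".join(body)))
    return KineticTrace(df["time_s"].to_numpy(), df["intensity"].to_numpy(), meta)


def _coerce(s: str):
    for cast in (int, float):
        try:
            return cast(s)
        except ValueError:
            pass
    return s
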