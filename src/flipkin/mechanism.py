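"""Mass-action model of the sequential protein–DNA base-flipping scheme.

The reaction scheme couples a bimolecular encounter step to up to two
unimolecular isomerisation steps::

    N + P  <-k1/k_m1->  NPns  <-k2/k_m2->  NPfl  <-k3/k_m3->  NPst

where N is the free (labelled) DNA duplex, P the free SRA protein, NPns the
non-specifically bound encounter complex, NPfl the base-flipped intermediate
and NPst the stabilised final complex.  Three variants of the scheme are
used: the full three-step mechanism (hemi-methylated duplex + SRA), a
two-step mechanism with the last step removed (non-methylated duplex + SRA)
and a binding-only mechanism (the flipping-incompetent G448D mutant).

Concentrations are handled internally in micromolar with the bimolecular
rate constant rescaled accordingly; this conditions the stiff system, whose
rates span roughly four decades (k1*Pt ~ 2e4 s^-1 versus k_m3 ~ 4 s^-1).
Public functions accept concentrations in molar by default (``units="M"``)
or micromolar (``units="uM"``).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from enum import Enum
from typing import Sequence

import numpy as np
import yaml
from scipy.integrate import solve_ivp
from scipy.integrate import odeint

__all__ = [
    "RateConstants",
    "MechanismVariant",
    "StateVector",
    "Trajectory",
    "EquilibriumConstants",
    "RelaxationSpectrum",
    "SolverError",
    "to_micromolar",
    "from_micromolar",
    "simulate_timecourse",
    "simulate_ensemble",
    "equilibrium_state",
    "equilibrium_constants_from_rates",
    "convention_discrepancy",
    "initial_rates_from_constants",
    "relaxation_rates_approx",
    "relaxation_rates_exact",
    "bound_chain_slowest_rate",
    "derive_k3_from_equilibrium",
    "k1_lower_bound",
    "rates_to_config",
    "rates_from_config",
    "save_rates",
    "load_rates",
]

_UNIT_TO_UM = {"M": 1e6, "mM": 1e3, "uM": 1.0, "µM": 1.0, "nM": 1e-3}


class SolverError(RuntimeError):
    """Raised when the stiff integrator fails to converge."""


def to_micromolar(value, units: str = "M"):
    """Convert a concentration (scalar or array) to micromolar."""
    try:
        scale = _UNIT_TO_UM[units]
    except KeyError:
        raise ValueError(f"unknown concentration unit {units!r}") from None
    return np.asarray(value, dtype=float) * scale if np.ndim(value) else float(value) * scale


def from_micromolar(value_uM, units: str = "M"):
    """Convert a micromolar concentration to the requested unit."""
    try:
        scale = _UNIT_TO_UM[units]
    except KeyError:
        raise ValueError(f"unknown concentration unit {units!r}") from None
    return np.asarray(value_uM, dtype=float) / scale if np.ndim(value_uM) else float(value_uM) / scale


class MechanismVariant(str, Enum):
    """Which steps of the scheme are active.

    ``three_step``  : full scheme (HM duplex + SRA)
    ``two_step``    : k3 = k_m3 = 0 (NM duplex + SRA)
    ``binding_only``: additionally k2 = k_m2 = 0 (SRA G448D)
    """

    THREE_STEP = "three_step"
    TWO_STEP = "two_step"
    BINDING_ONLY = "binding_only"

    def apply(self, rates: "RateConstants") -> "RateConstants":
        """Return a copy of *rates* with inactive steps forced to zero."""
        if self is MechanismVariant.THREE_STEP:
            return rates
        if self is MechanismVariant.TWO_STEP:
            return RateConstants(rates.k1, rates.k_m1, rates.k2, rates.k_m2, 0.0, 0.0)
        return RateConstants(rates.k1, rates.k_m1, 0.0, 0.0, 0.0, 0.0)

    @classmethod
    def for_scenario(cls, scenario: str) -> "MechanismVariant":
        """Map a duplex/protein scenario label (HM, NM, G448D) to a variant."""
        key = scenario.upper()
        table = {"HM": cls.THREE_STEP, "NM": cls.TWO_STEP, "G448D": cls.BINDING_ONLY}
        if key not in table:
            raise ValueError(f"unknown scenario {scenario!r}; expected HM, NM or G448D")
        return table[key]


@dataclass(frozen=True)
class RateConstants:
    """The six elementary rate constants of the scheme.

    k1 is bimolecular (M^-1 s^-1); all others are first order (s^-1).
    """

    k1: float
    k_m1: float
    k2: float = 0.0
    k_m2: float = 0.0
    k3: float = 0.0
    k_m3: float = 0.0

    def __post_init__(self):
        for name in ("k1", "k_m1", "k2", "k_m2", "k3", "k_m3"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"rate constant {name} must be finite and >= 0, got {v}")

    @property
    def K1(self) -> float:
        """Stepwise association constant k1/k_m1 (M^-1)."""
        if self.k_m1 == 0:
            raise ZeroDivisionError("K1 undefined: k_m1 = 0")
        return self.k1 / self.k_m1

    @property
    def K2(self) -> float:
        if self.k_m2 == 0:
            raise ZeroDivisionError("K2 undefined: k_m2 = 0")
        return self.k2 / self.k_m2

    @property
    def K3(self) -> float:
        if self.k_m3 == 0:
            raise ZeroDivisionError("K3 undefined: k_m3 = 0")
        return self.k3 / self.k_m3

    def as_dict(self) -> dict:
        return asdict(self)

    def replace(self, **kw) -> "RateConstants":
        d = self.as_dict()
        d.update(kw)
        return RateConstants(**d)


_SPECIES = ("N", "P", "NPns", "NPfl", "NPst")


@dataclass
class StateVector:
    """Concentrations of the five species, in micromolar."""

    N: float
    P: float
    NPns: float = 0.0
    NPfl: float = 0.0
    NPst: float = 0.0

    def __post_init__(self):
        for name in _SPECIES:
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"concentration {name} must be >= 0, got {v}")

    @property
    def total_duplex(self) -> float:
        return self.N + self.NPns + self.NPfl + self.NPst

    @property
    def total_protein(self) -> float:
        return self.P + self.NPns + self.NPfl + self.NPst

    @property
    def bound_fraction(self) -> float:
        """Fraction of duplex in any bound form."""
        nt = self.total_duplex
        return (self.NPns + self.NPfl + self.NPst) / nt if nt > 0 else 0.0

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, s) for s in _SPECIES], dtype=float)

    @classmethod
    def from_array(cls, y) -> "StateVector":
        return cls(*(float(v) for v in y))


@dataclass
class Trajectory:
    """Time-resolved species concentrations (micromolar) on a grid (seconds)."""

    t: np.ndarray
    N: np.ndarray
    P: np.ndarray
    NPns: np.ndarray
    NPfl: np.ndarray
    NPst: np.ndarray

    def state_at(self, i: int) -> StateVector:
        return StateVector(self.N[i], self.P[i], self.NPns[i], self.NPfl[i], self.NPst[i])

    @property
    def final_state(self) -> StateVector:
        return self.state_at(-1)

    def species_matrix(self) -> np.ndarray:
        """(n_times, 5) array in species order N, P, NPns, NPfl, NPst."""
        return np.column_stack([self.N, self.P, self.NPns, self.NPfl, self.NPst])


@dataclass(frozen=True)
class EquilibriumConstants:
    """Scenario-level association constants (M^-1) under a stated convention.

    ``final_state`` equates the measured constant with the stepwise product
    up to the last populated species (K_NM = K1*K2, K_HM = K1*K2*K3);
    ``total_bound`` counts every bound species (K_NM = K1*(1+K2),
    K_HM = K1*(1+K2+K2*K3)), which is what an anisotropy titration
    physically reports.
    """

    K_G448D: float
    K_NM: float
    K_HM: float
    convention: str = "final_state"


# ---------------------------------------------------------------------------
# mass-action right-hand side (micromolar units)

def _rate_tuple_uM(rates: RateConstants) -> tuple:
    # k1 rescaled M^-1 s^-1 -> uM^-1 s^-1
    return (rates.k1 * 1e-6, rates.k_m1, rates.k2, rates.k_m2, rates.k3, rates.k_m3)


def _rhs(y, k1u, km1, k2, km2, k3, km3):
    n, p, ns, fl, st = y
    v1 = k1u * n * p - km1 * ns
    v2 = k2 * ns - km2 * fl
    v3 = k3 * fl - km3 * st
    return np.array([-v1, -v1, v1 - v2, v2 - v3, v3])


def _jac(y, k1u, km1, k2, km2, k3, km3):
    n, p, ns, fl, st = y
    a = k1u * p
    b = k1u * n
    return np.array(
        [
            [-a, -b, km1, 0.0, 0.0],
            [-a, -b, km1, 0.0, 0.0],
            [a, b, -(km1 + k2), km2, 0.0],
            [0.0, 0.0, k2, -(km2 + k3), km3],
            [0.0, 0.0, 0.0, k3, -km3],
        ]
    )


def _check_conservation(traj: Trajectory, Nt_uM: float, Pt_uM: float, rtol: float = 1e-6):
    nt = traj.N + traj.NPns + traj.NPfl + traj.NPst
    pt = traj.P + traj.NPns + traj.NPfl + traj.NPst
    scale_n = max(Nt_uM, 1e-30)
    scale_p = max(Pt_uM, 1e-30)
    err_n = np.max(np.abs(nt - Nt_uM)) / scale_n
    err_p = np.max(np.abs(pt - Pt_uM)) / scale_p
    if err_n > rtol or err_p > rtol:
        raise SolverError(
            f"conservation violated (duplex {err_n:.2e}, protein {err_p:.2e} relative)"
        )


def pre_equilibrated_step1(rates: RateConstants, Nt_uM: float, Pt_uM: float) -> StateVector:
    """Equilibrium of the bimolecular step alone, as a t=0 starting state.

    Approximation mode mirroring the assumption that the encounter step is
    fully equilibrated within the instrument dead time.
    """
    if rates.k_m1 == 0:
        raise ValueError("step-1 pre-equilibration requires k_m1 > 0")
    K1u = rates.k1 * 1e-6 / rates.k_m1  # uM^-1
    b = Nt_uM + Pt_uM + 1.0 / K1u
    bound = 0.5 * (b - np.sqrt(b * b - 4.0 * Nt_uM * Pt_uM))
    bound = min(bound, Nt_uM, Pt_uM)
    return StateVector(Nt_uM - bound, Pt_uM - bound, bound, 0.0, 0.0)


def simulate_timecourse(
    rates: RateConstants,
    variant: MechanismVariant,
    Nt: float,
    Pt: float,
    t_grid: Sequence[float],
    initial: StateVector | str = "unmixed",
    units: str = "M",
    rtol: float = 1e-9,
    atol: float = 1e-12,
    pre_equilibrate_step1_flag: bool = False,
) -> Trajectory:
    """Integrate the mass-action ODE system on *t_grid*.

    Parameters
    ----------
    Nt, Pt
        Total duplex and protein concentrations (after mixing), in *units*.
    initial
        ``"unmixed"`` starts from free N and P at ``t_grid[0]``; otherwise a
        :class:`StateVector` (micromolar) consistent with the totals.
    pre_equilibrate_step1_flag
        If True, the encounter step is analytically equilibrated before the
        first grid point (documented approximation; default off).

    Returns a :class:`Trajectory` in micromolar.  Conservation of duplex and
    protein is verified at every point to 1e-6 relative.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size < 2 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing with >= 2 points")
    if Nt < 0 or Pt < 0:
        raise ValueError("Nt and Pt must be >= 0")
    Nt_uM = to_micromolar(Nt, units)
    Pt_uM = to_micromolar(Pt, units)
    r = variant.apply(rates)
    k = _rate_tuple_uM(r)

    if isinstance(initial, str):
        if initial != "unmixed":
            raise ValueError(f"unknown initial condition {initial!r}")
        if pre_equilibrate_step1_flag and Pt_uM > 0 and r.k_m1 > 0:
            y0 = pre_equilibrated_step1(r, Nt_uM, Pt_uM).as_array()
        else:
            y0 = np.array([Nt_uM, Pt_uM, 0.0, 0.0, 0.0])
    else:
        y0 = initial.as_array()
        if abs(y0[0] + y0[2:].sum() - Nt_uM) > 1e-6 * max(Nt_uM, 1e-30) or abs(
            y0[1] + y0[2:].sum() - Pt_uM
        ) > 1e-6 * max(Pt_uM, 1e-30):
            raise ValueError("initial state inconsistent with total concentrations")

    sol = solve_ivp(
        lambda t, y: _rhs(y, *k),
        (t_grid[0], t_grid[-1]),
        y0,
        method="LSODA",
        t_eval=t_grid,
        jac=lambda t, y: _jac(y, *k),
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        t_fail = sol.t[-1] if sol.t.size else t_grid[0]
        raise SolverError(
            f"stiff integrator failed near t = {t_fail:.3e} s "
            f"(reached {sol.t.size}/{t_grid.size} grid points): {sol.message}"
        )
    y = np.clip(sol.y, 0.0, None)  # remove sub-atol negative excursions
    traj = Trajectory(t_grid, y[0], y[1], y[2], y[3], y[4])
    _check_conservation(traj, Nt_uM, Pt_uM)
    return traj


def simulate_ensemble(
    rates_list: Sequence[RateConstants],
    variants: Sequence[MechanismVariant],
    Nt_uM: Sequence[float],
    Pt_uM: Sequence[float],
    t_eval: np.ndarray,
    rtol: float = 1e-8,
    atol: float = 1e-11,
) -> np.ndarray:
    """Integrate several independent reactions as one stacked stiff system.

    All reactions share the time grid *t_eval* (seconds, strictly increasing,
    need not start at zero; integration always starts from unmixed species at
    t = 0).  Concentrations are micromolar throughout — this is the fast path
    used by the global fit, where one LSODA call serves the whole trace
    ensemble.

    Returns an array of shape (n_reactions, n_times, 5).
    """
    n = len(rates_list)
    if not (len(variants) == len(Nt_uM) == len(Pt_uM) == n):
        raise ValueError("ensemble inputs must have equal length")
    t_eval = np.asarray(t_eval, dtype=float)
    if np.any(np.diff(t_eval) <= 0):
        raise ValueError("t_eval must be strictly increasing")
    ks = np.array([_rate_tuple_uM(v.apply(r)) for r, v in zip(rates_list, variants)])
    k1u, km1, k2, km2, k3, km3 = (ks[:, i] for i in range(6))

    y0 = np.zeros((n, 5))
    y0[:, 0] = Nt_uM
    y0[:, 1] = Pt_uM

    def rhs(y, t):
        z = y.reshape(n, 5)
        v1 = k1u * z[:, 0] * z[:, 1] - km1 * z[:, 2]
        v2 = k2 * z[:, 2] - km2 * z[:, 3]
        v3 = k3 * z[:, 3] - km3 * z[:, 4]
        out = np.empty_like(z)
        out[:, 0] = -v1
        out[:, 1] = -v1
        out[:, 2] = v1 - v2
        out[:, 3] = v2 - v3
        out[:, 4] = v3
        return out.ravel()

    def dfun(y, t):
        z = y.reshape(n, 5)
        J = np.zeros((5 * n, 5 * n))
        for i in range(n):
            a = k1u[i] * z[i, 1]
            b = k1u[i] * z[i, 0]
            s = slice(5 * i, 5 * i + 5)
            J[s, s] = [
                [-a, -b, km1[i], 0.0, 0.0],
                [-a, -b, km1[i], 0.0, 0.0],
                [a, b, -(km1[i] + k2[i]), km2[i], 0.0],
                [0.0, 0.0, k2[i], -(km2[i] + k3[i]), km3[i]],
                [0.0, 0.0, 0.0, k3[i], -km3[i]],
            ]
        return J

    prepend = t_eval[0] > 0.0
    tt = np.concatenate([[0.0], t_eval]) if prepend else t_eval
    with warnings.catch_warnings():
        # non-convergence is handled explicitly below via the status message
        warnings.simplefilter("ignore")
        y, info = odeint(
            rhs, y0.ravel(), tt, Dfun=dfun, rtol=rtol, atol=atol,
            mxstep=100000, full_output=True,
        )
    if info["message"] != "Integration successful.":
        raise SolverError(f"ensemble integration failed: {info['message']}")
    if prepend:
        y = y[1:]
    return np.clip(y.reshape(len(t_eval), n, 5).transpose(1, 0, 2), 0.0, None)


# ---------------------------------------------------------------------------
# equilibrium analysis

def equilibrium_state(
    rates: RateConstants,
    variant: MechanismVariant,
    Nt: float,
    Pt: float,
    units: str = "M",
) -> StateVector:
    """Closed-form equilibrium of the scheme.

    Summing the bound species with stepwise weights reduces the problem to a
    single quadratic in the total bound concentration B with an effective
    association constant K1*(1 + K2 + K2*K3); species follow from detailed
    balance.  Backward rate constants of active steps must be positive.
    """
    if Nt < 0 or Pt < 0:
        raise ValueError("Nt and Pt must be >= 0")
    Nt_uM = to_micromolar(Nt, units)
    Pt_uM = to_micromolar(Pt, units)
    r = variant.apply(rates)
    if r.k_m1 == 0:
        raise ValueError("equilibrium undefined: k_m1 = 0 for an active binding step")
    if r.k2 > 0 and r.k_m2 == 0:
        raise ValueError("equilibrium undefined: k_m2 = 0 with active step 2")
    if r.k3 > 0 and r.k_m3 == 0:
        raise ValueError("equilibrium undefined: k_m3 = 0 with active step 3")
    K1u = r.k1 * 1e-6 / r.k_m1
    K2 = r.k2 / r.k_m2 if r.k2 > 0 else 0.0
    K3 = (r.k3 / r.k_m3 if r.k3 > 0 else 0.0) if K2 > 0 else 0.0
    S = 1.0 + K2 + K2 * K3
    if Nt_uM == 0 or Pt_uM == 0 or K1u == 0:
        return StateVector(Nt_uM, Pt_uM, 0.0, 0.0, 0.0)
    Keff = K1u * S
    b = Nt_uM + Pt_uM + 1.0 / Keff
    bound = 0.5 * (b - np.sqrt(b * b - 4.0 * Nt_uM * Pt_uM))
    bound = min(bound, Nt_uM, Pt_uM)
    ns = bound / S
    return StateVector(Nt_uM - bound, Pt_uM - bound, ns, K2 * ns, K2 * K3 * ns)


def equilibrium_constants_from_rates(
    rates: RateConstants, convention: str = "final_state"
) -> EquilibriumConstants:
    """Scenario association constants implied by the rate constants."""
    K1, K2, K3 = rates.K1, rates.K2, rates.K3
    if convention == "final_state":
        return EquilibriumConstants(K1, K1 * K2, K1 * K2 * K3, convention)
    if convention == "total_bound":
        return EquilibriumConstants(K1, K1 * (1 + K2), K1 * (1 + K2 + K2 * K3), convention)
    raise ValueError(f"unknown convention {convention!r}")


def convention_discrepancy(rates: RateConstants) -> float:
    """Ratio K_HM(total_bound) / K_HM(final_state) = (1+K2+K2*K3)/(K2*K3).

    Quantifies the gap between equating a measured constant with the
    stepwise product versus with all bound species.
    """
    K2, K3 = rates.K2, rates.K3
    if K2 * K3 == 0:
        raise ZeroDivisionError("discrepancy undefined: K2*K3 = 0")
    return (1 + K2 + K2 * K3) / (K2 * K3)


def initial_rates_from_constants(
    K_G448D: float,
    K_NM: float,
    K_HM: float | None = None,
    k1_fixed: float = 3e9,
    kobs1: float | None = None,
    kobs2: float | None = None,
    k_m3_from_dissociation: float | None = None,
) -> RateConstants:
    """Starting rate constants from equilibrium constants and observed rates.

    Inverts the closure relations K1 = K_G448D, K1*K2 = K_NM, K1*K2*K3 = K_HM
    together with the relaxation relations kobs1 = k2 + k_m2 and
    kobs2 = k3*K2/(1+K2) + k_m3.  If a dissociation-derived k_m3 is given it
    takes precedence and k3 follows from kobs2; otherwise k_m3 is derived
    from (K_HM/K_NM, kobs2) so that every identity holds exactly.  With
    neither kobs2 nor K_HM the third step is left at zero (two-step start).
    """
    for name, v in (("K_G448D", K_G448D), ("K_NM", K_NM), ("k1_fixed", k1_fixed), ("kobs1", kobs1)):
        if v is None or v <= 0:
            raise ValueError(f"{name} must be a positive number, got {v}")
    if kobs2 is not None and kobs2 >= kobs1:
        raise ValueError(f"kobs1 ({kobs1}) must exceed kobs2 ({kobs2})")
    k_m1 = k1_fixed / K_G448D
    K2 = K_NM / K_G448D
    k_m2 = kobs1 / (1.0 + K2)
    k2 = kobs1 - k_m2
    if kobs2 is None:
        k3 = k_m3 = 0.0
    elif k_m3_from_dissociation is not None:
        k_m3 = k_m3_from_dissociation
        k3 = (kobs2 - k_m3) * (1.0 + K2) / K2
        if k3 < 0:
            raise ValueError(
                f"violated relation kobs2 >= k_m3: kobs2 = {kobs2}, k_m3 = {k_m3} imply k3 < 0"
            )
    else:
        if K_HM is None or K_HM <= 0:
            raise ValueError("need K_HM or k_m3_from_dissociation to place the third step")
        K3 = K_HM / K_NM
        k_m3 = kobs2 / (1.0 + K3 * K2 / (1.0 + K2))
        k3 = K3 * k_m3
    return RateConstants(k1_fixed, k_m1, k2, k_m2, k3, k_m3)


def relaxation_rates_approx(rates: RateConstants) -> tuple[float, float]:
    """Observed rate constants of the two resolvable phases.

    kobs1 = k2 + k_m2 and kobs2 = k3*(k2/k_m2)/(1+k2/k_m2) + k_m3, valid
    when the encounter step equilibrates within the dead time and step 2 is
    much faster than step 3.  In the limit k_m2 = 0 (with k3 > 0) the
    pre-equilibrium fraction is 1 and kobs2 = k3 + k_m3.
    """
    kobs1 = rates.k2 + rates.k_m2
    if rates.k_m2 > 0:
        K2 = rates.k2 / rates.k_m2
        kobs2 = rates.k3 * K2 / (1.0 + K2) + rates.k_m3
    else:
        kobs2 = rates.k3 + rates.k_m3
    return kobs1, kobs2


@dataclass
class RelaxationSpectrum:
    """Nonzero relaxation rates (|eigenvalues|, s^-1) sorted descending,
    with multiplicities for degenerate rates (grouped at 1e-6 relative)."""

    rates: np.ndarray
    multiplicities: np.ndarray

    @property
    def slowest(self) -> float:
        return float(self.rates[-1])


def relaxation_rates_exact(
    rates: RateConstants,
    Nt: float,
    Pt: float,
    variant: MechanismVariant = MechanismVariant.THREE_STEP,
    units: str = "M",
) -> RelaxationSpectrum:
    """Eigen-decomposition of the mass-action system linearised at equilibrium.

    Serves as the exact oracle for :func:`relaxation_rates_approx`.  Zero
    eigenvalues from the two conservation laws (and from inactive steps) are
    discarded.
    """
    eq = equilibrium_state(rates, variant, Nt, Pt, units=units)
    r = variant.apply(rates)
    J = _jac(eq.as_array(), *_rate_tuple_uM(r))
    lam = np.abs(np.real(np.linalg.eigvals(J)))
    lam_max = lam.max() if lam.size else 0.0
    lam = np.sort(lam[lam > 1e-9 * max(1.0, lam_max)])[::-1]
    # group degenerate rates
    vals, mults = [], []
    for v in lam:
        if vals and abs(v - vals[-1]) <= 1e-6 * vals[-1]:
            mults[-1] += 1
        else:
            vals.append(v)
            mults.append(1)
    return RelaxationSpectrum(np.array(vals), np.array(mults))


def bound_chain_slowest_rate(
    rates: RateConstants, variant: MechanismVariant = MechanismVariant.THREE_STEP
) -> float:
    """Rate-limiting dissociation rate of the pre-formed complex.

    When released protein cannot rebind (competitor chase), the bound
    species form a linear chain NPst -> NPfl -> NPns -> N whose slowest
    eigenvalue is the observed single-exponential decay rate.
    """
    r = variant.apply(rates)
    if r.k2 == 0:
        return r.k_m1
    A = np.array([
        [-(r.k_m1 + r.k2), r.k_m2, 0.0],
        [r.k2, -(r.k_m2 + r.k3), r.k_m3],
        [0.0, r.k3, -r.k_m3],
    ])
    if r.k3 == 0:
        A = A[:2, :2]
    lam = np.abs(np.real(np.linalg.eigvals(A)))
    return float(lam.min())


def derive_k3_from_equilibrium(Ka_HM: float, rates: RateConstants) -> float:
    """Forward rearrangement constant from the measured HM association constant.

    k3 = Ka_HM * k_m1 * k_m2 * k_m3 / (k1 * k2), i.e. the stepwise closure
    K1*K2*K3 = Ka_HM solved for k3 — used when no slow kinetic phase is
    detectable (the 6' label position).
    """
    if Ka_HM <= 0:
        raise ValueError("Ka_HM must be > 0")
    denom = rates.k1 * rates.k2
    if denom == 0:
        raise ZeroDivisionError("k1*k2 = 0: k3 undefined")
    return Ka_HM * rates.k_m1 * rates.k_m2 * rates.k_m3 / denom


def k1_lower_bound(kobs_max: float, P_min: float, units: str = "M") -> float:
    """Lower bound on the bimolecular constant from instrument resolution.

    The fastest measurable observed rate at the lowest protein concentration
    bounds k1 from below: k1 >= kobs_max / P_min (M^-1 s^-1).
    """
    P_min_M = from_micromolar(to_micromolar(P_min, units), "M")
    if P_min_M <= 0:
        raise ValueError("P_min must be > 0")
    if kobs_max < 0:
        raise ValueError("kobs_max must be >= 0")
    if kobs_max == 0:
        warnings.warn("kobs_max = 0: degenerate (zero) lower bound", stacklevel=2)
        return 0.0
    return kobs_max / P_min_M


# ---------------------------------------------------------------------------
# config (de)serialisation

def rates_to_config(
    rates: RateConstants,
    variant: MechanismVariant = MechanismVariant.THREE_STEP,
    convention: str = "final_state",
    units: str = "M",
) -> dict:
    d = rates.as_dict()
    d.update(variant=variant.value, convention=convention, units=units)
    return d


def rates_from_config(cfg: dict) -> tuple[RateConstants, MechanismVariant, str]:
    cfg = dict(cfg)
    variant = MechanismVariant(cfg.pop("variant", "three_step"))
    convention = cfg.pop("convention", "final_state")
    cfg.pop("units", None)
    rates = RateConstants(**cfg)
    return rates, variant, convention


def save_rates(path, rates, variant=MechanismVariant.THREE_STEP, convention="final_state"):
    cfg = rates_to_config(rates, variant, convention)
    path = str(path)
    with open(path, "w") as fh:
        if path.endswith(".json"):
            json.dump(cfg, fh, indent=2)
        else:
            yaml.safe_dump(cfg, fh)


def load_rates(path):
    path = str(path)
    with open(path) as fh:
        cfg = json.load(fh) if path.endswith(".json") else yaml.safe_load(fh)
    return rates_from_config(cfg)
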