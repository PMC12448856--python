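"""Equilibrium binding from fluorescence-anisotropy titrations.

The measured anisotropy of a labelled duplex titrated with protein is an
intensity-weighted mixture of free and bound signals,

    r = [theta * R * r_t - r_d * (theta - 1)] / (1 + R*theta - theta),

where r_d and r_t are the anisotropies of the free and saturated duplex, R
the quantum-yield ratio of bound over free duplex, and theta the bound
duplex fraction from 1:n mass balance,

    theta = [(1/Ka + n*Nt + Pt) - sqrt((1/Ka + n*Nt + Pt)^2 - 4n*Pt*Nt)] / (2*Nt).

Fitting the composite model to a titration yields the association constant
Ka.  Ka is fitted on a log10 scale (it spans 1e5–1e7 M^-1) and the
stoichiometry n is fixed at 1 by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import lmfit

__all__ = [
    "TitrationCurve",
    "TitrationParams",
    "TitrationFit",
    "NoBindingError",
    "fraction_bound",
    "anisotropy_model",
    "fit_titration",
    "validate_binding_constant",
    "free_energy_difference",
    "R_GAS_CAL",
]

R_GAS_CAL = 1.987  # cal mol^-1 K^-1


class NoBindingError(ValueError):
    """Raised when a titration curve is flat: no binding detected."""


@dataclass(frozen=True)
class TitrationParams:
    """Parameters of the anisotropy binding isotherm."""

    Ka: float        # association constant, M^-1
    r_d: float       # anisotropy of the free duplex
    r_t: float       # anisotropy at saturation
    R: float         # quantum-yield ratio bound/free
    n: float = 1.0   # proteins bound per duplex

    def __post_init__(self):
        if self.Ka <= 0 or self.n <= 0 or self.R <= 0:
            raise ValueError("Ka, n and R must all be > 0")


@dataclass
class TitrationCurve:
    """Anisotropy versus total protein concentration at fixed duplex Nt.

    Concentrations in molar; anisotropies dimensionless, restricted to the
    physical one-photon range (-0.2, 0.4).
    """

    Pt: np.ndarray
    r: np.ndarray
    Nt: float
    sd: np.ndarray | None = None
    label: str = ""

    def __post_init__(self):
        self.Pt = np.asarray(self.Pt, dtype=float)
        self.r = np.asarray(self.r, dtype=float)
        if self.sd is not None:
            self.sd = np.asarray(self.sd, dtype=float)
            if self.sd.shape != self.Pt.shape:
                raise ValueError("sd must match Pt in length")
        if self.Pt.shape != self.r.shape:
            raise ValueError("Pt and r must have equal length")
        if np.any(self.Pt < 0) or np.any(np.diff(self.Pt) <= 0):
            raise ValueError("Pt values must be nonnegative and strictly increasing")
        if np.any(self.r <= -0.2) or np.any(self.r >= 0.4):
            raise ValueError("anisotropy outside the physical range (-0.2, 0.4)")
        if self.Nt <= 0:
            raise ValueError("Nt must be > 0")

    def __len__(self):
        return self.Pt.size


def fraction_bound(params: TitrationParams, Pt, Nt) -> np.ndarray | float:
    """Bound duplex fraction from the quadratic 1:n mass balance.

    Exact closed form of Ka = [NP]/([N][P]) with conservation; values are
    clipped to [0, 1] only against sub-1e-12 floating-point excursions.
    """
    Pt = np.asarray(Pt, dtype=float)
    if Nt == 0:
        raise ValueError("Nt must be > 0 (division by zero in theta)")
    if np.any(Pt < 0) or Nt < 0:
        raise ValueError("Pt and Nt must be >= 0")
    b = 1.0 / params.Ka + params.n * Nt + Pt
    disc = b * b - 4.0 * params.n * Pt * Nt
    theta = (b - np.sqrt(disc)) / (2.0 * Nt)
    theta = np.clip(theta, 0.0, 1.0)
    return float(theta) if theta.ndim == 0 else theta


def anisotropy_model(params: TitrationParams, theta) -> np.ndarray | float:
    """Quantum-yield-corrected anisotropy for a bound fraction theta."""
    theta = np.asarray(theta, dtype=float)
    if np.any(theta < 0) or np.any(theta > 1):
        raise ValueError("theta must lie in [0, 1]")
    denom = 1.0 + params.R * theta - theta
    if np.any(denom <= 0):
        raise ValueError("unphysical quantum-yield ratio: denominator <= 0")
    r = (theta * params.R * params.r_t - params.r_d * (theta - 1.0)) / denom
    return float(r) if r.ndim == 0 else r


def _model_r(Pt, Nt, log10_Ka, r_d, r_t, R, n):
    p = TitrationParams(10.0 ** log10_Ka, r_d, r_t, R, n)
    return anisotropy_model(p, fraction_bound(p, Pt, Nt))


@dataclass
class TitrationFit:
    """Result of fitting the anisotropy isotherm to a titration curve."""

    params: TitrationParams
    stderr: dict
    rss: float
    success: bool
    message: str
    result: object = field(repr=False, default=None)

    def within_tolerance(self, Ka_target: float, tol: float = 0.20) -> bool:
        return validate_binding_constant(self.params.Ka, Ka_target, tol)


def fit_titration(
    curve: TitrationCurve,
    fix_n: float | None = 1.0,
    fix_R: float | None = None,
    flat_threshold: float = 3.0,
) -> TitrationFit:
    """Weighted nonlinear least-squares fit of the anisotropy isotherm.

    n is fixed (default 1, the measured stoichiometry) unless ``fix_n`` is
    None, in which case it floats with a lower bound of 0.1.  The quantum-
    yield ratio R floats by default; pass ``fix_R`` to pin it at the value
    measured from the intensity change during the same titration — R trades
    off strongly against Ka, so fixing it at its measured value sharpens the
    constant considerably.  Weights are inverse-variance when per-point
    standard deviations are available.

    Raises :class:`NoBindingError` when the curve is flat (signal span below
    ``flat_threshold`` times the median point uncertainty).
    """
    if len(curve) < 5:
        raise ValueError("need >= 5 titration points spanning sub- to super-saturation")
    span = np.ptp(curve.r)
    if curve.sd is not None:
        noise = float(np.median(curve.sd))
    else:  # robust noise estimate from first differences
        noise = 1.4826 * float(np.median(np.abs(np.diff(curve.r)))) / np.sqrt(2.0)
    if span < flat_threshold * max(noise, 1e-12):
        raise NoBindingError(
            f"no binding detected: anisotropy span {span:.2e} < "
            f"{flat_threshold} x point uncertainty {noise:.2e}"
        )

    r_lo, r_hi = float(curve.r[0]), float(curve.r[-1])
    pars = lmfit.Parameters()
    # crude half-saturation guess for Ka
    mid = r_lo + 0.5 * (r_hi - r_lo)
    i_mid = int(np.argmin(np.abs(curve.r - mid)))
    Pt_half = max(curve.Pt[i_mid], curve.Nt, 1e-9)
    pars.add("log10_Ka", value=np.log10(1.0 / Pt_half), min=2.0, max=12.0)
    pars.add("r_d", value=r_lo, min=-0.2, max=0.4)
    pars.add("r_t", value=r_hi, min=-0.2, max=0.4)
    if fix_R is None:
        pars.add("R", value=2.0, min=1e-3, max=1e3)
    else:
        pars.add("R", value=float(fix_R), vary=False)
    if fix_n is None:
        pars.add("n", value=1.0, min=0.1, max=10.0)
    else:
        pars.add("n", value=float(fix_n), vary=False)

    weights = 1.0 / curve.sd if curve.sd is not None else None

    def resid(p):
        model = _model_r(curve.Pt, curve.Nt, p["log10_Ka"].value, p["r_d"].value,
                         p["r_t"].value, p["R"].value, p["n"].value)
        res = model - curve.r
        return res * weights if weights is not None else res

    out = lmfit.minimize(resid, pars, method="leastsq")
    p = out.params
    Ka = 10.0 ** p["log10_Ka"].value
    fitted = TitrationParams(Ka, p["r_d"].value, p["r_t"].value, p["R"].value, p["n"].value)
    stderr = {}
    for name in ("r_d", "r_t", "R", "n"):
        stderr[name] = p[name].stderr
    if p["log10_Ka"].stderr is not None:  # delta method back to linear scale
        stderr["Ka"] = Ka * np.log(10.0) * p["log10_Ka"].stderr
    else:
        stderr["Ka"] = None
    return TitrationFit(
        params=fitted,
        stderr=stderr,
        rss=float(np.sum(np.asarray(out.residual) ** 2)),
        success=bool(out.success),
        message=str(out.message),
        result=out,
    )


def validate_binding_constant(Ka_est: float, Ka_target: float, tol: float = 0.20) -> bool:
    """Batch-validation gate: estimate within `tol` (inclusive) of target."""
    if Ka_est <= 0 or Ka_target <= 0:
        raise ValueError("binding constants must be > 0")
    return abs(Ka_est - Ka_target) / Ka_target <= tol


def free_energy_difference(affinity_ratio: float, T: float = 293.15) -> float:
    """Free-energy difference R*T*ln(ratio) in cal/mol at temperature T (K)."""
    if affinity_ratio <= 0 or T <= 0:
        raise ValueError("affinity ratio and temperature must be > 0")
    return R_GAS_CAL * T * np.log(affinity_ratio)


# ---------------------------------------------------------------------------
# delimited-text I/O

def write_titration_csv(curve: TitrationCurve, path) -> None:
    """CSV with a commented header block (# key: value) and columns
    Pt_M, anisotropy[, sd]."""
    with open(path, "w") as fh:
        fh.write(f"# Nt_M: {curve.Nt!r}\n")
        if curve.label:
            fh.write(f"# label: {curve.label}\n")
        cols = {"Pt_M": curve.Pt, "anisotropy": curve.r}
        if curve.sd is not None:
            cols["sd"] = curve.sd
        pd.DataFrame(cols).to_csv(fh, index=False)


def read_titration_csv(path) -> TitrationCurve:
    meta = {}
    with open(path) as fh:
        lines = fh.readlines()
    body = []
    for ln in lines:
        if ln.startswith("#"):
            key, _, val = ln[1:].partition(":")
            meta[key.strip()] = val.strip()
        else:
            body.append(ln)
    from io import StringIO

    df = pd.read_csv(StringIO("".join(body)))
    return TitrationCurve(
        Pt=df["Pt_M"].to_numpy(),
        r=df["anisotropy"].to_numpy(),
        Nt=float(meta["Nt_M"]),
        sd=df["sd"].to_numpy() if "sd" in df else None,
        label=meta.get("label", ""),
    )
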