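"""One-compartment first-order kinetic network of caffeine catabolism.

The model tracks ingested caffeine in the gut, its first-order absorption
into a single well-mixed body compartment, branching conversion to the
three dimethylxanthines (paraxanthine, theobromine, theophylline) and
first-order elimination of all four species:

    gut --k1--> caffeine --k2--> paraxanthine --k6-->
                         --k3--> theobromine  --k7-->
                         --k4--> theophylline --k8-->
                         --k5--> (direct elimination)

Because the cascade is linear, body concentrations have a closed-form
solution built from divided differences of ``exp(-x*t)``; an independent
numerical integrator (`ode_oracle`) is provided for cross-checking.

Measured finger-sweat signals are modelled as the product of the body
concentration and an unknown, time-point-specific sweat volume shared by
all four metabolites (`predicted_signal`).

Units: time in hours, rate constants in 1/h, dose in mg, volume of
distribution in L, concentrations in ug/L, sweat volumes in uL.
Internal bookkeeping is molar; branching fluxes are converted to mass
concentration via the molar-mass ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SPECIES",
    "MOLAR_MASS_DEFAULT",
    "PKConstants",
    "RateConstants",
    "InitialState",
    "ConcentrationTrajectory",
    "SweatVolumeSeries",
    "simulate",
    "caffeine_closed_form",
    "predicted_signal",
    "ode_oracle",
]

#: fixed species order used throughout the package
SPECIES = ("caffeine", "paraxanthine", "theobromine", "theophylline")

MOLAR_MASS_DEFAULT = {
    "caffeine": 194.19,
    "paraxanthine": 180.16,
    "theobromine": 180.16,
    "theophylline": 180.16,
}

# model bounds (1/h, ug/L, uL)
K1_MAX = 10.0
K_MAX = 0.2
C0_MAX = 1.0
V_SWEAT_MIN = 0.05
V_SWEAT_MAX = 4.0

# rate differences below this are treated as coalescent in the closed form
_COALESCE_TOL = 1e-9


class DomainError(ValueError):
    """Parameter outside the model's admissible region."""


class InputError(ValueError):
    """Malformed input data."""


@dataclass(frozen=True)
class PKConstants:
    """Fixed pharmacokinetic constants (not fitted).

    dose : ingested caffeine (mg); bioavailability : absorbed fraction;
    vd : steady-state volume of distribution per species (L);
    molar_mass : g/mol per species.
    """

    dose: float = 200.0
    bioavailability: float = 1.0
    vd: dict[str, float] = field(
        default_factory=lambda: {s: 36.0 for s in SPECIES}
    )
    molar_mass: dict[str, float] = field(
        default_factory=lambda: dict(MOLAR_MASS_DEFAULT)
    )

    def __post_init__(self) -> None:
        if not self.dose > 0:
            raise DomainError("dose must be positive")
        if not 0 < self.bioavailability <= 1:
            raise DomainError("bioavailability must be in (0, 1]")
        for s in SPECIES:
            if self.vd.get(s, 0) <= 0:
                raise DomainError(f"vd[{s}] must be positive")
            if self.molar_mass.get(s, 0) <= 0:
                raise DomainError(f"molar_mass[{s}] must be positive")

    @property
    def absorbed_dose(self) -> float:
        """F*D, the absorbable caffeine mass in the gut at t=0 (mg)."""
        return self.bioavailability * self.dose


@dataclass(frozen=True)
class RateConstants:
    """The eight first-order rate constants of the network (1/h).

    k1 gut->body uptake; k2/k3/k4 caffeine conversion to paraxanthine/
    theobromine/theophylline; k5 direct caffeine elimination; k6/k7/k8
    elimination of paraxanthine/theobromine/theophylline.
    """

    k1: float
    k2: float
    k3: float
    k4: float
    k5: float
    k6: float
    k7: float
    k8: float

    def __post_init__(self) -> None:
        if not 0 <= self.k1 <= K1_MAX:
            raise DomainError(f"k1 must be in [0, {K1_MAX}] 1/h")
        for name in ("k2", "k3", "k4", "k5", "k6", "k7", "k8"):
            v = getattr(self, name)
            if not 0 <= v <= K_MAX:
                raise DomainError(f"{name} must be in [0, {K_MAX}] 1/h")

    @property
    def kappa(self) -> float:
        """Total caffeine turnover k2+k3+k4+k5 (1/h)."""
        return self.k2 + self.k3 + self.k4 + self.k5

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.k1, self.k2, self.k3, self.k4,
             self.k5, self.k6, self.k7, self.k8]
        )


@dataclass(frozen=True)
class InitialState:
    """Initial condition: caffeine starts at zero (fasting), products may
    carry a small pre-dose baseline in [0, 1] ug/L."""

    c0_paraxanthine: float = 0.0
    c0_theobromine: float = 0.0
    c0_theophylline: float = 0.0

    def __post_init__(self) -> None:
        for name in ("c0_paraxanthine", "c0_theobromine", "c0_theophylline"):
            v = getattr(self, name)
            if not 0 <= v <= C0_MAX:
                raise DomainError(f"{name} must be in [0, {C0_MAX}] ug/L")

    def as_array(self) -> np.ndarray:
        """c0 per species in SPECIES order (caffeine fixed at 0)."""
        return np.array(
            [0.0, self.c0_paraxanthine, self.c0_theobromine,
             self.c0_theophylline]
        )


@dataclass(frozen=True)
class ConcentrationTrajectory:
    """Body concentrations (ug/L) of the four species on a time grid (h)."""

    times: np.ndarray
    conc: np.ndarray  # shape (T, 4), columns in SPECIES order

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.conc, dtype=float)
        if c.shape != (t.size, len(SPECIES)):
            raise InputError("conc must have shape (len(times), 4)")
        if not np.all(np.isfinite(c)):
            raise InputError("concentrations must be finite")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "conc", c)

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: time_h, species, concentration_ug_per_L."""
        return pd.DataFrame(
            {
                "time_h": np.repeat(self.times, len(SPECIES)),
                "species": list(SPECIES) * self.times.size,
                "concentration_ug_per_L": self.conc.ravel(),
            }
        )


@dataclass(frozen=True)
class SweatVolumeSeries:
    """Sweat volume per sampled time-point (uL), shared by all metabolites."""

    volumes: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.volumes, dtype=float)
        if v.ndim != 1 or v.size == 0:
            raise InputError("volumes must be a non-empty 1-D array")
        if np.any(v < V_SWEAT_MIN) or np.any(v > V_SWEAT_MAX):
            raise DomainError(
                f"sweat volumes must lie in [{V_SWEAT_MIN}, {V_SWEAT_MAX}] uL"
            )
        object.__setattr__(self, "volumes", v)


def _check_times(times: np.ndarray) -> np.ndarray:
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise InputError("times must be a non-empty 1-D array")
    if np.any(~np.isfinite(t)) or np.any(t < 0):
        raise InputError("times must be finite and non-negative")
    if np.any(np.diff(t) < 0):
        raise InputError("times must be sorted ascending")
    return t


def _phi2(a: float, b: float, t: np.ndarray) -> np.ndarray:
    """(exp(-a t) - exp(-b t)) / (b - a), continuous at a == b.

    This is the impulse response of two first-order stages in series
    (Bateman kernel); symmetric in (a, b) and positive for t > 0.
    """
    if abs(b - a) < _COALESCE_TOL:
        return t * np.exp(-a * t)
    return (np.exp(-a * t) - np.exp(-b * t)) / (b - a)


def _phi3(a: float, b: float, c: float, t: np.ndarray) -> np.ndarray:
    """Second divided difference of exp(-x t) over nodes (a, b, c).

    Impulse response of three first-order stages in series; symmetric in
    its nodes and positive for t > 0.  Nodes are sorted so the outermost
    pair is maximally separated, which keeps the difference quotient
    stable; fully coalescent nodes fall back to the analytic limit
    t^2/2 * exp(-a t).
    """
    lo, mid, hi = sorted((a, b, c))
    if hi - lo < _COALESCE_TOL:
        return 0.5 * t * t * np.exp(-lo * t)
    return (_phi2(lo, mid, t) - _phi2(mid, hi, t)) / (hi - lo)


def _moles(rates: RateConstants, constants: PKConstants,
           initial: InitialState, t: np.ndarray) -> np.ndarray:
    """Molar amounts (mmol) of [gut, caffeine, px, tb, tp] at times t."""
    m_caf = constants.molar_mass["caffeine"]
    n_g0 = constants.absorbed_dose / m_caf  # mg / (g/mol) = mmol
    k1, kap = rates.k1, rates.kappa

    n_gut = n_g0 * np.exp(-k1 * t)
    n_caf = n_g0 * k1 * _phi2(kap, k1, t)

    c0 = initial.as_array()
    out = np.empty((t.size, 5))
    out[:, 0] = n_gut
    out[:, 1] = n_caf
    conv = (rates.k2, rates.k3, rates.k4)
    elim = (rates.k6, rates.k7, rates.k8)
    for i, (kc, ke) in enumerate(zip(conv, elim)):
        sp = SPECIES[i + 1]
        n0 = c0[i + 1] * constants.vd[sp] / (1000.0 * constants.molar_mass[sp])
        out[:, i + 2] = (
            n0 * np.exp(-ke * t) + kc * k1 * n_g0 * _phi3(kap, k1, ke, t)
        )
    return out


def simulate(rates: RateConstants, constants: PKConstants,
             initial: InitialState, times) -> ConcentrationTrajectory:
    """Closed-form body concentrations of the four methylxanthines.

    Returns concentrations in ug/L on the given time grid (hours).  The
    linear cascade is solved exactly: each species is a short sum of
    exponentials expressed through divided differences of ``exp(-x t)``,
    so the evaluation is stable even when rate constants (nearly)
    coincide.
    """
    t = _check_times(times)
    n = _moles(rates, constants, initial, t)
    conc = np.empty((t.size, len(SPECIES)))
    for j, sp in enumerate(SPECIES):
        # mmol * g/mol / L = mg/L -> ug/L
        conc[:, j] = n[:, j + 1] * constants.molar_mass[sp] / constants.vd[sp] * 1000.0
    # clip tiny negative round-off
    np.clip(conc, 0.0, None, out=conc)
    return ConcentrationTrajectory(times=t, conc=conc)


def caffeine_closed_form(rates: RateConstants, constants: PKConstants,
                         t) -> np.ndarray:
    """Bateman solution for the caffeine channel alone (ug/L).

    C(t) = F*D*k1 / (Vd*(k1 - kappa)) * (exp(-kappa t) - exp(-k1 t)),
    with the analytic limit F*D*k1*t*exp(-k1 t)/Vd when k1 == kappa.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise InputError("t must be non-negative")
    fd = constants.absorbed_dose  # mg
    vd = constants.vd["caffeine"]
    return fd * rates.k1 * _phi2(rates.kappa, rates.k1, t) / vd * 1000.0


def predicted_signal(traj: ConcentrationTrajectory,
                     volumes: SweatVolumeSeries) -> np.ndarray:
    """Measured-signal model: signal_i(t_j) = V_sweat(t_j) * C_i(t_j).

    The same sweat volume multiplies all four species at a time-point;
    returned matrix has shape (T, 4) in SPECIES order.
    """
    if volumes.volumes.size != traj.times.size:
        raise InputError(
            "volumes and trajectory must share the same time grid length"
        )
    return volumes.volumes[:, None] * traj.conc


def ode_oracle(rates: RateConstants, constants: PKConstants,
               initial: InitialState, times) -> ConcentrationTrajectory:
    """Numerical integration of the cascade, for cross-checking `simulate`.

    Integrates the molar ODE system with a stiff-capable solver at tight
    tolerance.  Intended as an independent oracle, not for production use.
    """
    from scipy.integrate import solve_ivp

    t = _check_times(times)
    m_caf = constants.molar_mass["caffeine"]
    n_g0 = constants.absorbed_dose / m_caf
    c0 = initial.as_array()
    y0 = [n_g0, 0.0]
    for i, sp in enumerate(SPECIES[1:], start=1):
        y0.append(c0[i] * constants.vd[sp] / (1000.0 * constants.molar_mass[sp]))

    k = rates

    def rhs(_t, y):
        gut, caf, px, tb, tp = y
        return [
            -k.k1 * gut,
            k.k1 * gut - k.kappa * caf,
            k.k2 * caf - k.k6 * px,
            k.k3 * caf - k.k7 * tb,
            k.k4 * caf - k.k8 * tp,
        ]

    t_span = (0.0, max(float(t[-1]), 1e-9))
    # atol far below the smallest molar amounts of interest so that the
    # deep exponential tails are still resolved in relative terms
    sol = solve_ivp(rhs, t_span, y0, t_eval=t, method="DOP853",
                    rtol=1e-12, atol=1e-20)
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    conc = np.empty((t.size, len(SPECIES)))
    for j, sp in enumerate(SPECIES):
        conc[:, j] = sol.y[j + 1] * constants.molar_mass[sp] / constants.vd[sp] * 1000.0
    np.clip(conc, 0.0, None, out=conc)
    return ConcentrationTrajectory(times=t, conc=conc)


def total_moles(rates: RateConstants, constants: PKConstants,
                initial: InitialState, times) -> np.ndarray:
    """Total molar amount gut + four body species over time (mmol).

    Constant in time whenever all eliminations (k5..k8) vanish; used by
    conservation checks.
    """
    t = _check_times(times)
    return _moles(rates, constants, initial, t).sum(axis=1)
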