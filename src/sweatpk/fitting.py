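"""Per-profile estimation of kinetic constants and sweat volumes.

A volunteer profile is a table of internal-standard-normalized signals
for the four methylxanthines at T sampled time-points (with technical
replicates).  The measured signal is modelled as V_sweat(t_j) * C_i(t_j)
where the concentrations follow the first-order network of
:mod:`sweatpk.model` and each time-point's sweat volume is a free
nuisance parameter shared by all metabolites.

Fitting is bounded nonlinear least squares (trust-region reflective)
under a generalized robust loss, restarted from `n_starts` Monte-Carlo
initial points drawn uniformly within the bounds; the lowest-loss
solution is reported.  The full parameter vector is
``[k1..k8, c0_px, c0_tb, c0_tp, V_sweat(t_1)..V_sweat(t_T)]`` — the
number of fitted parameters grows with the number of time-points.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import t as t_dist

from .model import (
    C0_MAX,
    K1_MAX,
    K_MAX,
    SPECIES,
    V_SWEAT_MAX,
    V_SWEAT_MIN,
    DomainError,
    InitialState,
    InputError,
    PKConstants,
    RateConstants,
    SweatVolumeSeries,
    _phi2,
    _phi3,
)

__all__ = [
    "MeasurementTable",
    "FitConfig",
    "FitResult",
    "pack_parameters",
    "unpack_parameters",
    "default_bounds",
    "robust_loss",
    "objective",
    "fit_profile",
    "adjusted_r2",
    "confidence_intervals",
    "gauge_transform",
    "gauge_invariants",
]

N_KINETIC_PARAMS = 11  # 8 rate constants + 3 initial product concentrations


@dataclass
class MeasurementTable:
    """Normalized signals per (time, species, replicate) for one profile.

    ``data`` columns: time_h (float), species (one of SPECIES),
    replicate (identifier), signal (arbitrary units, >= 0), censored
    (bool, below-LOD flag).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        required = {"time_h", "species", "replicate", "signal", "censored"}
        missing = required - set(df.columns)
        if missing:
            raise InputError(f"missing columns: {sorted(missing)}")
        unknown = set(df["species"]) - set(SPECIES)
        if unknown:
            raise InputError(f"unknown species: {sorted(unknown)}")
        sig = df["signal"].to_numpy(dtype=float)
        if not np.all(np.isfinite(sig)) or np.any(sig < 0):
            raise InputError("signals must be finite and >= 0")
        if df["time_h"].nunique() < 2:
            raise InputError("need at least 2 distinct time-points")
        self.data = df.reset_index(drop=True)

    @property
    def times(self) -> np.ndarray:
        """Sorted unique sampling times (h)."""
        return np.sort(self.data["time_h"].unique())

    @property
    def n_timepoints(self) -> int:
        return self.times.size

    def _fit_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(time_index, species_index, signal) over non-censored rows."""
        df = self.data[~self.data["censored"].astype(bool)]
        if df.empty:
            raise InputError("no usable observations (all rows censored)")
        times = self.times
        t_idx = np.searchsorted(times, df["time_h"].to_numpy(dtype=float))
        s_idx = np.array([SPECIES.index(s) for s in df["species"]])
        return t_idx, s_idx, df["signal"].to_numpy(dtype=float)


@dataclass(frozen=True)
class FitConfig:
    """Settings for the multi-start robust fit.

    ``alphas`` is the grid of robust-loss shape parameters searched
    (2 = ordinary least squares, decreasing values are increasingly
    outlier-tolerant); the loss scale ``c`` defaults to the median
    absolute non-censored signal.
    """

    n_starts: int = 100
    rng_seed: int = 0
    tol: float = 1e-8
    alphas: Sequence[float] = (2.0, 1.0, 0.5, 0.0)
    loss_scale: float | None = None
    max_nfev: int | None = None

    def __post_init__(self) -> None:
        if self.n_starts < 1:
            raise DomainError("n_starts must be >= 1")
        if self.loss_scale is not None and self.loss_scale <= 0:
            raise DomainError("loss_scale must be positive")


@dataclass(frozen=True)
class StartRecord:
    """Convergence record of one optimizer start."""

    alpha: float
    index: int
    success: bool
    loss: float
    status: int
    nfev: int


@dataclass
class FitResult:
    """Best solution of the multi-start fit plus diagnostics."""

    rates: RateConstants
    initial: InitialState
    volumes: SweatVolumeSeries
    loss: float
    alpha: float
    loss_scale: float
    adjusted_r2: float
    n_obs: int
    df: int
    seed: int
    x: np.ndarray
    starts: list[StartRecord] = field(default_factory=list)
    ci: dict[str, tuple[float, float]] | None = None

    def parameter_names(self) -> list[str]:
        T = self.volumes.volumes.size
        return (
            [f"k{i}" for i in range(1, 9)]
            + ["c0_paraxanthine", "c0_theobromine", "c0_theophylline"]
            + [f"v_sweat_{j}" for j in range(T)]
        )


def pack_parameters(rates: RateConstants, initial: InitialState,
                    volumes: SweatVolumeSeries) -> np.ndarray:
    """Pack (rates, initial, volumes) into the flat fit vector."""
    return np.concatenate(
        [rates.as_array(), initial.as_array()[1:], volumes.volumes]
    )


def unpack_parameters(
    vector: np.ndarray, n_timepoints: int
) -> tuple[RateConstants, InitialState, SweatVolumeSeries]:
    """Inverse of :func:`pack_parameters`."""
    if n_timepoints < 1:
        raise InputError("n_timepoints must be >= 1")
    x = np.asarray(vector, dtype=float)
    if x.size != N_KINETIC_PARAMS + n_timepoints:
        raise InputError(
            f"expected vector of length {N_KINETIC_PARAMS + n_timepoints}, "
            f"got {x.size}"
        )
    rates = RateConstants(*x[:8])
    initial = InitialState(*x[8:11])
    volumes = SweatVolumeSeries(x[11:])
    return rates, initial, volumes


def default_bounds(n_timepoints: int) -> tuple[np.ndarray, np.ndarray]:
    """(lower, upper) bound arrays for the packed parameter vector."""
    lb = np.concatenate(
        [np.zeros(8), np.zeros(3), np.full(n_timepoints, V_SWEAT_MIN)]
    )
    ub = np.concatenate(
        [[K1_MAX], np.full(7, K_MAX), np.full(3, C0_MAX),
         np.full(n_timepoints, V_SWEAT_MAX)]
    )
    return lb, ub


def robust_loss(residual, alpha: float, scale: float):
    """Generalized robust loss rho(x, alpha, c).

    rho(x) = (|a-2|/a) * [((x/c)^2/|a-2| + 1)^(a/2) - 1] with the
    standard limits: alpha=2 quadratic, alpha=0 Cauchy/log, alpha=-inf
    Welsch.  Even in x, zero at zero, non-decreasing in |x|; smaller
    alpha down-weights large residuals.
    """
    if scale <= 0:
        raise DomainError("scale must be positive")
    x = np.asarray(residual, dtype=float)
    z = (x / scale) ** 2
    if alpha == 2.0:
        return 0.5 * z
    if alpha == 0.0:
        return np.log1p(0.5 * z)
    if alpha == -np.inf:
        return 1.0 - np.exp(-0.5 * z)
    b = abs(alpha - 2.0)
    return (b / alpha) * ((z / b + 1.0) ** (alpha / 2.0) - 1.0)


def _rho_z(alpha: float, scale: float):
    """scipy least_squares loss callable.

    scipy minimizes 0.5 * sum rho_z(f^2); rho_z is chosen so the cost
    equals sum robust_loss(f), and its first two derivatives are
    supplied for the trust-region scaling.
    """
    c2 = scale * scale

    def loss(z):
        out = np.empty((3, z.size))
        if alpha == 2.0:
            out[0] = z / c2
            out[1] = 1.0 / c2
            out[2] = 0.0
        elif alpha == 0.0:
            u = z / (2.0 * c2) + 1.0
            out[0] = 2.0 * np.log(u)
            out[1] = (1.0 / c2) / u
            out[2] = -1.0 / (2.0 * c2 * c2) / (u * u)
        else:
            b = abs(alpha - 2.0)
            u = z / (b * c2) + 1.0
            out[0] = 2.0 * (b / alpha) * (u ** (alpha / 2.0) - 1.0)
            out[1] = u ** (alpha / 2.0 - 1.0) / c2
            out[2] = (alpha / 2.0 - 1.0) * u ** (alpha / 2.0 - 2.0) / (b * c2 * c2)
        return out

    return loss


def _concentrations(x: np.ndarray, times: np.ndarray,
                    constants: PKConstants) -> np.ndarray:
    """Fast closed-form concentrations (T, 4) from a packed vector.

    Mirrors :func:`sweatpk.model.simulate` without dataclass overhead;
    used inside the optimizer's residual callback.
    """
    k1 = x[0]
    kap = x[1] + x[2] + x[3] + x[4]
    m_caf = constants.molar_mass["caffeine"]
    n_g0 = constants.absorbed_dose / m_caf
    conc = np.empty((times.size, 4))
    conc[:, 0] = n_g0 * k1 * _phi2(kap, k1, times) * m_caf \
        / constants.vd["caffeine"] * 1000.0
    for i, sp in enumerate(SPECIES[1:]):
        kc, ke = x[1 + i], x[5 + i]
        m, vd = constants.molar_mass[sp], constants.vd[sp]
        n0 = x[8 + i] * vd / (1000.0 * m)
        n = n0 * np.exp(-ke * times) + kc * k1 * n_g0 * _phi3(kap, k1, ke, times)
        conc[:, i + 1] = n * m / vd * 1000.0
    return conc


def _residuals(x: np.ndarray, times: np.ndarray, t_idx: np.ndarray,
               s_idx: np.ndarray, signal: np.ndarray,
               constants: PKConstants) -> np.ndarray:
    conc = _concentrations(x, times, constants)
    volumes = x[N_KINETIC_PARAMS:]
    return volumes[t_idx] * conc[t_idx, s_idx] - signal


def objective(vector: np.ndarray, table: MeasurementTable,
              constants: PKConstants, alpha: float = 2.0,
              scale: float | None = None
              ) -> tuple[float, np.ndarray]:
    """Total robust loss and residual vector at a parameter vector.

    Residuals r = V_sweat(t_j)*C_i(t_j) - signal over every non-censored
    row; replicates enter individually.  Returns (sum rho(r), r).
    """
    times = table.times
    x = np.asarray(vector, dtype=float)
    if x.size != N_KINETIC_PARAMS + times.size:
        raise InputError("parameter vector length does not match table")
    t_idx, s_idx, signal = table._fit_arrays()
    if scale is None:
        scale = _default_scale(signal)
    r = _residuals(x, times, t_idx, s_idx, signal, constants)
    return float(np.sum(robust_loss(r, alpha, scale))), r


def _default_scale(signal: np.ndarray) -> float:
    s = float(np.median(np.abs(signal)))
    return s if s > 0 else 1.0


def adjusted_r2(observed, fitted, n_params: int) -> float:
    """R^2 against the observed mean, penalized for model size:
    1 - (1 - R^2) * (n - 1) / (n - n_params - 1)."""
    obs = np.asarray(observed, dtype=float)
    fit = np.asarray(fitted, dtype=float)
    if obs.shape != fit.shape:
        raise InputError("observed and fitted must have the same shape")
    n = obs.size
    if n <= n_params + 1:
        raise InputError("insufficient degrees of freedom for adjusted R^2")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    ss_res = float(np.sum((obs - fit) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0 - ss_res
    return 1.0 - (1.0 - r2) * (n - 1) / (n - n_params - 1)


def fit_profile(table: MeasurementTable, constants: PKConstants,
                config: FitConfig = FitConfig()) -> FitResult:
    """Multi-start bounded robust least squares for one volunteer profile.

    For each of ``config.n_starts`` seeded Monte-Carlo draws the packed
    parameter vector is initialized uniformly within bounds and refined
    with the trust-region-reflective solver; within each robust-loss
    shape ``alpha`` the lowest-loss start wins, and across the alpha
    grid the solution with the highest adjusted R^2 is reported (robust
    losses at different alpha are not on a common scale).  Deterministic
    given ``config.rng_seed``.
    """
    times = table.times
    T = times.size
    t_idx, s_idx, signal = table._fit_arrays()
    n_obs = signal.size
    n_params = N_KINETIC_PARAMS + T
    lb, ub = default_bounds(T)
    scale = config.loss_scale if config.loss_scale is not None \
        else _default_scale(signal)

    # one master seed; per-start substreams so a longer run extends a
    # shorter one (prefix property) and starts are shared across alphas
    children = np.random.SeedSequence(config.rng_seed).spawn(config.n_starts)
    x0s = [np.random.default_rng(c).uniform(lb, ub) for c in children]

    def fun(x):
        return _residuals(x, times, t_idx, s_idx, signal, constants)

    records: list[StartRecord] = []
    best_per_alpha: dict[float, tuple[float, np.ndarray]] = {}
    for alpha in config.alphas:
        loss_cb = _rho_z(alpha, scale)
        best_loss, best_x = np.inf, None
        for i, x0 in enumerate(x0s):
            try:
                res = least_squares(
                    fun, x0, bounds=(lb, ub), method="trf", loss=loss_cb,
                    xtol=config.tol, ftol=config.tol, gtol=config.tol,
                    max_nfev=config.max_nfev,
                )
                loss_val = float(np.sum(robust_loss(res.fun, alpha, scale)))
                ok = bool(res.success) and np.isfinite(loss_val)
                records.append(StartRecord(alpha, i, ok, loss_val,
                                           int(res.status), int(res.nfev)))
            except Exception:  # non-finite loss / solver breakdown
                records.append(StartRecord(alpha, i, False, np.inf, -1, 0))
                continue
            if ok and loss_val < best_loss:
                best_loss, best_x = loss_val, res.x
        if best_x is not None:
            best_per_alpha[alpha] = (best_loss, best_x)

    if not best_per_alpha:
        raise RuntimeError(
            "all optimizer starts failed; per-start log: "
            + "; ".join(f"alpha={r.alpha} start={r.index} status={r.status}"
                        for r in records)
        )

    # cross-alpha selection by adjusted R^2 (losses are not commensurable)
    best_alpha, best_adj, chosen = None, -np.inf, None
    for alpha, (loss_val, x) in best_per_alpha.items():
        fitted = signal + _residuals(x, times, t_idx, s_idx, signal, constants)
        adj = adjusted_r2(signal, fitted, n_params)
        if adj > best_adj:
            best_alpha, best_adj, chosen = alpha, adj, (loss_val, x)

    loss_val, x = chosen
    x = np.clip(x, lb, ub)  # guard round-off at active bounds
    rates, initial, volumes = unpack_parameters(x, T)
    return FitResult(
        rates=rates, initial=initial, volumes=volumes,
        loss=loss_val, alpha=best_alpha, loss_scale=scale,
        adjusted_r2=best_adj, n_obs=n_obs, df=n_obs - n_params,
        seed=config.rng_seed, x=x, starts=records,
    )


def gauge_transform(vector: np.ndarray, times: np.ndarray,
                    delta: float) -> np.ndarray:
    """The model's exact structural-degeneracy direction.

    Because every sampled time-point carries a free sweat volume, the
    predicted signals are invariant under the one-parameter family

        k1, k5, k6, k7, k8  ->  + delta
        c0                  ->  c0 * (k1 + delta) / k1
        V_sweat(t_j)        ->  V_sweat(t_j) * k1/(k1+delta) * e^(delta t_j)

    (the volumes absorb the common exponential factor e^(-delta t) that
    the rate shift imprints on every concentration).  Hence k1, k5-k8
    and the volume series are identified only up to this family, while
    k2, k3, k4 and rate differences such as k6 - k5 are identifiable.
    Raises if the transformed vector leaves the model bounds.
    """
    x = np.asarray(vector, dtype=float).copy()
    t = np.asarray(times, dtype=float)
    k1 = x[0]
    x[0] += delta
    x[4:8] += delta
    x[8:11] *= x[0] / k1
    x[N_KINETIC_PARAMS:] *= (k1 / x[0]) * np.exp(delta * t)
    T = t.size
    unpack_parameters(x, T)  # bounds check
    return x


def gauge_invariants(rates: RateConstants) -> dict[str, float]:
    """Rate combinations unaffected by :func:`gauge_transform`."""
    return {
        "k2": rates.k2,
        "k3": rates.k3,
        "k4": rates.k4,
        "k6_minus_k5": rates.k6 - rates.k5,
        "k7_minus_k5": rates.k7 - rates.k5,
        "k8_minus_k5": rates.k8 - rates.k5,
        "k1_minus_kappa": rates.k1 - rates.kappa,
    }


def confidence_intervals(result: FitResult, cv_table: dict[str, float],
                         df: int | None = None
                         ) -> dict[str, tuple[float, float]]:
    """95% confidence intervals estimate +/- t(0.975, df) * CV * estimate.

    ``cv_table`` maps parameter names (see
    :meth:`FitResult.parameter_names`) to coefficients of variation of
    the fitting procedure; ``df`` defaults to the residual degrees of
    freedom recorded in the fit.
    """
    if df is None:
        df = result.df
    if df < 1:
        raise DomainError("df must be >= 1")
    names = result.parameter_names()
    missing = [n for n in names if n not in cv_table]
    if missing:
        raise InputError(f"missing CV for parameters: {missing}")
    bad = [n for n in names if cv_table[n] < 0]
    if bad:
        raise DomainError(f"negative CV for parameters: {bad}")
    q = float(t_dist.ppf(0.975, df))
    ci: dict[str, tuple[float, float]] = {}
    for name, est in zip(names, result.x):
        half = q * cv_table[name] * abs(est)
        ci[name] = (est - half, est + half)
    result.ci = ci
    return ci
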