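"""Two-compartment reaction model of a kinase-activity relocation sensor.

The sensor exists in four pools: unphosphorylated and phosphorylated, each
in the nucleus and in the cytoplasm.  The kinase (a MAPK, characterised by
its *activity* — the fraction of the kinase pool in the active state, in
[0, 1]) phosphorylates the sensor in both compartments with the same rate
constant; a constitutive phosphatase reverses the modification.  The sensor
exchanges passively between the compartments (flux proportional to the
concentration difference, both species), while only the unphosphorylated
sensor is actively imported into the nucleus.  High kinase activity
therefore shifts the sensor towards the phosphorylated, import-incompetent
form and lowers the nuclear-to-cytoplasmic concentration ratio.

Writing amounts ``Un, Pn, Uc, Pc`` (nuclear/cytoplasmic, un-/phosphorylated)
with nuclear volume 1 and cytoplasmic volume ``vol_ratio``, the model is the
linear system::

    dUn/dt = -k_phos*A*Un + k_dephos*Pn + k_imp*Uc/Vc + k_diff*(Uc/Vc - Un)
    dPn/dt = +k_phos*A*Un - k_dephos*Pn             + k_diff*(Pc/Vc - Pn)
    dUc/dt = -k_phos*A*Uc + k_dephos*Pc - k_imp*Uc/Vc - k_diff*(Uc/Vc - Un)
    dPc/dt = +k_phos*A*Uc - k_dephos*Pc             - k_diff*(Pc/Vc - Pn)

Transport fluxes act on concentrations, so the activity-0 fixed point has
the closed form ratio ``1 + k_imp/k_diff`` for any volume ratio, and total
sensor is conserved exactly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.interpolate import PchipInterpolator
from scipy.optimize import least_squares

logger = logging.getLogger(__name__)

__all__ = [
    "SensorModelParams",
    "ActivityProfile",
    "CalibrationCurve",
    "FitResult",
    "InvalidParameterError",
    "SimulationError",
    "CalibrationError",
    "FitError",
    "steady_state",
    "steady_state_ratio",
    "simulate_relocation",
    "build_calibration",
    "infer_activity_steady",
    "fit_activity_timecourse",
]


class InvalidParameterError(ValueError):
    """Model parameters are non-finite, negative or otherwise invalid."""


class SimulationError(RuntimeError):
    """The ODE integrator failed; the message carries its diagnostic."""


class CalibrationError(RuntimeError):
    """The computed activity→ratio curve is not invertible."""


class FitError(RuntimeError):
    """Profile fitting did not converge.

    Attributes
    ----------
    best_profile : ActivityProfile
        Best parameters found before failure.
    """

    def __init__(self, message: str, best_profile: "ActivityProfile | None" = None):
        super().__init__(message)
        self.best_profile = best_profile


@dataclass(frozen=True)
class SensorModelParams:
    """Rate constants and geometry of the relocation-sensor model.

    Parameters
    ----------
    k_phos : float
        Sensor phosphorylation rate at full kinase activity (1/min); the
        effective rate is ``k_phos * activity``.
    k_dephos : float
        Constitutive dephosphorylation rate (1/min).
    k_imp : float
        Active nuclear import rate of the unphosphorylated sensor (1/min,
        acting on the cytoplasmic concentration).
    k_diff : float
        Passive nucleus/cytoplasm exchange rate (1/min, acting on the
        concentration difference; both species, both directions).
    vol_ratio : float
        Cytoplasm-to-nucleus volume ratio (dimensionless, > 0).
    total_sensor : float
        Total sensor amount (arbitrary units, > 0); conserved.

    The defaults give a basal (activity 0) nuclear enrichment of
    ``1 + k_imp/k_diff = 3`` and relocation/recovery kinetics on the scale
    of a few minutes, matching the reporter's observed behaviour.
    """

    k_phos: float = 2.0
    k_dephos: float = 0.5
    k_imp: float = 1.0
    k_diff: float = 0.5
    vol_ratio: float = 7.0
    total_sensor: float = 1.0

    def __post_init__(self) -> None:
        rates = {
            "k_phos": self.k_phos,
            "k_dephos": self.k_dephos,
            "k_imp": self.k_imp,
            "k_diff": self.k_diff,
        }
        for name, value in rates.items():
            if not math.isfinite(value) or value < 0:
                raise InvalidParameterError(f"{name} must be finite and >= 0, got {value!r}")
        if not math.isfinite(self.vol_ratio) or self.vol_ratio <= 0:
            raise InvalidParameterError(f"vol_ratio must be finite and > 0, got {self.vol_ratio!r}")
        if not math.isfinite(self.total_sensor) or self.total_sensor <= 0:
            raise InvalidParameterError(
                f"total_sensor must be finite and > 0, got {self.total_sensor!r}"
            )

    def to_dict(self) -> dict[str, float]:
        return {
            "k_phos": self.k_phos,
            "k_dephos": self.k_dephos,
            "k_imp": self.k_imp,
            "k_diff": self.k_diff,
            "vol_ratio": self.vol_ratio,
            "total_sensor": self.total_sensor,
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "SensorModelParams":
        return cls(**{k: float(v) for k, v in d.items()})


@dataclass(frozen=True)
class ActivityProfile:
    """Parametric kinase activity as a function of time.

    ``A(t) = A0`` for ``t < t_on``; afterwards the activity rises
    exponentially from the baseline ``A0`` towards the plateau ``Amax`` with
    timescale ``tau_rise`` (minutes).  If ``tau_decay`` is set, the rise is
    multiplied by ``exp(-(t - t_on)/tau_decay)`` so the activity returns to
    baseline — a transient activation.  Values are clipped to [0, 1]: the
    activity is the fraction of the kinase pool in the active state.
    """

    a0: float = 0.0
    amax: float = 1.0
    t_on: float = 0.0
    tau_rise: float = 1.0
    tau_decay: float | None = None
    form: str = field(default="exp-rise", repr=False)

    def __post_init__(self) -> None:
        for name, value in (("a0", self.a0), ("amax", self.amax)):
            if not math.isfinite(value) or not 0.0 <= value <= 1.0:
                raise InvalidParameterError(f"{name} must lie in [0, 1], got {value!r}")
        if not math.isfinite(self.tau_rise) or self.tau_rise <= 0:
            raise InvalidParameterError(f"tau_rise must be > 0, got {self.tau_rise!r}")
        if self.tau_decay is not None and (not math.isfinite(self.tau_decay) or self.tau_decay <= 0):
            raise InvalidParameterError(f"tau_decay must be > 0, got {self.tau_decay!r}")

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        s = t - self.t_on
        rise = np.where(s > 0, -np.expm1(-np.maximum(s, 0.0) / self.tau_rise), 0.0)
        if self.tau_decay is not None:
            rise = rise * np.where(s > 0, np.exp(-np.maximum(s, 0.0) / self.tau_decay), 1.0)
        a = self.a0 + (self.amax - self.a0) * rise
        return np.clip(a, 0.0, 1.0)

    def to_dict(self) -> dict:
        d = {
            "form": self.form,
            "a0": float(self.a0),
            "amax": float(self.amax),
            "t_on": float(self.t_on),
            "tau_rise": float(self.tau_rise),
        }
        if self.tau_decay is not None:
            d["tau_decay"] = float(self.tau_decay)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ActivityProfile":
        d = dict(d)
        form = d.pop("form", "exp-rise")
        return cls(form=form, **{k: (float(v) if v is not None else None) for k, v in d.items()})


def _rate_matrix(params: SensorModelParams, activity: float) -> np.ndarray:
    """Linear generator of the amount vector [Un, Pn, Uc, Pc]."""
    kp = params.k_phos * activity
    kd = params.k_dephos
    ki = params.k_imp
    kx = params.k_diff
    vc = params.vol_ratio
    # transport coefficients act on concentrations: amount/volume
    return np.array(
        [
            [-kp - kx, kd, (ki + kx) / vc, 0.0],
            [kp, -kd - kx, 0.0, kx / vc],
            [kx, 0.0, -kp - (ki + kx) / vc, kd],
            [0.0, kx, kp, -kd - kx / vc],
        ]
    )


def steady_state(params: SensorModelParams, activity: float) -> np.ndarray:
    """Amounts [Un, Pn, Uc, Pc] at the unique fixed point for a constant activity.

    Solves the linear system ``M(A) x = 0`` under the conservation
    constraint ``sum(x) = total_sensor``.
    """
    _check_activity(activity)
    m = _rate_matrix(params, activity)
    a = np.vstack([m[:3], np.ones(4)])
    b = np.array([0.0, 0.0, 0.0, params.total_sensor])
    x = np.linalg.solve(a, b)
    if np.any(x < -1e-9 * params.total_sensor):
        raise InvalidParameterError(f"negative steady-state amounts for params {params!r}")
    return np.clip(x, 0.0, None)


def steady_state_ratio(params: SensorModelParams, activity: float) -> float:
    """Nuclear:cytoplasmic concentration ratio at the fixed point.

    Equals ``1 + k_imp/k_diff`` at activity 0 and 1 everywhere when
    ``k_imp = 0`` (pure diffusion equalizes concentrations).
    """
    un, pn, uc, pc = steady_state(params, activity)
    c_nuc = un + pn  # nuclear volume is 1
    c_cyt = (uc + pc) / params.vol_ratio
    if c_cyt <= 0:
        raise InvalidParameterError("degenerate steady state: empty cytoplasm")
    return float(c_nuc / c_cyt)


def _check_activity(activity: float) -> None:
    if not math.isfinite(activity) or not 0.0 <= activity <= 1.0:
        raise InvalidParameterError(f"activity must lie in [0, 1], got {activity!r}")


def _amounts_to_ratio(x: np.ndarray, vol_ratio: float) -> np.ndarray:
    c_nuc = x[0] + x[1]
    c_cyt = (x[2] + x[3]) / vol_ratio
    return c_nuc / c_cyt


def simulate_relocation(
    params: SensorModelParams,
    profile: ActivityProfile,
    times: Sequence[float],
    initial: np.ndarray | str = "steady-state-at-A0",
    rtol: float = 1e-8,
    atol: float | None = None,
    return_states: bool = False,
):
    """Integrate the model under a time-varying activity profile.

    Parameters
    ----------
    times : array of minutes, strictly increasing, length >= 2.
    initial : four non-negative amounts, or ``"steady-state-at-A0"`` to
        start from the fixed point of the profile's baseline activity.

    Returns
    -------
    ratios : ndarray matching ``times`` — nuclear:cytoplasmic concentration
        ratio along the trajectory.  With ``return_states=True``, also the
        (4, n_times) amount trajectory.
    """
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size < 2 or np.any(np.diff(t) <= 0):
        raise ValueError("times must be a strictly increasing 1-D array of length >= 2")
    if isinstance(initial, str):
        if initial != "steady-state-at-A0":
            raise ValueError(f"unknown initial condition {initial!r}")
        x0 = steady_state(params, float(profile(t[0])))
    else:
        x0 = np.asarray(initial, dtype=float)
        if x0.shape != (4,) or np.any(x0 < 0) or not np.all(np.isfinite(x0)):
            raise ValueError("initial state must be four finite non-negative amounts")
    if atol is None:
        atol = 1e-10 * params.total_sensor

    def rhs(ti, x):
        return _rate_matrix(params, float(profile(ti))) @ x

    def jac(ti, x):
        return _rate_matrix(params, float(profile(ti)))

    sol = solve_ivp(
        rhs, (t[0], t[-1]), x0, t_eval=t, method="LSODA", jac=jac, rtol=rtol, atol=atol
    )
    if not sol.success:
        raise SimulationError(f"ODE integration failed: {sol.message}")
    ratios = _amounts_to_ratio(sol.y, params.vol_ratio)
    if return_states:
        return ratios, sol.y
    return ratios


@dataclass(frozen=True)
class CalibrationCurve:
    """Monotone steady-state activity→ratio map and its inverse.

    ``activities`` ascending in [0, 1]; ``ratios`` strictly decreasing.
    Inversion uses a monotone (PCHIP) interpolant of activity against
    ratio, so the round trip activity → ratio → activity is the identity
    on the grid and monotone between grid points.
    """

    activities: np.ndarray
    ratios: np.ndarray
    _inverse: PchipInterpolator = field(repr=False, compare=False)

    @property
    def ratio_range(self) -> tuple[float, float]:
        return float(self.ratios[-1]), float(self.ratios[0])


def build_calibration(
    params: SensorModelParams, activity_grid: Sequence[float] | None = None
) -> CalibrationCurve:
    """Tabulate the steady-state ratio on an activity grid covering [0, 1].

    Raises :class:`CalibrationError` when the computed curve is not
    strictly decreasing (degenerate parameters, e.g. ``k_imp = 0``), since
    it is then not invertible.
    """
    if activity_grid is None:
        activity_grid = np.linspace(0.0, 1.0, 21)
    grid = np.asarray(activity_grid, dtype=float)
    if grid.ndim != 1 or grid.size < 11:
        raise ValueError("activity grid must be 1-D with at least 11 points")
    if np.any(np.diff(grid) <= 0) or grid[0] > 1e-12 or grid[-1] < 1 - 1e-12:
        raise ValueError("activity grid must be strictly increasing and cover [0, 1]")
    ratios = np.array([steady_state_ratio(params, a) for a in grid])
    if np.any(np.diff(ratios) >= 0):
        raise CalibrationError(
            "steady-state ratio is not strictly decreasing in activity; "
            "the calibration curve is not invertible (check k_imp and k_phos > 0)"
        )
    # PCHIP needs ascending x: invert on (ratio ascending, activity descending)
    inverse = PchipInterpolator(ratios[::-1], grid[::-1], extrapolate=False)
    return CalibrationCurve(activities=grid, ratios=ratios, _inverse=inverse)


def infer_activity_steady(ratio, curve: CalibrationCurve):
    """Invert measured ratio(s) to kinase activity via the calibration curve.

    Ratios outside the curve's range (possible for noisy measurements) are
    clipped: above the basal ratio maps to activity 0, below the
    full-activity ratio maps to 1; clipping is logged, not raised.
    """
    r = np.asarray(ratio, dtype=float)
    if not np.all(np.isfinite(r)):
        raise ValueError("ratio must be finite")
    lo, hi = curve.ratio_range
    n_clip = int(np.sum((r < lo) | (r > hi)))
    if n_clip:
        logger.warning(
            "%d ratio value(s) outside the calibration range [%.4g, %.4g]; clipped", n_clip, lo, hi
        )
    a = curve._inverse(np.clip(r, lo, hi))
    a = np.clip(a, 0.0, 1.0)
    return float(a) if np.isscalar(ratio) or np.ndim(ratio) == 0 else a


@dataclass(frozen=True)
class FitResult:
    """Outcome of an activity-profile fit to a measured ratio trace."""

    profile: ActivityProfile
    residual_norm: float
    converged: bool
    n_starts: int


# deterministic multi-start list (a0, amax, tau_rise) to avoid local minima
_FIT_STARTS = ((0.1, 0.9, 1.0), (0.3, 0.6, 3.0), (0.05, 0.99, 8.0))


def fit_activity_timecourse(
    times: Sequence[float],
    ratios: Sequence[float],
    params: SensorModelParams,
    t_on: float = 0.0,
    fit_decay: bool = False,
) -> FitResult:
    """Fit an activity profile to a measured nuclear:cytoplasmic ratio trace.

    The sensor's rate constants are fixed; only the profile parameters
    (baseline ``a0``, plateau ``amax``, rise timescale ``tau_rise`` and,
    with ``fit_decay``, ``tau_decay``) are optimized by bounded least
    squares from three fixed starting points, minimizing the sum of squared
    differences between the simulated and measured ratios.  Deterministic.

    Raises :class:`FitError` (carrying the best-so-far profile) when no
    start converges.
    """
    t = np.asarray(times, dtype=float)
    r = np.asarray(ratios, dtype=float)
    if t.size != r.size or t.size < 5:
        raise ValueError("need matching times/ratios with at least 5 points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")

    def make_profile(theta) -> ActivityProfile:
        a0, amax, tau = theta[:3]
        decay = theta[3] if fit_decay else None
        return ActivityProfile(a0=a0, amax=amax, t_on=t_on, tau_rise=tau, tau_decay=decay)

    def residuals(theta):
        return simulate_relocation(params, make_profile(theta), t) - r

    lb = [0.0, 0.0, 0.05] + ([0.5] if fit_decay else [])
    ub = [1.0, 1.0, 100.0] + ([500.0] if fit_decay else [])
    best = None
    any_ok = False
    for start in _FIT_STARTS:
        x0 = list(start) + ([20.0] if fit_decay else [])
        try:
            res = least_squares(residuals, x0, bounds=(lb, ub), method="trf", xtol=1e-10)
        except SimulationError:
            continue
        if best is None or res.cost < best.cost:
            best = res
        any_ok = any_ok or res.success
    if best is None:
        raise FitError("all fit starts failed during simulation")
    profile = make_profile(best.x)
    result = FitResult(
        profile=profile,
        residual_norm=float(np.sqrt(2.0 * best.cost)),
        converged=bool(any_ok),
        n_starts=len(_FIT_STARTS),
    )
    if not any_ok:
        raise FitError("optimizer did not converge from any start", best_profile=profile)
    return result


def fast_exchange_ratio(params: SensorModelParams, activity: float) -> float:
    """Closed-form ratio in the fast-exchange limit.

    When transport is fast relative to (de)phosphorylation — and import is
    weak relative to diffusion, so the phospho-state distribution stays
    spatially uniform — the unphosphorylated fraction is
    ``f_u = k_dephos / (k_phos*A + k_dephos)`` and the ratio is
    ``1 + (k_imp/k_diff) * f_u``.  Exact at activity 0 and whenever
    ``k_imp = 0`` for any rates.
    """
    _check_activity(activity)
    if params.k_diff == 0:
        raise InvalidParameterError("fast-exchange limit requires k_diff > 0")
    denom = params.k_phos * activity + params.k_dephos
    f_u = 1.0 if denom == 0 else params.k_dephos / denom
    return 1.0 + (params.k_imp / params.k_diff) * f_u


def rescale_params(params: SensorModelParams, **overrides) -> SensorModelParams:
    """Return a copy of ``params`` with the given fields replaced."""
    return replace(params, **overrides)
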