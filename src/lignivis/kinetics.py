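"""Second-order kinetics of lignin methylolation.

The methylolation of lignosulphonate (LS) with formaldehyde (F) is modelled
as a second-order reaction between free formaldehyde and the reactive part of
the type I+II phenolic hydroxyl pool (POH):

    -d[F]/dt = k1 * [POH]_r * [F] + k2 * [F]**2
    -d[POH]_r/dt = k1 * [POH]_r * [F]

where ``[POH]_r`` is the reactive phenolic pool.  Only a fraction of the
phenolic groups is available to react; the remainder (blocked ring positions,
mostly syringyl units in hardwood lignin) is treated as chemically inert, so
the observable total is ``[POH] = [POH]_r + f_nonreactive * [POH]_0``.  The
``k2 * [F]**2`` term lumps formaldehyde-only side reactions (Cannizzaro-type
self-disproportionation); it is zero for samples where formaldehyde and
phenolic consumption balance.

Units are mol/L and hours throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

__all__ = [
    "KineticParams",
    "InitialConditions",
    "ReactionTrajectory",
    "OfflineSeries",
    "FitResult",
    "reactive_pool",
    "simulate_trajectory",
    "extent",
    "fit_kinetics",
]

# Integrator tolerances for the coupled system (k2 > 0).  The closed form is
# used whenever k2 == 0, so the ODE path only ever sees the mildly nonlinear
# two-equation system.
_ODE_RTOL = 1e-8
_ODE_ATOL = 1e-9

# Threshold below which F0 and the reactive pool are treated as equal and the
# equal-concentration closed form 1/(b-x) - 1/b = k*t is used.
_EQUAL_CONC_TOL = 1e-12


@dataclass(frozen=True)
class KineticParams:
    """Rate constants and non-reactive phenolic fraction at one temperature.

    Parameters
    ----------
    k1 : float
        Methylolation rate constant, L mol^-1 h^-1.  Must be positive
        (use a very small value to emulate a frozen reaction; exactly 0 is
        accepted for degenerate-data tests).
    k2 : float
        Rate constant of the formaldehyde-consuming secondary reaction,
        L mol^-1 h^-1.  0 when no secondary reaction is modelled.
    f_nonreactive : float
        Fraction (0-1) of the initial phenolic pool that never reacts.
    temperature_C : float, optional
        Reaction temperature in degrees Celsius.  Metadata only: no
        Arrhenius relation is modelled.
    """

    k1: float
    k2: float = 0.0
    f_nonreactive: float = 0.0
    temperature_C: float | None = None

    def __post_init__(self) -> None:
        for name in ("k1", "k2", "f_nonreactive"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if self.k1 < 0:
            raise ValueError(f"k1 must be >= 0, got {self.k1}")
        if self.k2 < 0:
            raise ValueError(f"k2 must be >= 0, got {self.k2}")
        if not 0.0 <= self.f_nonreactive < 1.0:
            raise ValueError(
                f"f_nonreactive must lie in [0, 1), got {self.f_nonreactive}"
            )

    def to_dict(self) -> dict:
        return {
            "k1": self.k1,
            "k2": self.k2,
            "f_nonreactive": self.f_nonreactive,
            "temperature_C": self.temperature_C,
        }


@dataclass(frozen=True)
class InitialConditions:
    """Initial formaldehyde and total type I+II phenolic concentrations, mol/L."""

    F0: float
    POH0: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.F0) and self.F0 > 0):
            raise ValueError(f"F0 must be positive and finite, got {self.F0}")
        if not (math.isfinite(self.POH0) and self.POH0 > 0):
            raise ValueError(f"POH0 must be positive and finite, got {self.POH0}")


@dataclass(frozen=True)
class ReactionTrajectory:
    """Simulated time courses of [F], total [POH] and the reaction extent x.

    ``POH`` is the observable total: reactive pool remaining plus the constant
    non-reactive remainder.  ``x`` is the extent of the main reaction in
    mol/L, i.e. formaldehyde consumed by methylolation (excluding the
    secondary reaction).
    """

    times: np.ndarray
    F: np.ndarray
    POH: np.ndarray
    x: np.ndarray
    params: KineticParams
    init: InitialConditions

    def __post_init__(self) -> None:
        n = len(self.times)
        if not (len(self.F) == len(self.POH) == len(self.x) == n):
            raise ValueError("trajectory arrays must share one length")

    def poh_at(self, t: np.ndarray | float) -> np.ndarray:
        """Total [POH] linearly interpolated at arbitrary times (h)."""
        return np.interp(np.asarray(t, dtype=float), self.times, self.POH)

    def f_at(self, t: np.ndarray | float) -> np.ndarray:
        """[F] linearly interpolated at arbitrary times (h)."""
        return np.interp(np.asarray(t, dtype=float), self.times, self.F)


@dataclass(frozen=True)
class OfflineSeries:
    """Hourly off-line assay series: free formaldehyde and phenolic OH, mol/L.

    NaN marks a missing measurement; a time point may carry either or both
    assays.
    """

    times: np.ndarray
    F: np.ndarray
    POH: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.times) == len(self.F) == len(self.POH)):
            raise ValueError("offline series arrays must share one length")


@dataclass
class FitResult:
    """Fitted kinetic parameters plus goodness-of-fit diagnostics."""

    params: KineticParams
    sse: float
    residuals: np.ndarray
    n_points: int
    converged: bool
    degenerate: bool = False
    message: str = ""

    def to_dict(self) -> dict:
        d = self.params.to_dict()
        d.update(sse=self.sse, n_points=self.n_points, converged=self.converged)
        return d


def reactive_pool(POH0: float, f_nonreactive: float) -> float:
    """Initial reactive phenolic concentration, mol/L.

    The reactive pool is the part of the initial type I+II phenolic hydroxyl
    concentration available to formaldehyde: ``POH0 * (1 - f_nonreactive)``.
    """
    if not (math.isfinite(POH0) and POH0 > 0):
        raise ValueError(f"POH0 must be positive and finite, got {POH0}")
    if not (math.isfinite(f_nonreactive) and 0.0 <= f_nonreactive < 1.0):
        raise ValueError(
            f"f_nonreactive must lie in [0, 1), got {f_nonreactive}"
        )
    return POH0 * (1.0 - f_nonreactive)


def _extent_closed_form(
    t: np.ndarray, k1: float, a: float, b: float
) -> np.ndarray:
    """Extent x(t) of A + B -> C with rate k1*(a-x)*(b-x), x(0)=0.

    ``a`` is F0, ``b`` the reactive phenolic pool.  Uses the standard
    unequal-concentration logarithmic solution, falling back to the
    equal-concentration hyperbolic form ``1/(b-x) - 1/b = k1*t`` when
    a and b coincide.
    """
    t = np.asarray(t, dtype=float)
    if abs(a - b) <= _EQUAL_CONC_TOL * max(a, b):
        return b * b * k1 * t / (1.0 + b * k1 * t)
    # x = a*b*(E - 1)/(a*E - b) with E = exp((a-b)*k1*t); rewritten with
    # expm1 and exp(-(a-b)k1 t) on the growing branch for large-t stability.
    s = (a - b) * k1 * t
    with np.errstate(over="ignore"):
        em1 = np.expm1(s)
        x = a * b * em1 / (a * em1 + (a - b))
    # limit as s -> +/- inf: min(a, b)
    x = np.where(np.isfinite(x), x, min(a, b))
    return x


def simulate_trajectory(
    params: KineticParams,
    init: InitialConditions,
    times: np.ndarray,
) -> ReactionTrajectory:
    """Simulate [F](t), total [POH](t) and extent x(t) on the given time grid.

    When ``k2 == 0`` the closed-form second-order solution is used; when
    ``k2 > 0`` the coupled system

        dF/dt = -k1 * P * F - k2 * F**2,   dP/dt = -k1 * P * F

    (P the reactive pool) is integrated with an adaptive Runge-Kutta scheme
    (rtol 1e-8, atol 1e-9).  The reported POH adds back the constant
    non-reactive remainder.

    Raises
    ------
    ValueError
        If times are not sorted starting at 0, or parameters are not finite.
    RuntimeError
        If the ODE integration fails.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or len(times) == 0:
        raise ValueError("times must be a non-empty 1-D array")
    if times[0] != 0.0:
        raise ValueError(f"times must start at 0, got {times[0]}")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")

    a = init.F0
    b = reactive_pool(init.POH0, params.f_nonreactive)
    inert = init.POH0 - b

    if params.k2 == 0.0:
        x = _extent_closed_form(times, params.k1, a, b)
        F = a - x
        P = b - x
    else:
        def rhs(_t: float, y: np.ndarray) -> list[float]:
            f, p = y
            main = params.k1 * p * f
            return [-main - params.k2 * f * f, -main]

        sol = solve_ivp(
            rhs,
            (times[0], times[-1]),
            [a, b],
            t_eval=times,
            method="LSODA",
            rtol=_ODE_RTOL,
            atol=_ODE_ATOL,
        )
        if not sol.success:
            raise RuntimeError(f"kinetics integration failed: {sol.message}")
        F, P = sol.y
        # exact solutions stay non-negative; excursions beyond the integrator
        # tolerance indicate step-size failure
        if np.any(F < -1e-6) or np.any(P < -1e-6):
            raise RuntimeError("integrator produced negative concentrations")
        F = np.clip(F, 0.0, None)
        P = np.clip(P, 0.0, None)
        # t = 0 is the initial condition, not an integrator output
        F[0], P[0] = a, b
        x = b - P

    return ReactionTrajectory(
        times=times, F=F, POH=P + inert, x=x, params=params, init=init
    )


def extent(trajectory: ReactionTrajectory, init: InitialConditions) -> np.ndarray:
    """Formaldehyde-side reaction extent ``F0 - F(t)`` in mol/L.

    When no secondary reaction is present this equals the phenolic-side
    extent (the conservation relation of the second-order model), which is
    asserted here; with a secondary reaction the formaldehyde side exceeds
    the phenolic side.
    """
    xf = init.F0 - trajectory.F
    if trajectory.params.k2 == 0.0:
        b = reactive_pool(init.POH0, trajectory.params.f_nonreactive)
        inert = init.POH0 - b
        xp = b - (trajectory.POH - inert)
        if not np.allclose(xf, xp, atol=1e-9):
            raise AssertionError(
                "extent conservation violated: formaldehyde- and phenolic-side "
                "extents disagree beyond 1e-9 with k2 = 0"
            )
    return xf


# Multi-start grid for the least-squares fit; fixed order keeps the result
# deterministic.  Ties on SSE resolve to the smallest k1.
_K1_STARTS = (0.1, 0.5, 1.0, 2.0, 5.0)
_K2_STARTS = (0.0, 0.1)
_F_STARTS = (0.5, 0.7, 0.9)

_K1_MAX = 1e3
_K2_MAX = 1e3
_F_MAX = 1.0 - 1e-9


def fit_kinetics(
    offline: OfflineSeries,
    init: InitialConditions,
    model: str = "single",
    weights: tuple[float, float] = (1.0, 1.0),
    use_series: str = "both",
) -> FitResult:
    """Estimate k1 (and optionally k2) plus the non-reactive fraction.

    Minimises the joint sum of squared residuals of the simulated versus
    observed formaldehyde and phenolic series.  A fixed multi-start grid of
    initial guesses feeds a bounded trust-region least-squares solver; the
    best SSE wins, ties broken by the smallest k1, so the result is
    deterministic for given data.

    Parameters
    ----------
    offline : OfflineSeries
        Measured series; NaNs are skipped per-series.
    init : InitialConditions
        Known initial concentrations (not fitted).
    model : {"single", "with_secondary"}
        "single" fixes k2 = 0; "with_secondary" also fits k2.
    weights : (float, float)
        Relative weights of the F and POH residuals.
    use_series : {"both", "F", "POH"}
        Which assay series enter the objective.

    Returns
    -------
    FitResult
        Fitted parameters, SSE, per-point residuals and convergence flags.
        A fit whose best SSE sits on the k1 = 0 boundary is flagged
        ``degenerate``.
    """
    if model not in ("single", "with_secondary"):
        raise ValueError(f"unknown model {model!r}")
    if use_series not in ("both", "F", "POH"):
        raise ValueError(f"unknown use_series {use_series!r}")

    t = np.asarray(offline.times, dtype=float)
    f_obs = np.asarray(offline.F, dtype=float)
    p_obs = np.asarray(offline.POH, dtype=float)
    use_f = ~np.isnan(f_obs) if use_series in ("both", "F") else np.zeros(len(t), bool)
    use_p = ~np.isnan(p_obs) if use_series in ("both", "POH") else np.zeros(len(t), bool)

    n_points = int(np.count_nonzero(use_f | use_p))
    n_free = 3 if model == "with_secondary" else 2
    if n_points < max(4, n_free + 1):
        raise ValueError(
            f"need at least {max(4, n_free + 1)} time points with measurements, "
            f"got {n_points}"
        )

    # simulation grid: observation times (plus 0 if absent)
    if t[0] != 0.0:
        sim_t = np.concatenate([[0.0], t])
        obs_ix = np.arange(1, len(t) + 1)
    else:
        sim_t = t
        obs_ix = np.arange(len(t))

    wf, wp = float(weights[0]), float(weights[1])

    def residuals(theta: np.ndarray) -> np.ndarray:
        k1, k2, f = theta[0], (theta[1] if n_free == 3 else 0.0), theta[-1]
        try:
            traj = simulate_trajectory(
                KineticParams(k1=k1, k2=k2, f_nonreactive=f), init, sim_t
            )
        except RuntimeError:
            return np.full(n_points, 1e6)
        r = []
        if use_f.any():
            r.append(wf * (traj.F[obs_ix][use_f] - f_obs[use_f]))
        if use_p.any():
            r.append(wp * (traj.POH[obs_ix][use_p] - p_obs[use_p]))
        return np.concatenate(r)

    if n_free == 3:
        lo = [0.0, 0.0, 0.0]
        hi = [_K1_MAX, _K2_MAX, _F_MAX]
        starts = [
            (k1, k2, f)
            for k1 in _K1_STARTS
            for k2 in _K2_STARTS
            for f in _F_STARTS
        ]
    else:
        lo = [0.0, 0.0]
        hi = [_K1_MAX, _F_MAX]
        starts = [(k1, f) for k1 in _K1_STARTS for f in _F_STARTS]

    best = None
    for x0 in starts:
        sol = least_squares(
            residuals, x0, bounds=(lo, hi), method="trf", xtol=1e-12, ftol=1e-12
        )
        sse = float(2.0 * sol.cost)
        k1_here = float(sol.x[0])
        if (
            best is None
            or sse < best[0] - 1e-15
            or (abs(sse - best[0]) <= 1e-15 and k1_here < best[1])
        ):
            best = (sse, k1_here, sol)

    sse, _, sol = best
    if n_free == 3:
        k1, k2, f = (float(v) for v in sol.x)
    else:
        k1, f = (float(v) for v in sol.x)
        k2 = 0.0

    # Degeneracy guard: if the no-reaction model (k1 = k2 = 0) fits the data
    # as well as the optimum, the rate is unidentifiable (any k1 with a
    # vanishing reactive pool lies on an SSE ridge); report the k1 = 0
    # boundary solution and flag it.
    theta0 = np.zeros(n_free)
    r0 = residuals(theta0)
    sse0 = float(r0 @ r0)
    if sse0 <= sse + 1e-12:
        return FitResult(
            params=KineticParams(k1=0.0, k2=0.0, f_nonreactive=0.0),
            sse=sse0,
            residuals=r0,
            n_points=n_points,
            converged=True,
            degenerate=True,
            message="no-reaction model fits as well: k1 unidentifiable",
        )

    params = KineticParams(
        k1=k1, k2=k2, f_nonreactive=min(f, 1.0 - 1e-12)
    )
    degenerate = k1 <= 1e-9
    return FitResult(
        params=params,
        sse=sse,
        residuals=sol.fun,
        n_points=n_points,
        converged=bool(sol.success),
        degenerate=degenerate,
        message="k1 at zero boundary" if degenerate else sol.message,
    )
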