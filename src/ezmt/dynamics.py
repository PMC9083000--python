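"""Deterministic Langevin dynamics of the repelled probe.

The probe obeys m*x''(t) = F(x) - xi*x'(t) with F(x) = Q_eff * E(x), the
LPB field force, and Stokes drag xi = 6*pi*eta*a.  The stochastic thermal
force is deliberately omitted, so trajectories are deterministic and the
exclusion-zone (EZ) size is read off as the displacement x(t) - x(0).

The inertial relaxation time m/xi is a few picoseconds while the EZ
develops over tens of microseconds, so the problem is stiff: the default
integrator is stiff-capable (LSODA) on the full second-order system, and
an overdamped first-order mode x' = F(x)/xi is provided both as a fast
path and as an independent cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .fields import FieldSolution, make_field
from .parameters import Scenario


class IntegrationError(RuntimeError):
    """The ODE solver failed to converge."""


class FitError(RuntimeError):
    """The force-law fit could not be performed (degenerate trajectory)."""


def force(coord, solution: FieldSolution, Q_eff: float):
    """Electric force on the probe, F = Q_eff * E(coord) (N).

    Equals -dU/dcoord by construction; positive (outward) when Q_eff and
    the surface charge share a sign.
    """
    return Q_eff * solution.field(coord)


@dataclass(frozen=True)
class Trajectory:
    """Time series of the probe's position and velocity.

    ``t`` is strictly increasing with t[0] = 0 (s); ``x`` is the absolute
    coordinate (m, distance from the axis/centre/plane) and ``v`` the
    velocity (m/s).  For repulsive scenarios x is non-decreasing and
    v >= 0.
    """

    t: np.ndarray
    x: np.ndarray
    v: np.ndarray

    @property
    def displacement(self) -> np.ndarray:
        """x(t) - x(0): the EZ size as a function of time (m)."""
        return self.x - self.x[0]


@dataclass(frozen=True)
class EZProfile:
    """Exclusion-zone displacement versus time."""

    t: np.ndarray
    ez: np.ndarray


@dataclass(frozen=True)
class SolverControls:
    """Integrator configuration.

    mode : 'full' integrates the second-order (inertial) system with a
        stiff-capable method; 'overdamped' integrates x' = F(x)/xi.
    rtol, atol_x, atol_v : solver tolerances (atol in SI units).
    n_points : number of logarithmically spaced output samples.
    t_min : first nonzero output time (s); samples are log-spaced from
        t_min to the horizon, with t = 0 prepended.
    """

    mode: str = "overdamped"
    rtol: float = 1e-8
    atol_x: float = 1e-15
    atol_v: float = 1e-12
    n_points: int = 1200
    t_min: float = 1e-12

    def __post_init__(self) -> None:
        if self.mode not in ("full", "overdamped"):
            raise ValueError(f"mode must be 'full' or 'overdamped', got {self.mode!r}")


def _time_grid(t_max: float, controls: SolverControls) -> np.ndarray:
    grid = np.geomspace(controls.t_min, t_max, controls.n_points)
    grid[-1] = t_max
    return np.concatenate(([0.0], grid))


def integrate_motion(
    scenario: Scenario,
    controls: SolverControls = SolverControls(),
    solution: FieldSolution | None = None,
) -> Trajectory:
    """Integrate the probe's equation of motion over the scenario horizon.

    Initial conditions are x(0) = start position (per the scenario's start
    rule) and v(0) = 0.  Returns the trajectory on a logarithmic time grid
    (the motion is fast early and logarithmic late).

    Raises
    ------
    IntegrationError
        If the solver reports failure.
    """
    if solution is None:
        solution = make_field(scenario.surface, scenario.medium)
    Q_eff = scenario.probe.Q_eff
    xi = scenario.friction_coefficient
    m = scenario.probe.m
    t_eval = _time_grid(scenario.t_max, controls)

    if controls.mode == "overdamped":
        def rhs(t, y):
            return [force(y[0], solution, Q_eff) / xi]

        sol = solve_ivp(
            rhs, (0.0, scenario.t_max), [scenario.start_position],
            method="LSODA", t_eval=t_eval,
            rtol=controls.rtol, atol=controls.atol_x,
        )
        if not sol.success:
            raise IntegrationError(f"overdamped integration failed: {sol.message}")
        x = sol.y[0]
        v = np.asarray(force(x, solution, Q_eff)) / xi
        return Trajectory(t=sol.t, x=x, v=v)

    def rhs(t, y):
        f = force(y[0], solution, Q_eff)
        return [y[1], (f - xi * y[1]) / m]

    sol = solve_ivp(
        rhs, (0.0, scenario.t_max), [scenario.start_position, 0.0],
        method="LSODA", t_eval=t_eval,
        rtol=controls.rtol, atol=[controls.atol_x, controls.atol_v],
    )
    if not sol.success:
        raise IntegrationError(f"full integration failed: {sol.message}")
    return Trajectory(t=sol.t, x=sol.y[0], v=sol.y[1])


def ez_size(trajectory: Trajectory, t_eval: float) -> float:
    """EZ size at time t_eval (m): linearly interpolated displacement
    x(t_eval) - x(0).  t_eval must lie within the trajectory's span."""
    if not (trajectory.t[0] <= t_eval <= trajectory.t[-1]):
        raise ValueError(
            f"t_eval = {t_eval} s outside trajectory span "
            f"[{trajectory.t[0]}, {trajectory.t[-1]}] s"
        )
    return float(np.interp(t_eval, trajectory.t, trajectory.displacement))


def ez_profile(trajectory: Trajectory) -> EZProfile:
    """Displacement-versus-time profile of a trajectory."""
    return EZProfile(t=trajectory.t, ez=trajectory.displacement)


def time_to_fraction(trajectory: Trajectory, fraction: float = 0.9) -> float:
    """First time at which the displacement reaches the given fraction of
    its final value (s)."""
    target = fraction * trajectory.displacement[-1]
    if target <= 0:
        return 0.0
    idx = int(np.searchsorted(trajectory.displacement, target))
    if idx == 0:
        return float(trajectory.t[0])
    # linear interpolation between the bracketing samples
    d0, d1 = trajectory.displacement[idx - 1], trajectory.displacement[idx]
    t0, t1 = trajectory.t[idx - 1], trajectory.t[idx]
    return float(t0 + (target - d0) / (d1 - d0) * (t1 - t0))


@dataclass(frozen=True)
class ForceLawFit:
    """Exponential force-law fit F(x)/xi = K * exp(-kappa * x).

    K has units of velocity (m/s), kappa of inverse length (1/m).
    ``residual`` is the root-mean-square residual of log(F/xi); for the
    planar geometry, whose force is exactly exponential, it vanishes to
    numerical precision.
    """

    K: float
    kappa: float
    residual: float
    n_points: int

    @property
    def decay_length(self) -> float:
        """1/kappa (m); comparable to the Debye length."""
        return 1.0 / self.kappa

    def summary(self) -> str:
        return (
            "Exponential force-law fit  F(x)/xi = K exp(-kappa x)\n"
            f"  K            = {self.K:.6g} m/s\n"
            f"  kappa        = {self.kappa:.6g} 1/m\n"
            f"  1/kappa      = {1e9 / self.kappa:.4g} nm\n"
            f"  rms log-residual = {self.residual:.3g}  ({self.n_points} points)"
        )


def fit_force_law(
    trajectory: Trajectory,
    scenario: Scenario,
    solution: FieldSolution | None = None,
    rel_force_floor: float = 1e-6,
) -> ForceLawFit:
    """Fit K and kappa of F(x)/xi = K*exp(-kappa*x) to trajectory samples.

    Linear least squares on log(F/xi) over the trajectory's positions,
    restricted to points where the force exceeds ``rel_force_floor`` times
    its starting value (avoiding the log of the vanishing tail).  The fit
    is exact for the planar geometry and a good tail approximation for the
    cylinder and sphere.
    """
    if solution is None:
        solution = make_field(scenario.surface, scenario.medium)
    xi = scenario.friction_coefficient
    x = np.unique(trajectory.x)
    f = np.asarray(force(x, solution, scenario.probe.Q_eff), dtype=float)
    f0 = abs(f[0])
    if f0 == 0.0:
        raise FitError("zero force everywhere: nothing to fit")
    keep = np.abs(f) > rel_force_floor * f0
    x, f = x[keep], f[keep]
    if x.size < 10:
        raise FitError(
            f"only {x.size} usable samples (need >= 10): trajectory did not move"
        )
    y = np.log(np.abs(f) / xi)
    coeffs, res, *_ = np.polyfit(x, y, 1, full=True)
    slope, intercept = coeffs
    rms = float(np.sqrt(res[0] / x.size)) if res.size else 0.0
    return ForceLawFit(
        K=float(np.exp(intercept)), kappa=float(-slope),
        residual=rms, n_points=int(x.size),
    )


def friction_work(trajectory: Trajectory, xi: float) -> float:
    """Energy dissipated by Stokes drag along the trajectory (J),
    W = integral xi * v dx, by trapezoidal quadrature on the samples."""
    return float(np.trapezoid(xi * trajectory.v, trajectory.x))
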