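"""Time integration of the tropic model variants.

Method of lines: the curvature field C(s, t) is the state vector, advanced
with classical RK4; the angle field is recomputed from C at every stage by
trapezoid integration from the clamped base (A(0, t) = A0), so the two
fields can never drift apart.  Because every variant is linear and
time-invariant, an exact matrix-exponential stepper is also provided and
serves as an independent cross-check of the RK4 path.

The supplementary variant with a finite apex-to-base signal propagation
time T_B delays the apical photoceptive term at position s by
``tau(s) = T_B*(L - s)/L`` (linear apex-to-base profile); before the signal
first arrives at a node its apical term is zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numpy.typing import NDArray
from scipy.integrate import cumulative_trapezoid
from scipy.linalg import expm

from .geometry import OrganShape
from .models import (
    APICAL_VARIANTS,
    ConfigurationError,
    DomainError,
    TropicParams,
    growth_zone_mask,
    model_rhs,
    resultant_angle,
)

__all__ = [
    "Kinematics",
    "PropagationConfig",
    "SolverError",
    "SteadyStateResult",
    "simulate",
    "simulate_with_propagation",
    "detect_steady_state",
    "tip_angle_series",
]


class SolverError(RuntimeError):
    """Raised when the explicit stepper detects unbounded energy growth."""


@dataclass
class Kinematics:
    """Time-stacked organ shapes A(s, t), C(s, t) with a parameter snapshot.

    Fields are arrays of shape (n_times, n_nodes); row 0 is the initial
    straight tilted organ (A = A0, C = 0).
    """

    t_grid: NDArray[np.float64]
    s_grid: NDArray[np.float64]
    A_field: NDArray[np.float64]
    C_field: NDArray[np.float64]
    params: TropicParams
    variant: str
    meta: dict = field(default_factory=dict)

    def shape_at(self, index: int) -> OrganShape:
        return OrganShape(self.s_grid, self.A_field[index], self.C_field[index])

    def final_shape(self) -> OrganShape:
        return self.shape_at(-1)

    @property
    def n_times(self) -> int:
        return self.t_grid.size


@dataclass(frozen=True)
class PropagationConfig:
    """Apex-to-base signal propagation time T_B (T_C is reported for context)."""

    T_B: float
    T_C: float | None = None

    def __post_init__(self) -> None:
        if self.T_B < 0.0:
            raise DomainError("propagation time T_B must be >= 0")


def default_time_step(params: TropicParams) -> float:
    """Conservative explicit step from the relaxation and oscillation scales."""
    p = params
    relax = p.gamma + (p.beta + p.nu) * p.L_gz
    osc = math.sqrt((p.beta + p.nu) * p.L_gz) if (p.beta + p.nu) > 0 else 0.0
    fastest = max(relax, osc, 1e-12)
    return 0.05 / fastest


def _angles_from_C(C: NDArray, s: NDArray, A0: float) -> NDArray:
    return A0 + cumulative_trapezoid(C, s, initial=0.0)


def _blowup_guard(C: NDArray, params: TropicParams) -> None:
    scale = (abs(params.A0) + abs(params.A_P) + abs(params.GSA) + 1.0) / params.L
    if not np.all(np.isfinite(C)) or np.max(np.abs(C)) > 1e6 * scale:
        raise SolverError(
            "curvature field is growing without bound; "
            "reduce the time step (dt) or check the parameter regime"
        )


def simulate(
    variant: str,
    params: TropicParams,
    t_end: float,
    *,
    n_nodes: int = 201,
    dt: float | None = None,
    save_every: int | None = None,
    method: str = "rk4",
    sine_law: bool = False,
) -> Kinematics:
    """Integrate one model variant from a straight tilted initial condition.

    Parameters
    ----------
    t_end:
        Final time (> 0).
    dt:
        Solver step; defaults to :func:`default_time_step` (the actual step
        is rounded so an integer number of steps lands exactly on t_end).
    save_every:
        Output cadence in solver steps; defaults to ~200 saved frames.
    method:
        ``"rk4"`` (default) or ``"expm"`` — the exact matrix-exponential
        stepper for the linear system, used as a cross-check oracle.
    """
    if variant not in ("AC", "AaC", "ARC", "ARaC"):
        raise ConfigurationError(f"unknown model variant {variant!r}")
    if t_end <= 0.0:
        raise DomainError("t_end must be positive")
    if method not in ("rk4", "expm"):
        raise ConfigurationError(f"unknown method {method!r}")

    p = params
    s = np.linspace(0.0, p.L, n_nodes)
    if dt is None:
        dt = default_time_step(p)
    n_steps = max(1, math.ceil(t_end / dt - 1e-12))
    dt = t_end / n_steps
    if save_every is None:
        save_every = max(1, n_steps // 200)

    if method == "expm":
        if sine_law:
            raise ConfigurationError("the exact stepper applies to the linear model only")
        return _simulate_expm(variant, p, s, dt, n_steps, save_every)
    return _simulate_rk4(
        variant, p, s, dt, n_steps, save_every, sine_law=sine_law, delay=None
    )


def simulate_with_propagation(
    params: TropicParams,
    propagation: PropagationConfig,
    t_end: float,
    *,
    variant: str = "AaC",
    n_nodes: int = 201,
    dt: float | None = None,
    save_every: int | None = None,
) -> Kinematics:
    """Apical-perception variant with a finite basipetal propagation time.

    With ``T_B = 0`` this delegates to :func:`simulate` (identical stepper,
    identical trajectory).
    """
    if variant not in APICAL_VARIANTS:
        raise ConfigurationError("propagation applies to apical variants (AaC, ARaC)")
    if propagation.T_B == 0.0:
        return simulate(
            variant, params, t_end, n_nodes=n_nodes, dt=dt, save_every=save_every
        )
    p = params
    s = np.linspace(0.0, p.L, n_nodes)
    if dt is None:
        dt = min(default_time_step(p), propagation.T_B / 10.0)
    n_steps = max(1, math.ceil(t_end / dt - 1e-12))
    dt = t_end / n_steps
    if save_every is None:
        save_every = max(1, n_steps // 200)
    kin = _simulate_rk4(
        variant, p, s, dt, n_steps, save_every, sine_law=False, delay=propagation.T_B
    )
    kin.meta["T_B"] = propagation.T_B
    return kin


def _simulate_rk4(
    variant: str,
    p: TropicParams,
    s: NDArray,
    dt: float,
    n_steps: int,
    save_every: int,
    *,
    sine_law: bool,
    delay: float | None,
) -> Kinematics:
    n = s.size
    mask = growth_zone_mask(s, p)
    sense = np.sin if sine_law else (lambda x: x)
    apical = variant in APICAL_VARIANTS
    gravi = variant in ("AC", "ARC", "ARaC")

    tau = delay * (p.L - s) / p.L if delay is not None else None
    hist_t = [0.0]
    hist_tip = [p.A0]

    def rhs(C: NDArray, t: float) -> NDArray:
        A = _angles_from_C(C, s, p.A0)
        rate = -p.gamma * C
        if gravi:
            rate = rate - p.beta * sense(A - p.GSA)
        if variant == "ARC":
            rate = rate - p.nu * sense(A - p.A_P)
        elif apical:
            if tau is None:
                rate = rate - p.nu * sense(A[-1] - p.A_P)
            else:
                tip_delayed = np.interp(t - tau, hist_t, hist_tip)
                term = np.where(t >= tau, p.nu * sense(tip_delayed - p.A_P), 0.0)
                rate = rate - term
        return rate * mask

    C = np.zeros(n)
    t = 0.0
    times = [0.0]
    A_frames = [np.full(n, float(p.A0))]
    C_frames = [C.copy()]
    for step in range(1, n_steps + 1):
        k1 = rhs(C, t)
        k2 = rhs(C + 0.5 * dt * k1, t + 0.5 * dt)
        k3 = rhs(C + 0.5 * dt * k2, t + 0.5 * dt)
        k4 = rhs(C + dt * k3, t + dt)
        C = C + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        t = step * dt
        _blowup_guard(C, p)
        if tau is not None:
            hist_t.append(t)
            hist_tip.append(float(_angles_from_C(C, s, p.A0)[-1]))
        if step % save_every == 0 or step == n_steps:
            times.append(t)
            A_frames.append(_angles_from_C(C, s, p.A0))
            C_frames.append(C.copy())

    return Kinematics(
        t_grid=np.array(times),
        s_grid=s,
        A_field=np.array(A_frames),
        C_field=np.array(C_frames),
        params=p,
        variant=variant,
        meta={"method": "rk4", "dt": dt, "n_steps": n_steps, "sine_law": sine_law},
    )


def _trapezoid_matrix(s: NDArray) -> NDArray:
    """Lower-triangular matrix T with (T @ C)[i] = trapezoid integral of C to s_i."""
    n = s.size
    T = np.zeros((n, n))
    h = np.diff(s)
    for i in range(1, n):
        T[i, : i + 1] = T[i - 1, : i + 1]
        T[i, i - 1] += 0.5 * h[i - 1]
        T[i, i] += 0.5 * h[i - 1]
    return T


def _simulate_expm(
    variant: str,
    p: TropicParams,
    s: NDArray,
    dt: float,
    n_steps: int,
    save_every: int,
) -> Kinematics:
    n = s.size
    mask = growth_zone_mask(s, p)
    T = _trapezoid_matrix(s)
    F = -p.gamma * np.eye(n)
    g = np.zeros(n)
    if variant in ("AC", "ARC", "ARaC"):
        F = F - p.beta * T
        g = g - p.beta * (p.A0 - p.GSA) * np.ones(n)
    if variant == "ARC":
        F = F - p.nu * T
        g = g - p.nu * (p.A0 - p.A_P) * np.ones(n)
    elif variant in APICAL_VARIANTS:
        F = F - p.nu * np.outer(np.ones(n), T[-1])
        g = g - p.nu * (p.A0 - p.A_P) * np.ones(n)
    F = mask[:, None] * F
    g = mask * g

    aug = np.zeros((n + 1, n + 1))
    aug[:n, :n] = F
    aug[:n, n] = g
    E = expm(aug * (dt * save_every))

    z = np.zeros(n + 1)
    z[n] = 1.0
    times = [0.0]
    A_frames = [np.full(n, float(p.A0))]
    C_frames = [np.zeros(n)]
    n_out = n_steps // save_every
    for k in range(1, n_out + 1):
        z = E @ z
        C = z[:n]
        times.append(k * save_every * dt)
        A_frames.append(_angles_from_C(C, s, p.A0))
        C_frames.append(C.copy())
    if n_out * save_every < n_steps:  # land exactly on t_end
        rem = (n_steps - n_out * save_every) * dt
        z = expm(aug * rem) @ z
        C = z[:n]
        times.append(n_steps * dt)
        A_frames.append(_angles_from_C(C, s, p.A0))
        C_frames.append(C.copy())

    return Kinematics(
        t_grid=np.array(times),
        s_grid=s,
        A_field=np.array(A_frames),
        C_field=np.array(C_frames),
        params=p,
        variant=variant,
        meta={"method": "expm", "dt": dt, "n_steps": n_steps},
    )


@dataclass(frozen=True)
class SteadyStateResult:
    """Outcome of steady-state detection; non-convergence is a result, not an error."""

    converged: bool
    time: float | None
    index: int | None
    shape: OrganShape | None
    threshold: float

    def __bool__(self) -> bool:
        return self.converged


def _reference_set_point(params: TropicParams, variant: str) -> float:
    if params.nu > 0.0 and variant == "AaC":
        return params.A_P  # no graviceptive term: the light direction is the target
    if params.nu > 0.0 and variant in ("ARC", "ARaC"):
        return resultant_angle(params)
    return params.GSA


def detect_steady_state(
    kinematics: Kinematics,
    rel_tol: float = 1e-3,
    *,
    eps: float = 1e-6,
) -> SteadyStateResult:
    """Earliest output time at which the curvature field has stopped evolving.

    Criterion: ``max_s |dC/dt| < rel_tol * gamma * max(|A0 - A_R|, eps)``,
    with dC/dt evaluated from the model right-hand side on each stored slice.
    A gamma = 0 run can never satisfy this (the dark model then oscillates
    indefinitely) and is reported as non-converged.
    """
    kin = kinematics
    p = kin.params
    A_ref = _reference_set_point(p, kin.variant)
    threshold = rel_tol * p.gamma * max(abs(p.A0 - A_ref), eps)
    for i in range(kin.n_times):
        rate = model_rhs(kin.variant, kin.shape_at(i), p,
                         sine_law=bool(kin.meta.get("sine_law", False)))
        if np.max(np.abs(rate)) < threshold:
            return SteadyStateResult(
                converged=True,
                time=float(kin.t_grid[i]),
                index=i,
                shape=kin.shape_at(i),
                threshold=threshold,
            )
    return SteadyStateResult(
        converged=False, time=None, index=None, shape=None, threshold=threshold
    )


def tip_angle_series(kinematics: Kinematics) -> tuple[NDArray, NDArray]:
    """Apical angle A(L, t) at every stored time."""
    return kinematics.t_grid, kinematics.A_field[:, -1]
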