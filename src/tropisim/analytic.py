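"""Closed-form transients, steady states and limit cases of the model family.

All formulas support a growth zone shorter than the organ: below
``s0 = L - L_gz`` the organ is rigid and stays at the initial tilt, and the
arc-length coordinate entering the exponential profiles is measured from the
top of the rigid segment.  With the default ``L_gz = L`` they reduce to the
familiar whole-organ expressions, e.g. the dark (AC) steady state
``A(s) = A0*exp(-B*s/L)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numpy.typing import ArrayLike, NDArray

from .geometry import OrganShape
from .models import DomainError, TropicParams, resultant_angle


class NoSteadyStateError(ValueError):
    """Raised when the requested regime has no steady state (e.g. gamma=0 AC)."""


@dataclass(frozen=True)
class NoSteadyState:
    """Marker result for regimes that oscillate indefinitely (B -> inf)."""

    case: str
    reason: str = "graviception dominates proprioception; no steady state exists"


def _gz_coordinate(s: NDArray[np.float64], params: TropicParams) -> NDArray[np.float64]:
    """Arc length measured from the top of the rigid basal segment, >= 0."""
    return np.maximum(s - (params.L - params.L_gz), 0.0)


def aac_transient(
    params: TropicParams,
    s: ArrayLike,
    t: ArrayLike,
) -> tuple[NDArray[np.float64], NDArray[np.float64]]:
    """Exact transient of the apical photoproprioceptive (AaC) model.

    The curvature is uniform along the responsive zone (the organ is an arc
    of a circle at every instant) and relaxes exponentially with rate
    ``nu*L_gz + gamma``; for a zenithal light (A_P = 0) over the whole organ::

        C(t) = -(A0/L) * (1 / (1 + gamma/(nu*L))) * (1 - exp(-(nu*L+gamma)*t))
        A(s, t) = A0 * (1 - (s/L) * (1 / (1 + gamma/(nu*L))) * (1 - exp(-(nu*L+gamma)*t)))

    A nonzero light direction A_P replaces A0 by (A0 - A_P) in the curvature
    amplitude.  Returns angle and curvature broadcast over ``s`` x ``t``
    (squeezed when either input is scalar).
    """
    p = params
    rate = p.nu * p.L_gz + p.gamma
    if rate <= 0.0:
        raise DomainError("AaC transient requires nu*L_gz + gamma > 0")
    s_arr = np.atleast_1d(np.asarray(s, dtype=float))
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    amplitude = -((p.A0 - p.A_P) / p.L_gz) * (p.nu * p.L_gz / rate)
    c_t = amplitude * (1.0 - np.exp(-rate * t_arr))  # (nt,)
    sigma = _gz_coordinate(s_arr, p)  # (ns,)
    angle = p.A0 + np.outer(sigma, c_t)  # (ns, nt)
    curvature = np.broadcast_to(c_t, angle.shape).copy()
    if p.L_gz < p.L:
        curvature[s_arr <= p.L - p.L_gz, :] = 0.0
    if np.isscalar(t) or np.ndim(t) == 0:
        angle, curvature = angle[:, 0], curvature[:, 0]
        if np.isscalar(s) or np.ndim(s) == 0:
            return float(angle[0]), float(curvature[0])
    elif np.isscalar(s) or np.ndim(s) == 0:
        angle, curvature = angle[0], curvature[0]
    return angle, curvature


def steady_state(
    variant: str,
    params: TropicParams,
    s_grid: ArrayLike,
) -> OrganShape:
    """Closed-form steady-state shape of a model variant.

    AC:   A(s) = A0*exp(-beta*s/gamma)
    ARC:  A(s) = (A0-A_R)*exp(-(beta+nu)*s/gamma) + A_R
    AaC:  uniform curvature -nu*A0/(gamma+nu*L_gz); tip angle A0/(1+D)
    ARaC: A(s) = (A0-A_R)*(exp(-B*s/L) - exp(-B)*(1-exp(-B*s/L))/(M+1-exp(-B))) + A_R
    """
    p = params
    s = np.asarray(s_grid, dtype=float)
    sigma = _gz_coordinate(s, p)
    in_gz = s > p.L - p.L_gz if p.L_gz < p.L else np.ones_like(s, dtype=bool)

    if variant == "AC":
        if p.gamma == 0.0:
            raise NoSteadyStateError(
                "AC with gamma=0 oscillates indefinitely; there is no steady state"
            )
        decay = np.exp(-p.beta * sigma / p.gamma)
        angle = p.GSA + (p.A0 - p.GSA) * decay
        curvature = np.where(in_gz, -(p.beta / p.gamma) * (angle - p.GSA), 0.0)
        return OrganShape(s, angle, curvature)

    if variant == "ARC":
        if p.gamma == 0.0:
            raise NoSteadyStateError("ARC with gamma=0 has no steady state")
        A_R = resultant_angle(p)
        k = (p.beta + p.nu) / p.gamma
        decay = np.exp(-k * sigma)
        angle = (p.A0 - A_R) * decay + A_R
        curvature = np.where(in_gz, -k * (angle - A_R), 0.0)
        return OrganShape(s, angle, curvature)

    if variant == "AaC":
        rate = p.gamma + p.nu * p.L_gz
        if p.nu == 0.0 and p.gamma == 0.0:
            raise NoSteadyStateError("AaC needs nu > 0 or gamma > 0")
        c_inf = -p.nu * (p.A0 - p.A_P) / rate
        angle = p.A0 + c_inf * sigma
        curvature = np.where(in_gz, c_inf, 0.0)
        return OrganShape(s, angle, curvature)

    if variant == "ARaC":
        if p.gamma == 0.0:
            raise NoSteadyStateError("ARaC with gamma=0 has no steady state")
        A_R = resultant_angle(p)
        if p.beta == 0.0:
            # B -> 0: the AaC arc, shifted to the light-set resultant angle
            rate = p.gamma + p.nu * p.L_gz
            c_inf = -p.nu * (p.A0 - A_R) / rate
            angle = p.A0 + c_inf * sigma
            curvature = np.where(in_gz, c_inf, 0.0)
            return OrganShape(s, angle, curvature)
        B = p.beta * p.L_gz / p.gamma
        M = p.beta / p.nu if p.nu > 0 else math.inf
        eB = np.exp(-B)
        K = M + 1.0 - eB
        corr = eB / K if math.isfinite(K) else 0.0
        decay = np.exp(-p.beta * sigma / p.gamma)
        a_prime = (p.A0 - A_R) * (decay - corr * (1.0 - decay))
        angle = a_prime + A_R
        curvature = np.where(
            in_gz, -(p.A0 - A_R) * (p.beta / p.gamma) * decay * (1.0 + corr), 0.0
        )
        return OrganShape(s, angle, curvature)

    raise DomainError(f"unknown model variant {variant!r}")


def limit_case_shape(
    case: str,
    params: TropicParams,
    s_grid: ArrayLike,
) -> OrganShape | NoSteadyState:
    """Steady state of the ARaC model in one of its four limit regimes.

    ``B_zero``: proprioception dominates graviception; the AaC arc with the
    apex set by the light direction.  ``M_inf``: graviception dominates
    photoception; the dark AC profile.  ``M_zero``: photoception dominates;
    the apex sits exactly at A_P but the curved zone is still shaped by B.
    ``B_inf`` has no steady state and returns a marker.
    """
    p = params
    s = np.asarray(s_grid, dtype=float)
    sigma = _gz_coordinate(s, p)
    in_gz = s > p.L - p.L_gz if p.L_gz < p.L else np.ones_like(s, dtype=bool)

    if case == "B_inf":
        return NoSteadyState(case="B_inf")

    if case == "B_zero":
        if p.gamma == 0.0 and p.nu == 0.0:
            raise DomainError("B_zero limit needs nu > 0 or gamma > 0")
        A_R = p.A_P  # M = B/D -> 0, so the set point is the light direction
        rate = p.gamma + p.nu * p.L_gz
        c_inf = -p.nu * (p.A0 - A_R) / rate
        angle = p.A0 + c_inf * sigma
        return OrganShape(s, angle, np.where(in_gz, c_inf, 0.0))

    if case == "M_inf":
        if p.beta == 0.0 or p.gamma == 0.0:
            raise DomainError("M_inf limit needs beta > 0 and gamma > 0")
        decay = np.exp(-p.beta * sigma / p.gamma)
        angle = p.A0 * decay
        return OrganShape(s, angle, np.where(in_gz, -(p.beta / p.gamma) * angle, 0.0))

    if case == "M_zero":
        if p.nu == 0.0:
            raise DomainError("M_zero limit contradicts nu = 0")
        if p.beta == 0.0 or p.gamma == 0.0:
            raise DomainError("M_zero limit needs beta > 0 and gamma > 0 (else use B_zero)")
        B = p.beta * p.L_gz / p.gamma
        A_R = p.A_P
        a0p = p.A0 - A_R
        decay = np.exp(-p.beta * sigma / p.gamma)
        a_prime = a0p * (decay - (1.0 - decay) / (math.exp(B) - 1.0))
        angle = a_prime + A_R
        curvature = np.where(
            in_gz, -a0p * (p.beta / p.gamma) * decay / (1.0 - math.exp(-B)), 0.0
        )
        return OrganShape(s, angle, curvature)

    raise DomainError(f"unknown limit case {case!r}")


def characteristic_quantities(params: TropicParams) -> tuple[float, float, float]:
    """Characteristic time T_c, convergence length L_c and steady tip angle.

    ``T_c = 1/(gamma + nu*L_gz)`` — time scale of the apical reorientation;
    ``L_c = L/B'`` — length of the curved zone at steady state;
    ``tip_limit = (A0 - A_R)*exp(-(B+D)) + A_R`` — apical angle of the
    local-perception (ARC) steady state.
    """
    p = params
    if p.beta == 0.0 and p.gamma == 0.0 and p.nu == 0.0:
        raise DomainError("all sensitivities are zero")
    denom = p.gamma + p.nu * p.L_gz
    if denom <= 0.0:
        raise DomainError("T_c requires gamma + nu*L_gz > 0")
    T_c = 1.0 / denom
    if p.gamma > 0.0:
        B_prime = (p.beta + p.nu) * p.L_gz / p.gamma
    else:
        B_prime = math.inf
    L_c = p.L / B_prime if B_prime > 0 else math.inf
    A_R = resultant_angle(p)
    tip_limit = (p.A0 - A_R) * math.exp(-B_prime) + A_R
    return T_c, L_c, tip_limit


def tip_near_set_point(params: TropicParams) -> bool:
    """True when exp(-(B+D)) < 0.01, i.e. the steady tip is at A_R in practice."""
    p = params
    if p.gamma == 0.0:
        return True  # B + D -> inf
    return math.exp(-(p.beta + p.nu) * p.L_gz / p.gamma) < 0.01
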