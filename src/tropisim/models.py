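"""Tropic model variants, parameter sets and dimensionless control numbers.

Four linear model variants describe the local curvature dynamics of a shoot
organ driven by graviception (sensitivity ``beta``), photoception
(sensitivity ``nu``, either local or apical) and proprioception
(sensitivity ``gamma``), inside the growth zone of length ``L_gz``::

    AC    dC/dt = -beta*(A(s) - GSA)                      - gamma*C(s)
    AaC   dC/dt =                    - nu*(A(L) - A_P)    - gamma*C(s)
    ARC   dC/dt = -beta*(A(s) - GSA) - nu*(A(s) - A_P)    - gamma*C(s)
    ARaC  dC/dt = -beta*(A(s) - GSA) - nu*(A(L) - A_P)    - gamma*C(s)

and ``dC/dt = 0`` outside the growth zone.  ``A_P`` is the light direction
w.r.t. the vertical, GSA the gravitropic set-point angle (0 for
ortho-gravitropic organs).  The sensing terms are the small-angle
linearization of the Lambert-cosine photoception law and the gravitropic
sine law; an optional ``sine_law`` mode keeps the full sine terms, which is
where the linear model is known to break down for tilts beyond 90 degrees.

The dynamics are controlled by three dimensionless numbers:

* ``B = beta*L_gz/gamma`` — graviproprioceptive number,
* ``D = nu*L_gz/gamma``   — photoproprioceptive number,
* ``M = beta/nu = B/D``   — photograviceptive number,

and the apex aligns toward the photogravitropic set-point angle
``A_R = A_P/(1 + M)``.  The dependence of M on the light fluence rate I is
expressed either as a Stevens power law ``M = a*I**b`` (b < 0 empirically,
magnitude ~0.4) or a Weber-Fechner logarithmic law ``M = c + d*log(I)``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
from numpy.typing import ArrayLike, NDArray

from .geometry import OrganShape

VARIANTS = ("AC", "AaC", "ARC", "ARaC")
#: variants whose photoceptive term reads the apical angle A(L)
APICAL_VARIANTS = ("AaC", "ARaC")


class DomainError(ValueError):
    """Raised when a parameter combination leaves a formula's domain."""


class ConfigurationError(ValueError):
    """Raised for unknown variants or law kinds."""


class InvalidIntensityResponse(UserWarning):
    """Emitted when an intensity law returns a negative (invalid) M."""


@dataclass(frozen=True)
class TropicParams:
    """Sensitivities, geometry and field directions of a tropic experiment.

    Units: ``beta`` and ``nu`` in 1/(length*time), ``gamma`` in 1/time,
    ``L`` and ``L_gz`` in length, angles in radians.
    """

    beta: float = 0.0
    gamma: float = 1.0
    nu: float = 0.0
    A0: float = 0.0
    A_P: float = 0.0
    L: float = 1.0
    L_gz: float | None = None
    GSA: float = 0.0

    def __post_init__(self) -> None:
        if self.L_gz is None:
            object.__setattr__(self, "L_gz", self.L)
        if self.beta < 0 or self.gamma < 0 or self.nu < 0:
            raise DomainError("sensitivities beta, gamma, nu must be >= 0")
        if self.L <= 0:
            raise DomainError("organ length L must be positive")
        if not 0 < self.L_gz <= self.L:
            raise DomainError("growth zone must satisfy 0 < L_gz <= L")

    def negated(self) -> "TropicParams":
        """Mirror the bending plane: flip A0, A_P and GSA."""
        return replace(self, A0=-self.A0, A_P=-self.A_P, GSA=-self.GSA)


@dataclass(frozen=True)
class DerivedNumbers:
    """Dimensionless numbers and derived scales of a parameter set."""

    B: float
    D: float
    M: float
    B_prime: float
    A_R: float
    T_c: float
    L_c: float


def derived_numbers(params: TropicParams) -> DerivedNumbers:
    """Compute B, D, M, B', A_R, T_c and L_c from a parameter set.

    ``M = beta/nu`` is ``inf`` for a dark experiment (nu = 0); ``L_c`` is
    ``inf`` when neither external tropism is active.
    """
    p = params
    if p.gamma == 0.0:
        raise DomainError("B and D are undefined for gamma = 0")
    if p.beta == 0.0 and p.nu == 0.0:
        raise DomainError("A_R is undefined when beta = nu = 0")
    B = p.beta * p.L_gz / p.gamma
    D = p.nu * p.L_gz / p.gamma
    M = p.beta / p.nu if p.nu > 0 else math.inf
    B_prime = B + D
    A_R = p.A_P * p.nu / (p.nu + p.beta)
    T_c = 1.0 / (p.gamma + p.nu * p.L_gz)
    L_c = p.L / B_prime if B_prime > 0 else math.inf
    return DerivedNumbers(B=B, D=D, M=M, B_prime=B_prime, A_R=A_R, T_c=T_c, L_c=L_c)


def resultant_angle(params: TropicParams) -> float:
    """Photogravitropic set-point angle A_R = A_P*nu/(nu+beta) = A_P/(1+M)."""
    if params.beta == 0.0 and params.nu == 0.0:
        raise DomainError("A_R is undefined when beta = nu = 0")
    return params.A_P * params.nu / (params.nu + params.beta)


# --------------------------------------------------------------------------
# intensity-response laws

@dataclass(frozen=True)
class IntensityLaw:
    """Response law M(I): Stevens power law or Weber-Fechner log law.

    ``stevens_power``:     M(I) = a * I**b   (a > 0; b signed, empirically < 0)
    ``weber_fechner_log``: M(I) = c + d * log(I)  (natural log; I > 0 only)
    """

    kind: str
    a: float = 1.0
    b: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("stevens_power", "weber_fechner_log"):
            raise ConfigurationError(f"unknown intensity law kind {self.kind!r}")
        if self.kind == "stevens_power" and self.a <= 0:
            raise DomainError("Stevens prefactor a must be positive")

    @property
    def c(self) -> float:  # Weber-Fechner aliases
        return self.a

    @property
    def d(self) -> float:
        return self.b


def intensity_to_M(I: ArrayLike, law: IntensityLaw) -> NDArray[np.float64] | float:
    """Evaluate M(I).  Negative outputs are flagged, never silently clamped."""
    I_arr = np.asarray(I, dtype=float)
    if np.any(I_arr <= 0.0):
        raise DomainError("fluence rate I must be positive")
    if law.kind == "stevens_power":
        m = law.a * I_arr ** law.b
    else:
        m = law.a + law.b * np.log(I_arr)
    if np.any(m < 0.0):
        warnings.warn(
            "intensity law produced negative M; flagged invalid",
            InvalidIntensityResponse,
            stacklevel=2,
        )
    return m if m.ndim else float(m)


def valid_M_mask(m: ArrayLike) -> NDArray[np.bool_]:
    """Validity of M values: finite and non-negative."""
    m_arr = np.asarray(m, dtype=float)
    return np.isfinite(m_arr) & (m_arr >= 0.0)


# --------------------------------------------------------------------------
# model right-hand sides

def growth_zone_mask(s_grid: NDArray[np.floating], params: TropicParams) -> NDArray[np.float64]:
    """1 inside the responsive growth zone, 0 below it.

    When the whole organ is responsive (L_gz = L, the default) every node
    including the clamped base is active, so the base curvature is free to
    evolve toward its nonzero steady-state value.
    """
    if params.L_gz >= params.L:
        return np.ones_like(s_grid, dtype=float)
    return (s_grid > params.L - params.L_gz).astype(float)


def model_rhs(
    variant: str,
    shape: OrganShape,
    params: TropicParams,
    *,
    sine_law: bool = False,
) -> NDArray[np.float64]:
    """Curvature rate field dC/dt at every grid node for one model variant."""
    if variant not in VARIANTS:
        raise ConfigurationError(f"unknown model variant {variant!r}")
    A = shape.angle
    C = shape.curvature
    p = params
    sense = np.sin if sine_law else (lambda x: x)
    rate = -p.gamma * C
    if variant in ("AC", "ARC", "ARaC"):
        rate = rate - p.beta * sense(A - p.GSA)
    if variant == "ARC":
        rate = rate - p.nu * sense(A - p.A_P)
    elif variant in APICAL_VARIANTS:
        rate = rate - p.nu * sense(A[-1] - p.A_P)
    return rate * growth_zone_mask(shape.s_grid, p)


def symmetry_transform(obj, params: TropicParams | None = None):
    """Mirror a shape or kinematics through the vertical plane.

    Negates the angle and curvature fields; when params are attached (or
    passed) their A0, A_P and GSA are negated too, so ``model_rhs`` commutes
    with the transform.  Applying it twice is the identity.
    """
    from .simulate import Kinematics  # local import to avoid a cycle

    if isinstance(obj, OrganShape):
        flipped = OrganShape(obj.s_grid.copy(), -obj.angle, -obj.curvature)
        if params is None:
            return flipped
        return flipped, params.negated()
    if isinstance(obj, Kinematics):
        return Kinematics(
            t_grid=obj.t_grid.copy(),
            s_grid=obj.s_grid.copy(),
            A_field=-obj.A_field,
            C_field=-obj.C_field,
            params=obj.params.negated(),
            variant=obj.variant,
            meta=dict(obj.meta),
        )
    raise TypeError(f"cannot symmetry-transform object of type {type(obj)!r}")
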