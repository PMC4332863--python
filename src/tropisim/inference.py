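"""Inference of tropic control numbers from photogravitropic equilibrium data.

A photogravitropic-equilibrium (PGEA) dataset is a table of records
(initial tilt A0, light direction A_P, fluence rate I, measured equilibrium
tip angle), in the style of tilted-coleoptile experiments where the light is
held perpendicular to the initial orientation.  Because the model predicts
the tip aligns to ``A_R = A_P/(1+M)``, each record yields a direct estimate
``M = A_P/tip - 1`` of the photograviceptive number, and the collection of
(I, M) pairs is fitted with an intensity-response law:

* Stevens power law, fitted as a line in log-log space, or
* Weber-Fechner logarithmic law, fitted as a line in semi-log space,

in both cases by an orthogonal (total least squares, unit error ratio) line
fit minimizing perpendicular distances.  Records with M <= 0, mismatched
signs, or initial tilts beyond 90 degrees (where the small-angle model is
known to fail) are excluded and reported with a reason code.

The module also provides the morphometric estimators: B from the dark
(gravitropic) steady shape, M from the equilibrium tip angle, and D = B/M.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.typing import ArrayLike, NDArray
from scipy.optimize import curve_fit

from .geometry import OrganShape
from .models import DomainError, IntensityLaw

PGEA_COLUMNS = ["protocol", "A0", "A_P", "I", "tip_angle", "replicate"]

#: exclusion reason codes
REASON_OK = "ok"
REASON_M_NONPOSITIVE = "M_nonpositive"
REASON_A0_BEYOND_90 = "A0_beyond_90deg"
REASON_SIGN_MISMATCH = "tip_sign_mismatch"
REASON_TIP_ZERO = "tip_zero_M_infinite"
REASON_NONFINITE = "nonfinite"


class InsufficientDataError(ValueError):
    """Fewer than 3 valid records, or no spread in fluence rate."""


class EmptyFitError(ValueError):
    """Every record was excluded by the validity mask."""


class BelowThresholdWarning(UserWarning):
    """Fluence rate below the sensing threshold of the phenomenological law."""


def M_from_equilibrium(A_P: float, tip_angle: float) -> float:
    """Photograviceptive number from an equilibrium tip angle: M = A_P/tip - 1.

    A tip angle of exactly zero means pure gravitropic alignment and returns
    ``inf`` (a marker, not an exception).  Negative results (tip beyond the
    light direction) are returned as-is; callers mask them as invalid.
    """
    if tip_angle == 0.0:
        return math.inf
    return A_P / tip_angle - 1.0


def _record_validity(df: pd.DataFrame) -> pd.Series:
    """Per-record reason codes; 'ok' marks records usable for law fitting."""
    reasons = []
    for _, row in df.iterrows():
        a0, ap, tip, I = row["A0"], row["A_P"], row["tip_angle"], row["I"]
        if not all(np.isfinite([a0, ap, tip, I])) or I <= 0:
            reasons.append(REASON_NONFINITE)
        elif abs(a0) > math.pi / 2 + 1e-12:
            reasons.append(REASON_A0_BEYOND_90)
        elif tip == 0.0:
            reasons.append(REASON_TIP_ZERO)
        elif tip * ap <= 0.0:
            reasons.append(REASON_SIGN_MISMATCH)
        elif ap / tip - 1.0 <= 0.0:
            reasons.append(REASON_M_NONPOSITIVE)
        else:
            reasons.append(REASON_OK)
    return pd.Series(reasons, index=df.index, name="reason")


# --------------------------------------------------------------------------
# orthogonal (total least squares) line fit

@dataclass(frozen=True)
class OrthogonalLineFit:
    """Line y = intercept + slope*x minimizing perpendicular distances."""

    slope: float
    intercept: float
    R_squared: float
    residual_ss: float  # sum of squared perpendicular distances
    n: int


def orthogonal_line_fit(x: ArrayLike, y: ArrayLike) -> OrthogonalLineFit:
    """Total-least-squares line through (x, y) with unit error-variance ratio.

    The fitted direction is the principal eigenvector of the 2x2 scatter
    matrix about the centroid; the perpendicular residual sum of squares is
    n times the minor eigenvalue, and R^2 is defined as
    1 - (orthogonal residual SS)/(total scatter about the centroid)
    = lambda_major/(lambda_major + lambda_minor).
    """
    x_arr = np.asarray(x, dtype=float)
    y_arr = np.asarray(y, dtype=float)
    n = x_arr.size
    if n < 2:
        raise InsufficientDataError("need at least 2 points for a line fit")
    xc = x_arr - x_arr.mean()
    yc = y_arr - y_arr.mean()
    S = np.array([[xc @ xc, xc @ yc], [xc @ yc, yc @ yc]]) / n
    evals, evecs = np.linalg.eigh(S)  # ascending eigenvalues
    v = evecs[:, 1]
    if v[0] == 0.0:
        raise InsufficientDataError("degenerate design: no spread in x")
    slope = v[1] / v[0]
    intercept = y_arr.mean() - slope * x_arr.mean()
    total = evals[0] + evals[1]
    r2 = 1.0 if total == 0.0 else float(evals[1] / total)
    return OrthogonalLineFit(
        slope=float(slope),
        intercept=float(intercept),
        R_squared=r2,
        residual_ss=float(n * max(evals[0], 0.0)),
        n=n,
    )


def ordinary_line_fit(x: ArrayLike, y: ArrayLike) -> OrthogonalLineFit:
    """Ordinary least squares, same container, for comparison."""
    x_arr = np.asarray(x, dtype=float)
    y_arr = np.asarray(y, dtype=float)
    slope, intercept = np.polyfit(x_arr, y_arr, 1)
    resid = y_arr - (intercept + slope * x_arr)
    tot = np.sum((y_arr - y_arr.mean()) ** 2)
    r2 = 1.0 if tot == 0.0 else 1.0 - float(np.sum(resid**2) / tot)
    return OrthogonalLineFit(float(slope), float(intercept), r2,
                             float(np.sum(resid**2)), x_arr.size)


# --------------------------------------------------------------------------
# intensity-law fitting

@dataclass
class IntensityLawFit:
    """Result of fitting M(I) to equilibrium records."""

    kind: str
    intercept: float
    slope: float
    R_squared: float
    residual_ss: float
    n_used: int
    fit_space: str  # "log-log" | "semi-log"
    validity: pd.Series = field(repr=False)
    law: IntensityLaw = None  # type: ignore[assignment]

    @property
    def n_excluded(self) -> int:
        return int((self.validity != REASON_OK).sum())


def _fit_space_coords(df: pd.DataFrame, law_kind: str):
    m = df["A_P"] / df["tip_angle"] - 1.0
    x = np.log(df["I"].to_numpy(dtype=float))
    if law_kind == "stevens_power":
        return x, np.log(m.to_numpy(dtype=float)), "log-log"
    if law_kind == "weber_fechner_log":
        return x, m.to_numpy(dtype=float), "semi-log"
    raise DomainError(f"unknown law kind {law_kind!r}")


def fit_intensity_law(
    dataset: pd.DataFrame,
    law_kind: str = "stevens_power",
    *,
    method: str = "orthogonal",
) -> IntensityLawFit:
    """Fit M(I) = A_P/tip - 1 against fluence rate with an orthogonal line fit.

    Power law: line in (log I, log M); the slope is the signed Stevens
    exponent b and exp(intercept) the prefactor a.  Log law: line in
    (log I, M); slope d, intercept c.
    """
    df = dataset
    reasons = _record_validity(df)
    valid = df[reasons == REASON_OK]
    if len(valid) == 0:
        raise EmptyFitError("no valid records after applying the validity mask")
    if len(valid) < 3:
        raise InsufficientDataError(f"only {len(valid)} valid records; need >= 3")
    x, y, space = _fit_space_coords(valid, law_kind)
    if np.unique(np.round(x, 12)).size < 2:
        raise InsufficientDataError("fluence rate must span more than one value")
    fitter = orthogonal_line_fit if method == "orthogonal" else ordinary_line_fit
    fit = fitter(x, y)
    if law_kind == "stevens_power":
        law = IntensityLaw("stevens_power", a=math.exp(fit.intercept), b=fit.slope)
    else:
        law = IntensityLaw("weber_fechner_log", a=fit.intercept, b=fit.slope)
    return IntensityLawFit(
        kind=law_kind,
        intercept=fit.intercept,
        slope=fit.slope,
        R_squared=fit.R_squared,
        residual_ss=fit.residual_ss,
        n_used=fit.n,
        fit_space=space,
        validity=reasons,
        law=law,
    )


@dataclass
class CollapseReport:
    """Do per-tilt response curves collapse on a single master curve?"""

    collapsed: bool
    group_slopes: dict
    slope_dispersion: float
    pooled_rms: float
    mean_group_rms: float
    rms_ratio: float
    threshold: float
    n_groups: int
    excluded: pd.DataFrame = field(repr=False, default=None)  # type: ignore[assignment]
    trivially_collapsed: bool = False


def master_curve_collapse(
    dataset: pd.DataFrame,
    law_kind: str = "stevens_power",
    *,
    threshold: float = 1.2,
) -> CollapseReport:
    """Compare per-A0-group fits with a pooled fit.

    Verdict "collapsed" when the pooled per-point perpendicular RMS is at
    most ``threshold`` times the mean grouped RMS (with an absolute floor so
    exactly-collapsing noiseless data pass).
    """
    df = dataset
    reasons = _record_validity(df)
    valid = df[reasons == REASON_OK]
    excluded = df[reasons != REASON_OK].assign(reason=reasons[reasons != REASON_OK])
    if len(valid) < 3:
        raise InsufficientDataError("too few valid records for a collapse test")

    groups = valid.groupby("A0")
    group_slopes: dict = {}
    group_rms = []
    for a0, g in groups:
        if len(g) < 3:
            continue
        x, y, _ = _fit_space_coords(g, law_kind)
        if np.unique(np.round(x, 12)).size < 2:
            continue
        fit = orthogonal_line_fit(x, y)
        group_slopes[float(a0)] = fit.slope
        group_rms.append(math.sqrt(fit.residual_ss / fit.n))

    x, y, _ = _fit_space_coords(valid, law_kind)
    pooled = orthogonal_line_fit(x, y)
    pooled_rms = math.sqrt(pooled.residual_ss / pooled.n)
    # zero-residual floor: sqrt of the eigenvalue round-off (~1e-16*scatter),
    # orders of magnitude below any physical measurement noise
    scale = float(np.std(y)) if np.std(y) > 0 else 1.0
    floor = 1e-6 * scale

    if len(group_slopes) < 2:
        return CollapseReport(
            collapsed=True,
            group_slopes=group_slopes,
            slope_dispersion=0.0,
            pooled_rms=pooled_rms,
            mean_group_rms=float("nan"),
            rms_ratio=float("nan"),
            threshold=threshold,
            n_groups=len(group_slopes),
            excluded=excluded,
            trivially_collapsed=True,
        )

    mean_group_rms = float(np.mean(group_rms))
    ratio = pooled_rms / mean_group_rms if mean_group_rms > 0 else math.inf
    slopes = np.array(list(group_slopes.values()))
    collapsed = pooled_rms <= max(threshold * mean_group_rms, floor)
    return CollapseReport(
        collapsed=bool(collapsed),
        group_slopes=group_slopes,
        slope_dispersion=float(slopes.max() - slopes.min()),
        pooled_rms=pooled_rms,
        mean_group_rms=mean_group_rms,
        rms_ratio=float(ratio),
        threshold=threshold,
        n_groups=len(group_slopes),
        excluded=excluded,
    )


def invert_law_for_intensity(law: IntensityLaw, target_M: float) -> float:
    """Fluence rate I at which the law gives M(I) = target_M."""
    if not math.isfinite(target_M) or target_M <= 0.0:
        raise DomainError("target M must be finite and positive")
    if law.kind == "stevens_power":
        if law.b == 0.0:
            raise DomainError("flat power law cannot be inverted")
        return float((target_M / law.a) ** (1.0 / law.b))
    if law.b == 0.0:
        raise DomainError("flat log law cannot be inverted")
    return float(math.exp((target_M - law.a) / law.b))


def equilibrium_tip_angle(kinematics, rel_tol: float = 1e-3) -> tuple[float, str]:
    """Equilibrium tip angle from a kinematics run, strict or windowed.

    Uses steady-state detection; if the run never converged, the mean apical
    angle over the last 10% of stored times is returned with a ``transient``
    flag (the tip direction stabilizes before the full shape does).
    """
    from .simulate import detect_steady_state

    res = detect_steady_state(kinematics, rel_tol=rel_tol)
    if res.converged:
        return float(res.shape.tip_angle()), "steady"
    tail = max(1, kinematics.n_times // 10)
    return float(np.mean(kinematics.A_field[-tail:, -1])), "transient"


# --------------------------------------------------------------------------
# morphometric estimators

@dataclass(frozen=True)
class BEstimate:
    B: float
    A0: float
    residual_norm: float
    flat_profile: bool = False
    sign_warning: bool = False


def estimate_B_from_dark_shape(shape: OrganShape) -> BEstimate:
    """Graviproprioceptive number from a dark (gravitropic) steady shape.

    Nonlinear least squares of ``A(s) = A0*exp(-B*s/L)`` over the whole
    profile; returns the fitted B, the fitted A0 and the residual 2-norm.
    """
    s = shape.s_grid
    a = shape.angle
    L = shape.length
    a0_guess = float(a[0])
    if a0_guess == 0.0:
        a0_guess = float(np.max(np.abs(a))) or 1.0
    sign_warning = bool(np.any(a * np.sign(a0_guess) < -1e-6 * abs(a0_guess)))
    span = np.max(np.abs(a)) - np.min(np.abs(a))
    if span < 1e-12 * max(abs(a0_guess), 1.0):
        return BEstimate(B=0.0, A0=a0_guess, residual_norm=0.0, flat_profile=True)
    tip = a[-1]
    if tip * a0_guess > 0:
        b_guess = max(math.log(abs(a0_guess) / abs(tip)), 0.1) if tip != 0 else 3.0
    else:
        b_guess = 3.0

    def model(s_, a0_, b_):
        return a0_ * np.exp(-b_ * s_ / L)

    popt, _ = curve_fit(model, s, a, p0=[a0_guess, b_guess], maxfev=10000)
    resid = a - model(s, *popt)
    return BEstimate(
        B=float(popt[1]),
        A0=float(popt[0]),
        residual_norm=float(np.linalg.norm(resid)),
        sign_warning=sign_warning,
    )


def estimate_D(B_estimate: float, M_estimate: float) -> float:
    """Photoproprioceptive number from the identity D = B/M.

    ``M = inf`` (pure gravitropic alignment) gives D = 0; ``M = 0`` gives an
    infinite-D marker.
    """
    if M_estimate < 0.0:
        raise DomainError("M must be >= 0")
    if math.isinf(M_estimate):
        return 0.0
    if M_estimate == 0.0:
        return math.inf
    return B_estimate / M_estimate


def pgea_phenomenological(I: float, I0: float, k: float, g: float, A0: float) -> float:
    """Additive log-intensity / sine-of-tilt equilibrium-angle baseline.

    ``PGEA = k*log(I/I0) - g*sin(A0)``.  This is the phenomenological law the
    set-point model argues against: in darkness it predicts an equilibrium
    that depends on the initial tilt, and in bright light an angle that grows
    without saturation.  Provided purely as a comparison baseline.
    """
    if I0 <= 0.0:
        raise DomainError("threshold intensity I0 must be positive")
    if I < I0:
        warnings.warn(
            "fluence rate below the sensing threshold I0",
            BelowThresholdWarning,
            stacklevel=2,
        )
    return k * math.log(I / I0) - g * math.sin(A0)
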