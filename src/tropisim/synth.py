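"""Synthetic data with known ground truth.

Two generators feed the inference pipeline:

* Galland-style photogravitropic-equilibrium (PGEA) datasets: tilted
  organs, collimated light held perpendicular to the initial orientation
  (A_P = A0 + pi/2), fluence rates spanning ~5 decades, ~15 replicates per
  condition, Gaussian measurement noise on the tip angle.  PROT1 varies the
  fluence rate at fixed tilts; PROT2 tunes the fluence rate so the organ
  holds its initial tilt (A_R = A0).  The default tilt list includes 120
  degrees, beyond the small-angle validity of the model, to exercise the
  exclusion logic downstream.
* Noisy kinematics maps A(s, t), C(s, t): a clean simulation plus i.i.d.
  Gaussian angle noise, with curvature recomputed from the noisy angles, as
  a stand-in for digitized time-lapse midlines.

Every output records the seed and the generating truth so recovery tests
can close the generate -> infer loop.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import angles_to_curvature
from .inference import invert_law_for_intensity
from .models import IntensityLaw, TropicParams, intensity_to_M
from .simulate import Kinematics, simulate

#: Galland-style default tilt list (degrees 0, 10, 30, 90, 120)
DEFAULT_A0_DEG = (0.0, 10.0, 30.0, 90.0, 120.0)
#: default tip-angle measurement noise: 2 degrees, a protractor-scale error
DEFAULT_SIGMA = math.radians(2.0)


@dataclass
class GeneratorSpec:
    """Design of a synthetic photogravitropic-equilibrium experiment."""

    protocol: str = "PROT1"
    A0_list: tuple = tuple(math.radians(a) for a in DEFAULT_A0_DEG)
    I_min: float = 1e-2
    decades: float = 5.0
    n_intensities: int = 12
    law: IntensityLaw = field(default_factory=lambda: IntensityLaw("stevens_power", a=1.0, b=-0.4))
    noise_sigma: float = DEFAULT_SIGMA
    intensity_jitter: float = 0.0
    replicates: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.protocol not in ("PROT1", "PROT2"):
            raise ValueError("protocol must be PROT1 or PROT2")
        if self.noise_sigma < 0 or self.intensity_jitter < 0:
            raise ValueError("noise levels must be >= 0")
        if self.I_min <= 0:
            raise ValueError("intensity grid must be positive")

    def intensity_grid(self) -> np.ndarray:
        lo = math.log10(self.I_min)
        return np.logspace(lo, lo + self.decades, self.n_intensities)


def generate_pgea_dataset(spec: GeneratorSpec) -> pd.DataFrame:
    """Generate equilibrium tip-angle records with known ground truth.

    PROT1: for each (A0, I, replicate), A_P = A0 + pi/2, the true tip angle
    is A_R = A_P/(1 + M(I)), and the observed tip adds Gaussian noise.
    PROT2: for each A0 != 0, the fluence rate solves M(I) = A_P/A0 - 1 so
    the organ holds its tilt; the recorded tip is A0 plus noise.  A0 = 0
    rows are skipped with a warning (the required fluence rate is infinite
    for a decreasing law).

    Returns a DataFrame (columns protocol, A0, A_P, I, tip_angle, replicate;
    angles in radians) whose ``attrs`` echo the truth law, sigma and seed.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    if spec.protocol == "PROT1":
        for a0 in spec.A0_list:
            a_p = a0 + math.pi / 2.0
            for I in spec.intensity_grid():
                m_true = float(intensity_to_M(I, spec.law))
                tip_true = a_p / (1.0 + m_true)
                for rep in range(spec.replicates):
                    I_obs = I
                    if spec.intensity_jitter > 0:
                        I_obs = I * math.exp(rng.normal(0.0, spec.intensity_jitter))
                    tip = tip_true + (rng.normal(0.0, spec.noise_sigma)
                                      if spec.noise_sigma > 0 else 0.0)
                    rows.append(("PROT1", a0, a_p, I_obs, tip, rep))
    else:
        for a0 in spec.A0_list:
            if a0 == 0.0:
                warnings.warn(
                    "PROT2 skips A0 = 0 (infinite target fluence rate)",
                    UserWarning,
                    stacklevel=2,
                )
                continue
            a_p = a0 + math.pi / 2.0
            m_target = a_p / a0 - 1.0
            I_star = invert_law_for_intensity(spec.law, m_target)
            for rep in range(spec.replicates):
                I_obs = I_star
                if spec.intensity_jitter > 0:
                    I_obs = I_star * math.exp(rng.normal(0.0, spec.intensity_jitter))
                tip = a0 + (rng.normal(0.0, spec.noise_sigma)
                            if spec.noise_sigma > 0 else 0.0)
                rows.append(("PROT2", a0, a_p, I_obs, tip, rep))

    df = pd.DataFrame(rows, columns=["protocol", "A0", "A_P", "I", "tip_angle", "replicate"])
    df.attrs["truth"] = {
        "law_kind": spec.law.kind,
        "a": spec.law.a,
        "b": spec.law.b,
        "noise_sigma": spec.noise_sigma,
        "seed": spec.seed,
        "replicates": spec.replicates,
    }
    return df


def generate_noisy_kinematics(
    variant: str,
    params: TropicParams,
    noise_sigma: float,
    seed: int,
    *,
    t_end: float | None = None,
    **simulate_kwargs,
) -> Kinematics:
    """Simulate, then corrupt the angle field with i.i.d. Gaussian noise.

    Curvature is recomputed from the noisy angles slice by slice, mimicking
    a measured kinematics map.  With ``noise_sigma = 0`` the clean
    simulation is returned unchanged.
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    if t_end is None:
        from .analytic import characteristic_quantities

        T_c, _, _ = characteristic_quantities(params)
        t_end = 20.0 * T_c
    kin = simulate(variant, params, t_end, **simulate_kwargs)
    if noise_sigma == 0.0:
        kin.meta.update({"noise_sigma": 0.0, "seed": seed})
        return kin
    rng = np.random.default_rng(seed)
    noisy_A = kin.A_field + rng.normal(0.0, noise_sigma, size=kin.A_field.shape)
    noisy_C = np.vstack(
        [angles_to_curvature(noisy_A[i], kin.s_grid) for i in range(kin.n_times)]
    )
    return Kinematics(
        t_grid=kin.t_grid,
        s_grid=kin.s_grid,
        A_field=noisy_A,
        C_field=noisy_C,
        params=kin.params,
        variant=kin.variant,
        meta={**kin.meta, "noise_sigma": noise_sigma, "seed": seed},
    )


def lle_preset_params(gamma: float = 1.0, L: float = 1.0) -> TropicParams:
    """Vertical organ, horizontal light: the lateral-light experiment layout.

    Gravi-dominated proprioception with strong apical photoception (B = 2,
    D = 20), the regime where the whole organ first curves toward the light
    and the curvature then concentrates near the base.
    """
    return TropicParams(
        beta=2.0 * gamma / L,
        gamma=gamma,
        nu=20.0 * gamma / L,
        A0=0.0,
        A_P=math.pi / 2.0,
        L=L,
    )
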