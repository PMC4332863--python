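"""Plain-text file formats: shape/kinematics CSV, PGEA CSV, TOML config, JSON sidecars.

All tables are comma-delimited with ``#`` comment headers declaring units.
Angles are radians inside the library; files may declare degrees
(``angle=deg`` in the unit header, or the ``*_deg`` column names of the
PGEA format) and are converted at this boundary.
"""

from __future__ import annotations

import dataclasses
import json
import math
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import OrganShape
from .models import IntensityLaw, TropicParams
from .simulate import Kinematics

SHAPE_COLUMNS = ["s", "t", "angle", "curvature"]
PGEA_FILE_COLUMNS = ["protocol", "A0_deg", "AP_deg", "I", "tip_angle_deg", "replicate"]


class SchemaError(ValueError):
    """Missing/malformed columns or rows in a delimited input file."""


class UnitError(ValueError):
    """Inconsistent or unknown unit declaration."""


def _unit_header(angle_unit: str) -> str:
    return f"# units: s=length, t=time, angle={angle_unit}, curvature=1/length\n"


def _parse_angle_unit(path: Path) -> str:
    unit = "rad"
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if "angle=deg" in line:
                unit = "deg"
            elif "angle=rad" in line:
                unit = "rad"
    return unit


def _read_numeric_csv(path: Path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    for col in required:
        if col in ("protocol",):
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            # +2: header line and 1-based numbering (comment lines excluded)
            raise SchemaError(
                f"{path}: malformed value in column {col!r} at data row "
                f"{int(bad[0]) + 2}"
            )
        df[col] = coerced
    return df


# --------------------------------------------------------------------------
# shape / kinematics tables (long format: s,t,angle,curvature)

def write_shape(path, shape: OrganShape, *, t: float = 0.0, degrees: bool = False) -> None:
    path = Path(path)
    factor = 180.0 / math.pi if degrees else 1.0
    df = pd.DataFrame(
        {
            "s": shape.s_grid,
            "t": np.full_like(shape.s_grid, t),
            "angle": shape.angle * factor,
            "curvature": shape.curvature,
        }
    )
    with open(path, "w") as fh:
        fh.write(_unit_header("deg" if degrees else "rad"))
        df.to_csv(fh, index=False, float_format="%.17g")


def read_shape(path) -> OrganShape:
    path = Path(path)
    unit = _parse_angle_unit(path)
    df = _read_numeric_csv(path, SHAPE_COLUMNS)
    times = df["t"].unique()
    if times.size > 1:
        raise SchemaError(f"{path}: expected a single time slice, found {times.size}")
    angle = df["angle"].to_numpy(dtype=float)
    if unit == "deg":
        angle = np.radians(angle)
    return OrganShape(
        df["s"].to_numpy(dtype=float), angle, df["curvature"].to_numpy(dtype=float)
    )


def write_kinematics(path, kin: Kinematics, *, degrees: bool = False) -> None:
    path = Path(path)
    factor = 180.0 / math.pi if degrees else 1.0
    nt, ns = kin.A_field.shape
    df = pd.DataFrame(
        {
            "s": np.tile(kin.s_grid, nt),
            "t": np.repeat(kin.t_grid, ns),
            "angle": kin.A_field.ravel() * factor,
            "curvature": kin.C_field.ravel(),
        }
    )
    with open(path, "w") as fh:
        fh.write(_unit_header("deg" if degrees else "rad"))
        df.to_csv(fh, index=False, float_format="%.17g")
    write_sidecar(path, _kinematics_meta(kin))


def read_kinematics(path) -> Kinematics:
    path = Path(path)
    unit = _parse_angle_unit(path)
    df = _read_numeric_csv(path, SHAPE_COLUMNS)
    t_grid = np.unique(df["t"].to_numpy(dtype=float))
    s_grid = np.unique(df["s"].to_numpy(dtype=float))
    nt, ns = t_grid.size, s_grid.size
    if nt * ns != len(df):
        raise SchemaError(f"{path}: table is not a complete (s, t) grid")
    order = np.lexsort((df["s"].to_numpy(), df["t"].to_numpy()))
    A = df["angle"].to_numpy(dtype=float)[order].reshape(nt, ns)
    C = df["curvature"].to_numpy(dtype=float)[order].reshape(nt, ns)
    if unit == "deg":
        A = np.radians(A)
    meta = read_sidecar(path)
    params = TropicParams(**meta["params"]) if "params" in meta else TropicParams()
    return Kinematics(
        t_grid=t_grid,
        s_grid=s_grid,
        A_field=A,
        C_field=C,
        params=params,
        variant=meta.get("variant", "AC"),
        meta=meta.get("solver", {}),
    )


def _kinematics_meta(kin: Kinematics) -> dict:
    return {
        "variant": kin.variant,
        "params": dataclasses.asdict(kin.params),
        "solver": {k: v for k, v in kin.meta.items()},
    }


def sidecar_path(path) -> Path:
    return Path(str(path) + ".meta.json")


def write_sidecar(path, meta: dict) -> None:
    with open(sidecar_path(path), "w") as fh:
        json.dump(meta, fh, indent=2, default=str)
        fh.write("\n")


def read_sidecar(path) -> dict:
    sp = sidecar_path(path)
    if not sp.exists():
        return {}
    with open(sp) as fh:
        return json.load(fh)


# --------------------------------------------------------------------------
# PGEA datasets (degrees on disk, radians in memory)

def write_pgea(path, dataset: pd.DataFrame) -> None:
    path = Path(path)
    out = pd.DataFrame(
        {
            "protocol": dataset["protocol"],
            "A0_deg": np.degrees(dataset["A0"]),
            "AP_deg": np.degrees(dataset["A_P"]),
            "I": dataset["I"],
            "tip_angle_deg": np.degrees(dataset["tip_angle"]),
            "replicate": dataset["replicate"],
        }
    )
    with open(path, "w") as fh:
        fh.write("# units: angles=deg, I=fluence-rate (arbitrary)\n")
        out.to_csv(fh, index=False, float_format="%.17g")
    if dataset.attrs:
        write_sidecar(path, dataset.attrs)


def read_pgea(path) -> pd.DataFrame:
    path = Path(path)
    df = _read_numeric_csv(path, PGEA_FILE_COLUMNS)
    out = pd.DataFrame(
        {
            "protocol": df["protocol"],
            "A0": np.radians(df["A0_deg"]),
            "A_P": np.radians(df["AP_deg"]),
            "I": df["I"],
            "tip_angle": np.radians(df["tip_angle_deg"]),
            "replicate": df["replicate"].astype(int),
        }
    )
    out.attrs = read_sidecar(path)
    return out


# --------------------------------------------------------------------------
# run configuration (TOML)

@dataclass
class RunConfig:
    """Resolved run configuration: variant, parameters, solver options, law."""

    variant: str = "AC"
    params: TropicParams = field(default_factory=TropicParams)
    t_end: float | None = None
    dt: float | None = None
    n_nodes: int = 201
    seed: int = 0
    intensity_law: IntensityLaw | None = None

    def to_dict(self) -> dict:
        d = {
            "variant": self.variant,
            "params": dataclasses.asdict(self.params),
            "t_end": self.t_end,
            "dt": self.dt,
            "n_nodes": self.n_nodes,
            "seed": self.seed,
        }
        if self.intensity_law is not None:
            d["intensity_law"] = {
                "kind": self.intensity_law.kind,
                "a": self.intensity_law.a,
                "b": self.intensity_law.b,
            }
        return d


def load_config(path) -> RunConfig:
    """Read a flat TOML parameter file.

    Recognized keys: beta, gamma, nu, A0_deg, AP_deg, L, Lgz, GSA_deg,
    variant, t_end, dt, nodes, seed and an ``[intensity_law]`` table with
    kind plus (a, b) or (c, d) coefficients.  Angles in the file are degrees.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    params = TropicParams(
        beta=float(raw.get("beta", 0.0)),
        gamma=float(raw.get("gamma", 1.0)),
        nu=float(raw.get("nu", 0.0)),
        A0=math.radians(float(raw.get("A0_deg", 0.0))),
        A_P=math.radians(float(raw.get("AP_deg", 0.0))),
        L=float(raw.get("L", 1.0)),
        L_gz=float(raw["Lgz"]) if "Lgz" in raw else None,
        GSA=math.radians(float(raw.get("GSA_deg", 0.0))),
    )
    law = None
    if "intensity_law" in raw:
        tbl = raw["intensity_law"]
        kind = tbl.get("kind", "stevens_power")
        if kind == "stevens_power":
            law = IntensityLaw(kind, a=float(tbl.get("a", 1.0)), b=float(tbl.get("b", -0.4)))
        else:
            law = IntensityLaw(kind, a=float(tbl.get("c", 0.0)), b=float(tbl.get("d", 1.0)))
    return RunConfig(
        variant=str(raw.get("variant", "AC")),
        params=params,
        t_end=float(raw["t_end"]) if "t_end" in raw else None,
        dt=float(raw["dt"]) if "dt" in raw else None,
        n_nodes=int(raw.get("nodes", 201)),
        seed=int(raw.get("seed", 0)),
        intensity_law=law,
    )
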