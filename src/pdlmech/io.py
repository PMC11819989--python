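"""Readers, writers, specimen geometry and run configuration.

Curve files are comma-separated UTF-8 text with a mandatory header. The
stress column is ``stress_MPa``; the abscissa is either ``stretch`` (λ,
dimensionless, 1 at rest) or ``strain`` (Green strain ε, converted on read
via λ = (1+2ε)^(1/2)). A ``--delimiter``/``delimiter=`` escape hatch
covers other dialects.

Raw force–displacement records are converted to Cauchy stress with the
initial cross-section A0 and the incompressibility relation σ11 = λ·Fu/A0
(first Piola–Kirchhoff stress Fu/A0 times λ); computing λ from
displacement requires the gauge length, which is therefore a required
config field for force files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .constitutive import StressStrainCurve
from .fitting import FitResult
from .kinematics import stretch_from_green_strain

__all__ = [
    "SampleGeometry",
    "RunConfig",
    "SAMPLE_DIMENSIONS_MM",
    "area_from_dimensions",
    "pk1_from_force",
    "cauchy_from_force",
    "read_curve",
    "write_curve",
    "read_mask",
    "write_mask",
    "write_fit_report",
    "load_run_config",
    "setup_logging",
]

logger = logging.getLogger("pdlmech")

#: printed (length, width, thickness) in mm of the six incisor
#: bone–ligament–dentin specimens, keyed by "<region>_<tooth>"
SAMPLE_DIMENSIONS_MM: dict[str, tuple[float, float, float]] = {
    "neck_central": (2.53, 2.16, 0.25),
    "middle_central": (2.60, 2.08, 0.25),
    "apex_central": (2.23, 2.20, 0.25),
    "neck_lateral": (2.27, 2.22, 0.25),
    "middle_lateral": (2.40, 1.96, 0.25),
    "apex_lateral": (2.57, 2.03, 0.25),
}


@dataclass(frozen=True)
class SampleGeometry:
    """Specimen dimensions; cross-section A0 = length × width (mm²)."""

    length: float
    width: float
    thickness: float = 0.25
    area: float = None  # type: ignore[assignment]

    def __post_init__(self):
        if min(self.length, self.width, self.thickness) <= 0:
            raise ValueError("all dimensions must be positive")
        product = area_from_dimensions(self.length, self.width)
        if self.area is None:
            object.__setattr__(self, "area", product)
        elif abs(self.area - product) > 1e-4:
            raise ValueError(
                f"area {self.area} inconsistent with length x width = {product}"
            )


def area_from_dimensions(length: float, width: float) -> float:
    """Cross-section area length × width in mm², rounded to 4 decimals
    (the reporting convention for specimen tables)."""
    if length <= 0 or width <= 0:
        raise ValueError(f"dimensions must be positive, got {length} x {width}")
    return round(length * width, 4)


def pk1_from_force(force_N: float, area_mm2: float):
    """First Piola–Kirchhoff stress Fu/A0 in MPa (N/mm² = MPa)."""
    area_mm2 = float(area_mm2)
    if area_mm2 <= 0:
        raise ValueError(f"initial area must be positive, got {area_mm2}")
    out = np.asarray(force_N, dtype=float) / area_mm2
    return float(out) if out.ndim == 0 else out


def cauchy_from_force(lam, force_N, area_mm2: float):
    """Cauchy stress σ11 = λ·Fu/A0 in MPa (incompressible, J = 1)."""
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0):
        raise ValueError(f"stretch must be positive, got {lam!r}")
    out = lam * pk1_from_force(force_N, area_mm2)
    return float(out) if np.ndim(out) == 0 else out


def read_curve(path, delimiter: str = ",", region: str = "", tooth: str = "",
               rate: str = "") -> StressStrainCurve:
    """Read a stress–stretch curve from delimited text.

    Requires a ``stress_MPa`` column and either ``stretch`` or ``strain``
    (Green strain, auto-converted). Raises descriptive errors for missing
    columns, empty files, NaNs and non-monotone stretch.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, delimiter=delimiter, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty curve file") from None
    if df.empty:
        raise ValueError(f"{path}: empty curve (header only, zero rows)")
    cols = {c.strip(): c for c in df.columns}
    if "stress_MPa" not in cols:
        raise ValueError(f"{path}: missing required column 'stress_MPa' "
                         f"(found {list(df.columns)})")
    stress = df[cols["stress_MPa"]].to_numpy(dtype=float)
    if "stretch" in cols:
        stretch = df[cols["stretch"]].to_numpy(dtype=float)
    elif "strain" in cols:
        stretch = stretch_from_green_strain(df[cols["strain"]].to_numpy(dtype=float))
    else:
        raise ValueError(f"{path}: need a 'stretch' or 'strain' column "
                         f"(found {list(df.columns)})")
    for name, arr in (("stretch", stretch), ("stress_MPa", stress)):
        bad = np.flatnonzero(~np.isfinite(arr))
        if bad.size:
            # +2: one for the header row, one for 1-based line numbering
            raise ValueError(f"{path}: non-finite {name} at line {bad[0] + 2}")
    try:
        return StressStrainCurve(stretch=stretch, stress=stress,
                                 region=region, tooth=tooth, rate=rate)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from None


def write_curve(curve: StressStrainCurve, path, delimiter: str = ",") -> None:
    """Write a curve as (stretch, stress_MPa) delimited text; round-trips
    through :func:`read_curve` losslessly (values printed at full
    double precision)."""
    df = pd.DataFrame({"stretch": curve.stretch, "stress_MPa": curve.stress})
    df.to_csv(path, sep=delimiter, index=False, float_format="%.17g")


def read_mask(path) -> np.ndarray:
    """Read a grayscale/binary image file as a boolean mask (nonzero = true)."""
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:  # collapse RGB(A): any nonzero channel counts
        arr = arr[..., :3].max(axis=-1)
    return arr > 0


def write_mask(mask: np.ndarray, path) -> None:
    """Write a boolean mask as an 8-bit PNG/TIFF (255 = fiber)."""
    import imageio.v3 as iio

    iio.imwrite(path, (np.asarray(mask, dtype=bool) * np.uint8(255)))


def write_fit_report(result: FitResult, path) -> None:
    """Serialise a :class:`FitResult` to JSON (params expanded inline)."""
    payload = {
        "free": {"c1": result.free[0], "c3": result.free[1], "c5": result.free[2]},
        "params": {k: getattr(result.params, k)
                   for k in ("c1", "c2", "c3", "c4", "c5", "c6", "Vf", "Vm")},
        "r_squared": result.r_squared,
        "residual_norm_MPa": result.residual_norm,
        "n_points": result.n_points,
        "converged": result.converged,
        "init": list(result.init),
        "n_starts": result.n_starts,
        "message": result.message,
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


@dataclass
class RunConfig:
    """Serializable description of one analysis run (inputs + options).

    A run is reproducible from its config and seed alone; ``config_hash``
    gives a stable fingerprint for log lines and provenance records.
    """

    curve_path: str = ""
    region: str = ""
    tooth: str = ""
    vf: Optional[float] = None
    vf_source: str = "table"  # "table" (regional mean) or "measured"
    gauge_length_mm: Optional[float] = None  # required for raw force files
    init: tuple = (1.0, 1.0, 1.0)
    multistart: int = 1
    seed: Optional[int] = None
    no_constraints: bool = False
    out_dir: str = "."

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def load_run_config(path) -> RunConfig:
    """Load a :class:`RunConfig` from a YAML (or flat key: value) file."""
    import yaml

    data = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(data) - set(RunConfig.__dataclass_fields__)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "init" in data:
        data["init"] = tuple(data["init"])
    return RunConfig(**data)


def setup_logging(level: int = logging.INFO) -> None:
    """Configure INFO logging with timestamps for the CLI entry points."""
    logging.basicConfig(
        level=level,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
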