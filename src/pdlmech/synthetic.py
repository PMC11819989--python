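"""Synthetic tensile curves and fiber masks for exercising the pipeline.

Raw PDL tensile data are not publicly deposited, so the test surface runs
on synthetic stand-ins generated from the published regional coefficient
presets:

* stress–stretch curves: the closed-form model evaluated on a stretch grid
  (default 30 points, λ ∈ [1.0, 1.20] — the regime where real curves are
  flat below λ ≈ 1.05 and steepen above 1.1, with peak stresses well under
  the ~1.4 MPa observed experimentally) plus additive homoscedastic
  Gaussian noise (default sd 0.01 MPa, small against peak stress but large
  enough to make recovery non-trivial);
* binary fiber masks with an exact prescribed pixel fraction, placed by
  seeded shuffling.

Every generator is deterministic given its seed. Loading-rate labels are
metadata only: the hyperelastic model is rate-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

from .constitutive import MaterialParams, StressStrainCurve, curve_predict
from .fitting import DEFAULT_CONSTRAINTS, expand_constraints

__all__ = [
    "RegionalPreset",
    "CurveGenSpec",
    "REGION_MEAN_VF",
    "regional_presets",
    "preset_by_name",
    "generate_curve",
    "generate_fiber_mask",
]

#: regional mean collagen fiber volume fractions (proportions) from the
#: five-section histology averages
REGION_MEAN_VF = {"neck": 0.60312, "middle": 0.63142, "apex": 0.51988}

#: published free triplets (c1, c3, c5) per region × tooth
_PRESET_TRIPLETS = {
    ("neck", "central"): (25.57, 9.76, -6.61),
    ("neck", "lateral"): (-7.13, 40.93, 55.60),
    ("middle", "central"): (24.30, -15.23, 18.00),
    ("middle", "lateral"): (35.33, -16.01, 20.90),
    ("apex", "central"): (8.12, 0.58, 1.69),
    ("apex", "lateral"): (8.31, 7.05, -4.27),
}


@dataclass(frozen=True)
class RegionalPreset:
    """A published regional coefficient set with its measured Vf."""

    region: str
    tooth: str
    params: MaterialParams

    @property
    def name(self) -> str:
        return f"{self.region}_{self.tooth}"

    @property
    def free(self) -> tuple[float, float, float]:
        return (self.params.c1, self.params.c3, self.params.c5)


def regional_presets() -> list[RegionalPreset]:
    """The six regional presets, dependent coefficients expanded exactly
    through the default affine constraints and Vf set to the regional
    histology mean."""
    presets = []
    for (region, tooth), (c1, c3, c5) in _PRESET_TRIPLETS.items():
        params = expand_constraints(
            (c1, c3, c5), DEFAULT_CONSTRAINTS, Vf=REGION_MEAN_VF[region]
        )
        presets.append(RegionalPreset(region=region, tooth=tooth, params=params))
    return presets


def preset_by_name(name: str) -> RegionalPreset:
    """Look up a preset by ``"<region>_<tooth>"``, e.g. ``"apex_central"``."""
    for preset in regional_presets():
        if preset.name == name:
            return preset
    valid = ", ".join(p.name for p in regional_presets())
    raise KeyError(f"unknown preset {name!r}; valid: {valid}")


def _default_grid() -> np.ndarray:
    return np.linspace(1.0, 1.20, 30)


@dataclass(frozen=True)
class CurveGenSpec:
    """Recipe for one synthetic tensile curve."""

    params: Union[MaterialParams, str]
    lam_grid: np.ndarray = field(default_factory=_default_grid)
    noise_sd: float = 0.01
    seed: Optional[int] = None
    region: str = ""
    tooth: str = ""
    rate: str = ""

    def __post_init__(self):
        grid = np.asarray(self.lam_grid, dtype=float)
        if grid.size == 0 or np.any(np.diff(grid) <= 0) or grid[0] < 1.0:
            raise ValueError("lam_grid must be strictly increasing from >= 1.0")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be non-negative, got {self.noise_sd}")
        object.__setattr__(self, "lam_grid", grid)

    def resolve_params(self) -> tuple[MaterialParams, str, str]:
        if isinstance(self.params, str):
            preset = preset_by_name(self.params)
            return preset.params, self.region or preset.region, self.tooth or preset.tooth
        return self.params, self.region, self.tooth


def generate_curve(spec: CurveGenSpec) -> StressStrainCurve:
    """Noise-free model curve plus seeded additive Gaussian stress noise.

    σᵢ = σ11(λᵢ) + εᵢ with εᵢ ~ N(0, noise_sd²); identical spec + seed
    reproduces the curve bitwise. Model overflow anywhere on the grid is
    reported with the offending stretch.
    """
    params, region, tooth = spec.resolve_params()
    clean = curve_predict(spec.lam_grid, params, region=region, tooth=tooth,
                          rate=spec.rate)
    stress = clean.stress
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        stress = stress + rng.normal(0.0, spec.noise_sd, size=stress.shape)
    return StressStrainCurve(
        stretch=clean.stretch, stress=stress,
        region=region, tooth=tooth, rate=spec.rate,
    )


def generate_fiber_mask(
    target_vf: float, shape: tuple[int, int], seed: Optional[int] = None
) -> np.ndarray:
    """Binary mask with exactly round(target_vf·h·w) fiber pixels.

    Pixels are placed by a seeded permutation of the flattened index space,
    so the measured fraction equals the rounded target exactly and the
    spatial arrangement is uniform-random (no fiber-bundle texture).
    """
    if not 0.0 <= target_vf <= 1.0:
        raise ValueError(f"target_vf must lie in [0, 1], got {target_vf}")
    h, w = (int(v) for v in shape)
    if h < 1 or w < 1 or h * w < 1:
        raise ValueError(f"mask shape must be at least 1x1, got {shape}")
    n_pixels = h * w
    n_fiber = int(round(target_vf * n_pixels))
    rng = np.random.default_rng(seed)
    flat = np.zeros(n_pixels, dtype=bool)
    flat[rng.permutation(n_pixels)[:n_fiber]] = True
    return flat.reshape(h, w)
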