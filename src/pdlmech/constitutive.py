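"""Two-phase exponential strain-energy model and closed-form uniaxial stress.

The PDL is modelled as an incompressible mixture of an isotropic matrix
phase (ground substance) and a fiber phase (collagen bundles aligned with
the loading axis), weighted by their volume fractions:

    W = Vm·c1·(e^{Q1} − 1) + Vf·c2·(e^{Q2} − 1)
    Q1 = c3·(I1 − 3)² + c4·(α − 1)⁴
    Q2 = c5·(I1 − 3)² + c6·(α − 1)⁴

with α = √I4 = λ the fiber elongation. c1, c2 carry stress units (MPa);
c3…c6 are dimensionless exponent coefficients. Under incompressible
uniaxial tension the Cauchy stress in the loading direction has the closed
form (the Lagrange pressure eliminated by σ22 = σ33 = 0):

    σ11 = (λ² − 1/λ)·[4·Vm·c1·e^{Q1}·c3·(I1−3) + 4·Vf·c2·e^{Q2}·c5·(I1−3)]
          + 4·c4·λ·(λ−1)³·Vm·c1·e^{Q1} + 4·c6·λ·(λ−1)³·Vf·c2·e^{Q2}

which is identical to λ·dW/dλ along the uniaxial path.

No sign restrictions are imposed on c1…c6: fitted coefficient sets for
real tissue include negative stress scales, and the model remains a valid
interpolant even where the energy is not globally convex. The
:func:`energy_diagnostics` helper reports negative-energy stretches
instead of forbidding such parameter sets.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "MaterialParams",
    "StressStrainCurve",
    "exponents",
    "strain_energy",
    "pressure_term",
    "cauchy_stress_uniaxial",
    "curve_predict",
    "energy_diagnostics",
]

#: |Q| beyond which exp(Q) is refused (double overflow is ~709)
OVERFLOW_LIMIT = 700.0


@dataclass(frozen=True)
class MaterialParams:
    """Coefficients of the two-phase exponential strain energy.

    Parameters
    ----------
    c1, c2 : float
        Matrix / fiber stress-scale coefficients, MPa.
    c3, c4 : float
        Matrix exponent coefficients (on (I1−3)² and (α−1)⁴), dimensionless.
    c5, c6 : float
        Fiber exponent coefficients, dimensionless.
    Vf : float
        Collagen fiber volume fraction, in [0, 1].
    Vm : float, optional
        Matrix fraction; defaults to 1 − Vf and must satisfy Vm + Vf = 1.
    """

    c1: float
    c2: float
    c3: float
    c4: float
    c5: float
    c6: float
    Vf: float
    Vm: Optional[float] = None

    def __post_init__(self):
        if not 0.0 <= self.Vf <= 1.0:
            raise ValueError(f"Vf must lie in [0, 1], got {self.Vf}")
        if self.Vm is None:
            object.__setattr__(self, "Vm", 1.0 - self.Vf)
        elif abs(self.Vm + self.Vf - 1.0) > 1e-9:
            raise ValueError(
                f"phase fractions must sum to 1: Vm={self.Vm}, Vf={self.Vf}"
            )

    def swapped_phases(self) -> "MaterialParams":
        """Exchange matrix and fiber roles; σ11 is invariant under this."""
        return replace(
            self, c1=self.c2, c2=self.c1, c3=self.c5, c5=self.c3,
            c4=self.c6, c6=self.c4, Vf=self.Vm, Vm=self.Vf,
        )


@dataclass(frozen=True)
class StressStrainCurve:
    """Paired (λ, σ11) samples from one specimen/condition.

    ``stretch`` must be strictly increasing with ``stretch[0] ≥ 1``;
    ``stress`` is Cauchy stress in MPa. Region/tooth/rate are metadata
    labels (the hyperelastic model itself is rate-independent).
    """

    stretch: np.ndarray
    stress: np.ndarray
    region: str = ""
    tooth: str = ""
    rate: str = ""

    def __post_init__(self):
        stretch = np.asarray(self.stretch, dtype=float)
        stress = np.asarray(self.stress, dtype=float)
        if stretch.shape != stress.shape or stretch.ndim != 1:
            raise ValueError("stretch and stress must be equal-length 1-D arrays")
        if stretch.size == 0:
            raise ValueError("empty curve")
        if np.any(np.diff(stretch) <= 0):
            raise ValueError("stretch must be strictly increasing")
        if stretch[0] < 1.0:
            raise ValueError(f"stretch must start at >= 1, got {stretch[0]}")
        if np.any(~np.isfinite(stretch)) or np.any(~np.isfinite(stress)):
            raise ValueError("curve contains non-finite values")
        object.__setattr__(self, "stretch", stretch)
        object.__setattr__(self, "stress", stress)

    def __len__(self) -> int:
        return self.stretch.size


def _q_terms(lam, p: MaterialParams):
    """Return (I1−3, (λ−1), Q1, Q2) for scalar or array λ."""
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0):
        raise ValueError(f"stretch must be positive, got {lam!r}")
    i1m3 = lam**2 + 2.0 / lam - 3.0
    am1 = lam - 1.0
    Q1 = p.c3 * i1m3**2 + p.c4 * am1**4
    Q2 = p.c5 * i1m3**2 + p.c6 * am1**4
    for name, Q in (("Q1", Q1), ("Q2", Q2)):
        bad = np.abs(Q) > OVERFLOW_LIMIT
        if np.any(bad):
            lam_bad = lam[bad] if lam.ndim else lam
            raise OverflowError(
                f"exponent {name} out of range at stretch {lam_bad} "
                f"(|{name}| > {OVERFLOW_LIMIT:g})"
            )
    return i1m3, am1, Q1, Q2


def exponents(lam, p: MaterialParams):
    """Exponent arguments (Q1, Q2) at stretch λ.

    Q1 = c3(I1−3)² + c4(λ−1)⁴ for the matrix phase, Q2 likewise with
    (c5, c6) for the fiber phase; both vanish at λ = 1.
    """
    _, _, Q1, Q2 = _q_terms(lam, p)
    if np.ndim(Q1) == 0:
        return float(Q1), float(Q2)
    return Q1, Q2


def strain_energy(lam, p: MaterialParams):
    """Strain-energy density W(λ) in MPa; W(1) = 0."""
    _, _, Q1, Q2 = _q_terms(lam, p)
    W = p.Vm * p.c1 * np.expm1(Q1) + p.Vf * p.c2 * np.expm1(Q2)
    return float(W) if np.ndim(W) == 0 else W


def pressure_term(lam, p: MaterialParams):
    """Lagrange pressure p(λ) enforcing incompressibility, MPa.

    This is exactly the multiplier that annihilates the lateral Cauchy
    stresses (σ22 = σ33 = 0):

        p = (1/λ)·[4·Vm·c1·e^{Q1}·c3·(I1−3) + 4·Vf·c2·e^{Q2}·c5·(I1−3)]
    """
    lam = np.asarray(lam, dtype=float)
    i1m3, _, Q1, Q2 = _q_terms(lam, p)
    bracket = 4.0 * i1m3 * (
        p.Vm * p.c1 * np.exp(Q1) * p.c3 + p.Vf * p.c2 * np.exp(Q2) * p.c5
    )
    out = bracket / lam
    return float(out) if np.ndim(out) == 0 else out


def cauchy_stress_uniaxial(lam, p: MaterialParams):
    """Closed-form axial Cauchy stress σ11(λ) in MPa.

    Equals λ·dW/dλ along the incompressible uniaxial path and the
    tensor-pipeline push-forward F·S·Fᵀ; σ11(1) = 0 for any parameters.
    Accepts scalar or array λ.
    """
    lam = np.asarray(lam, dtype=float)
    i1m3, am1, Q1, Q2 = _q_terms(lam, p)
    e1 = np.exp(Q1)
    e2 = np.exp(Q2)
    isotropic = (lam**2 - 1.0 / lam) * 4.0 * i1m3 * (
        p.Vm * p.c1 * e1 * p.c3 + p.Vf * p.c2 * e2 * p.c5
    )
    fiber = 4.0 * lam * am1**3 * (
        p.c4 * p.Vm * p.c1 * e1 + p.c6 * p.Vf * p.c2 * e2
    )
    sigma = isotropic + fiber
    return float(sigma) if np.ndim(sigma) == 0 else sigma


def curve_predict(
    lam_grid: Sequence[float],
    p: MaterialParams,
    region: str = "",
    tooth: str = "",
    rate: str = "",
) -> StressStrainCurve:
    """Model-predicted stress curve on a strictly increasing λ grid (λ ≥ 1)."""
    lam_grid = np.asarray(lam_grid, dtype=float)
    try:
        stress = cauchy_stress_uniaxial(lam_grid, p)
    except OverflowError as exc:
        raise OverflowError(f"model evaluation failed on grid: {exc}") from exc
    return StressStrainCurve(
        stretch=lam_grid, stress=np.atleast_1d(stress),
        region=region, tooth=tooth, rate=rate,
    )


def energy_diagnostics(p: MaterialParams, lam_grid=None) -> dict:
    """Report where W(λ) < 0 on a grid (possible with negative coefficients).

    Returns a dict with the grid fraction of negative-energy points and the
    most negative value; purely informational, never raises.
    """
    if lam_grid is None:
        lam_grid = np.linspace(1.0, 1.25, 101)
    W = strain_energy(lam_grid, p)
    W = np.atleast_1d(W)
    neg = W < 0
    return {
        "negative_fraction": float(np.mean(neg)),
        "min_energy_MPa": float(W.min()),
        "n_grid": int(W.size),
    }
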