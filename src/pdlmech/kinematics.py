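"""Kinematics of incompressible uniaxial tension.

The periodontal ligament (PDL) specimens are stretched along a single axis
(the collagen-fiber direction). Under the incompressibility assumption the
full deformation state is determined by the axial stretch ``λ`` alone:

* lateral stretches ``λ2 = λ3 = λ**(-1/2)`` so that ``det F = 1``,
* right Cauchy–Green tensor ``C = diag(λ², 1/λ, 1/λ)``,
* first invariant ``I1 = tr(C) = λ² + 2/λ``,
* fiber invariant ``I4 = N·C·N = λ²`` for fiber direction ``N = (1,0,0)``,
* fiber elongation ``α = √I4 = λ``.

Green strain ``ε`` and stretch are related by ``λ = (1 + 2ε)^(1/2)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "UniaxialState",
    "DeformationState",
    "stretch_from_green_strain",
    "green_strain_from_stretch",
    "uniaxial_deformation",
    "invariants_uniaxial",
]

#: fiber direction: collagen bundles align with the loading axis after preload
FIBER_DIRECTION = np.array([1.0, 0.0, 0.0])

#: tolerance for closed-form tensor consistency checks
TENSOR_TOL = 1e-12


@dataclass(frozen=True)
class UniaxialState:
    """Scalar kinematic state at one loading point.

    Attributes
    ----------
    stretch : float
        Principal stretch λ in the loading direction (dimensionless, > 0).
    green_strain : float
        Green strain ε = (λ² − 1)/2.
    I1 : float
        First invariant of C; equals λ² + 2/λ under incompressibility.
    I4 : float
        Fiber invariant N·C·N = λ².
    alpha : float
        Fiber elongation α = √I4 = λ.
    """

    stretch: float
    green_strain: float
    I1: float
    I4: float
    alpha: float


@dataclass(frozen=True)
class DeformationState:
    """Diagonal deformation tensors for uniaxial incompressible tension."""

    F: np.ndarray
    C: np.ndarray
    J: float
    N: np.ndarray = field(default_factory=lambda: FIBER_DIRECTION.copy())


def _validate_stretch(lam) -> np.ndarray:
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0):
        raise ValueError(f"stretch must be positive, got {lam!r}")
    return lam


def stretch_from_green_strain(eps):
    """Convert Green strain ε to stretch λ = (1 + 2ε)^(1/2).

    Accepts scalars or arrays. ε must exceed −0.5 (the non-physical
    collapse limit where 1 + 2ε ≤ 0).
    """
    eps = np.asarray(eps, dtype=float)
    if np.any(eps <= -0.5):
        raise ValueError(f"Green strain must exceed -0.5, got {eps!r}")
    lam = np.sqrt(1.0 + 2.0 * eps)
    return float(lam) if lam.ndim == 0 else lam


def green_strain_from_stretch(lam):
    """Inverse of :func:`stretch_from_green_strain`: ε = (λ² − 1)/2."""
    lam = _validate_stretch(lam)
    eps = 0.5 * (lam**2 - 1.0)
    return float(eps) if eps.ndim == 0 else eps


def uniaxial_deformation(lam: float) -> DeformationState:
    """Deformation state for axial stretch λ.

    F = diag(λ, λ^(−1/2), λ^(−1/2)) enforces det F = 1 exactly up to
    floating point; C = FᵀF is diagonal with entries (λ², 1/λ, 1/λ).
    """
    lam = float(_validate_stretch(lam))
    lat = lam ** (-0.5)
    F = np.diag([lam, lat, lat])
    C = F.T @ F
    return DeformationState(F=F, C=C, J=float(np.linalg.det(F)))


def invariants_uniaxial(lam: float) -> UniaxialState:
    """Invariants I1 = λ² + 2/λ and I4 = λ² at axial stretch λ.

    By the AM–GM inequality I1 ≥ 3 with equality only at λ = 1, so the
    undeformed state is the unique invariant minimum.
    """
    lam = float(_validate_stretch(lam))
    return UniaxialState(
        stretch=lam,
        green_strain=green_strain_from_stretch(lam),
        I1=lam**2 + 2.0 / lam,
        I4=lam**2,
        alpha=lam,
    )
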