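"""Independent re-derivations of the uniaxial Cauchy stress.

Three routes to σ11 that must agree:

1. the closed form in :mod:`pdlmech.constitutive` (this module does not
   re-use it, only checks against it),
2. the full continuum pipeline: energy partials ∂W/∂I1, ∂W/∂I4 → second
   Piola–Kirchhoff stress S = 2(∂W/∂I1)E + 2(∂W/∂I4)N⊗N − pC⁻¹ →
   push-forward σ = F·S·Fᵀ (J = 1),
3. a central finite difference of the path energy, σ11 = λ·dŴ/dλ.

Routes 1 and 2 are exact algebra and agree to ~1e−9 relative; route 3 is
O(h²) accurate. The lateral components of route 2 vanish identically —
that is the defining property of the pressure term.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constitutive import MaterialParams, cauchy_stress_uniaxial, exponents, pressure_term, strain_energy
from .kinematics import FIBER_DIRECTION, invariants_uniaxial, uniaxial_deformation

__all__ = [
    "Pk2Stress",
    "energy_partials",
    "second_pk_stress",
    "cauchy_via_tensor",
    "cauchy_via_finite_difference",
    "triangle_report",
]


@dataclass(frozen=True)
class Pk2Stress:
    """Second Piola–Kirchhoff stress S (diagonal, MPa) and pressure p (MPa)."""

    S: np.ndarray
    p: float


def energy_partials(lam: float, p: MaterialParams) -> tuple[float, float]:
    """(∂W/∂I1, ∂W/∂I4) at stretch λ, in MPa.

    ∂W/∂I1 = 2(I1−3)·[Vm c1 e^{Q1} c3 + Vf c2 e^{Q2} c5]
    ∂W/∂I4 = 2·I4^{−1/2}(√I4 − 1)³·[Vm c1 e^{Q1} c4 + Vf c2 e^{Q2} c6]
    """
    st = invariants_uniaxial(lam)
    Q1, Q2 = exponents(lam, p)
    e1, e2 = np.exp(Q1), np.exp(Q2)
    dW_dI1 = 2.0 * (st.I1 - 3.0) * (p.Vm * p.c1 * e1 * p.c3 + p.Vf * p.c2 * e2 * p.c5)
    root = np.sqrt(st.I4)
    dW_dI4 = (
        2.0 / root * (root - 1.0) ** 3
        * (p.Vm * p.c1 * e1 * p.c4 + p.Vf * p.c2 * e2 * p.c6)
    )
    return float(dW_dI1), float(dW_dI4)


def second_pk_stress(lam: float, params: MaterialParams) -> Pk2Stress:
    """S = 2(∂W/∂I1)·E + 2(∂W/∂I4)·N⊗N − p·C⁻¹ at stretch λ.

    C⁻¹ is formed analytically from the diagonal uniaxial C, so no matrix
    inversion tolerance enters the oracle.
    """
    dW_dI1, dW_dI4 = energy_partials(lam, params)
    press = pressure_term(lam, params)
    NN = np.outer(FIBER_DIRECTION, FIBER_DIRECTION)
    # diagonal C = (λ², 1/λ, 1/λ) ⇒ C⁻¹ = diag(1/λ², λ, λ)
    C_inv = np.diag([lam**-2, lam, lam])
    S = 2.0 * dW_dI1 * np.eye(3) + 2.0 * dW_dI4 * NN - press * C_inv
    return Pk2Stress(S=S, p=float(press))


def cauchy_via_tensor(lam: float, params: MaterialParams) -> float:
    """σ11 from the push-forward F·S·Fᵀ (J = 1)."""
    return float(full_cauchy_tensor(lam, params)[0, 0])


def full_cauchy_tensor(lam: float, params: MaterialParams) -> np.ndarray:
    """Full Cauchy tensor σ = F·S·Fᵀ; lateral entries vanish within 1e−9 MPa."""
    defo = uniaxial_deformation(lam)
    pk2 = second_pk_stress(lam, params)
    return defo.F @ pk2.S @ defo.F.T


def cauchy_via_finite_difference(
    lam: float, params: MaterialParams, h: float = 1e-6
) -> float:
    """σ11 ≈ λ·(W(λ+h) − W(λ−h))/(2h), second-order accurate in h.

    Valid for incompressible uniaxial tension where σ11 = λ·dŴ/dλ. The
    default step 1e−6 balances truncation against round-off for O(1 MPa)
    stresses in double precision.
    """
    if not 0.0 < h <= 1e-3:
        raise ValueError(f"step h must lie in (0, 1e-3], got {h}")
    if lam - h <= 0:
        raise ValueError(f"stretch - h must stay positive (lam={lam}, h={h})")
    Wp = strain_energy(lam + h, params)
    Wm = strain_energy(lam - h, params)
    return lam * (Wp - Wm) / (2.0 * h)


def triangle_report(
    params: MaterialParams,
    lam_grid=None,
    h: float = 1e-6,
) -> dict:
    """Pairwise agreement of the three σ11 routes over a stretch grid.

    Returns max relative discrepancies closed-vs-tensor, closed-vs-finite-
    difference, and the max |σ22|, |σ33| of the tensor route. Used by the
    ``verify`` CLI subcommand and the acceptance checks.
    """
    if lam_grid is None:
        lam_grid = np.linspace(1.001, 1.25, 25)
    worst_ct = worst_cf = worst_lat = 0.0
    for lam in np.asarray(lam_grid, dtype=float):
        closed = cauchy_stress_uniaxial(lam, params)
        sigma = full_cauchy_tensor(lam, params)
        fd = cauchy_via_finite_difference(lam, params, h=h)
        scale = max(abs(closed), 1e-12)
        worst_ct = max(worst_ct, abs(closed - sigma[0, 0]) / scale)
        worst_cf = max(worst_cf, abs(closed - fd) / scale)
        worst_lat = max(worst_lat, abs(sigma[1, 1]), abs(sigma[2, 2]))
    return {
        "max_rel_closed_vs_tensor": worst_ct,
        "max_rel_closed_vs_fd": worst_cf,
        "max_abs_lateral_stress_MPa": worst_lat,
        "n_grid": int(np.asarray(lam_grid).size),
    }
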