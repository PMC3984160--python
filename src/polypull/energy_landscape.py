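"""Closed-form dynamic force spectroscopy and landscape summaries.

The Bell-Evans-Ritchie (BER) model gives the most probable rupture force of
a single-barrier system under a constant loading rate nu::

    F(nu) = (k_BT / dx_u) * ln( nu * dx_u / (k_u0 * k_BT) )

so mean rupture force is linear in ln(nu) with slope k_BT/dx_u — the
deterministic counterpart to calibrating (k_u0, dx_u) by Monte Carlo.  The
barrier height follows from the Arrhenius relation dG = RT*ln(k_A/k_u0)
with attempt frequency k_A (1e9 1/s for protein folding dynamics), and a
harmonic approximation of the folded well gives its stiffness
k_s = 2*dG/dx_u^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import KCAL_PER_MOL_IN_J, Thermal, ROOM
from .pulling_simulator import SpeedForceDatum, TwoStateKinetics

__all__ = [
    "LandscapeSummary",
    "BERFit",
    "ber_mean_force",
    "fit_ber",
    "barrier_height",
    "potential_spring_constant",
    "summarize_landscape",
]

DEFAULT_ATTEMPT_FREQUENCY = 1e9  # 1/s


@dataclass(frozen=True)
class LandscapeSummary:
    """Two-state unfolding landscape: kinetics, barrier, and well stiffness."""

    kinetics: TwoStateKinetics
    barrier_kcal_mol: float
    attempt_frequency: float
    spring_constant_N_m: float


@dataclass(frozen=True)
class BERFit:
    """Result of a Bell-Evans-Ritchie regression of force on ln(loading rate)."""

    kinetics: TwoStateKinetics
    dx_u_se: float
    k_u0_se: float
    slope: float
    intercept: float


def ber_mean_force(loading_rate: float, kinetics: TwoStateKinetics, thermal: Thermal = ROOM) -> float:
    """Most probable rupture force at loading rate ``nu`` (pN/s), in pN.

    Clamped at 0 for sub-threshold loading rates (log argument < 1), where
    rupture occurs essentially spontaneously.
    """
    if not loading_rate > 0:
        raise ValueError(f"loading rate must be > 0, got {loading_rate}")
    arg = loading_rate * kinetics.dx_u / (kinetics.k_u0 * thermal.kT)
    return max(0.0, (thermal.kT / kinetics.dx_u) * np.log(arg))


def fit_ber(data: list[SpeedForceDatum], thermal: Thermal = ROOM) -> BERFit:
    """Extract (k_u0, dx_u) from mean rupture force vs loading rate.

    Ordinary least squares of mean force on ln(nu): the slope is k_BT/dx_u
    and the intercept fixes k_u0.  Standard errors are propagated by the
    delta method from the OLS covariance.
    """
    if len(data) < 3:
        raise ValueError("need data at >= 3 speeds")
    lnv = np.array([np.log(d.loading_rate) for d in data])
    F = np.array([d.mean_force for d in data])
    if np.ptp(lnv) == 0:
        raise ValueError("zero variance in ln(loading rate)")

    X = np.column_stack([lnv, np.ones_like(lnv)])
    coef, res, *_ = np.linalg.lstsq(X, F, rcond=None)
    a, b = coef
    if a <= 0:
        raise ValueError("non-positive slope: forces do not increase with loading rate")
    n = len(F)
    dof = max(n - 2, 1)
    resid = F - X @ coef
    s2 = float(resid @ resid) / dof
    cov = s2 * np.linalg.inv(X.T @ X)

    kT = thermal.kT
    dx = kT / a
    k_u0 = dx / (kT * np.exp(b / a))
    # delta method: dx = kT/a; ln k_u0 = -ln a - b/a
    ddx_da = -kT / a**2
    dx_se = abs(ddx_da) * np.sqrt(cov[0, 0])
    dlnk_da = -1.0 / a + b / a**2
    dlnk_db = -1.0 / a
    grad = np.array([dlnk_da, dlnk_db])
    lnk_se = float(np.sqrt(grad @ cov @ grad))
    return BERFit(
        kinetics=TwoStateKinetics(float(k_u0), float(dx)),
        dx_u_se=float(dx_se),
        k_u0_se=float(k_u0 * lnk_se),
        slope=float(a),
        intercept=float(b),
    )


def barrier_height(
    k_u0: float,
    k_A: float = DEFAULT_ATTEMPT_FREQUENCY,
    thermal: Thermal = ROOM,
) -> float:
    """Arrhenius barrier to unfolding, RT·ln(k_A/k_u0), in kcal/mol."""
    if not 0 < k_u0 <= k_A:
        raise ValueError(f"require 0 < k_u0 <= k_A, got k_u0={k_u0}, k_A={k_A}")
    return thermal.RT * np.log(k_A / k_u0)


def potential_spring_constant(barrier_kcal_mol: float, dx_u: float) -> float:
    """Stiffness of a harmonic folded well, k_s = 2*dG/dx_u^2, in N/m.

    ``barrier_kcal_mol`` is converted to joules per molecule and ``dx_u``
    (nm) to metres.
    """
    if barrier_kcal_mol < 0:
        raise ValueError("barrier must be >= 0")
    if not dx_u > 0:
        raise ValueError("dx_u must be > 0")
    dG_J = barrier_kcal_mol * KCAL_PER_MOL_IN_J
    dx_m = dx_u * 1e-9
    return 2.0 * dG_J / dx_m**2


def summarize_landscape(
    kinetics: TwoStateKinetics,
    k_A: float = DEFAULT_ATTEMPT_FREQUENCY,
    thermal: Thermal = ROOM,
    reference: "LandscapeSummary | None" = None,
    reference_loading_rate: float = 40000.0,
) -> LandscapeSummary | tuple[LandscapeSummary, dict]:
    """Compose barrier height and well stiffness into a landscape summary.

    With a ``reference`` summary (e.g. apo when summarizing holo), also
    returns the contrasts: change in dx_u, in barrier, and the BER force
    shift at ``reference_loading_rate``.
    """
    dG = barrier_height(kinetics.k_u0, k_A, thermal)
    summary = LandscapeSummary(
        kinetics=kinetics,
        barrier_kcal_mol=float(dG),
        attempt_frequency=k_A,
        spring_constant_N_m=potential_spring_constant(dG, kinetics.dx_u),
    )
    if reference is None:
        return summary
    contrasts = {
        "d_dx_u_nm": kinetics.dx_u - reference.kinetics.dx_u,
        "d_barrier_kcal_mol": summary.barrier_kcal_mol - reference.barrier_kcal_mol,
        "d_spring_constant_N_m": summary.spring_constant_N_m
        - reference.spring_constant_N_m,
        "force_shift_pN": ber_mean_force(reference_loading_rate, kinetics, thermal)
        - ber_mean_force(reference_loading_rate, reference.kinetics, thermal),
    }
    return summary, contrasts
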