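"""Worm-like chain (WLC) entropic elasticity.

The interpolation formula of Bustamante/Marko–Siggia relates the stretching
force on a semiflexible polymer to its fractional extension::

    F(x) = (k_BT / p) * [ 1/4 (1 - x/L_c)^-2 - 1/4 + x/L_c ]

with persistence length ``p`` and contour length ``L_c``.  Unfolding one
domain of a tandem polyprotein lengthens ``L_c`` by a fixed increment, which
is what the per-peak contour-length fits in this module measure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, curve_fit

from .constants import RISE_PER_RESIDUE_NM, Thermal, ROOM

__all__ = [
    "WLCParams",
    "wlc_force",
    "wlc_extension_at_force",
    "wlc_stiffness",
    "expected_contour_increment",
    "fit_wlc_contour",
    "WLCFitError",
]

#: Default persistence length for polyprotein stretches, nm.
DEFAULT_PERSISTENCE_NM = 0.4


@dataclass(frozen=True)
class WLCParams:
    """Persistence length and contour length of a worm-like chain, in nm."""

    persistence_length: float
    contour_length: float

    def __post_init__(self) -> None:
        if not self.persistence_length > 0:
            raise ValueError(f"persistence_length must be > 0, got {self.persistence_length}")
        if not self.contour_length > 0:
            raise ValueError(f"contour_length must be > 0, got {self.contour_length}")


class WLCFitError(RuntimeError):
    """Raised when a per-peak contour-length fit cannot converge."""


def _check_extension(extension: np.ndarray, contour_length: float) -> np.ndarray:
    x = np.asarray(extension, dtype=float)
    if np.any(~np.isfinite(x)) or np.any(x < 0):
        raise ValueError("extension must be finite and non-negative")
    if np.any(x >= contour_length):
        raise ValueError(
            f"extension must be < contour_length ({contour_length} nm); got max {np.max(x)}"
        )
    return x


def wlc_force(extension, params: WLCParams, thermal: Thermal = ROOM):
    """Entropic restoring force of a WLC at a given end-to-end extension.

    Parameters
    ----------
    extension : float or array-like
        End-to-end extension in nm, ``0 <= x < L_c``.

    Returns
    -------
    float or ndarray
        Force in pN; strictly increasing in extension and divergent as
        ``x -> L_c``.
    """
    x = _check_extension(extension, params.contour_length)
    z = x / params.contour_length
    f = (thermal.kT / params.persistence_length) * (0.25 / (1.0 - z) ** 2 - 0.25 + z)
    return f if np.ndim(extension) else float(f)


def wlc_extension_at_force(force: float, params: WLCParams, thermal: Thermal = ROOM) -> float:
    """Invert the WLC force law: extension (nm) at which the chain pulls back
    with the given force (pN).

    Solved by bracketed root-finding on ``[0, L_c(1 - 1e-12)]``; the force law
    is strictly increasing so the bracket is guaranteed.
    """
    if not np.isfinite(force):
        raise ValueError(f"force must be finite, got {force}")
    if force < 0:
        raise ValueError(f"force must be >= 0, got {force}")
    if force == 0.0:
        return 0.0
    L = params.contour_length
    hi = L * (1.0 - 1e-12)
    if wlc_force(hi, params, thermal) <= force:  # pragma: no cover - astronomically large F
        return hi
    x = brentq(
        lambda xx: wlc_force(xx, params, thermal) - force,
        0.0,
        hi,
        xtol=1e-15,
        rtol=1e-14,
    )
    return float(x)


def wlc_stiffness(extension, params: WLCParams, thermal: Thermal = ROOM):
    """Analytic derivative dF/dx of the WLC force law, in pN/nm.

    Approaches ``(3/2)·k_BT/(p·L_c)`` as ``x -> 0`` and diverges at full
    extension; used for loading-rate diagnostics.
    """
    x = _check_extension(extension, params.contour_length)
    z = x / params.contour_length
    k = (thermal.kT / (params.persistence_length * params.contour_length)) * (
        0.5 / (1.0 - z) ** 3 + 1.0
    )
    return k if np.ndim(extension) else float(k)


def expected_contour_increment(
    n_residues: int,
    nc_distance: float,
    rise_per_residue: float = RISE_PER_RESIDUE_NM,
) -> float:
    """Contour-length gain expected from unfolding one domain, in nm.

    A domain of ``n_residues`` contributes ``n_residues * rise_per_residue``
    of stretchable backbone once unfolded, minus the N-to-C distance it
    already spanned while folded.  For an 85-residue domain with a 1.5 nm
    folded N–C span this is 85*0.36 - 1.5 = 29.1 nm.
    """
    if not n_residues > 0:
        raise ValueError(f"n_residues must be > 0, got {n_residues}")
    if nc_distance < 0:
        raise ValueError(f"nc_distance must be >= 0, got {nc_distance}")
    stretched = n_residues * rise_per_residue
    if nc_distance >= stretched:
        raise ValueError(
            f"nc_distance ({nc_distance} nm) must be below the stretched length ({stretched} nm)"
        )
    return stretched - nc_distance


def fit_wlc_contour(
    points,
    persistence_length: float = DEFAULT_PERSISTENCE_NM,
    thermal: Thermal = ROOM,
) -> tuple[float, float]:
    """Least-squares fit of the WLC contour length to (extension, force) points.

    The persistence length is held fixed; only ``L_c`` is free, which is the
    standard choice for per-peak sawtooth fits where the data poorly
    constrain both parameters.

    Parameters
    ----------
    points : sequence of (extension_nm, force_pN)
        At least 5 points with positive forces.

    Returns
    -------
    (contour_length_nm, rms_residual_pN)
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 5:
        raise ValueError("need at least 5 (extension, force) points")
    x, f = pts[:, 0], pts[:, 1]
    if np.any(f <= 0):
        raise ValueError("forces must be positive for a WLC fit")

    x_max = float(np.max(x))

    def model(xx, lc):
        return wlc_force(xx, WLCParams(persistence_length, lc), thermal)

    # crude 1-D bracket scan for a starting value, then refine with curve_fit
    lo = x_max * (1.0 + 1e-9)
    grid = x_max / np.linspace(0.999, 0.05, 60)
    sse = [np.sum((model(x, lc) - f) ** 2) for lc in grid]
    lc0 = float(grid[int(np.argmin(sse))])
    try:
        popt, _ = curve_fit(
            model, x, f, p0=[max(lc0, lo * (1 + 1e-6))], bounds=(lo, np.inf), maxfev=2000
        )
    except (RuntimeError, ValueError) as exc:
        raise WLCFitError(f"WLC contour-length fit failed to converge: {exc}") from exc
    lc = float(popt[0])
    rms = float(np.sqrt(np.mean((model(x, lc) - f) ** 2)))
    return lc, rms
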