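"""Reference parameter sets for apo and Ca2+-bound (holo) M-crystallin.

The Monte Carlo calibration constrains the spontaneous unfolding rate only
to a range (fits of mean, mean-SD and mean+SD forces); a single
representative k_u0 is taken as the geometric mean of that range, the
natural point estimate for a log-scale parameter.
"""

from __future__ import annotations

import math

from .binding_thermo import SiteThermo
from .pulling_simulator import TandemConstruct, TwoStateKinetics

__all__ = [
    "APO_MC_KU0_RANGE",
    "HOLO_MC_KU0_RANGE",
    "apo_kinetics",
    "holo_kinetics",
    "octamer_construct",
    "octamer_binding_sites",
    "monomer_binding_sites",
]

#: Monte Carlo k_u0 range for apo M-crystallin, 1/s (upper, lower fits).
APO_MC_KU0_RANGE = (1.0e-4, 1.1e-2)
#: Monte Carlo k_u0 range for holo M-crystallin, 1/s.
HOLO_MC_KU0_RANGE = (5.0e-4, 1.1e-2)

APO_DX_U_NM = 0.55
HOLO_DX_U_NM = 0.38

#: Contour-length increment per unfolding event: 85 aa x 0.36 nm - 1.5 nm.
DELTA_LC_NM = 29.1
#: Folded N-C span per domain, from the NMR structure.
FOLDED_NC_NM = 1.5
N_DOMAINS = 8


def geometric_mean(lo: float, hi: float) -> float:
    return math.sqrt(lo * hi)


def apo_kinetics() -> TwoStateKinetics:
    """Representative apo landscape: dx_u = 0.55 nm, k_u0 ~ 1.05e-3 1/s."""
    return TwoStateKinetics(geometric_mean(*APO_MC_KU0_RANGE), APO_DX_U_NM)


def holo_kinetics() -> TwoStateKinetics:
    """Representative holo landscape: dx_u = 0.38 nm, k_u0 ~ 2.35e-3 1/s."""
    return TwoStateKinetics(geometric_mean(*HOLO_MC_KU0_RANGE), HOLO_DX_U_NM)


def octamer_construct(persistence_length: float = 0.4) -> TandemConstruct:
    """The 8-domain construct: dLc = 29.1 nm, folded contour 8 x 1.5 nm."""
    return TandemConstruct(
        n_domains=N_DOMAINS,
        delta_Lc=DELTA_LC_NM,
        initial_Lc=N_DOMAINS * FOLDED_NC_NM,
        persistence_length=persistence_length,
    )


def octamer_binding_sites() -> tuple[SiteThermo, SiteThermo]:
    """Ca2+ sites of the octamer: K_d ~ 31 uM / 166 uM, both enthalpy-driven
    at site I (dH1 = -8.5 kcal/mol) and partly entropy-driven at site II."""
    return (
        SiteThermo(K_d=31e-6, dH=-8.5, dS=-7.9, dG=-6.2),
        SiteThermo(K_d=166e-6, dH=-3.2, dS=6.6, dG=-5.2),
    )


def monomer_binding_sites() -> tuple[SiteThermo, SiteThermo]:
    """Ca2+ sites of the monomer: K_d ~ 31 uM / 200 uM."""
    return (
        SiteThermo(K_d=31e-6, dH=-7.7, dS=-5.2, dG=-6.2),
        SiteThermo(K_d=200e-6, dH=-3.2, dS=6.2, dG=-5.0),
    )
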