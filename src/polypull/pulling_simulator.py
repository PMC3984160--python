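"""Monte Carlo simulation of constant-velocity pulling of a tandem polyprotein.

An N-domain construct is stretched between a surface and a Hookean cantilever
moving at constant speed.  The unfolded chain is a worm-like chain whose
contour length grows by one increment per unfolding event; each folded domain
escapes over a single barrier with the force-activated Bell rate

    k_u(F) = k_u0 * exp(F * dx_u / k_BT).

At each time step the equilibrium force is solved from the series coupling of
chain and cantilever, the unfolding probability P_u = N_f * k_u(F) * dt is
compared with a uniform random number, and on unfolding the contour length is
incremented and the folded count decremented, until every domain has unfolded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import Thermal, ROOM
from .polymer_elasticity import WLCParams, wlc_force, wlc_stiffness

__all__ = [
    "TwoStateKinetics",
    "TandemConstruct",
    "PullingProtocol",
    "RuptureEvent",
    "SimulatedTrace",
    "SpeedForceDatum",
    "EnsembleResult",
    "SimulationError",
    "bell_rate",
    "equilibrium_force",
    "simulate_pull",
    "simulate_ensemble",
    "mean_force_vs_speed",
    "fit_landscape_mc",
]

#: Cap on the Bell exponent; beyond this the rate is astronomically large and
#: the evaluation is flagged rather than overflowing.
_EXP_CAP = 700.0


class SimulationError(RuntimeError):
    """Raised when a pulling simulation cannot proceed (force cap, no root)."""


@dataclass(frozen=True)
class TwoStateKinetics:
    """Two-state unfolding landscape: spontaneous rate and barrier distance.

    Attributes
    ----------
    k_u0 : float
        Spontaneous (zero-force) unfolding rate, 1/s.
    dx_u : float
        Distance from the native state to the unfolding transition state
        along the pulling coordinate, nm.
    """

    k_u0: float
    dx_u: float

    def __post_init__(self) -> None:
        if not self.k_u0 > 0:
            raise ValueError(f"k_u0 must be > 0, got {self.k_u0}")
        if not self.dx_u > 0:
            raise ValueError(f"dx_u must be > 0, got {self.dx_u}")


@dataclass(frozen=True)
class TandemConstruct:
    """Geometry of the tandem repeat being pulled.

    ``initial_Lc`` is the contour length presented by the fully folded
    construct (folded N–C spans plus linkers); each unfolding event adds
    ``delta_Lc``.  ``initial_Lc = 0`` denotes a rigid attachment with no
    compliant chain, useful for analytic limits.
    """

    n_domains: int = 8
    delta_Lc: float = 29.1
    initial_Lc: float = 12.0
    persistence_length: float = 0.4

    def __post_init__(self) -> None:
        if self.n_domains < 1:
            raise ValueError(f"n_domains must be >= 1, got {self.n_domains}")
        if not self.delta_Lc > 0:
            raise ValueError(f"delta_Lc must be > 0, got {self.delta_Lc}")
        if self.initial_Lc < 0:
            raise ValueError(f"initial_Lc must be >= 0, got {self.initial_Lc}")
        if not self.persistence_length > 0:
            raise ValueError("persistence_length must be > 0")


@dataclass(frozen=True)
class PullingProtocol:
    """Constant-velocity pulling protocol and time-step policy.

    The default step is ``min(dt_max, max_step_nm / speed)``; whenever the
    per-step unfolding probability would exceed ``max_pu`` the step is
    refined so the first-order hazard rule stays accurate.
    """

    speed: float
    cantilever_k: float = 40.0
    dt_max: float = 1e-4
    max_step_nm: float = 0.1
    max_pu: float = 0.05
    max_force: float = 1000.0
    compliant_cantilever: bool = True

    def __post_init__(self) -> None:
        if not self.speed > 0:
            raise ValueError(f"speed must be > 0, got {self.speed}")
        if not self.cantilever_k > 0:
            raise ValueError("cantilever_k must be > 0")
        if not self.dt_max > 0:
            raise ValueError("dt_max must be > 0")
        if not 0 < self.max_pu <= 1:
            raise ValueError("max_pu must be in (0, 1]")

    @property
    def loading_rate(self) -> float:
        """Nominal loading rate speed × cantilever stiffness, pN/s."""
        return self.speed * self.cantilever_k


@dataclass(frozen=True)
class RuptureEvent:
    force: float
    extension: float
    time: float
    peak_index: int


@dataclass
class SimulatedTrace:
    """One simulated pull: sampled mechanics plus the rupture-event ladder."""

    base_position: np.ndarray
    extension: np.ndarray
    force: np.ndarray
    n_folded: np.ndarray
    rupture_events: list[RuptureEvent]
    metadata: dict = field(default_factory=dict)
    aborted: bool = False
    rate_capped: bool = False


@dataclass(frozen=True)
class SpeedForceDatum:
    """Pooled rupture-force statistics at one pulling speed."""

    speed: float
    loading_rate: float
    mean_force: float
    sd_force: float
    n_events: int

    def __post_init__(self) -> None:
        if self.n_events < 1:
            raise ValueError("n_events must be >= 1")
        if self.sd_force < 0:
            raise ValueError("sd_force must be >= 0")


@dataclass
class EnsembleResult:
    datum: SpeedForceDatum
    forces: np.ndarray
    histogram: tuple[np.ndarray, np.ndarray]
    per_peak_means: np.ndarray
    events: list[list[RuptureEvent]]
    traces: list[SimulatedTrace] | None = None
    rate_capped: bool = False


def bell_rate(force, kinetics: TwoStateKinetics, thermal: Thermal = ROOM):
    """Force-activated unfolding rate k_u0·exp(F·dx_u/k_BT), 1/s.

    The exponent is capped at 700 to avoid overflow; callers that need to
    know whether the cap engaged should check the exponent themselves (the
    simulator flags such traces).
    """
    f = np.asarray(force, dtype=float)
    if np.any(f < 0):
        raise ValueError("force must be >= 0")
    expo = np.minimum(f * kinetics.dx_u / thermal.kT, _EXP_CAP)
    r = kinetics.k_u0 * np.exp(expo)
    return r if np.ndim(force) else float(r)


def equilibrium_force(
    base_position: float,
    current_Lc: float,
    construct: TandemConstruct,
    protocol: PullingProtocol,
    thermal: Thermal = ROOM,
) -> tuple[float, float]:
    """Force and chain extension at a cantilever base position.

    Solves the series-compliance balance ``base = x + F/k_c`` with
    ``F = wlc_force(x)`` by bracketed root-finding.  In the rigid-cantilever
    limit the extension equals the base position.
    """
    from scipy.optimize import brentq

    if base_position < 0:
        raise ValueError("base_position must be >= 0")
    if base_position == 0.0:
        return 0.0, 0.0
    if current_Lc == 0.0:
        return protocol.cantilever_k * base_position, 0.0
    params = WLCParams(construct.persistence_length, current_Lc)
    if not protocol.compliant_cantilever:
        if base_position >= current_Lc:
            raise SimulationError("base position beyond contour length with rigid cantilever")
        return wlc_force(base_position, params, thermal), base_position

    kc = protocol.cantilever_k

    def g(x):
        return x + wlc_force(x, params, thermal) / kc - base_position

    hi = min(base_position, current_Lc * (1.0 - 1e-12))
    if g(hi) < 0:
        raise SimulationError("no equilibrium root in bracket")
    x = brentq(g, 0.0, hi, xtol=1e-13, rtol=1e-12)
    return float(wlc_force(x, params, thermal)), float(x)


def _solve_forces(
    x: np.ndarray,
    base: float,
    Lc: np.ndarray,
    p: float,
    kc: float,
    kT: float,
    compliant: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized equilibrium solve, warm-started from the previous extension.

    Newton iteration on g(x) = x + F_wlc(x)/kc - base, safeguarded to stay
    inside [0, Lc).  g' = 1 + k_wlc/kc > 1, so convergence is fast from any
    warm start.
    """
    rigid_chain = Lc == 0.0
    if not compliant:
        if np.any(base >= Lc[~rigid_chain] * (1 - 1e-9)):
            raise SimulationError("base position beyond contour length with rigid cantilever")
        xx = np.where(rigid_chain, 0.0, base)
        z = np.where(rigid_chain, 0.0, xx / np.maximum(Lc, 1e-300))
        F = (kT / p) * (0.25 / (1.0 - z) ** 2 - 0.25 + z)
        return np.where(rigid_chain, kc * base, F), xx

    hi = Lc * (1.0 - 1e-9)
    xx = np.clip(x, 0.0, np.maximum(hi, 0.0))
    safe_Lc = np.maximum(Lc, 1e-300)
    for _ in range(60):
        z = xx / safe_Lc
        F = (kT / p) * (0.25 / (1.0 - z) ** 2 - 0.25 + z)
        g = xx + F / kc - base
        g = np.where(rigid_chain, 0.0, g)
        if np.all(np.abs(g) < 1e-10 * max(1.0, base)):
            break
        kw = (kT / (p * safe_Lc)) * (0.5 / (1.0 - z) ** 3 + 1.0)
        step = g / (1.0 + kw / kc)
        xx = np.clip(xx - step, 0.0, hi)
    z = xx / safe_Lc
    F = (kT / p) * (0.25 / (1.0 - z) ** 2 - 0.25 + z)
    F = np.where(rigid_chain, kc * base, F)
    xx = np.where(rigid_chain, 0.0, xx)
    return F, xx


def _simulate_batch(
    construct: TandemConstruct,
    kinetics: TwoStateKinetics,
    protocol: PullingProtocol,
    thermal: Thermal,
    n_traces: int,
    rng: np.random.Generator,
    record: bool = False,
    tail_nm: float = 2.0,
):
    """Run ``n_traces`` pulls in lock-step on a shared base-position schedule.

    The global time step adapts to the fastest-unfolding trace so that
    P_u <= max_pu everywhere; inactive traces simply stop accumulating
    hazard.  Returns per-trace event lists plus (optionally) full sampled
    traces.
    """
    kT = thermal.kT
    p = construct.persistence_length
    kc = protocol.cantilever_k
    dLc = construct.delta_Lc
    beta_dx = kinetics.dx_u / kT

    Lc = np.full(n_traces, float(construct.initial_Lc))
    nf = np.full(n_traces, construct.n_domains, dtype=int)
    x = np.zeros(n_traces)
    F = np.zeros(n_traces)
    aborted = np.zeros(n_traces, dtype=bool)
    capped = np.zeros(n_traces, dtype=bool)
    events: list[list[RuptureEvent]] = [[] for _ in range(n_traces)]

    base = 0.0
    t = 0.0
    dt_base = min(protocol.dt_max, protocol.max_step_nm / protocol.speed)
    dt_min = 1e-9
    tail_time = tail_nm / protocol.speed

    rec_base: list[float] = []
    rec_x: list[np.ndarray] = []
    rec_F: list[np.ndarray] = []
    rec_nf: list[np.ndarray] = []
    end_time = np.full(n_traces, np.inf)

    # hard stop: base travel past the fully unfolded contour plus tail
    final_Lc = construct.initial_Lc + construct.n_domains * dLc
    base_stop = final_Lc + protocol.max_force / kc + tail_nm

    while True:
        active = (nf > 0) & ~aborted
        if not np.any(active):
            if not record or t >= np.max(end_time[~aborted], initial=0.0):
                break
        if base > base_stop:
            aborted |= active
            break

        # adaptive step: keep the hazard per step below max_pu with margin
        expo = np.minimum(F * beta_dx, _EXP_CAP)
        rate = nf * kinetics.k_u0 * np.exp(expo)
        max_rate = np.max(rate[active], initial=0.0)
        dt = dt_base if max_rate <= 0 else min(dt_base, 0.5 * protocol.max_pu / max_rate)
        dt = max(dt, dt_min)

        base += protocol.speed * dt
        t += dt
        F, x = _solve_forces(x, base, Lc, p, kc, kT, protocol.compliant_cantilever)

        over = active & (F > protocol.max_force)
        if np.any(over):
            aborted |= over
            active &= ~over

        expo = F * beta_dx
        capped |= active & (expo > _EXP_CAP)
        rate = nf * kinetics.k_u0 * np.exp(np.minimum(expo, _EXP_CAP))
        pu = np.clip(rate * dt, 0.0, 1.0)
        u = rng.random(n_traces)
        rupture = active & (u < pu)

        if record:
            # pre-rupture state: the trace must contain the force apex
            rec_base.append(base)
            rec_x.append(x.copy())
            rec_F.append(F.copy())
            rec_nf.append(nf.copy())

        if np.any(rupture):
            idx = np.flatnonzero(rupture)
            for i in idx:
                peak = construct.n_domains - nf[i] + 1
                events[i].append(RuptureEvent(float(F[i]), float(x[i]), t, int(peak)))
            nf[idx] -= 1
            Lc[idx] += dLc
            done = idx[nf[idx] == 0]
            end_time[done] = t + tail_time
            # relax the ruptured traces onto the longer chain immediately
            F, x = _solve_forces(x, base, Lc, p, kc, kT, protocol.compliant_cantilever)

        if record and np.all((nf == 0) | aborted) and t >= np.max(end_time[~aborted], initial=0.0):
            break

    traces = None
    if record:
        rb = np.asarray(rec_base)
        rx = np.asarray(rec_x)
        rf = np.asarray(rec_F)
        rn = np.asarray(rec_nf)
        times = np.cumsum(np.diff(rb, prepend=0.0)) / protocol.speed
        traces = []
        for i in range(n_traces):
            stop = np.searchsorted(times, end_time[i], side="right") if np.isfinite(end_time[i]) else len(rb)
            traces.append(
                SimulatedTrace(
                    base_position=rb[:stop].copy(),
                    extension=rx[:stop, i].copy(),
                    force=rf[:stop, i].copy(),
                    n_folded=rn[:stop, i].copy(),
                    rupture_events=events[i],
                    metadata={
                        "speed_nm_s": protocol.speed,
                        "cantilever_k_pN_nm": kc,
                        "k_u0_s": kinetics.k_u0,
                        "dx_u_nm": kinetics.dx_u,
                    },
                    aborted=bool(aborted[i]),
                    rate_capped=bool(capped[i]),
                )
            )
    return events, traces, aborted, capped


def simulate_pull(
    construct: TandemConstruct,
    kinetics: TwoStateKinetics,
    protocol: PullingProtocol,
    thermal: Thermal = ROOM,
    rng_seed: int | np.random.SeedSequence = 0,
) -> SimulatedTrace:
    """Simulate a single constant-velocity pull and return the full trace.

    The trace records base position, chain extension, force and folded count
    at every step, ends a short tail past the final rupture, and carries the
    rupture-event ladder.  An ``aborted`` trace hit the protocol force cap
    before all domains unfolded (e.g. vanishing kinetics).
    """
    rng = np.random.default_rng(rng_seed)
    _, traces, _, _ = _simulate_batch(
        construct, kinetics, protocol, thermal, 1, rng, record=True
    )
    trace = traces[0]
    trace.metadata["seed"] = rng_seed if isinstance(rng_seed, int) else None
    return trace


def simulate_ensemble(
    construct: TandemConstruct,
    kinetics: TwoStateKinetics,
    protocol: PullingProtocol,
    thermal: Thermal = ROOM,
    n_traces: int = 100,
    rng_seed: int | np.random.SeedSequence = 0,
    record: bool = False,
    bins: int = 30,
) -> EnsembleResult:
    """Simulate many pulls and pool their rupture forces.

    Returns pooled mean/SD/count, a force histogram, and per-peak-index mean
    forces (peak 1 = first domain to unfold).
    """
    if n_traces < 1:
        raise ValueError("n_traces must be >= 1")
    rng = np.random.default_rng(rng_seed)
    events, traces, aborted, capped = _simulate_batch(
        construct, kinetics, protocol, thermal, n_traces, rng, record=record
    )
    if np.any(aborted):
        raise SimulationError(
            f"{int(np.sum(aborted))}/{n_traces} traces hit the force cap "
            f"({protocol.max_force} pN) before completing"
        )
    forces = np.array([ev.force for evs in events for ev in evs])
    peaks = np.array([ev.peak_index for evs in events for ev in evs])
    counts, edges = np.histogram(forces, bins=bins)
    per_peak = np.array(
        [forces[peaks == k].mean() for k in range(1, construct.n_domains + 1)]
    )
    datum = SpeedForceDatum(
        speed=protocol.speed,
        loading_rate=protocol.loading_rate,
        mean_force=float(forces.mean()),
        sd_force=float(forces.std(ddof=1)) if forces.size > 1 else 0.0,
        n_events=int(forces.size),
    )
    return EnsembleResult(
        datum=datum,
        forces=forces,
        histogram=(counts, edges),
        per_peak_means=per_peak,
        events=events,
        traces=traces,
        rate_capped=bool(np.any(capped)),
    )


def mean_force_vs_speed(
    construct: TandemConstruct,
    kinetics: TwoStateKinetics,
    protocol_template: PullingProtocol,
    speeds,
    thermal: Thermal = ROOM,
    n_traces: int = 100,
    rng_seed: int | np.random.SeedSequence = 0,
) -> list[SpeedForceDatum]:
    """Pooled mean rupture force at each pulling speed (one datum per speed)."""
    from dataclasses import replace

    speeds = list(speeds)
    if any(s <= 0 for s in speeds):
        raise ValueError("speeds must be positive")
    seeds = np.random.SeedSequence(rng_seed).spawn(len(speeds))
    out = []
    for speed, seed in zip(speeds, seeds):
        protocol = replace(protocol_template, speed=speed)
        res = simulate_ensemble(
            construct, kinetics, protocol, thermal, n_traces=n_traces, rng_seed=seed
        )
        out.append(res.datum)
    return out


def fit_landscape_mc(
    observed: list[SpeedForceDatum],
    construct: TandemConstruct,
    protocol_template: PullingProtocol,
    thermal: Thermal = ROOM,
    k_u0_grid=None,
    dx_u_grid=None,
    n_traces: int = 50,
    rng_seed: int | np.random.SeedSequence = 0,
) -> tuple[TwoStateKinetics, float, bool]:
    """Grid calibration of (k_u0, dx_u) against observed mean forces.

    For every grid pair the ensemble is re-simulated at the observed speeds
    with common random numbers and scored by the sum of squared differences
    of mean forces.  Returns the best kinetics, the objective value, and a
    flag that is True when the optimum sits on the grid boundary (the grid
    then fails to bracket the optimum).
    """
    if len(observed) < 3:
        raise ValueError("need data at >= 3 speeds")
    if k_u0_grid is None:
        k_u0_grid = np.logspace(-5, -1, 9)
    if dx_u_grid is None:
        dx_u_grid = np.linspace(0.2, 0.9, 8)
    k_u0_grid = np.asarray(k_u0_grid, dtype=float)
    dx_u_grid = np.asarray(dx_u_grid, dtype=float)
    speeds = [d.speed for d in observed]
    target = np.array([d.mean_force for d in observed])

    best = None
    best_obj = np.inf
    for ku in k_u0_grid:
        for dx in dx_u_grid:
            kin = TwoStateKinetics(ku, dx)
            try:
                data = mean_force_vs_speed(
                    construct, kin, protocol_template, speeds, thermal,
                    n_traces=n_traces, rng_seed=rng_seed,
                )
            except SimulationError:
                continue
            obj = float(np.sum((np.array([d.mean_force for d in data]) - target) ** 2))
            if obj < best_obj:
                best_obj = obj
                best = kin
    if best is None:
        raise SimulationError("no grid point produced a complete ensemble")
    on_boundary = (
        best.k_u0 in (k_u0_grid[0], k_u0_grid[-1])
        or best.dx_u in (dx_u_grid[0], dx_u_grid[-1])
    )
    return best, best_obj, bool(on_boundary)
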