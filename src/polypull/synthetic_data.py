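"""Synthetic noisy data emulating the raw experimental inputs.

The simulator produces ideal mechanics; this module dresses them with the
artifacts an AFM actually records — Gaussian force noise, slow baseline
drift, an optional non-specific adhesion bump at small extension — and
likewise adds proportional noise to modelled ITC thermograms.  Every
generator carries the ground truth along in metadata/manifests so detection
and fitting can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import yaml

from .binding_thermo import ITCExperiment, ITCThermogram, SiteThermo, sequential_heats
from .constants import Thermal, ROOM
from .pulling_simulator import (
    PullingProtocol,
    SimulatedTrace,
    TandemConstruct,
    TwoStateKinetics,
    simulate_ensemble,
)
from .trace_analysis import ForceExtensionTrace
from . import io as _io

__all__ = ["NoiseModel", "synthesize_trace", "synthesize_experiment", "synthesize_itc"]


@dataclass(frozen=True)
class NoiseModel:
    """Instrument-noise description for synthetic force-extension traces.

    force_noise_sd : i.i.d. Gaussian force noise, pN (AFM thermal noise).
    baseline_drift : linear baseline in pN per nm of extension.
    adhesion_peak  : optional (amplitude_pN, decay_nm) exponential bump at
                     small extension mimicking non-specific surface adhesion.
    """

    force_noise_sd: float = 5.0
    baseline_drift: float = 0.0
    adhesion_peak: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.force_noise_sd < 0 or abs(self.baseline_drift) < 0:
            raise ValueError("noise magnitudes must be non-negative")
        if self.adhesion_peak is not None and (
            self.adhesion_peak[0] < 0 or self.adhesion_peak[1] <= 0
        ):
            raise ValueError("adhesion peak needs amplitude >= 0 and decay > 0")


def synthesize_trace(
    simulated: SimulatedTrace,
    noise: NoiseModel,
    rng_seed: int | np.random.SeedSequence | np.random.Generator = 0,
) -> ForceExtensionTrace:
    """Overlay instrument noise on a simulated trace.

    The true rupture ladder is preserved in ``metadata['true_events']`` so
    round-trip tests can score detection exactly.
    """
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    force = simulated.force.copy()
    x = simulated.extension
    if noise.force_noise_sd > 0:
        force = force + rng.normal(0.0, noise.force_noise_sd, size=force.shape)
    if noise.baseline_drift != 0.0:
        force = force + noise.baseline_drift * x
    if noise.adhesion_peak is not None:
        amp, decay = noise.adhesion_peak
        force = force + amp * np.exp(-x / decay)
    meta = dict(simulated.metadata)
    meta["true_events"] = [
        {"force_pN": ev.force, "extension_nm": ev.extension, "peak_index": ev.peak_index}
        for ev in simulated.rupture_events
    ]
    return ForceExtensionTrace(extension=x.copy(), force=force, metadata=meta)


def synthesize_experiment(
    kinetics: TwoStateKinetics,
    construct: TandemConstruct,
    speeds,
    n_traces_per_speed: int,
    noise: NoiseModel,
    out_dir,
    protocol_template: PullingProtocol | None = None,
    thermal: Thermal = ROOM,
    rng_seed: int = 0,
) -> Path:
    """Write a desk-scale replica of a speed-dependence dataset.

    One TSV per trace plus a YAML manifest recording the truth kinetics and
    per-trace true event ladders.  Returns the manifest path.
    """
    speeds = list(speeds)
    if n_traces_per_speed < 1:
        raise ValueError("n_traces_per_speed must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if protocol_template is None:
        protocol_template = PullingProtocol(speed=1000.0)

    root = np.random.SeedSequence(rng_seed)
    sim_seeds = root.spawn(len(speeds))
    noise_rng = np.random.default_rng(root.spawn(1)[0])

    manifest = {
        "truth": {"k_u0_s": kinetics.k_u0, "dx_u_nm": kinetics.dx_u},
        "construct": {
            "n_domains": construct.n_domains,
            "delta_Lc_nm": construct.delta_Lc,
            "initial_Lc_nm": construct.initial_Lc,
            "persistence_length_nm": construct.persistence_length,
        },
        "cantilever_k_pN_nm": protocol_template.cantilever_k,
        "noise": {
            "force_noise_sd_pN": noise.force_noise_sd,
            "baseline_drift_pN_per_nm": noise.baseline_drift,
        },
        "rng_seed": rng_seed,
        "traces": [],
    }
    for speed, seed in zip(speeds, sim_seeds):
        protocol = replace(protocol_template, speed=speed)
        result = simulate_ensemble(
            construct, kinetics, protocol, thermal,
            n_traces=n_traces_per_speed, rng_seed=seed, record=True,
        )
        for j, sim in enumerate(result.traces):
            trace = synthesize_trace(sim, noise, noise_rng)
            name = f"trace_v{speed:g}_{j:03d}.tsv"
            meta = {k: v for k, v in trace.metadata.items() if k != "true_events"}
            _io.write_trace_tsv(
                out_dir / name,
                trace.extension,
                trace.force,
                metadata=meta,
                base_position=sim.base_position,
                n_folded=sim.n_folded,
            )
            manifest["traces"].append(
                {
                    "file": name,
                    "speed_nm_s": float(speed),
                    "true_events": trace.metadata["true_events"],
                }
            )
    manifest_path = out_dir / "manifest.yaml"
    with open(manifest_path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return manifest_path


def synthesize_itc(
    sites: tuple[SiteThermo, SiteThermo],
    experiment: ITCExperiment,
    noise_sd_fraction: float = 0.02,
    rng_seed: int | np.random.SeedSequence = 0,
) -> ITCThermogram:
    """Model thermogram plus Gaussian noise scaled to the largest heat."""
    if noise_sd_fraction < 0:
        raise ValueError("noise_sd_fraction must be >= 0")
    rng = np.random.default_rng(rng_seed)
    gram = sequential_heats(sites, experiment)
    scale = noise_sd_fraction * float(np.max(np.abs(gram.heats_ucal)))
    heats = gram.heats_ucal + (rng.normal(0.0, scale, size=gram.heats_ucal.shape) if scale else 0.0)
    return ITCThermogram(
        heats_ucal=heats,
        molar_ratio=gram.molar_ratio,
        metadata={
            **gram.metadata,
            "noise_sd_fraction": noise_sd_fraction,
            "truth": {
                "K_d1_M": sites[0].K_d,
                "K_d2_M": sites[1].K_d,
                "dH1_kcal_mol": sites[0].dH,
                "dH2_kcal_mol": sites[1].dH,
            },
        },
    )
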