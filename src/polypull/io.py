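"""Plain-text file dialects used across the pipeline.

Traces are TSV with '#'-prefixed ``key: value`` metadata lines and the
columns base_position_nm, extension_nm, force_pN, n_folded.  Events, speed
series and ITC thermograms are small CSVs.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .binding_thermo import ITCThermogram
from .pulling_simulator import SpeedForceDatum
from .trace_analysis import ForceExtensionTrace

TRACE_COLUMNS = ["base_position_nm", "extension_nm", "force_pN", "n_folded"]


def write_trace_tsv(path, extension, force, metadata=None, base_position=None, n_folded=None) -> None:
    path = Path(path)
    n = len(extension)
    df = pd.DataFrame(
        {
            "base_position_nm": base_position if base_position is not None else np.full(n, np.nan),
            "extension_nm": extension,
            "force_pN": force,
            "n_folded": n_folded if n_folded is not None else np.full(n, -1),
        }
    )
    with open(path, "w") as fh:
        for key, val in (metadata or {}).items():
            fh.write(f"# {key}: {val}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def read_trace_tsv(path) -> ForceExtensionTrace:
    path = Path(path)
    meta = {}
    with open(path) as fh:
        pos = 0
        for line in fh:
            if not line.startswith("#"):
                break
            pos += len(line)
            key, _, val = line[1:].strip().partition(":")
            meta[key.strip()] = val.strip()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t")
    missing = set(TRACE_COLUMNS[:3]) - set(df.columns)
    if missing:
        raise ValueError(f"trace file {path} missing columns: {sorted(missing)}")
    meta.setdefault("source_id", path.stem)
    return ForceExtensionTrace(
        extension=df["extension_nm"].to_numpy(),
        force=df["force_pN"].to_numpy(),
        metadata=meta,
    )


def write_events_csv(path, rows) -> None:
    """rows: iterable of dicts with trace_id, peak_index, force_pN, extension_nm, Lc_nm."""
    pd.DataFrame(rows, columns=["trace_id", "peak_index", "force_pN", "extension_nm", "Lc_nm"]).to_csv(
        path, index=False
    )


def write_speed_csv(path, data: list[SpeedForceDatum]) -> None:
    pd.DataFrame(
        {
            "speed_nm_s": [d.speed for d in data],
            "mean_force_pN": [d.mean_force for d in data],
            "sd_pN": [d.sd_force for d in data],
            "n": [d.n_events for d in data],
        }
    ).to_csv(path, index=False)


def read_speed_csv(path, cantilever_k: float = 40.0) -> list[SpeedForceDatum]:
    df = pd.read_csv(path)
    required = {"speed_nm_s", "mean_force_pN"}
    if not required <= set(df.columns):
        raise ValueError(f"speed CSV {path} must have columns {sorted(required)}")
    out = []
    for _, row in df.iterrows():
        out.append(
            SpeedForceDatum(
                speed=float(row["speed_nm_s"]),
                loading_rate=float(row["speed_nm_s"]) * cantilever_k,
                mean_force=float(row["mean_force_pN"]),
                sd_force=float(row.get("sd_pN", 0.0)),
                n_events=int(row.get("n", 1)),
            )
        )
    return out


def write_thermogram_csv(path, thermogram: ITCThermogram, injection_volumes=None) -> None:
    n = len(thermogram.heats_ucal)
    vols = (
        np.asarray(injection_volumes, dtype=float) * 1e6
        if injection_volumes is not None
        else np.full(n, np.nan)
    )
    pd.DataFrame(
        {
            "injection_index": np.arange(1, n + 1),
            "volume_uL": vols,
            "heat_ucal": thermogram.heats_ucal,
            "molar_ratio": thermogram.molar_ratio,
        }
    ).to_csv(path, index=False)


def read_thermogram_csv(path) -> tuple[ITCThermogram, np.ndarray | None]:
    df = pd.read_csv(path)
    if "heat_ucal" not in df.columns:
        raise ValueError(f"thermogram CSV {path} must have a heat_ucal column")
    ratio = (
        df["molar_ratio"].to_numpy()
        if "molar_ratio" in df.columns
        else np.arange(1, len(df) + 1, dtype=float)
    )
    vols = df["volume_uL"].to_numpy() * 1e-6 if "volume_uL" in df.columns else None
    if vols is not None and np.any(np.isnan(vols)):
        vols = None
    return ITCThermogram(heats_ucal=df["heat_ucal"].to_numpy(), molar_ratio=ratio), vols
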