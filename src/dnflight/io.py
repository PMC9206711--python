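"""File formats: morphometrics YAML, tidy CSVs, TIFF movies, JSON reports.

All tabular data are plain CSV; movies are multi-page TIFF (one file per
channel); configs are flat YAML.  Writers and readers round-trip losslessly
except for the stated float32 quantisation of TIFF intensities.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import tifffile
import yaml

from .aero_power import Isoline, Morphometrics
from .imaging import BehaviorTrace, StimulusProtocol, TwoChannelMovie
from .opto_response import LineSummary, TrialTrace

__all__ = [
    "read_morphometrics", "write_morphometrics",
    "write_isoline_csv", "read_isoline_csv",
    "write_trace_csv", "read_trace_csv",
    "write_pulses_csv", "read_pulses_csv",
    "write_catalogue_csv", "read_catalogue_csv",
    "write_line_summaries", "read_line_summaries",
    "write_movie_tiff", "read_movie_tiff",
    "write_protocol_csv", "read_protocol_csv",
    "write_behavior_csv", "read_behavior_csv",
    "write_json_report", "read_json_report",
]


def _require_columns(df: pd.DataFrame, columns: list[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{what}: missing column(s) {missing}")


# --- morphometrics ---------------------------------------------------------

def write_morphometrics(morph: Morphometrics, path: str | Path) -> None:
    data = dataclasses.asdict(morph)
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def read_morphometrics(path: str | Path) -> Morphometrics:
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a flat key-value mapping")
    return Morphometrics(**data)


def morphometrics_hash(morph: Morphometrics) -> str:
    payload = json.dumps(dataclasses.asdict(morph), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


# --- isolines --------------------------------------------------------------

def write_isoline_csv(isoline: Isoline, morph: Morphometrics, path: str | Path) -> None:
    """Two-column CSV (n_hz, phi_deg); header comments record level + params."""
    lines = [f"# P_level_w_per_kg={isoline.P_level!r}",
             f"# morphometrics_sha={morphometrics_hash(morph)}",
             "n_hz,phi_deg"]
    for n, phi_deg in zip(isoline.n, isoline.phi_deg):
        lines.append(f"{float(n)!r},{float(phi_deg)!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_isoline_csv(path: str | Path) -> Isoline:
    text = Path(path).read_text().splitlines()
    level = None
    for line in text:
        if line.startswith("# P_level_w_per_kg="):
            level = float(line.split("=", 1)[1])
    if level is None:
        raise ValueError(f"{path}: missing P_level header comment")
    df = pd.read_csv(path, comment="#")
    _require_columns(df, ["n_hz", "phi_deg"], str(path))
    return Isoline(P_level=level, n=df["n_hz"].to_numpy(),
                   phi=np.deg2rad(df["phi_deg"].to_numpy()))


# --- optogenetic session tables -------------------------------------------

def write_trace_csv(trace: TrialTrace, path: str | Path) -> None:
    pd.DataFrame({
        "fly_id": trace.fly_id, "line_id": trace.line_id, "t": trace.t,
        "wba_left": trace.wba_left, "wba_right": trace.wba_right,
        "freq": trace.freq,
    }).to_csv(path, index=False)


def read_trace_csv(path: str | Path, pulses: np.ndarray, fs: float) -> TrialTrace:
    df = pd.read_csv(path)
    _require_columns(df, ["fly_id", "line_id", "t", "wba_left", "wba_right", "freq"],
                     str(path))
    return TrialTrace(
        t=df["t"].to_numpy(), wba_left=df["wba_left"].to_numpy(),
        wba_right=df["wba_right"].to_numpy(), freq=df["freq"].to_numpy(),
        pulse_onsets=np.asarray(pulses, dtype=float), fs=fs,
        fly_id=str(df["fly_id"].iloc[0]), line_id=str(df["line_id"].iloc[0]))


def write_pulses_csv(onsets_by_fly: dict[str, np.ndarray], path: str | Path) -> None:
    rows = [{"fly_id": fly, "onset_s": float(o)}
            for fly, onsets in onsets_by_fly.items() for o in onsets]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_pulses_csv(path: str | Path) -> dict[str, np.ndarray]:
    df = pd.read_csv(path)
    _require_columns(df, ["fly_id", "onset_s"], str(path))
    return {str(fly): g["onset_s"].to_numpy()
            for fly, g in df.groupby("fly_id", sort=False)}


def write_catalogue_csv(n_pairs_by_line: dict[str, int], path: str | Path) -> None:
    pd.DataFrame({"line_id": list(n_pairs_by_line),
                  "n_pairs": list(n_pairs_by_line.values())}).to_csv(path, index=False)


def read_catalogue_csv(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path)
    _require_columns(df, ["line_id", "n_pairs"], str(path))
    return dict(zip(df["line_id"].astype(str), df["n_pairs"].astype(int)))


def write_line_summaries(lines: list[LineSummary], path: str | Path) -> None:
    rows = []
    for l in lines:
        for v in l.per_fly_values:
            rows.append({"line_id": l.line_id, "n_pairs": l.n_pairs, "delta_wba": v})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_line_summaries(path: str | Path) -> list[LineSummary]:
    df = pd.read_csv(path)
    _require_columns(df, ["line_id", "n_pairs", "delta_wba"], str(path))
    out = []
    for line_id, g in df.groupby("line_id", sort=False):
        out.append(LineSummary(line_id=str(line_id),
                               n_pairs=int(g["n_pairs"].iloc[0]),
                               per_fly_values=g["delta_wba"].to_numpy()))
    return out


# --- imaging ---------------------------------------------------------------

def write_movie_tiff(movie: TwoChannelMovie, gcamp_path: str | Path,
                     tdtom_path: str | Path) -> None:
    """One float32 multi-page TIFF per channel (stated quantisation)."""
    tifffile.imwrite(gcamp_path, movie.gcamp.astype(np.float32))
    tifffile.imwrite(tdtom_path, movie.tdtom.astype(np.float32))


def read_movie_tiff(gcamp_path: str | Path, tdtom_path: str | Path,
                    frame_rate: float) -> TwoChannelMovie:
    gcamp = tifffile.imread(gcamp_path)
    tdtom = tifffile.imread(tdtom_path)
    return TwoChannelMovie(gcamp=np.asarray(gcamp, dtype=float),
                           tdtom=np.asarray(tdtom, dtype=float),
                           frame_rate=frame_rate)


def write_protocol_csv(protocol: StimulusProtocol, path: str | Path) -> None:
    protocol.epochs.to_csv(path, index=False)


def read_protocol_csv(path: str | Path) -> StimulusProtocol:
    df = pd.read_csv(path)
    _require_columns(df, ["pattern_id", "onset_s", "duration_s"], str(path))
    return StimulusProtocol(epochs=df)


def write_behavior_csv(behavior: BehaviorTrace, path: str | Path) -> None:
    pd.DataFrame({"t": behavior.t, "wba_left": behavior.wba_left,
                  "wba_right": behavior.wba_right}).to_csv(path, index=False)


def read_behavior_csv(path: str | Path, fs: float = 32.0,
                      lag_corrected: bool = False) -> BehaviorTrace:
    df = pd.read_csv(path)
    _require_columns(df, ["t", "wba_left", "wba_right"], str(path))
    return BehaviorTrace(t=df["t"].to_numpy(), wba_left=df["wba_left"].to_numpy(),
                         wba_right=df["wba_right"].to_numpy(), fs=fs,
                         lag_corrected=lag_corrected)


# --- reports ---------------------------------------------------------------

def _jsonable(obj: Any) -> Any:
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_json_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_jsonable(report), indent=2, sort_keys=True) + "\n")


def read_json_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
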