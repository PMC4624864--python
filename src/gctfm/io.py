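"""File formats: per-frame CSV + JSON manifests, multi-page TIFF.

Vector-field series are written as one CSV per frame (columns x, y and the
two vector components) plus a JSON manifest carrying grid spacing, frame
interval, units, and any stage parameters.  Images go through tifffile.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile

from .comoving import AverageStressField
from .fields import DisplacementField, TractionMap
from .localize import Trajectory
from .peaks import PeakTrack
from .tension import AutocorrelationResult, MsdResult, TensionSeries


def write_manifest(path: Path, payload: dict) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(f"not JSON serializable: {type(o)}")

    path.write_text(json.dumps(payload, indent=2, default=default))


def read_manifest(path: Path) -> dict:
    return json.loads(Path(path).read_text())


def _frame_df(fld, cols: tuple[str, str]) -> pd.DataFrame:
    xx, yy = np.meshgrid(fld.x, fld.y)
    a = getattr(fld, cols[0])
    b = getattr(fld, cols[1])
    return pd.DataFrame(
        {
            "x": xx.ravel(),
            "y": yy.ravel(),
            cols[0]: a.ravel(),
            cols[1]: b.ravel(),
        }
    )


def write_field_series(
    directory: Path,
    fields: Sequence[TractionMap] | Sequence[DisplacementField],
    manifest_extra: Optional[dict] = None,
) -> None:
    """One CSV per frame plus manifest.json."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    is_traction = isinstance(fields[0], TractionMap)
    cols = ("tx", "ty") if is_traction else ("ux", "uy")
    for i, fld in enumerate(fields):
        _frame_df(fld, cols).to_csv(directory / f"frame_{i:04d}.csv", index=False)
    manifest = {
        "kind": "traction" if is_traction else "displacement",
        "units": {"x": "um", "y": "um", cols[0]: "Pa" if is_traction else "um"},
        "grid_spacing_um": fields[0].spacing,
        "n_frames": len(fields),
        "timestamps_s": [f.t for f in fields],
    }
    manifest.update(manifest_extra or {})
    write_manifest(directory / "manifest.json", manifest)


def read_field_series(directory: Path) -> list[TractionMap] | list[DisplacementField]:
    directory = Path(directory)
    manifest = read_manifest(directory / "manifest.json")
    is_traction = manifest["kind"] == "traction"
    cols = ("tx", "ty") if is_traction else ("ux", "uy")
    out = []
    for i, t in enumerate(manifest["timestamps_s"]):
        df = pd.read_csv(directory / f"frame_{i:04d}.csv")
        x = np.unique(df["x"].to_numpy())
        y = np.unique(df["y"].to_numpy())
        a = df[cols[0]].to_numpy().reshape(y.size, x.size)
        b = df[cols[1]].to_numpy().reshape(y.size, x.size)
        if is_traction:
            out.append(TractionMap(x=x, y=y, t=t, tx=a, ty=b))
        else:
            out.append(DisplacementField(x=x, y=y, t=t, ux=a, uy=b))
    return out


def write_tiff(path: Path, frames: np.ndarray) -> None:
    """Multi-page TIFF, 32-bit float, row index = y index (y up in analysis)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(frames, np.float32))


def read_tiff(path: Path) -> np.ndarray:
    return tifffile.imread(path).astype(float)


def write_trajectory(path: Path, traj: Trajectory) -> None:
    n = traj.n_frames
    step_valid = np.zeros(n, bool)
    step_valid[: n - 1] = traj.valid_step
    df = pd.DataFrame(
        {
            "frame": np.arange(n),
            "t": traj.t,
            "x_raw": traj.positions[:, 0],
            "y_raw": traj.positions[:, 1],
            "x_smooth": traj.smoothed[:, 0],
            "y_smooth": traj.smoothed[:, 1],
            "vx": np.append(traj.velocities[:, 0], np.nan),
            "vy": np.append(traj.velocities[:, 1], np.nan),
            "valid": step_valid,
        }
    )
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def write_average_field(directory: Path, avg: AverageStressField) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    xx, yy = np.meshgrid(avg.x, avg.y)
    pd.DataFrame(
        {
            "x": xx.ravel(),
            "y": yy.ravel(),
            "tx_mean": avg.tx_mean.ravel(),
            "ty_mean": avg.ty_mean.ravel(),
            "count": avg.count.ravel(),
        }
    ).to_csv(directory / "average_field.csv", index=False)
    write_manifest(
        directory / "average_field.json",
        {
            "net_force_nN": avg.net,
            "n_frames": avg.n_frames,
            "grid_spacing_um": avg.spacing,
            "sign_convention": "traction exerted by cell on substrate; "
            "axon tension is the negative of the net traction force",
        },
    )


def write_tracks(path: Path, tracks: Sequence[PeakTrack]) -> None:
    rows = []
    for tid, tr in enumerate(tracks):
        for d in tr.detections:
            rows.append(
                {
                    "track_id": tid,
                    "frame": d.frame,
                    "t": d.frame * tr.dt,
                    "x": d.position[0],
                    "y": d.position[1],
                    "peak_stress": d.stress,
                }
            )
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_lifetimes(path: Path, tracks: Sequence[PeakTrack]) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {"track_id": np.arange(len(tracks)), "lifetime_s": [t.lifetime for t in tracks]}
    ).to_csv(path, index=False)


def write_tension(path: Path, series: TensionSeries) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {"t": series.dt * np.arange(series.F.size), "F_nN": series.F}
    ).to_csv(path, index=False)


def write_autocorrelation(path: Path, result: AutocorrelationResult) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"lag_s": result.lags, "R": result.R}).to_csv(path, index=False)


def write_msd(path: Path, result: MsdResult) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    col = "msd_norm" if result.normalized else "msd"
    pd.DataFrame({"lag_s": result.lags, col: result.msd}).to_csv(path, index=False)
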