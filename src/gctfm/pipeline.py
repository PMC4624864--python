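"""End-to-end orchestration: configuration, staged execution, provenance.

A run goes simulate (or reconstruct from TIFF) → localize → co-moving
average → peak tracking → tension statistics, writing every stage artifact
under one output directory together with a manifest recording the resolved
configuration, software version, input checksums and per-stage frame usage.
All randomness flows from the single configured seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import __version__
from . import io as gio
from .comoving import average_frames, rotate_map_to_frame
from .fields import TractionMap
from .localize import estimate_noise, track_growth_cone
from .peaks import (
    FIT_WINDOW,
    detect_peaks,
    fit_exponential_lifetime,
    lifetime_histogram,
    link_peaks,
)
from .reconstruct import (
    GelSubstrate,
    compute_reference_image,
    compute_traction,
    correct_drift,
    measure_displacements,
    project_stack,
)
from .synthetic import SimulationConfig, simulate_traction_series
from .tension import (
    AUTOCORR_FIT_WINDOW,
    MAX_LAG_AUTOCORR,
    MAX_LAG_MSD,
    MSD_FIT_WINDOW,
    autocorrelation,
    fit_autocorr_decay,
    fit_msd_exponent,
    msd,
    tension_series,
)

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "report"]


@dataclass
class PipelineConfig:
    """Resolved configuration for one pipeline run.

    Defaults follow the published analysis settings: threshold multiplier 3,
    0.75 μm grid, lifetime fit window [30, 150] s, autocorrelation window
    [10, 80] s with lags to 480 s, MSD window [2, 200] s with lags to 900 s.
    """

    output_dir: str = "gctfm_run"
    images: Optional[str] = None          # TIFF input; None → simulate
    g_prime: Optional[float] = 100.0      # Pa (storage modulus)
    nu: float = 0.45
    E: Optional[float] = None             # overrides g_prime when given
    pixel_size: float = 0.25              # μm/px for TIFF input
    grid_spacing: float = 0.75            # μm
    dt: float = 2.0                       # s
    lam: float = 0.0                      # FTTC Tikhonov parameter
    threshold_multiplier: float = 3.0
    t_smooth: float = 360.0               # s
    comoving_half_width: float = 15.0     # μm
    link_distance: float = 2.0            # μm
    peak_min_separation: float = 2.0      # μm
    lifetime_bin_width: float = 10.0      # s
    lifetime_fit_window: tuple[float, float] = FIT_WINDOW
    autocorr_fit_window: tuple[float, float] = AUTOCORR_FIT_WINDOW
    msd_fit_window: tuple[float, float] = MSD_FIT_WINDOW
    max_lag_autocorr: float = MAX_LAG_AUTOCORR
    max_lag_msd: float = MAX_LAG_MSD
    seed: int = 0
    simulation: dict = field(default_factory=dict)  # SimulationConfig overrides

    def __post_init__(self) -> None:
        if self.threshold_multiplier != 3.0:
            raise ValueError("threshold multiplier is fixed at 3 by the method")
        self.gel()  # validate elastic parameters up front

    def gel(self) -> GelSubstrate:
        if self.E is not None:
            return GelSubstrate(E=self.E, nu=self.nu)
        return GelSubstrate.from_storage_modulus(self.g_prime, self.nu)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class RunManifest:
    """Provenance record of a run: rerunning with the same manifest
    reproduces deterministic stage outputs bit-identically."""

    config: dict
    version: str
    input_checksums: dict
    stages: dict

    def write(self, path: Path) -> None:
        gio.write_manifest(path, dataclasses.asdict(self))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _reconstruct_stage(cfg: PipelineConfig, out: Path) -> list[TractionMap]:
    frames = gio.read_tiff(cfg.images)
    if frames.ndim == 4:  # (t, z, h, w) stacks → projected 2D frames
        frames = np.stack([project_stack(f) for f in frames])
    corrected, shifts = correct_drift(frames)
    reference = compute_reference_image(corrected)
    gel = cfg.gel()
    maps = []
    for i, img in enumerate(corrected):
        disp = measure_displacements(
            img,
            reference,
            pixel_size=cfg.pixel_size,
            grid_spacing=cfg.grid_spacing,
            t=i * cfg.dt,
        )
        maps.append(compute_traction(disp, gel, lam=cfg.lam))
    np.savetxt(out / "drift_shifts.csv", shifts, delimiter=",", header="dy,dx")
    return maps


def run_pipeline(cfg: PipelineConfig) -> RunManifest:
    """Execute all stages and write every artifact under ``cfg.output_dir``."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: dict = {}
    checksums: dict = {}

    # --- traction maps: simulate or reconstruct ---
    if cfg.images is None:
        sim_kwargs = dict(cfg.simulation)
        sim_kwargs.setdefault("seed", cfg.seed)
        sim_kwargs.setdefault("dt", cfg.dt)
        sim_kwargs.setdefault("spacing", cfg.grid_spacing)
        sim = SimulationConfig(**sim_kwargs)
        maps, truth = simulate_traction_series(sim)
        gio.write_manifest(
            out / "ground_truth.json",
            {
                "centroid_um": truth.centroid,
                "velocity_um_s": truth.velocity,
                "net_force_nN": truth.net_force,
                "n_foci": len(truth.foci),
            },
        )
        stages["simulate"] = {"n_frames": len(maps), "config": dataclasses.asdict(sim)}
    else:
        checksums[str(cfg.images)] = _sha256(cfg.images)
        maps = _reconstruct_stage(cfg, out)
        stages["reconstruct"] = {"n_frames": len(maps)}
    gio.write_field_series(out / "traction", maps, {"dt_s": cfg.dt})

    # --- localization ---
    traj = track_growth_cone(maps, cfg.dt, t_smooth=cfg.t_smooth)
    gio.write_trajectory(out / "trajectory.csv", traj)
    stages["localize"] = {
        "n_frames": traj.n_frames,
        "n_valid_steps": int(traj.valid_step.sum()),
    }

    # --- co-moving average ---
    rotated, used = [], []
    for n in range(len(maps) - 1):
        if not traj.valid_step[n]:
            continue
        c = traj.positions[n]
        v = traj.velocities[n]
        if not (np.all(np.isfinite(c)) and np.all(np.isfinite(v))):
            continue
        if not np.linalg.norm(v) > 0:
            continue
        rotated.append(
            rotate_map_to_frame(maps[n], c, v, half_width=cfg.comoving_half_width)
        )
        used.append(n)
    avg = average_frames(rotated)
    gio.write_average_field(out, avg)
    stages["average"] = {"frames_used": used, "net_force_nN": avg.net.tolist()}

    # --- peak tracking and lifetimes ---
    dets = [
        detect_peaks(tm, estimate_noise(tm), d_min=cfg.peak_min_separation, frame=i)
        for i, tm in enumerate(maps)
    ]
    tracks = link_peaks(dets, max_link_distance=cfg.link_distance, dt=cfg.dt)
    gio.write_tracks(out / "tracks.csv", tracks)
    gio.write_lifetimes(out / "lifetimes.csv", tracks)
    fits: dict = {}
    if tracks:
        hist = lifetime_histogram(tracks, bin_width=cfg.lifetime_bin_width)
        try:
            fit = fit_exponential_lifetime(hist, window=cfg.lifetime_fit_window)
            fits["lifetime"] = {
                "tau_s": fit.tau,
                "stderr_s": fit.stderr,
                "window_s": list(fit.window),
                "bin_width_s": cfg.lifetime_bin_width,
                "n_tracks": len(tracks),
                "valid": fit.valid,
            }
        except ValueError as e:
            fits["lifetime"] = {"error": str(e)}
    stages["peaks"] = {"n_tracks": len(tracks)}

    # --- tension statistics ---
    ts = tension_series(maps, dt=cfg.dt)
    gio.write_tension(out / "tension.csv", ts)
    ac = autocorrelation(ts, max_lag=cfg.max_lag_autocorr)
    gio.write_autocorrelation(out / "autocorrelation.csv", ac)
    try:
        fits["autocorr_decay_s"] = fit_autocorr_decay(ac, window=cfg.autocorr_fit_window)
    except ValueError as e:
        fits["autocorr_decay_s"] = None
        fits["autocorr_error"] = str(e)
    ms = msd(ts, max_lag=cfg.max_lag_msd)
    gio.write_msd(out / "msd.csv", ms)
    try:
        fits["msd_exponent"] = fit_msd_exponent(ms, window=cfg.msd_fit_window)
    except ValueError as e:
        fits["msd_exponent"] = None
        fits["msd_error"] = str(e)
    gio.write_manifest(out / "fits.json", fits)
    stages["tension"] = {
        "mean_nN": ts.mean,
        "std_nN": ts.std,
        "n_frames": ts.F.size,
    }

    manifest = RunManifest(
        config=cfg.to_dict(),
        version=__version__,
        input_checksums=checksums,
        stages=stages,
    )
    manifest.write(out / "manifest.json")
    return manifest


def report(output_dir: str | Path, filename: str = "report.png") -> Path:
    """Render a multi-panel summary (trajectory, average field, lifetime
    histogram with log-linear inset, tension trace, autocorrelation, MSD)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import pandas as pd

    out = Path(output_dir)
    fig, axes = plt.subplots(2, 3, figsize=(15, 9))

    ax = axes[0, 0]
    try:
        traj = pd.read_csv(out / "trajectory.csv")
        ax.plot(traj["x_raw"], traj["y_raw"], "o", ms=3, alpha=0.4, label="raw")
        ax.plot(traj["x_smooth"], traj["y_smooth"], "-", label="smoothed")
        ax.set_xlabel("x (μm)")
        ax.set_ylabel("y (μm)")
        ax.legend()
        ax.set_title("Growth-cone trajectory")
    except FileNotFoundError:
        ax.set_title("trajectory: missing")

    ax = axes[0, 1]
    try:
        af = pd.read_csv(out / "average_field.csv")
        x = np.unique(af["x"])
        y = np.unique(af["y"])
        mag = np.hypot(af["tx_mean"], af["ty_mean"]).to_numpy().reshape(y.size, x.size)
        ax.imshow(
            mag, origin="lower", extent=(x[0], x[-1], y[0], y[-1]), cmap="inferno"
        )
        step = max(1, x.size // 16)
        xx, yy = np.meshgrid(x, y)
        ax.quiver(
            xx[::step, ::step],
            yy[::step, ::step],
            af["tx_mean"].to_numpy().reshape(y.size, x.size)[::step, ::step],
            af["ty_mean"].to_numpy().reshape(y.size, x.size)[::step, ::step],
            color="w",
            scale_units="xy",
        )
        ax.set_title("Average stress field (cone frame)")
    except FileNotFoundError:
        ax.set_title("average field: missing")

    ax = axes[0, 2]
    try:
        lt = pd.read_csv(out / "lifetimes.csv")["lifetime_s"]
        shown = lt[(lt >= 15) & (lt <= 600)]
        if len(shown):
            ax.hist(shown, bins=np.arange(15, 615, 15), color="steelblue")
            ax.set_title("Stress-peak lifetimes")
        else:
            ax.set_title("no tracks in display range")
        ax.set_xlabel("lifetime (s)")
    except FileNotFoundError:
        ax.set_title("lifetimes: missing")

    ax = axes[1, 0]
    try:
        tn = pd.read_csv(out / "tension.csv")
        ax.plot(tn["t"], tn["F_nN"])
        ax.set_xlabel("t (s)")
        ax.set_ylabel("|F| (nN)")
        ax.set_title("Net tension vs time")
    except FileNotFoundError:
        ax.set_title("tension: missing")

    ax = axes[1, 1]
    try:
        acd = pd.read_csv(out / "autocorrelation.csv")
        ax.plot(acd["lag_s"], acd["R"])
        ax.axhline(0, color="k", lw=0.5)
        ax.set_xlabel("lag (s)")
        ax.set_ylabel("R")
        ax.set_title("Tension autocorrelation")
    except FileNotFoundError:
        ax.set_title("autocorrelation: missing")

    ax = axes[1, 2]
    try:
        msdd = pd.read_csv(out / "msd.csv")
        col = "msd_norm" if "msd_norm" in msdd else "msd"
        sel = msdd["lag_s"] > 0
        ax.loglog(msdd["lag_s"][sel], msdd[col][sel])
        ax.set_xlabel("lag (s)")
        ax.set_ylabel("normalized MSD")
        ax.set_title("Tension MSD")
    except FileNotFoundError:
        ax.set_title("msd: missing")

    fig.tight_layout()
    path = out / filename
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return path
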